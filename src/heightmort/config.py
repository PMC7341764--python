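"""Shared configuration objects and error types."""

from __future__ import annotations

from dataclasses import dataclass


class ConfigError(ValueError):
    """A configuration file or object failed validation."""


class ConvergenceError(RuntimeError):
    """An MCMC run failed its convergence check (Gelman-Rubin > threshold)."""


@dataclass(frozen=True)
class MCMCConfig:
    """Settings for a Markov chain Monte Carlo run.

    Defaults match the study protocol: three unthinned chains of 20,000
    iterations each, the first 5,000 discarded as burn-in, leaving
    3 x 15,000 = 45,000 kept draws.
    """

    n_chains: int = 3
    iterations: int = 20_000
    burn_in: int = 5_000
    thinning: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_chains < 1:
            raise ConfigError("n_chains must be >= 1")
        if self.thinning < 1:
            raise ConfigError("thinning must be >= 1")
        if not 0 <= self.burn_in < self.iterations:
            raise ConfigError(
                f"burn_in ({self.burn_in}) must be in [0, iterations={self.iterations})"
            )

    @property
    def kept_per_chain(self) -> int:
        return (self.iterations - self.burn_in) // self.thinning
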