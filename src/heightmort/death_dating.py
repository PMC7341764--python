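"""Dating tree death from snag condition.

Standing dead trees ("snags") are assigned an ordinal retention class in
the field from their foliage and fine-twig condition. For a calibration
set of snags with exactly known death years, this module fits a gamma
distribution of time-since-death for every (calibration group x retention
class) cell, then converts each surveyed snag's retention class into the
probability ``q`` that it died within the drought window rather than
earlier.

Conventions
-----------
* A death in calendar year ``y`` observed at ``survey_year`` is treated as
  time-since-death ``survey_year - y + 0.5`` years (mid-year convention).
* For a window ``[first, last]`` surveyed in ``last``, a snag died within
  the window iff its time-since-death is below
  ``T* = survey_year - first + 1`` years, so
  ``q = GammaCDF(T*; shape, rate)``.
* Rare species without their own calibration sample borrow a similar
  taxon's distributions via a species -> calibration-group map: firs and
  other uncommon conifers borrow *Abies concolor*; *Pinus jeffreyi* uses
  the combined *P. ponderosa* + *P. lambertiana* sample; angiosperms use
  *Quercus kelloggii*.
* Cells with fewer than ``min_per_cell`` calibration trees (or degenerate
  all-identical times) borrow the calibration group's pooled fit across
  retention classes and are flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from .config import MCMCConfig
from .diagnostics import gelman_rubin

PONDEROSA_LAMBERTIANA = "Pinus ponderosa + Pinus lambertiana"

#: Species that borrow another taxon's calibration sample.
DEFAULT_BORROW_RULES: dict[str, str] = {
    "Abies magnifica": "Abies concolor",
    "Torreya californica": "Abies concolor",
    "Pinus jeffreyi": PONDEROSA_LAMBERTIANA,
    "Pinus ponderosa": PONDEROSA_LAMBERTIANA,
    "Pinus lambertiana": PONDEROSA_LAMBERTIANA,
}


def default_calibration_map(species_to_group: Mapping[str, str],
                            angiosperm_group: str = "angiosperm") -> dict[str, str]:
    """Build a species -> calibration-group map from taxonomic groups.

    All angiosperms share the *Quercus kelloggii* calibration; the named
    borrow rules apply to the listed conifers; every other species is
    self-calibrated.
    """
    out = {}
    for sp, grp in species_to_group.items():
        if grp == angiosperm_group:
            out[sp] = "Quercus kelloggii"
        else:
            out[sp] = DEFAULT_BORROW_RULES.get(sp, sp)
    return out


def map_calibration_group(species: str, cmap: Mapping[str, str]) -> str:
    """Calibration group for one species; errors naming an unmapped species."""
    try:
        return cmap[species]
    except KeyError:
        raise KeyError(f"species {species!r} has no calibration-group mapping") from None


def time_since_death(death_year, survey_year) -> np.ndarray:
    """Mid-year elapsed time: ``survey_year - death_year + 0.5`` years."""
    t = np.asarray(survey_year, float) - np.asarray(death_year, float) + 0.5
    if np.any(t <= 0):
        raise ValueError("death_year must not exceed survey_year")
    return t


# ---------------------------------------------------------------------------
# Gamma fitting
# ---------------------------------------------------------------------------

def fit_gamma_mle(times: np.ndarray) -> tuple[float, float]:
    """Maximum-likelihood (shape, rate) of a gamma sample (location fixed at 0)."""
    times = np.asarray(times, float)
    if len(times) < 2 or np.ptp(times) == 0:
        raise ValueError("degenerate sample: gamma MLE needs >= 2 distinct times")
    shape, _, scale = stats.gamma.fit(times, floc=0)
    return float(shape), float(1.0 / scale)


def _gamma_log_posterior(la: float, lr: float, n: int, sum_log_t: float,
                         sum_t: float, prior_sd: float = 10.0) -> float:
    """Log posterior of (log shape, log rate) under wide log-normal priors.

    Uses the gamma sufficient statistics (n, sum log t, sum t).
    """
    a, r = np.exp(la), np.exp(lr)
    ll = n * (a * lr - gammaln(a)) + (a - 1.0) * sum_log_t - r * sum_t
    lp = -(la**2 + lr**2) / (2.0 * prior_sd**2)
    return ll + lp


def fit_gamma_bayes(times: np.ndarray, mcmc: MCMCConfig,
                    prior_sd: float = 10.0) -> dict:
    """Random-walk Metropolis posterior for gamma (shape, rate).

    Samples on the (log shape, log mean) scale, where the posterior is
    close to orthogonal even for narrow time distributions whose shape
    and rate are strongly correlated. Chains are independently seeded from
    ``mcmc.seed``; each coordinate's proposal scale adapts toward ~40%
    acceptance during burn-in only. Returns posterior draw arrays,
    posterior means, and the R-hat of the shape chains.
    """
    times = np.asarray(times, float)
    try:
        a0, r0 = fit_gamma_mle(times)
    except ValueError:
        a0, r0 = 1.0, 1.0 / max(times.mean(), 0.1)
    x0 = np.array([np.log(a0), np.log(a0 / r0)])  # (log shape, log mean)
    stats_ = (len(times), float(np.log(times).sum()), float(times.sum()))

    def logpost(x):
        la, lr = x[0], x[0] - x[1]
        return _gamma_log_posterior(la, lr, *stats_, prior_sd)

    seeds = np.random.SeedSequence(mcmc.seed).spawn(mcmc.n_chains)
    kept = mcmc.kept_per_chain
    shape_draws = np.empty((mcmc.n_chains, kept))
    rate_draws = np.empty((mcmc.n_chains, kept))
    for c, ss in enumerate(seeds):
        rng = np.random.default_rng(ss)
        x = x0 + 0.05 * rng.standard_normal(2)
        lp = logpost(x)
        step = np.array([0.2, 0.2])
        acc = np.zeros(2)
        k = 0
        for it in range(mcmc.iterations):
            for coord in (0, 1):  # one-coordinate-at-a-time updates
                prop = x.copy()
                prop[coord] += step[coord] * rng.standard_normal()
                lp_prop = logpost(prop)
                if np.log(rng.uniform()) < lp_prop - lp:
                    x, lp = prop, lp_prop
                    acc[coord] += 1
            if it < mcmc.burn_in and (it + 1) % 50 == 0:
                step *= np.exp(0.5 * (acc / 50.0 - 0.4))
                acc[:] = 0
            if it >= mcmc.burn_in and (it - mcmc.burn_in) % mcmc.thinning == 0 and k < kept:
                shape_draws[c, k] = np.exp(x[0])
                rate_draws[c, k] = np.exp(x[0] - x[1])
                k += 1
    return {
        "shape_draws": shape_draws,
        "rate_draws": rate_draws,
        "shape": float(shape_draws.mean()),
        "rate": float(rate_draws.mean()),
        "rhat_shape": gelman_rubin(shape_draws) if mcmc.n_chains > 1 else np.nan,
    }


@dataclass
class GammaDeathModel:
    """Fitted time-since-death distributions per (calibration group, retention class).

    ``table`` columns: calibration_group, retention_class, shape, rate, n,
    method, pooled_fallback, rhat_shape. ``draws`` holds per-cell posterior
    sample arrays when fitted by MCMC.
    """

    table: pd.DataFrame
    method: str
    draws: dict = field(default_factory=dict)

    def params_for(self, group: str, retention_class) -> tuple[float, float]:
        sub = self.table[(self.table.calibration_group == group)
                         & (self.table.retention_class == retention_class)]
        if sub.empty:
            raise KeyError(f"no fitted cell for ({group!r}, retention {retention_class!r})")
        row = sub.iloc[0]
        return float(row["shape"]), float(row["rate"])

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "GammaDeathModel":
        table = pd.read_csv(path)
        method = table["method"].iloc[0] if len(table) else "mle"
        return cls(table=table, method=method)


def fit_gamma_death_model(
    calibration: pd.DataFrame,
    cmap: Mapping[str, str],
    method: str = "mle",
    mcmc: MCMCConfig | None = None,
    min_per_cell: int = 3,
) -> GammaDeathModel:
    """Fit gamma time-since-death models from known-death-year snags.

    ``calibration`` columns: species, retention_class, death_year,
    survey_year. Cells with < ``min_per_cell`` trees, or with degenerate
    all-identical times, borrow the group's pooled fit (flagged
    ``pooled_fallback``).
    """
    if method not in ("mle", "bayes"):
        raise ValueError("method must be 'mle' or 'bayes'")
    if method == "bayes" and mcmc is None:
        mcmc = MCMCConfig(iterations=4000, burn_in=1000)
    calib = calibration.copy()
    calib["calibration_group"] = [map_calibration_group(s, cmap) for s in calib["species"]]
    calib["t"] = time_since_death(calib["death_year"], calib["survey_year"])

    def _fit(times: np.ndarray, seed_offset: int):
        if method == "mle":
            shape, rate = fit_gamma_mle(times)
            return shape, rate, np.nan, None
        res = fit_gamma_bayes(times, MCMCConfig(
            n_chains=mcmc.n_chains, iterations=mcmc.iterations,
            burn_in=mcmc.burn_in, thinning=mcmc.thinning,
            seed=mcmc.seed + seed_offset))
        return res["shape"], res["rate"], res["rhat_shape"], res

    rows = []
    draws = {}
    pooled_cache = {}
    offset = 0
    for (grp, rcls), sub in calib.groupby(["calibration_group", "retention_class"], sort=True):
        times = sub["t"].to_numpy()
        offset += 1
        pooled = False
        try:
            if len(times) < min_per_cell:
                raise ValueError("too few calibration trees")
            shape, rate, rhat, res = _fit(times, offset)
        except ValueError:
            pooled = True
            if grp not in pooled_cache:
                all_t = calib.loc[calib.calibration_group == grp, "t"].to_numpy()
                pooled_cache[grp] = _fit(all_t, 10_000 + offset)
            shape, rate, rhat, res = pooled_cache[grp]
        rows.append({"calibration_group": grp, "retention_class": rcls,
                     "shape": shape, "rate": rate, "n": len(times),
                     "method": method, "pooled_fallback": pooled, "rhat_shape": rhat})
        if res is not None:
            draws[(grp, rcls)] = (res["shape_draws"], res["rate_draws"])
    return GammaDeathModel(table=pd.DataFrame(rows), method=method, draws=draws)


# ---------------------------------------------------------------------------
# Death-window probabilities
# ---------------------------------------------------------------------------

def window_threshold(survey_year: int, window=(2014, 2016)) -> float:
    """Elapsed-time cut T* separating in-window from pre-window deaths."""
    t_star = survey_year - window[0] + 1
    if t_star <= 0:
        raise ValueError("drought window must start at or before the survey year")
    return float(t_star)


def cell_q(model: GammaDeathModel, group: str, retention_class,
           t_star: float) -> float:
    """P(time-since-death <= T*) for one (group, retention class) cell.

    For Bayesian fits this averages the gamma CDF over the posterior draws
    (full uncertainty propagation); for MLE it evaluates at the point fit.
    """
    key = (group, retention_class)
    if model.method == "bayes" and key in model.draws:
        a, r = model.draws[key]
        return float(stats.gamma.cdf(t_star, a.ravel(), scale=1.0 / r.ravel()).mean())
    shape, rate = model.params_for(group, retention_class)
    return float(stats.gamma.cdf(t_star, shape, scale=1.0 / rate))


def cell_q_draws(model: GammaDeathModel, group: str, retention_class,
                 t_star: float) -> np.ndarray:
    """Per-posterior-draw q values for one cell (Bayesian fits only)."""
    key = (group, retention_class)
    if key not in model.draws:
        raise KeyError(f"no posterior draws for cell {key}")
    a, r = model.draws[key]
    return stats.gamma.cdf(t_star, a.ravel(), scale=1.0 / r.ravel())


def prob_death_in_window(
    model: GammaDeathModel,
    dead_trees: pd.DataFrame,
    cmap: Mapping[str, str],
    survey_year: int,
    window=(2014, 2016),
) -> pd.Series:
    """Probability ``q`` that each surveyed snag died within the window.

    ``dead_trees`` must contain only dead trees (columns species,
    retention_class; a status column, if present, is checked). Returns q
    indexed like ``dead_trees``.
    """
    if "status" in dead_trees.columns and (dead_trees["status"] != "dead").any():
        raise ValueError("prob_death_in_window applies to dead trees only")
    t_star = window_threshold(survey_year, window)
    groups = pd.Series([map_calibration_group(s, cmap) for s in dead_trees["species"]],
                       index=dead_trees.index)
    q = pd.Series(np.nan, index=dead_trees.index, name="q")
    for (grp, rcls), sub in dead_trees.groupby([groups, dead_trees["retention_class"]],
                                               sort=False):
        q.loc[sub.index] = cell_q(model, grp, rcls, t_star)
    return q
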