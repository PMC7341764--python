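"""Pipeline orchestration: simulate -> date deaths -> fit mortality -> decompose.

The full analysis chain mirrors the field study: an inventory of living
and standing-dead trees in 5-cm DBH classes is binned into height classes
by species-specific allometry; snag retention classes plus a known-death-
year calibration set yield each snag's probability of in-window death;
per-(group x height class) mortality is estimated by MCMC; and the pooled
height-mortality trend is decomposed into compositional and group-level
components via direct standardization.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import allometry as allo
from . import decomposition as dec
from . import synthetic
from .config import ConfigError, ConvergenceError, MCMCConfig
from .death_dating import (GammaDeathModel, default_calibration_map,
                           fit_gamma_death_model, prob_death_in_window)
from .mortality import PosteriorSamples, fit_mortality, summarize

log = logging.getLogger("heightmort")

RHAT_LIMIT = 1.1


@dataclass(frozen=True)
class PipelineConfig:
    """Everything one run needs; the global seed feeds every stochastic stage."""

    sim: synthetic.SimConfig = field(default_factory=synthetic.SimConfig)
    mcmc: MCMCConfig = field(default_factory=MCMCConfig)
    #: z-update scheme for the mortality sampler. The imputation scheme is
    #: the estimation default because q comes from an external calibration;
    #: see the mortality module docstring and the methods note.
    z_update: str = "imputation"
    #: prior on each cell's logit-mortality: diffuse normal (sd 10), which
    #: leaves a zero-death cell's posterior mass at ~0 mortality.
    prior: str = "normal"
    gamma_method: str = "bayes"
    gamma_mcmc: MCMCConfig = field(default_factory=lambda: MCMCConfig(
        iterations=4000, burn_in=1000))
    n_calibration: int = 2297
    seed: int = 0
    outdir: str = "out"
    inventory: str | None = None
    calibration: str | None = None
    allometry_file: str | None = None

    def reseeded(self, seed: int) -> "PipelineConfig":
        """Propagate one global seed to every stage (distinct sub-streams)."""
        return replace(self, seed=seed,
                       sim=replace(self.sim, seed=seed),
                       mcmc=replace(self.mcmc, seed=seed + 1),
                       gamma_mcmc=replace(self.gamma_mcmc, seed=seed + 2))


def load_config(path) -> PipelineConfig:
    """Read a YAML pipeline config; unknown or malformed fields raise ConfigError."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    known = {"sim", "mcmc", "z_update", "prior", "gamma_method", "gamma_mcmc",
             "n_calibration", "seed", "outdir", "inventory", "calibration",
             "allometry_file"}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"{path}: unknown config fields {sorted(unknown)}")
    kwargs = {}
    if "sim" in data:
        kwargs["sim"] = synthetic.config_from_dict(data["sim"])
    for key in ("mcmc", "gamma_mcmc"):
        if key in data:
            try:
                kwargs[key] = MCMCConfig(**data[key])
            except TypeError as exc:
                raise ConfigError(f"{path}: field {key!r}: {exc}") from exc
    for key in ("z_update", "prior", "gamma_method", "n_calibration", "seed",
                "outdir", "inventory", "calibration", "allometry_file"):
        if key in data:
            kwargs[key] = data[key]
    cfg = PipelineConfig(**kwargs)
    if cfg.gamma_method not in ("mle", "bayes"):
        raise ConfigError(f"{path}: gamma_method must be 'mle' or 'bayes'")
    if cfg.z_update not in ("conditional", "imputation"):
        raise ConfigError(f"{path}: z_update must be 'conditional' or 'imputation'")
    if cfg.prior not in ("uniform", "normal"):
        raise ConfigError(f"{path}: prior must be 'uniform' or 'normal'")
    return cfg.reseeded(int(cfg.seed))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _write_manifest(outdir: Path, stage: str, seed: int, files: list[Path]) -> dict:
    manifest = {"stage": stage, "seed": seed,
                "files": [{"name": f.name, "sha256": _sha256(f)} for f in files]}
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def run_simulate(cfg: PipelineConfig) -> dict:
    """Write inventory.csv, calibration.csv and truth.csv; return the manifest."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = time.perf_counter()
    inventory, truth = synthetic.generate_inventory(cfg.sim)
    calib = synthetic.generate_calibration(cfg.sim, cfg.n_calibration)
    inv_path = outdir / "inventory.csv"
    cal_path = outdir / "calibration.csv"
    truth_path = outdir / "truth.csv"
    inventory.to_csv(inv_path, index=False)
    calib.to_csv(cal_path, index=False)
    synthetic.write_truth_csv(truth, truth_path)
    manifest = _write_manifest(outdir, "simulate", cfg.seed,
                               [inv_path, cal_path, truth_path])
    log.info("simulate: seed=%d trees=%d calib=%d elapsed=%.1fs",
             cfg.seed, len(inventory), len(calib), time.perf_counter() - t0)
    return manifest


@dataclass
class FullRunResult:
    cell_summary: pd.DataFrame
    pooled: pd.DataFrame
    composition: pd.DataFrame
    standardized: pd.DataFrame
    diagnostics: pd.DataFrame
    samples: PosteriorSamples
    gamma_model: GammaDeathModel
    max_rhat: float
    files: list


def _load_or_simulate(cfg: PipelineConfig):
    if cfg.inventory is not None:
        inventory = pd.read_csv(cfg.inventory)
        required = {"tree_id", "species", "group", "dbh_class", "status",
                    "retention_class"}
        missing = required - set(inventory.columns)
        if missing:
            raise ConfigError(f"inventory {cfg.inventory}: missing columns {sorted(missing)}")
    else:
        inventory, _ = synthetic.generate_inventory(cfg.sim)
    if cfg.calibration is not None:
        calib = pd.read_csv(cfg.calibration)
        missing = {"species", "retention_class", "death_year", "survey_year"} - set(calib.columns)
        if missing:
            raise ConfigError(f"calibration {cfg.calibration}: missing columns {sorted(missing)}")
    else:
        calib = synthetic.generate_calibration(cfg.sim, cfg.n_calibration)
    return inventory, calib


def pooled_mortality_draws(samples: PosteriorSamples) -> pd.DataFrame:
    """Posterior of the pooled per-class mortality M via per-draw back-calculation.

    For every kept draw, back-calculates each cell's start-of-window
    population and deaths and pools them within height class; the
    resulting M draws give the all-trees-combined mean and credible band.
    """
    pooled = samples.pooled                         # (draws, cells)
    n2016 = samples.n2016[None, :]
    n2013 = n2016 / (1.0 - pooled)
    deaths = n2013 - n2016
    classes = sorted({hc for _, hc in samples.cells},
                     key=lambda h: (list(allo.HEIGHT_CLASSES) + [h]).index(h))
    rows = []
    for hc in classes:
        idx = [j for j, (_, h) in enumerate(samples.cells) if h == hc]
        m_draws = deaths[:, idx].sum(axis=1) / n2013[:, idx].sum(axis=1)
        lo, hi = np.percentile(m_draws, [2.5, 97.5])
        rows.append({"height_class": hc, "n2013": float(n2013[:, idx].sum(axis=1).mean()),
                     "d": float(deaths[:, idx].sum(axis=1).mean()),
                     "M": float(m_draws.mean()), "lo95": float(lo), "hi95": float(hi)})
    return pd.DataFrame(rows)


def run_full(cfg: PipelineConfig, smoke: bool = False) -> FullRunResult:
    """Run the whole chain and write the four analysis tables plus diagnostics.

    Outputs (CSV, in ``cfg.outdir``): cell_mortality (per-cell posterior,
    the group x height analogue), pooled_mortality (all trees combined),
    composition (2013 group proportions per class), standardized_mortality
    (constant-composition and constant-focal-group counterfactuals), and
    diagnostics (R-hat / ESS per monitored parameter).

    Raises :class:`ConvergenceError` after writing outputs if any R-hat
    exceeds 1.1.
    """
    cfg = replace(cfg, mcmc=replace(cfg.mcmc, iterations=2000, burn_in=500),
                  gamma_method="mle") if smoke else cfg
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = time.perf_counter()

    inventory, calib = _load_or_simulate(cfg)
    allometry = (allo.read_allometry_csv(cfg.allometry_file)
                 if cfg.allometry_file else dict(cfg.sim.allometry))
    thresholds = {sp: allo.compute_thresholds(p) for sp, p in allometry.items()}
    trees = inventory.drop(columns=["true_death_year"], errors="ignore").copy()
    trees["height_class"] = allo.assign_height_classes(trees, thresholds)
    n_below = int((trees.height_class == allo.BELOW_MIN).sum())
    trees = trees[trees.height_class != allo.BELOW_MIN].copy()
    log.info("allometry: %d trees >=5 m retained, %d below 5 m excluded",
             len(trees), n_below)

    cmap = default_calibration_map(cfg.sim.species_to_group(),
                                   angiosperm_group=cfg.sim.group_names[0])
    gamma_model = fit_gamma_death_model(
        calib, cmap, method=cfg.gamma_method, mcmc=cfg.gamma_mcmc)
    dead = trees[trees.status == "dead"]
    q = prob_death_in_window(gamma_model, dead, cmap, cfg.sim.survey_year,
                             cfg.sim.drought_window)
    trees["q"] = np.nan
    trees.loc[q.index, "q"] = q
    log.info("death dating: %d snags dated, method=%s", len(dead), cfg.gamma_method)

    samples = fit_mortality(trees, cfg.mcmc, prior=cfg.prior, z_update=cfg.z_update)
    cell_summary = summarize(samples)
    log.info("mortality MCMC: %d cells, %d chains x %d kept, elapsed=%.1fs",
             len(cell_summary), cfg.mcmc.n_chains, cfg.mcmc.kept_per_chain,
             time.perf_counter() - t0)

    counts = cell_summary.rename(columns={"n2013": "n"})[
        ["height_class", "group", "n", "d"]].copy()
    order = [hc for hc in allo.HEIGHT_CLASSES if hc in set(counts.height_class)]
    counts["height_class"] = pd.Categorical(counts.height_class, order, ordered=True)
    counts = counts.sort_values(["height_class", "group"]).reset_index(drop=True)
    counts["height_class"] = counts.height_class.astype(str)

    pooled = pooled_mortality_draws(samples)
    comp = dec.proportions(counts).reset_index().melt(
        id_vars="height_class", var_name="group", value_name="p")
    ref_p = dec.pooled_reference_proportions(counts)
    focal = cfg.sim.group_names[-1]
    standardized = pd.DataFrame({
        "height_class": order,
        "M_observed": dec.pooled_mortality(counts).to_numpy(),
        "M_constant_composition": dec.standardize_composition(counts, ref_p).to_numpy(),
        f"M_constant_{focal.replace(' ', '_')}_mortality":
            dec.standardize_group_mortality(counts, focal).to_numpy(),
    })

    diag_rows = [{"parameter": f"m[{g},{h}]", "rhat": r.rhat, "ess": r.ess,
                  "low_ess": r.low_ess}
                 for _, r in cell_summary.iterrows()
                 for g, h in [(r.group, r.height_class)]]
    for _, r in gamma_model.table.iterrows():
        if np.isfinite(r.get("rhat_shape", np.nan)):
            diag_rows.append({"parameter": f"gamma_shape[{r.calibration_group},"
                                           f"{r.retention_class}]",
                              "rhat": r.rhat_shape, "ess": np.nan, "low_ess": False})
    diagnostics = pd.DataFrame(diag_rows)
    max_rhat = float(diagnostics.rhat.max())
    if diagnostics.low_ess.any():
        log.warning("low effective draw count for: %s",
                    diagnostics.loc[diagnostics.low_ess, "parameter"].tolist())

    files = []
    for name, df in [("cell_mortality", cell_summary), ("pooled_mortality", pooled),
                     ("composition", comp), ("standardized_mortality", standardized),
                     ("diagnostics", diagnostics)]:
        path = outdir / f"{name}.csv"
        df.to_csv(path, index=False)
        files.append(path)
    gamma_model.to_csv(outdir / "gamma_model.csv")
    _write_manifest(outdir, "full", cfg.seed, files)
    log.info("full run: max R-hat=%.4f, elapsed=%.1fs", max_rhat,
             time.perf_counter() - t0)

    result = FullRunResult(cell_summary=cell_summary, pooled=pooled,
                           composition=comp, standardized=standardized,
                           diagnostics=diagnostics, samples=samples,
                           gamma_model=gamma_model, max_rhat=max_rhat, files=files)
    if max_rhat > RHAT_LIMIT:
        raise ConvergenceError(
            f"Gelman-Rubin diagnostic exceeded {RHAT_LIMIT}: max R-hat={max_rhat:.3f}")
    return result


def format_report(outdir) -> str:
    """Human-readable summary assembled from a finished run's CSV tables."""
    outdir = Path(outdir)
    lines = ["height-stratified mortality report", "=" * 36]
    pooled = pd.read_csv(outdir / "pooled_mortality.csv")
    lines.append("\nPooled 2014-2016 mortality by height class (posterior mean [95% CI]):")
    for _, r in pooled.iterrows():
        lines.append(f"  {r.height_class:>7}: M = {r.M:.3f} [{r.lo95:.3f}, {r.hi95:.3f}]")
    cells = pd.read_csv(outdir / "cell_mortality.csv")
    lines.append("\nPer-group mortality (posterior mean [95% CI], n2016):")
    for _, r in cells.iterrows():
        lines.append(f"  {r.group:>18} {r.height_class:>7}: "
                     f"{r['mean']:.3f} [{r.lo95:.3f}, {r.hi95:.3f}]  n2016={int(r.n2016)}")
    std = pd.read_csv(outdir / "standardized_mortality.csv")
    lines.append("\nCounterfactual standardizations:")
    lines.append(std.to_string(index=False, float_format=lambda x: f"{x:.3f}"))
    diag = pd.read_csv(outdir / "diagnostics.csv")
    lines.append(f"\nConvergence: max R-hat = {diag.rhat.max():.4f} "
                 f"({'OK' if diag.rhat.max() <= RHAT_LIMIT else 'FAILED'})")
    return "\n".join(lines) + "\n"
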