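"""Synthetic forest inventories, calibration sets, and scenario tables.

The generator emulates the statistical structure the downstream analysis
assumes: ~89 plots of a mixed old-growth forest surveyed in 2016 holding
roughly 5,900 trees at least 5 m tall in three taxonomic groups
(angiosperms, non-*Pinus* conifers, *Pinus*), whose relative abundances
shift from angiosperm-heavy short classes to conifer/pine-heavy tall
classes, with per-(group x height class) drought-window (2014-2016)
mortality probabilities. Standing dead trees carry ordinal foliage/twig
retention classes drawn from an ordered-logit model of time-since-death,
and a configurable fraction of snags pre-date the drought window.

Trees are generated height-class-first and given a DBH consistent with
that class by inverting the species' allometric curve; the analysis
pipeline then re-derives the class from DBH alone, so quantization to
5-cm classes is exercised end to end. A :class:`TruthTable` records every
latent quantity for parameter-recovery tests; inference never reads it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from . import allometry as allo
from .config import ConfigError

GROUPS_DEFAULT = ("angiosperm", "non-pinus conifer", "pinus")

SPECIES_PER_GROUP_DEFAULT = {
    "angiosperm": ("Quercus kelloggii", "Quercus chrysolepis"),
    "non-pinus conifer": ("Abies concolor", "Abies magnifica",
                          "Calocedrus decurrens", "Torreya californica"),
    "pinus": ("Pinus ponderosa", "Pinus lambertiana", "Pinus jeffreyi"),
}

#: Relative group abundances conditional on height class (short, mid, tall):
#: angiosperm-heavy short classes, pine-heavier tall classes.
COMPOSITION_DEFAULT = {
    allo.SHORT: (0.57, 0.35, 0.08),
    allo.MID: (0.28, 0.60, 0.12),
    allo.TALL: (0.06, 0.72, 0.22),
}

#: Drought-window mortality per group across (short, mid, tall): low and
#: declining in angiosperms, intermediate and declining in non-pine
#: conifers, high and steeply increasing in pines.
MORTALITY_DEFAULT = {
    "angiosperm": (0.08, 0.04, 0.01),
    "non-pinus conifer": (0.26, 0.21, 0.17),
    "pinus": (0.17, 0.35, 0.56),
}


@dataclass(frozen=True)
class RetentionModel:
    """Ordered-logit model linking time-since-death to retention class.

    Class 1 is the freshest snag (full fine-twig retention). A snag dead
    for ``t`` years gets class ``1 + #{cutpoints below t + noise}`` where
    the noise is logistic with the given scale; ``scale = 0`` collapses to
    a deterministic step function of time-since-death.
    """

    cutpoints: tuple = (1.0, 3.0, 6.0, 12.0)
    scale: float = 0.75

    def __post_init__(self) -> None:
        if any(b <= a for a, b in zip(self.cutpoints, self.cutpoints[1:])):
            raise ConfigError("retention cutpoints must be strictly increasing")
        if self.scale < 0:
            raise ConfigError("retention scale must be non-negative")

    @property
    def n_classes(self) -> int:
        return len(self.cutpoints) + 1

    def sample(self, times: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        t = np.asarray(times, float)
        if self.scale > 0:
            u = rng.uniform(size=t.shape)
            t = t + self.scale * np.log(u / (1.0 - u))
        return np.searchsorted(np.asarray(self.cutpoints), t, side="right") + 1


@dataclass(frozen=True)
class SimConfig:
    """Full parameterization of the synthetic forest survey."""

    n_plots: int = 89
    trees_per_plot_mean: float = 66.0
    group_names: tuple = GROUPS_DEFAULT
    species_per_group: Mapping[str, tuple] = field(
        default_factory=lambda: dict(SPECIES_PER_GROUP_DEFAULT))
    composition_by_height: Mapping[str, tuple] = field(
        default_factory=lambda: dict(COMPOSITION_DEFAULT))
    mortality_by_cell: Mapping[str, tuple] = field(
        default_factory=lambda: dict(MORTALITY_DEFAULT))
    height_class_probs: tuple = (0.50, 0.35, 0.15)
    below_min_fraction: float = 0.04
    dbh_distribution: Mapping[str, tuple] = field(default_factory=dict)
    retention_model: RetentionModel = field(default_factory=RetentionModel)
    allometry: Mapping[str, allo.AllometryParams] = field(
        default_factory=allo.default_allometry)
    survey_year: int = 2016
    drought_window: tuple = (2014, 2016)
    background_dead_fraction: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        k = len(self.group_names)
        for hc, probs in self.composition_by_height.items():
            if len(probs) != k:
                raise ConfigError(
                    f"composition for {hc!r} has {len(probs)} entries for {k} groups")
            if abs(sum(probs) - 1.0) > 1e-12:
                raise ConfigError(f"composition for {hc!r} sums to {sum(probs)}, not 1")
        if abs(sum(self.height_class_probs) - 1.0) > 1e-12:
            raise ConfigError("height_class_probs must sum to 1")
        for grp, ms in self.mortality_by_cell.items():
            if grp not in self.group_names:
                raise ConfigError(f"mortality given for unknown group {grp!r}")
            if any(not 0.0 <= m <= 1.0 for m in ms):
                raise ConfigError(f"mortality probabilities for {grp!r} not in [0, 1]")
        for grp in self.group_names:
            if grp not in self.species_per_group:
                raise ConfigError(f"no species list for group {grp!r}")
            if grp not in self.mortality_by_cell:
                raise ConfigError(f"no mortality entry for group {grp!r}")
        if not 0.0 <= self.background_dead_fraction < 1.0:
            raise ConfigError("background_dead_fraction must lie in [0, 1)")
        if not (self.drought_window[0] <= self.drought_window[1] <= self.survey_year):
            raise ConfigError("drought_window must end at or before survey_year")

    def species_to_group(self) -> dict[str, str]:
        return {sp: grp for grp, sps in self.species_per_group.items() for sp in sps}

    def dbh_lognormal(self, species: str) -> tuple:
        """(mu, sigma) of log DBH for a species; a generic right-skewed default."""
        return tuple(self.dbh_distribution.get(species, (3.3, 0.6)))


@dataclass
class TruthTable:
    """Latent ground truth of one simulated inventory (never read by inference)."""

    cells: pd.DataFrame  # group, height_class, true_m, n_2013, window_deaths
    trees: pd.DataFrame  # tree_id, true_death_year, true_height_class


# ---------------------------------------------------------------------------
# Inventory generation
# ---------------------------------------------------------------------------

def _class_dbh_intervals(params: allo.AllometryParams,
                         breaks=allo.HEIGHT_BREAKS) -> dict[str, tuple]:
    """Continuous DBH interval per attainable height class for one species."""
    cuts = [allo.invert_height(params, h) for h in breaks]
    out = {}
    labels = (allo.SHORT, allo.MID, allo.TALL)
    for k, lab in enumerate(labels):
        lo = cuts[k]
        if not np.isfinite(lo):
            continue
        if k + 1 < len(cuts):
            hi = cuts[k + 1]
            if not np.isfinite(hi):
                hi = _tall_upper(params, breaks[k])
        else:
            hi = _tall_upper(params, breaks[k])
        if np.isfinite(hi) and hi > lo:
            out[lab] = (lo, hi)
    out[allo.BELOW_MIN] = (0.5, max(cuts[0], 1.0))
    return out


def _tall_upper(params: allo.AllometryParams, brk: float) -> float:
    """Upper DBH bound for the open top class: 80% of the way to the asymptote."""
    hmax = params.max_height
    target = brk + 0.8 * (hmax - brk) if np.isfinite(hmax) else brk + 15.0
    return allo.invert_height(params, target)


def _truncated_lognormal(rng, mu, sigma, lo, hi, size):
    """Lognormal(mu, sigma) draws restricted to [lo, hi) via inverse CDF."""
    a = norm.cdf((np.log(lo) - mu) / sigma)
    b = norm.cdf((np.log(hi) - mu) / sigma)
    u = rng.uniform(a, b, size=size)
    return np.exp(mu + sigma * norm.ppf(u))


def generate_inventory(config: SimConfig) -> tuple[pd.DataFrame, TruthTable]:
    """Simulate one survey; identical config (incl. seed) gives identical output.

    Returns the inventory table (tree_id, plot_id, species, group,
    dbh_class, status, retention_class, true_death_year) and the
    :class:`TruthTable`. ``true_death_year`` is carried in the inventory
    for convenience but is latent truth; the analysis pipeline drops it.
    """
    rng = np.random.default_rng(config.seed)
    groups = list(config.group_names)
    classes = list(allo.HEIGHT_CLASSES)
    intervals = {sp: _class_dbh_intervals(config.allometry[sp])
                 for grp in groups for sp in config.species_per_group[grp]}
    eligible = {(grp, hc): [sp for sp in config.species_per_group[grp]
                            if hc in intervals[sp]]
                for grp in groups for hc in classes + [allo.BELOW_MIN]}
    for (grp, hc), sps in eligible.items():
        if hc in classes and config.composition_by_height[hc][groups.index(grp)] > 0 and not sps:
            raise ConfigError(f"no species of group {grp!r} can attain class {hc!r}")

    plot_sizes = rng.poisson(config.trees_per_plot_mean, size=config.n_plots)
    below_sizes = rng.poisson(config.trees_per_plot_mean * config.below_min_fraction,
                              size=config.n_plots)
    window = config.drought_window

    # --- main (>= 5 m) trees, vectorized ------------------------------------
    n_main = int(plot_sizes.sum())
    plot_id = np.repeat([f"P{p + 1:03d}" for p in range(config.n_plots)], plot_sizes)
    hc_idx = rng.choice(len(classes), size=n_main,
                        p=np.asarray(config.height_class_probs, float))
    grp_idx = np.empty(n_main, dtype=int)
    for k, hc in enumerate(classes):
        sel = hc_idx == k
        grp_idx[sel] = rng.choice(len(groups), size=int(sel.sum()),
                                  p=np.asarray(config.composition_by_height[hc], float))
    m_lookup = np.array([[config.mortality_by_cell[g][k] for k in range(len(classes))]
                         for g in groups])
    dies = rng.uniform(size=n_main) < m_lookup[grp_idx, hc_idx]
    death_year = np.where(dies,
                          rng.integers(window[0], window[1] + 1, size=n_main),
                          -1).astype(float)

    # --- sub-5-m stems (excluded from all mortality analyses downstream) ----
    n_below = int(below_sizes.sum())
    plot_b = np.repeat([f"P{p + 1:03d}" for p in range(config.n_plots)], below_sizes)
    grp_b = rng.choice(len(groups), size=n_below,
                       p=np.asarray(config.composition_by_height[allo.SHORT], float))

    # --- pre-window snags: bdf share of standing dead, per cell -------------
    bdf = config.background_dead_fraction
    pre_plot, pre_grp, pre_hc, pre_year = [], [], [], []
    if bdf > 0:
        ratio = bdf / (1.0 - bdf)
        for k, hc in enumerate(classes):
            for g, grp in enumerate(groups):
                d_cell = int((dies & (hc_idx == k) & (grp_idx == g)).sum())
                n_pre = rng.poisson(d_cell * ratio)
                if n_pre:
                    pre_plot.append(rng.integers(config.n_plots, size=n_pre))
                    pre_grp.append(np.full(n_pre, g))
                    pre_hc.append(np.full(n_pre, k))
                    pre_year.append(rng.integers(window[0] - 12, window[0], size=n_pre))
    n_pre_tot = sum(len(a) for a in pre_plot)

    plot_all = np.concatenate([
        plot_id, plot_b,
        np.array([f"P{p + 1:03d}" for p in np.concatenate(pre_plot)], dtype=object)
        if n_pre_tot else np.empty(0, object)])
    grp_all = np.concatenate([grp_idx, grp_b,
                              np.concatenate(pre_grp).astype(int) if n_pre_tot
                              else np.empty(0, int)])
    hc_all = np.concatenate([
        np.array(classes, object)[hc_idx],
        np.full(n_below, allo.BELOW_MIN, dtype=object),
        np.array(classes, object)[np.concatenate(pre_hc).astype(int)] if n_pre_tot
        else np.empty(0, object)])
    year_all = np.concatenate([death_year, np.full(n_below, -1.0),
                               np.concatenate(pre_year).astype(float) if n_pre_tot
                               else np.empty(0)])
    status_all = np.where(year_all >= 0, "dead", "live")

    # --- species and DBH, vectorized per (group, class) and species ---------
    n_tot = len(grp_all)
    species_all = np.empty(n_tot, dtype=object)
    dbh_all = np.empty(n_tot)
    for g, grp in enumerate(groups):
        for hc in classes + [allo.BELOW_MIN]:
            sel = np.flatnonzero((grp_all == g) & (hc_all == hc))
            if not len(sel):
                continue
            sps = eligible[(grp, hc)]
            sp_pick = rng.integers(len(sps), size=len(sel))
            for s, sp in enumerate(sps):
                idx = sel[sp_pick == s]
                if not len(idx):
                    continue
                lo, hi = intervals[sp][hc]
                mu, sigma = config.dbh_lognormal(sp)
                species_all[idx] = sp
                dbh_all[idx] = _truncated_lognormal(rng, mu, sigma, lo, hi, len(idx))

    df = pd.DataFrame({
        "plot_id": plot_all,
        "species": species_all,
        "group": np.array(groups, object)[grp_all],
        "dbh_class": 5.0 * np.floor(dbh_all / 5.0),
        "status": status_all,
        "death_year": np.where(year_all >= 0, year_all, np.nan),
        "hclass": hc_all,
    })
    df.insert(0, "tree_id", [f"T{i + 1:06d}" for i in range(len(df))])
    dead_mask = df.status == "dead"
    # deaths occur year-round: condition snag decay on a continuous elapsed
    # time (recorded death year +/- half a year around the mid-year value)
    tsd = (config.survey_year - df.loc[dead_mask, "death_year"].astype(float) + 0.5
           + rng.uniform(-0.5, 0.5, size=int(dead_mask.sum())))
    rclass = pd.Series(pd.NA, index=df.index, dtype="object")
    rclass.loc[dead_mask] = config.retention_model.sample(tsd.to_numpy(), rng)
    df["retention_class"] = rclass
    df = df.rename(columns={"death_year": "true_death_year"})

    truth_trees = df[["tree_id", "true_death_year"]].copy()
    truth_trees["true_height_class"] = df["hclass"]
    main = df[df.hclass != allo.BELOW_MIN]
    in_window = main["true_death_year"].between(window[0], window[1])
    cells = []
    for k, hc in enumerate(classes):
        for grp in groups:
            sub = main[(main.group == grp) & (main.hclass == hc)]
            alive = int((sub.status == "live").sum())
            wdead = int(in_window.loc[sub.index].fillna(False).sum())
            cells.append({"group": grp, "height_class": hc,
                          "true_m": config.mortality_by_cell[grp][k],
                          "n_2013": alive + wdead, "window_deaths": wdead})
    truth = TruthTable(cells=pd.DataFrame(cells), trees=truth_trees)
    inventory = df[["tree_id", "plot_id", "species", "group", "dbh_class",
                    "status", "retention_class", "true_death_year"]].copy()
    return inventory, truth


def generate_calibration(config: SimConfig, n_trees: int) -> pd.DataFrame:
    """Snags with exactly known death years for fitting the dating model.

    The calibration population emulates the standing-snag population of
    the same landscape: death years are a mixture of drought-window years
    (weight ``1 - background_dead_fraction``) and the preceding twelve
    years, matching the process that generates inventory snags, so the
    retention-class -> death-window probabilities the fits imply are
    calibrated for the surveyed plots. Retention classes follow the
    configured retention model. Seeded from ``config.seed`` (independent
    stream from the inventory).
    """
    if n_trees <= 0:
        raise ValueError("n_trees must be positive")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 104729]))
    species = [sp for grp in config.group_names for sp in config.species_per_group[grp]]
    sp = rng.choice(species, size=n_trees)
    w0, w1 = config.drought_window
    pre = rng.uniform(size=n_trees) < config.background_dead_fraction
    death_year = np.where(pre,
                          rng.integers(w0 - 12, w0, size=n_trees),
                          rng.integers(w0, w1 + 1, size=n_trees))
    t_cont = (config.survey_year - death_year + 0.5
              + rng.uniform(-0.5, 0.5, size=n_trees))
    rclass = config.retention_model.sample(t_cont, rng)
    return pd.DataFrame({"species": sp, "retention_class": rclass,
                         "death_year": death_year,
                         "survey_year": config.survey_year})


# ---------------------------------------------------------------------------
# Parameter-recovery benchmark cells
# ---------------------------------------------------------------------------

def generate_recovery_cells(
    n_cells: int,
    n_per_cell: int,
    rng: np.random.Generator,
    m_range: tuple = (0.02, 0.6),
    background_ratio: float = 0.3 / 0.7,
    signal_sd: float = 0.35,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Independent cells with known mortality and calibrated dating noise.

    Each cell starts with ``n_per_cell`` trees alive at the window start;
    window deaths are binomial with the cell's true mortality, and
    pre-window snags are added at ``background_ratio`` of window deaths.
    Every dead tree receives a Gaussian condition signal (+1 mean if
    in-window, -1 if older, sd ``signal_sd``) and its exactly calibrated
    posterior probability q of in-window death given that signal — so
    coverage of the mortality credible intervals tests the latent-
    indicator machinery, not just the binomial part. The default signal
    noise keeps most q near 0 or 1, reflecting the method's premise that
    snag condition dates deaths reliably; see the methods note for how
    recovery degrades as dating blurs.

    Returns a trees table ready for :func:`heightmort.mortality.fit_mortality`
    (cells keyed by ``group``) and the vector of true mortalities.
    """
    true_m = rng.uniform(*m_range, size=n_cells)
    frames = []
    for j in range(n_cells):
        d = rng.binomial(n_per_cell, true_m[j])
        b = rng.poisson(d * background_ratio)
        live = n_per_cell - d
        n_dead = d + b
        status = np.array(["live"] * live + ["dead"] * n_dead)
        q = np.full(live + n_dead, np.nan)
        if n_dead:
            in_window = np.array([True] * d + [False] * b)
            s = rng.normal(np.where(in_window, 1.0, -1.0), signal_sd)
            pi = d / n_dead
            num = pi * norm.pdf(s, 1.0, signal_sd)
            den = num + (1.0 - pi) * norm.pdf(s, -1.0, signal_sd)
            q[live:] = num / den
        frames.append(pd.DataFrame({
            "group": f"cell{j:03d}", "height_class": "all",
            "status": status, "q": q}))
    return pd.concat(frames, ignore_index=True), true_m


# ---------------------------------------------------------------------------
# Two-group hypothetical scenarios
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScenarioSpec:
    """A hypothetical stratified forest: proportions and mortalities per class."""

    groups: tuple
    height_classes: tuple
    proportions: Mapping[str, Sequence[float]]   # group -> p per class
    mortalities: Mapping[str, Sequence[float]]   # group -> m per class
    class_totals: tuple = ()

    def __post_init__(self) -> None:
        k = len(self.height_classes)
        totals = self.class_totals or tuple([1000.0] * k)
        object.__setattr__(self, "class_totals", totals)
        for i in range(k):
            s = sum(self.proportions[g][i] for g in self.groups)
            if abs(s - 1.0) > 1e-9:
                raise ConfigError(
                    f"proportions in class {self.height_classes[i]!r} sum to {s}, not 1")
        for g in self.groups:
            if any(not 0.0 <= m <= 1.0 for m in self.mortalities[g]):
                raise ConfigError(f"mortalities for group {g!r} not in [0, 1]")


def scenario_table(spec: ScenarioSpec) -> pd.DataFrame:
    """Counts table (height_class, group, n, d) realizing a scenario exactly."""
    rows = []
    for i, hc in enumerate(spec.height_classes):
        for g in spec.groups:
            n = spec.proportions[g][i] * spec.class_totals[i]
            rows.append({"height_class": hc, "group": g,
                         "n": n, "d": spec.mortalities[g][i] * n})
    return pd.DataFrame(rows)


#: Scenario 1: both species' mortality declines with height, but the
#: high-mortality species B dominates the tall classes — pooled mortality
#: rises with height (a composition-driven Simpson reversal).
SCENARIO_COMPOSITION_SHIFT = ScenarioSpec(
    groups=("A", "B"),
    height_classes=allo.HEIGHT_CLASSES,
    proportions={"A": (0.9, 0.5, 0.1), "B": (0.1, 0.5, 0.9)},
    mortalities={"A": (0.15, 0.10, 0.05), "B": (0.45, 0.40, 0.35)},
)

#: Scenario 2: constant composition, but the minority species D's
#: mortality rises sharply with height while C's declines — pooled
#: mortality rises without any composition shift.
SCENARIO_OPPOSING_TRENDS = ScenarioSpec(
    groups=("C", "D"),
    height_classes=allo.HEIGHT_CLASSES,
    proportions={"C": (0.7, 0.7, 0.7), "D": (0.3, 0.3, 0.3)},
    mortalities={"C": (0.20, 0.15, 0.10), "D": (0.10, 0.30, 0.60)},
)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_truth_csv(truth: TruthTable, path) -> None:
    """One CSV holding both truth tables, distinguished by a ``record`` column."""
    cells = truth.cells.copy()
    cells.insert(0, "record", "cell")
    trees = truth.trees.copy()
    trees.insert(0, "record", "tree")
    pd.concat([cells, trees], ignore_index=True).to_csv(path, index=False)


def read_truth_csv(path) -> TruthTable:
    df = pd.read_csv(path)
    cells = df[df.record == "cell"].dropna(axis=1, how="all").drop(columns="record")
    trees = df[df.record == "tree"].dropna(axis=1, how="all").drop(columns="record")
    return TruthTable(cells=cells.reset_index(drop=True), trees=trees.reset_index(drop=True))


def config_to_dict(config: SimConfig) -> dict:
    """Plain-dict form of a SimConfig for YAML round-tripping."""
    return {
        "n_plots": config.n_plots,
        "trees_per_plot_mean": config.trees_per_plot_mean,
        "group_names": list(config.group_names),
        "species_per_group": {g: list(s) for g, s in config.species_per_group.items()},
        "composition_by_height": {h: list(p) for h, p in config.composition_by_height.items()},
        "mortality_by_cell": {g: list(m) for g, m in config.mortality_by_cell.items()},
        "height_class_probs": list(config.height_class_probs),
        "below_min_fraction": config.below_min_fraction,
        "dbh_distribution": {s: list(v) for s, v in config.dbh_distribution.items()},
        "retention_model": {"cutpoints": list(config.retention_model.cutpoints),
                            "scale": config.retention_model.scale},
        "allometry": {s: {"form": p.form, **dict(p.parameters)}
                      for s, p in config.allometry.items()},
        "survey_year": config.survey_year,
        "drought_window": list(config.drought_window),
        "background_dead_fraction": config.background_dead_fraction,
        "seed": config.seed,
    }


def config_from_dict(data: Mapping) -> SimConfig:
    kwargs = dict(data)
    try:
        if "retention_model" in kwargs:
            rm = kwargs["retention_model"]
            kwargs["retention_model"] = RetentionModel(
                cutpoints=tuple(rm.get("cutpoints", RetentionModel.cutpoints)),
                scale=float(rm.get("scale", RetentionModel.scale)))
        if "allometry" in kwargs:
            kwargs["allometry"] = {
                s: allo.AllometryParams(s, p["form"],
                                        {k: v for k, v in p.items() if k != "form"})
                for s, p in kwargs["allometry"].items()}
        for key in ("group_names", "height_class_probs", "drought_window"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        for key in ("species_per_group", "composition_by_height",
                    "mortality_by_cell", "dbh_distribution"):
            if key in kwargs:
                kwargs[key] = {k: tuple(v) for k, v in kwargs[key].items()}
        return SimConfig(**kwargs)
    except (TypeError, KeyError) as exc:
        raise ConfigError(f"invalid simulation config: {exc}") from exc


def with_seed(config: SimConfig, seed: int) -> SimConfig:
    return replace(config, seed=seed)
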