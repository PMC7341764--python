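"""Height-diameter allometry and height-class assignment.

Field crews record trunk diameter at breast height (DBH, breast height
1.37 m) in 5-cm classes. Stature bins (5-15 m, 15-30 m, >30 m) are derived
by inverting a species-specific height-diameter curve at the class breaks
and rounding the resulting DBH thresholds to the nearest 5-cm class.

Two functional forms are provided:

* ``chapman_richards`` -- saturating curve
  ``H = 1.37 + asymptote * (1 - exp(-rate * dbh)) ** shape``,
  the standard choice for height-diameter modelling; total height
  approaches ``asymptote + 1.37`` for very large stems.
* ``linear`` -- ``H = 1.37 + slope * dbh``, a toy form useful for
  closed-form checks.

Height-class breaks a species cannot attain (break height above the
curve's asymptote) are reported as the sentinel ``UNREACHABLE`` (infinity).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.optimize import brentq

BREAST_HEIGHT = 1.37
"""Breast height in metres; DBH is measured here, so H(dbh -> 0) -> 1.37."""

HEIGHT_BREAKS = (5.0, 15.0, 30.0)

BELOW_MIN = "<5m"
SHORT = "5-15m"
MID = "15-30m"
TALL = ">30m"
HEIGHT_CLASSES = (SHORT, MID, TALL)

UNREACHABLE = math.inf


def _chapman_richards(dbh, p):
    return p["asymptote"] * (1.0 - np.exp(-p["rate"] * np.asarray(dbh, float))) ** p["shape"]


def _linear(dbh, p):
    return p["slope"] * np.asarray(dbh, float)


_FORMS = {"chapman_richards": _chapman_richards, "linear": _linear}
_FORM_PARAMS = {"chapman_richards": ("asymptote", "rate", "shape"), "linear": ("slope",)}


@dataclass(frozen=True)
class AllometryParams:
    """Species-specific height-diameter curve parameters."""

    species: str
    form: str
    parameters: Mapping[str, float]

    def __post_init__(self) -> None:
        if self.form not in _FORMS:
            raise ValueError(f"unknown allometry form {self.form!r}; options: {sorted(_FORMS)}")
        missing = [k for k in _FORM_PARAMS[self.form] if k not in self.parameters]
        if missing:
            raise ValueError(f"{self.species}: form {self.form!r} missing parameters {missing}")
        if any(v <= 0 for v in self.parameters.values()):
            raise ValueError(f"{self.species}: allometry parameters must be positive")

    @property
    def max_height(self) -> float:
        """Total height approached as DBH grows without bound (m)."""
        if self.form == "chapman_richards":
            return BREAST_HEIGHT + self.parameters["asymptote"]
        return math.inf


def predict_height(params: AllometryParams, dbh) -> np.ndarray | float:
    """Predicted total tree height (m) at diameter ``dbh`` (cm).

    Strictly increasing in DBH; tends to :data:`BREAST_HEIGHT` as dbh -> 0.
    Raises on non-positive DBH.
    """
    d = np.asarray(dbh, dtype=float)
    if np.any(d <= 0):
        raise ValueError("dbh must be positive")
    h = BREAST_HEIGHT + _FORMS[params.form](d, params.parameters)
    return float(h) if np.isscalar(dbh) or d.ndim == 0 else h


def invert_height(params: AllometryParams, height: float, xtol: float = 0.01) -> float:
    """Continuous DBH (cm) at which the curve reaches ``height`` (m).

    Returns :data:`UNREACHABLE` when the break exceeds the species'
    asymptotic height. Root found by scalar bracketing to ``xtol`` cm.
    """
    if height <= BREAST_HEIGHT:
        raise ValueError(f"height must exceed breast height ({BREAST_HEIGHT} m)")
    if height >= params.max_height:
        return UNREACHABLE
    lo, hi = 1e-9, 10.0
    while predict_height(params, hi) < height:
        hi *= 2.0
        if hi > 1e6:  # pragma: no cover - guards a pathological flat curve
            return UNREACHABLE
    return brentq(lambda d: predict_height(params, d) - height, lo, hi, xtol=xtol)


def round_to_class(dbh: float, width: float = 5.0) -> float:
    """Round a DBH to the nearest multiple of ``width``; exact ties round up."""
    if not math.isfinite(dbh):
        return dbh
    return width * math.floor(dbh / width + 0.5)


@dataclass(frozen=True)
class HeightClassThresholds:
    """Per-species DBH-class cut points between height classes (cm).

    Each threshold is the 5-cm class label (bin lower edge) at or above
    which a tree falls in the taller class. ``UNREACHABLE`` marks a break
    the species' curve never attains.
    """

    species: str
    dbh_at_5m: float
    dbh_at_15m: float
    dbh_at_30m: float

    def __post_init__(self) -> None:
        t = [self.dbh_at_5m, self.dbh_at_15m, self.dbh_at_30m]
        finite = [x for x in t if math.isfinite(x)]
        if any(b <= a for a, b in zip(finite, finite[1:])):
            raise ValueError(f"{self.species}: thresholds must be strictly increasing: {t}")

    def classify(self, dbh_class: float) -> str:
        """Height class of a tree whose 5-cm DBH class label is ``dbh_class``."""
        if dbh_class < 0 or dbh_class % 5:
            raise ValueError(f"dbh_class must be a non-negative multiple of 5, got {dbh_class}")
        if dbh_class >= self.dbh_at_30m:
            return TALL
        if dbh_class >= self.dbh_at_15m:
            return MID
        if dbh_class >= self.dbh_at_5m:
            return SHORT
        return BELOW_MIN


def compute_thresholds(
    params: AllometryParams,
    height_breaks=HEIGHT_BREAKS,
    xtol: float = 0.01,
) -> HeightClassThresholds:
    """Invert the species curve at each height break, rounding to 5-cm classes.

    A probe of the curve on a diameter grid guards against non-monotone
    parameterizations before inversion.
    """
    probe = predict_height(params, np.linspace(0.5, 400.0, 200))
    if np.any(np.diff(probe) <= 0):
        raise ValueError(f"{params.species}: height curve is not strictly increasing")
    cuts = [round_to_class(invert_height(params, h, xtol=xtol)) for h in height_breaks]
    return HeightClassThresholds(params.species, *cuts)


def assign_height_class(dbh_class: float, thresholds: HeightClassThresholds) -> str:
    """Height class for one tree; see :meth:`HeightClassThresholds.classify`."""
    return thresholds.classify(dbh_class)


def assign_height_classes(
    trees: pd.DataFrame,
    thresholds_by_species: Mapping[str, HeightClassThresholds],
    species_col: str = "species",
    dbh_col: str = "dbh_class",
) -> pd.Series:
    """Vectorized height-class assignment for an inventory table.

    Raises ``KeyError`` naming any species without thresholds.
    """
    unknown = sorted(set(trees[species_col]) - set(thresholds_by_species))
    if unknown:
        raise KeyError(f"no allometry thresholds for species: {unknown}")
    out = pd.Series(index=trees.index, dtype=object, name="height_class")
    for sp, sub in trees.groupby(species_col, sort=False):
        thr = thresholds_by_species[sp]
        d = sub[dbh_col].to_numpy(float)
        cls = np.full(len(sub), BELOW_MIN, dtype=object)
        cls[d >= thr.dbh_at_5m] = SHORT
        cls[d >= thr.dbh_at_15m] = MID
        cls[d >= thr.dbh_at_30m] = TALL
        out.loc[sub.index] = cls
    return out


def write_allometry_csv(params: Mapping[str, AllometryParams], path) -> None:
    rows = []
    for p in params.values():
        row = {"species": p.species, "form": p.form}
        row.update(p.parameters)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_allometry_csv(path) -> dict[str, AllometryParams]:
    df = pd.read_csv(path)
    out = {}
    for _, row in df.iterrows():
        form = row["form"]
        pars = {k: float(row[k]) for k in _FORM_PARAMS[form] if pd.notna(row.get(k))}
        out[row["species"]] = AllometryParams(row["species"], form, pars)
    return out


def default_allometry() -> dict[str, AllometryParams]:
    """Chapman-Richards parameter sets for the default simulated community.

    Asymptotes reflect typical stature: angiosperms top out near 30-38 m,
    the large conifers near 55-62 m. *Torreya californica* (asymptote
    below 30 m) exercises the unreachable-threshold path.
    """
    cr = lambda sp, a, k, c: AllometryParams(sp, "chapman_richards",
                                             {"asymptote": a, "rate": k, "shape": c})
    specs = [
        ("Quercus kelloggii", 36.0, 0.040, 1.10),
        ("Quercus chrysolepis", 30.0, 0.045, 1.10),
        ("Abies concolor", 55.0, 0.025, 1.20),
        ("Abies magnifica", 58.0, 0.024, 1.20),
        ("Calocedrus decurrens", 48.0, 0.030, 1.30),
        ("Torreya californica", 26.0, 0.040, 1.10),
        ("Pinus ponderosa", 55.0, 0.028, 1.15),
        ("Pinus lambertiana", 60.0, 0.022, 1.20),
        ("Pinus jeffreyi", 52.0, 0.027, 1.15),
    ]
    return {sp: cr(sp, a, k, c) for sp, a, k, c in specs}
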