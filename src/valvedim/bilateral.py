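"""Directional bilateral asymmetry and left/right data combination.

Limbs and hemipenis components are measured on both body sides where
preservation allows.  Sides are not interchangeable: limbs on the left
run ~0.5-1% larger than the right, and the hemipenis shows the reverse.
This module quantifies that directional asymmetry (mean L-R with a
paired-t 95% CI), converts right-side values to left-side equivalents
via per-species left-on-right regressions, and combines both sides into
one value per specimen and variable:

* left only            -> left value as-is
* right only           -> intercept + slope * right
* both                 -> mean(left, predicted-from-right)

Specimens whose side labels were lost at dissection get the larger limb
assigned to the left; such side-imputed pairs are excluded from
asymmetry estimation but kept for all downstream analyses.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "BilateralPair",
    "SideRegression",
    "BilateralSummary",
    "SecondaryTraitIndices",
    "directional_asymmetry",
    "percent_asymmetry",
    "fit_left_on_right",
    "combine_sides",
    "assign_unknown_sides",
    "walking_leg_indices",
]


@dataclass
class BilateralPair:
    specimen_id: str
    variable: str
    left: float | None = None
    right: float | None = None
    side_known: bool = True

    def __post_init__(self) -> None:
        if self.left is None and self.right is None:
            raise ValueError("at least one of left/right must be present")

    @property
    def complete(self) -> bool:
        return self.left is not None and self.right is not None


@dataclass(frozen=True)
class SideRegression:
    """OLS of left on right values, fitted within one species."""

    species: str
    variable: str
    intercept: float
    slope: float
    r_squared: float
    n: int

    def predict(self, right: float) -> float:
        return self.intercept + self.slope * right


IDENTITY_REGRESSION = SideRegression("any", "any", 0.0, 1.0, 1.0, 3)


@dataclass(frozen=True)
class BilateralSummary:
    """Per species/sex/variable asymmetry summary (Table-3/4 layout)."""

    species: str
    sex: str
    variable: str
    mean_left: float
    cv_left: float
    mean_diff: float
    ci_low: float
    ci_high: float
    p_value: float
    n_pairs: int

    @property
    def significant(self) -> bool:
        return bool(self.p_value < 0.05)


@dataclass(frozen=True)
class SecondaryTraitIndices:
    """Male clasping-leg transformation indices (left minus right)."""

    specimen_id: str
    width_asym: float
    curvature_asym: float


def _pairs_arrays(pairs, *, known_only: bool = True):
    """Left/right arrays over complete (and, by default, side-known) pairs."""
    use = [p for p in pairs if p.complete and (p.side_known or not known_only)]
    left = np.array([p.left for p in use], dtype=float)
    right = np.array([p.right for p in use], dtype=float)
    return left, right


def directional_asymmetry(pairs, species: str, sex: str,
                          variable: str) -> BilateralSummary:
    """Mean(L-R) with a paired-t 95% CI and two-sided p against zero.

    Side-imputed pairs (``side_known=False``) never enter this estimate.
    Left-side mean and CV are computed over all side-known left values
    (single-sided specimens included), matching how the descriptive
    columns of the asymmetry tables are tallied.
    """
    lefts = np.array([p.left for p in pairs
                      if p.left is not None and p.side_known], dtype=float)
    mean_left = float(lefts.mean()) if len(lefts) else math.nan
    cv_left = (float(100.0 * lefts.std(ddof=1) / lefts.mean())
               if len(lefts) >= 2 and lefts.mean() != 0 else math.nan)

    left, right = _pairs_arrays(pairs)
    d = left - right
    n = len(d)
    if n < 2:
        warnings.warn(f"{species}/{sex}/{variable}: <2 complete pairs; "
                      "CI undefined", stacklevel=2)
        md = float(d.mean()) if n else math.nan
        return BilateralSummary(species, sex, variable, mean_left, cv_left,
                                md, math.nan, math.nan, math.nan, n)
    md = float(d.mean())
    sd = float(d.std(ddof=1))
    se = sd / math.sqrt(n)
    if se == 0.0:
        # all differences identical: degenerate t
        p = 1.0 if md == 0.0 else 0.0
        return BilateralSummary(species, sex, variable, mean_left, cv_left,
                                md, md, md, p, n)
    tcrit = stats.t.ppf(0.975, n - 1)
    t = md / se
    p = float(2.0 * stats.t.sf(abs(t), n - 1))
    return BilateralSummary(species, sex, variable, mean_left, cv_left, md,
                            md - tcrit * se, md + tcrit * se, p, n)


def percent_asymmetry(pairs):
    """Per-specimen percent asymmetry 100*(L-R)/L and its running mean.

    Returns ``(percents, cumulative_means)`` over complete side-known
    pairs in input order; pairs with L == 0 are excluded with a warning.
    The cumulative-mean trajectory supports the stabilization-with-n
    check: estimates wobble at low n, then settle (for the limbs, at
    left sides ~0.5-1% larger).
    """
    left, right = _pairs_arrays(pairs)
    keep = left != 0
    if not np.all(keep):
        warnings.warn(f"excluded {int((~keep).sum())} pair(s) with L == 0",
                      stacklevel=2)
    left, right = left[keep], right[keep]
    pct = 100.0 * (left - right) / left
    cum = (np.cumsum(pct) / np.arange(1, len(pct) + 1)) if len(pct) else pct
    return pct, cum


def fit_left_on_right(pairs, species: str, variable: str) -> SideRegression:
    """OLS regression predicting left values from right values."""
    left, right = _pairs_arrays(pairs, known_only=True)
    if len(left) < 3:
        raise ValueError(f"{species}/{variable}: need >= 3 complete pairs, "
                         f"got {len(left)}")
    if np.ptp(right) == 0:
        raise ValueError(f"{species}/{variable}: zero variance in right values")
    res = stats.linregress(right, left)
    return SideRegression(species, variable, float(res.intercept),
                          float(res.slope), float(res.rvalue ** 2), len(left))


def combine_sides(pair: BilateralPair,
                  regression: SideRegression | None = None) -> float:
    """One left-equivalent value per specimen-variable."""
    if pair.right is None:
        return float(pair.left)
    if regression is None:
        raise ValueError(
            f"{pair.specimen_id}/{pair.variable}: right value present but "
            "no left-on-right regression supplied")
    pred = regression.predict(pair.right)
    if pair.left is None:
        return float(pred)
    return float((pair.left + pred) / 2.0)


def assign_unknown_sides(value_a: float, value_b: float) -> BilateralPair:
    """Assign the larger of two unknown-side values to the left.

    The returned pair is flagged ``side_known=False`` so it is excluded
    from asymmetry estimation.  Ties keep both values and are flagged in
    no special way beyond ``side_known=False``.
    """
    left, right = (value_a, value_b) if value_a >= value_b else (value_b, value_a)
    return BilateralPair(specimen_id="", variable="", left=float(left),
                         right=float(right), side_known=False)


def walking_leg_indices(specimen_id: str, left_width: float,
                        right_width: float, left_curve: float,
                        left_linear: float, right_curve: float,
                        right_linear: float) -> SecondaryTraitIndices:
    """Clasping-leg width and curvature asymmetry for one male.

    ``width_asym = L_W - R_W``; ``curvature_asym = (L_C - L_Li) -
    (R_C - R_Li)``.  Transformed (wider, more curved) right legs give
    negative values for both indices.
    """
    for name, v in (("left_width", left_width), ("right_width", right_width),
                    ("left_curve", left_curve), ("left_linear", left_linear),
                    ("right_curve", right_curve), ("right_linear", right_linear)):
        if v is None or not math.isfinite(v):
            raise ValueError(f"missing or non-finite input {name}")
    return SecondaryTraitIndices(
        specimen_id=specimen_id,
        width_asym=float(left_width - right_width),
        curvature_asym=float((left_curve - left_linear)
                             - (right_curve - right_linear)),
    )
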