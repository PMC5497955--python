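"""Composite traits, dimorphism, allometry and partial correlations.

The headline question: after removing the shared dependence on overall
(soft-part) body size, do male sexual traits — basal-capsule size
(HemiBC), terminal-extension area and copulatory-process length
(HemiTE A / HemiTE L), clasping-leg width and curvature asymmetry
(1WL W / 1WL L) — still correlate with valve size (log area) and valve
shape (log L/H)?

Conventions, fixed throughout:

* natural logs; sexual dimorphism is the M-F difference of log means,
  hence proportional and comparable across species;
* Welch's (unequal-variance) two-sample t with Satterthwaite df, group
  order female-first so that larger males give negative t;
* soft-part size = mean of log(1A, 2A, Md, 3WL); HemiBC size = mean of
  the three log basal-capsule support lengths (the sum differs only by
  the factor 3 and leaves every correlation, t and p unchanged);
* static allometry regresses log(trait) on log(sqrt(valve area)) so
  isometry means unit slope — except area-on-area (HemiTE A), which is
  already dimensionally matched;
* partial correlation = Pearson correlation of the residuals from
  regressing each variable on soft-part size; its p equals the p of the
  male-trait coefficient in valve ~ softpart + male_trait.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
import statsmodels.api as sm

__all__ = [
    "DimorphismEstimate",
    "AllometryFit",
    "PartialCorrelationResult",
    "composite_softpart_size",
    "composite_hemibc",
    "welch_t",
    "dimorphism",
    "female_centered_deviations",
    "coefficient_of_variation",
    "static_allometry",
    "evolutionary_allometry",
    "pearson_correlation",
    "partial_correlation",
]


@dataclass(frozen=True)
class DimorphismEstimate:
    species: str
    trait: str
    diff: float  # M - F difference of log means
    t: float     # Welch t, female-first ordering
    df: float
    p: float


@dataclass(frozen=True)
class AllometryFit:
    species: str
    trait: str
    size_proxy: str  # "sqrt_valve_area" or "valve_area"
    intercept: float
    intercept_ci: tuple[float, float]
    slope: float
    slope_ci: tuple[float, float]
    r2_adj: float
    slope_p: float      # H0: slope = 0
    isometry_p: float   # H0: slope = 1
    n: int
    kind: str = "static"  # or "evolutionary"


@dataclass(frozen=True)
class PartialCorrelationResult:
    species: str
    male_trait: str
    valve_trait: str
    r_p: float
    df: int  # n - 3
    p: float


def _finite(name, *arrays):
    out = []
    for a in arrays:
        a = np.asarray(a, dtype=float)
        if not np.all(np.isfinite(a)):
            raise ValueError(f"{name}: inputs must be finite and complete")
        out.append(a)
    return out


def composite_softpart_size(log_1a, log_2a, log_md, log_3wl):
    """Soft-part body size: mean of the four log reference-limb lengths."""
    vals = _finite("composite_softpart_size", log_1a, log_2a, log_md, log_3wl)
    return np.mean(np.broadcast_arrays(*vals), axis=0)


def composite_hemibc(log_bcd, log_bc12, log_bc34):
    """Basal-capsule size: mean of the three log support lengths."""
    vals = _finite("composite_hemibc", log_bcd, log_bc12, log_bc34)
    return np.mean(np.broadcast_arrays(*vals), axis=0)


def welch_t(group_f, group_m):
    """Welch two-sample t with Satterthwaite df, female group first.

    With females first, species whose males are larger yield negative t,
    matching the reporting convention used throughout.
    """
    f, m = _finite("welch_t", group_f, group_m)
    if len(f) < 2 or len(m) < 2:
        raise ValueError("each group needs n >= 2")
    if f.var(ddof=1) == 0 and m.var(ddof=1) == 0:
        if f.mean() == m.mean():
            return 0.0, float(len(f) + len(m) - 2), 1.0
        raise ValueError("degenerate zero-variance groups with unequal means")
    vf, vm = f.var(ddof=1) / len(f), m.var(ddof=1) / len(m)
    t = (f.mean() - m.mean()) / math.sqrt(vf + vm)
    df = (vf + vm) ** 2 / (vf ** 2 / (len(f) - 1) + vm ** 2 / (len(m) - 1))
    p = float(2.0 * sps.t.sf(abs(t), df))
    return float(t), float(df), p


def dimorphism(values_f, values_m, species: str = "",
               trait: str = "") -> DimorphismEstimate:
    """Sexual dimorphism of a log-scale trait: M-F mean difference + Welch t."""
    f, m = _finite("dimorphism", values_f, values_m)
    if len(f) < 2 or len(m) < 2:
        raise ValueError("both sexes need n >= 2")
    t, df, p = welch_t(f, m)
    return DimorphismEstimate(species=species, trait=trait,
                              diff=float(m.mean() - f.mean()),
                              t=t, df=df, p=p)


def female_centered_deviations(log_size, log_shape, is_female):
    """Per-specimen (dlog_size, dlog_shape) from the female centroid.

    The female population mean maps to the origin; the male centroid's
    coordinates equal the size and shape dimorphism vector.
    """
    size, shape = _finite("female_centered_deviations", log_size, log_shape)
    fem = np.asarray(is_female, dtype=bool)
    if not fem.any():
        raise ValueError("no females: female centroid undefined")
    return size - size[fem].mean(), shape - shape[fem].mean()


def coefficient_of_variation(values) -> float:
    """CV in percent: 100 * sample sd (n-1) / mean."""
    (v,) = _finite("coefficient_of_variation", values)
    if len(v) < 2:
        raise ValueError("CV needs n >= 2")
    mu = v.mean()
    if mu == 0:
        raise ValueError("CV undefined for zero mean")
    return float(100.0 * v.std(ddof=1) / mu)


def _ols_fit(x, y, species, trait, size_proxy, kind, min_n) -> AllometryFit:
    if len(x) < min_n:
        raise ValueError(f"{species}/{trait}: need n >= {min_n}, got {len(x)}")
    if np.ptp(x) == 0:
        raise ValueError(f"{species}/{trait}: zero variance in size proxy")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    ci = model.conf_int(alpha=0.05)
    b, se_b = model.params[1], model.bse[1]
    iso_t = (b - 1.0) / se_b
    iso_p = float(2.0 * sps.t.sf(abs(iso_t), model.df_resid))
    return AllometryFit(
        species=species, trait=trait, size_proxy=size_proxy,
        intercept=float(model.params[0]),
        intercept_ci=(float(ci[0, 0]), float(ci[0, 1])),
        slope=float(b), slope_ci=(float(ci[1, 0]), float(ci[1, 1])),
        r2_adj=float(model.rsquared_adj), slope_p=float(model.pvalues[1]),
        isometry_p=iso_p, n=len(x), kind=kind)


def static_allometry(trait_values, valve_areas, species: str = "",
                     trait: str = "", *,
                     same_dimensionality: bool = False) -> AllometryFit:
    """Within-species allometry of log(trait) on log valve size.

    Valve area is square-root transformed first so a length-dimension
    trait has unit expected slope under isometry; pass
    ``same_dimensionality=True`` for area-dimension traits (HemiTE A) to
    regress on log(area) directly.  Raw (unlogged) trait values and
    areas are expected.
    """
    t, a = _finite("static_allometry", trait_values, valve_areas)
    if np.any(t <= 0) or np.any(a <= 0):
        raise ValueError("trait values and areas must be positive")
    x = np.log(a) if same_dimensionality else np.log(np.sqrt(a))
    proxy = "valve_area" if same_dimensionality else "sqrt_valve_area"
    return _ols_fit(x, np.log(t), species, trait, proxy, "static", min_n=4)


def evolutionary_allometry(species_mean_traits, species_mean_areas,
                           trait: str = "", *,
                           same_dimensionality: bool = False) -> AllometryFit:
    """Across-species allometry through species mean points.

    A 3-point fit in practice: computed, but to be read with the low-n
    caveat attached (kind == "evolutionary").
    """
    t, a = _finite("evolutionary_allometry", species_mean_traits,
                   species_mean_areas)
    if np.any(t <= 0) or np.any(a <= 0):
        raise ValueError("species means must be positive")
    x = np.log(a) if same_dimensionality else np.log(np.sqrt(a))
    proxy = "valve_area" if same_dimensionality else "sqrt_valve_area"
    return _ols_fit(x, np.log(t), "all", trait, proxy, "evolutionary", min_n=3)


def pearson_correlation(x, y):
    """Pearson r with df = n - 2 and two-sided t-based p."""
    x, y = _finite("pearson_correlation", x, y)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need matched vectors with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance input")
    r, p = sps.pearsonr(x, y)
    return float(r), len(x) - 2, float(p)


def partial_correlation(male_trait, valve_trait, softpart_size,
                        species: str = "", male_name: str = "",
                        valve_name: str = "") -> PartialCorrelationResult:
    """Partial correlation of a male trait and a valve trait given body size.

    Both variables are regressed (OLS with intercept) on soft-part size
    and the Pearson correlation of the two residual vectors is returned
    with df = n - 3 and p from t = r * sqrt(df / (1 - r^2)).  This p is
    numerically the p of the male-trait coefficient in the multiple
    regression valve ~ softpart + male_trait.
    """
    m, v, s = _finite("partial_correlation", male_trait, valve_trait,
                      softpart_size)
    n = len(m)
    if not (len(v) == len(s) == n) or n < 4:
        raise ValueError("need matched complete triples with n >= 4")
    if np.ptp(s) == 0:
        raise ValueError("zero variance in softpart size")
    x = sm.add_constant(s)
    res_m = m - x @ np.linalg.lstsq(x, m, rcond=None)[0]
    res_v = v - x @ np.linalg.lstsq(x, v, rcond=None)[0]
    if np.allclose(res_m, 0):
        raise ValueError("male trait is collinear with softpart size")
    if np.allclose(res_v, 0):
        raise ValueError("valve trait is collinear with softpart size")
    r = float(np.corrcoef(res_m, res_v)[0, 1])
    df = n - 3
    if abs(r) >= 1.0:
        p = 0.0
    else:
        t = r * math.sqrt(df / (1.0 - r * r))
        p = float(2.0 * sps.t.sf(abs(t), df))
    return PartialCorrelationResult(species=species, male_trait=male_name,
                                    valve_trait=valve_name, r_p=r, df=df, p=p)
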