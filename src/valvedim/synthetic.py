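"""Seeded synthetic Cyprideis-like populations with known ground truth.

The generator emulates the statistical structure the analysis assumes,
so every pipeline stage is testable without specimens:

* three species x two sexes, each specimen carrying a latent body-size
  factor ``s`` (the log square-root valve area) that drives all limb
  and valve dimensions through log-linear static allometries;
* valve size and shape with log-scale sex offsets (males larger in two
  of three species, always more elongate by ~0.08-0.10 log units);
* subtle directional asymmetry: limbs ~0.75% larger on the left,
  hemipenis components slightly larger on the right; left valves larger
  and less elongate than right valves;
* the male-only transformation of the right first walking leg (wider
  and more curved than the left);
* hemipenis traits present in males only, with shared latent factors
  for the basal capsule and terminal extension whose residual variation
  can leak into male valve size (the "partial effect" the headline
  analysis estimates);
* MCAR missingness at the few-percent level in the two composite-trait
  datasets, plus single-side loss and lost side labels.

Landmark sets are generated so the geometry module recovers the
intended measurement values: valve outlines are ellipses with small
radial noise, curves are circular arcs with the intended curve and
chord lengths, linear dimensions are landmark pairs.  Missingness and
side-label loss are applied to the measurement table (they emulate
loss at dissection, recorded in the data table); landmark sets
represent the complete digitization.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .tps import LandmarkSet

__all__ = [
    "TraitTruth",
    "SpeciesTruth",
    "SyntheticTruth",
    "SyntheticPopulation",
    "default_truth",
    "null_truth",
    "generate_population",
    "apply_missingness",
    "population_partial_r",
    "population_dimorphism",
    "population_allometry_slope",
]

SOFTPART_VARS = ("1A", "2A", "Md", "3WL")
HEMIBC_VARS = ("HemiBCd_L", "HemiBC12_L", "HemiBC34_L")
HEMITE_VARS = ("HemiTE_L", "HemiTE_A")
WL1_VARS = ("1WL_W", "1WL_Lc", "1WL_Lli")
VALVE_VARS = ("valve_area", "valve_length", "valve_height")

_S_REF = 6.5  # reference log(sqrt area) at which trait means are specified


@dataclass(frozen=True)
class TraitTruth:
    """Log-linear trait model: log(T) = alpha + slope * s + residual.

    ``mean_ref`` (um or um^2) anchors the intercept at s = 6.5; ``asym``
    is the proportional directional L-R offset (positive = left larger);
    ``latent`` names the shared male latent factor ("bc" or "te") and
    ``latent_sd`` its loading on this trait's log value.
    """

    mean_ref: float
    slope: float
    resid_sd: float
    asym: float
    male_only: bool = False
    latent: str | None = None
    latent_sd: float = 0.0

    @property
    def alpha(self) -> float:
        return math.log(self.mean_ref) - self.slope * _S_REF


@dataclass(frozen=True)
class SpeciesTruth:
    """Per-species population parameters on the latent-size scale."""

    name: str
    n_f: int = 50
    n_m: int = 50
    mean_s_f: float = 6.5          # female mean log(sqrt valve area)
    s_sd: float = 0.025            # sd of s within sex
    size_dimorphism: float = 0.04  # M-F difference of mean log valve area
    shape_mean_f: float = 0.53     # female mean log(L/H)
    shape_dimorphism: float = 0.09  # M-F difference of mean log(L/H)
    shape_sd: float = 0.012


def _default_traits() -> dict[str, TraitTruth]:
    return {
        "1A": TraitTruth(130.0, 0.63, 0.020, 0.0075),
        "2A": TraitTruth(160.0, 0.63, 0.020, 0.0075),
        "Md": TraitTruth(285.0, 0.76, 0.020, 0.0075),
        "3WL": TraitTruth(165.0, 0.77, 0.020, 0.0075),
        "HemiBCd_L": TraitTruth(490.0, 0.85, 0.012, -0.005, True, "bc", 0.020),
        "HemiBC12_L": TraitTruth(310.0, 0.85, 0.012, -0.005, True, "bc", 0.020),
        "HemiBC34_L": TraitTruth(260.0, 0.85, 0.012, -0.005, True, "bc", 0.020),
        "HemiTE_L": TraitTruth(135.0, 0.35, 0.025, -0.005, True, "te", 0.010),
        "HemiTE_A": TraitTruth(25000.0, 1.18, 0.040, -0.005, True, "te", 0.030),
    }


@dataclass
class SyntheticTruth:
    """Complete ground truth for one synthetic study."""

    species: list[SpeciesTruth] = field(default_factory=lambda: [
        SpeciesTruth("MEXI", mean_s_f=6.409, size_dimorphism=0.002,
                     shape_mean_f=0.531, shape_dimorphism=0.08),
        SpeciesTruth("SALE", mean_s_f=6.696, size_dimorphism=0.038,
                     shape_mean_f=0.470, shape_dimorphism=0.10),
        SpeciesTruth("TORO", mean_s_f=6.520, size_dimorphism=0.047,
                     shape_mean_f=0.531, shape_dimorphism=0.09),
    ])
    traits: dict[str, TraitTruth] = field(default_factory=_default_traits)
    side_noise_sd: float = 0.004        # per-side log measurement noise
    valve_area_asym: float = 0.02       # L-R offset of log valve area
    valve_shape_asym: float = -0.04     # L-R offset of log L/H
    valve_side_noise_sd: float = 0.004  # per-side log valve noise
    outline_noise_um: float = 1.0       # radial noise on valve outlines
    outline_points: int = 100
    # male 1WL transformation (right leg wider and more curved)
    wl1_width_ref: float = 40.0
    wl1_linear_ref: float = 108.0
    wl1_slope: float = 0.6
    wl1_resid_sd: float = 0.03
    wl1_curv_female: float = 0.03
    wl1_curv_sd: float = 0.005
    wl1_male_width_factor: float = 0.20
    wl1_male_width_sd: float = 0.05
    wl1_curv_male_right: float = 0.10
    wl1_curv_male_sd: float = 0.015
    # hemipenis-valve partial effects: loading of the male latent factors
    # on male log valve area and log shape
    gamma_bc_size: float = 0.008
    gamma_te_size: float = 0.006
    gamma_bc_shape: float = 0.0
    gamma_te_shape: float = 0.0
    # data-degradation rates
    missing_rate_softpart: float = 0.027
    missing_rate_hemibc: float = 0.017
    single_side_rate: float = 0.08
    unknown_side_rate: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        for sp in self.species:
            if sp.s_sd <= 0 or sp.shape_sd <= 0:
                raise ValueError(f"{sp.name}: sds must be positive")
        for rate in (self.missing_rate_softpart, self.missing_rate_hemibc,
                     self.single_side_rate, self.unknown_side_rate):
            if not (0.0 <= rate < 1.0):
                raise ValueError(f"rate {rate} outside [0, 1)")
        for name, tr in self.traits.items():
            if tr.mean_ref <= 0 or tr.resid_sd <= 0:
                raise ValueError(f"{name}: infeasible trait parameters")

    def to_dict(self) -> dict:
        return {
            "species": [asdict(sp) for sp in self.species],
            "traits": {k: asdict(v) for k, v in self.traits.items()},
            **{k: v for k, v in self.__dict__.items()
               if k not in ("species", "traits")},
        }


def default_truth(seed: int = 0, **overrides) -> SyntheticTruth:
    """The default study conditions (population scales echo the genus)."""
    return SyntheticTruth(seed=seed, **overrides)


def null_truth(seed: int = 0, **overrides) -> SyntheticTruth:
    """Conditions with a genuinely zero hemipenis-valve partial association.

    Merely setting the direct loadings (gamma) to zero is not enough:
    because the soft-part composite is a noisy proxy for latent body
    size, any trait that scales with size retains a positive partial
    correlation with valve size (residual confounding).  The null
    population therefore also makes the hemipenis traits independent of
    body size (slope 0), so the population partial correlation is
    exactly zero and the 5% rejection rate can be checked.
    """
    traits = _default_traits()
    for name in HEMIBC_VARS + HEMITE_VARS:
        tr = traits[name]
        traits[name] = TraitTruth(tr.mean_ref, 0.0, tr.resid_sd, tr.asym,
                                  tr.male_only, None, 0.0)
    kw = dict(traits=traits, gamma_bc_size=0.0, gamma_te_size=0.0,
              gamma_bc_shape=0.0, gamma_te_shape=0.0, wl1_slope=0.0)
    kw.update(overrides)
    return SyntheticTruth(seed=seed, **kw)


@dataclass
class SyntheticPopulation:
    landmark_sets: list[LandmarkSet]
    metadata: pd.DataFrame       # specimen_id, species, sex, sample_id, adult
    structures: pd.DataFrame     # image -> specimen_id, structure, side
    measurements: pd.DataFrame   # tidy long table (with side_known column)
    truth: SyntheticTruth


def apply_missingness(matrix, rate: float, seed) -> np.ndarray:
    """MCAR cell deletion at ``rate``, keeping each row's last value.

    Independent Bernoulli(rate) deletion per cell, except that a row is
    never left with zero observed values: one randomly chosen surviving
    cell is retained in rows that would otherwise be emptied.
    """
    if not (0.0 <= rate < 1.0):
        raise ValueError(f"rate must be in [0, 1), got {rate}")
    x = np.array(matrix, dtype=float, copy=True)
    if rate == 0.0 or x.size == 0:
        return x
    rng = np.random.default_rng(seed)
    kill = rng.random(x.shape) < rate
    kill &= ~np.isnan(x)
    for i in range(x.shape[0]):
        observed = ~np.isnan(x[i])
        if observed.any() and (kill[i] | ~observed).all():
            keep = rng.choice(np.flatnonzero(observed))
            kill[i, keep] = False
    x[kill] = np.nan
    return x


def _arc_points(curve_len: float, chord: float, n: int = 21) -> np.ndarray:
    """Points on a circular arc with the given arc and chord lengths."""
    if chord >= curve_len:
        t = np.linspace(0.0, 1.0, n)
        return np.column_stack([t * chord, np.zeros(n)])
    ratio = chord / curve_len  # = sin(theta/2) / (theta/2)
    f = lambda th: math.sin(th / 2.0) / (th / 2.0) - ratio
    theta = brentq(f, 1e-6, 2.0 * math.pi - 1e-9)
    radius = curve_len / theta
    ang = np.linspace(-theta / 2.0, theta / 2.0, n)
    pts = np.column_stack([radius * np.sin(ang),
                           radius * (np.cos(ang) - math.cos(theta / 2.0))])
    # rotate so the chord lies on the x-axis starting at the origin
    pts -= pts[0]
    return pts


def _place(pts: np.ndarray, rng) -> np.ndarray:
    """Random rigid motion; all measurements are invariant to it."""
    th = rng.uniform(0.0, 2.0 * math.pi)
    rot = np.array([[math.cos(th), -math.sin(th)],
                    [math.sin(th), math.cos(th)]])
    return pts @ rot.T + rng.uniform(0.0, 2000.0, size=2)


def _ellipse_outline(area: float, ratio: float, n: int, noise: float,
                     rng) -> np.ndarray:
    a = math.sqrt(area * ratio / math.pi)
    b = a / ratio
    ang = np.linspace(0.0, 2.0 * math.pi, n, endpoint=False)
    r_noise = rng.normal(0.0, noise, size=n)
    x = (a + r_noise) * np.cos(ang)
    y = (b + r_noise * b / a) * np.sin(ang)
    return np.column_stack([x, y])


def _side_values(value: float, asym: float, noise_sd: float, rng):
    """Left/right um values around a specimen value with L-R offset."""
    half = math.log1p(asym) / 2.0
    left = value * math.exp(half + rng.normal(0.0, noise_sd))
    right = value * math.exp(-half + rng.normal(0.0, noise_sd))
    return left, right


def generate_population(truth: SyntheticTruth, *,
                        landmarks: bool = True) -> SyntheticPopulation:
    """Generate one complete seeded synthetic population.

    With ``landmarks=False`` only the measurement table is built (the
    same values, much faster) — useful for replicate studies that never
    touch the geometry layer.  The measurement table is identical either
    way for a given seed.
    """
    rng = np.random.default_rng(truth.seed)
    lm_rng = np.random.default_rng(np.random.SeedSequence(
        (truth.seed, 0x1a5d)))
    meta_rows, struct_rows, rows, sets = [], [], [], []

    def add_row(sid, species, sex, variable, side, value, side_known=True):
        rows.append(dict(specimen_id=sid, species=species, sex=sex,
                         variable=variable, side=side, value=value,
                         side_known=side_known))

    def add_set(sid, structure, side, points, roles=None, closed=False):
        image = f"{sid}_{structure}_{side}.jpg"
        struct_rows.append(dict(image=image, specimen_id=sid,
                                structure=structure, side=side))
        sets.append(LandmarkSet(
            specimen_id=sid, points=points, structure=structure, side=side,
            point_roles=roles or [], closed=closed, scale=1.0,
            meta={"IMAGE": image}))

    for sp in truth.species:
        for sex, n in (("F", sp.n_f), ("M", sp.n_m)):
            for k in range(n):
                sid = f"{sp.name}_{sex}{k:03d}"
                meta_rows.append(dict(specimen_id=sid, species=sp.name,
                                      sex=sex, sample_id=f"{sp.name}_S1",
                                      adult=True))
                is_male = sex == "M"
                s = rng.normal(
                    sp.mean_s_f + (sp.size_dimorphism / 2.0 if is_male else 0.0),
                    sp.s_sd)
                h_bc = rng.normal() if is_male else 0.0
                h_te = rng.normal() if is_male else 0.0

                # ---- valve (per side) ----
                log_area = 2.0 * s
                log_shape = rng.normal(
                    sp.shape_mean_f + (sp.shape_dimorphism if is_male else 0.0),
                    sp.shape_sd)
                if is_male:
                    log_area += (truth.gamma_bc_size * h_bc
                                 + truth.gamma_te_size * h_te)
                    log_shape += (truth.gamma_bc_shape * h_bc
                                  + truth.gamma_te_shape * h_te)
                for side, sgn in (("L", 1.0), ("R", -1.0)):
                    la = (log_area + sgn * truth.valve_area_asym / 2.0
                          + rng.normal(0.0, truth.valve_side_noise_sd))
                    lsh = (log_shape + sgn * truth.valve_shape_asym / 2.0
                           + rng.normal(0.0, truth.valve_side_noise_sd))
                    area, ratio = math.exp(la), math.exp(lsh)
                    length = math.sqrt(4.0 * area * ratio / math.pi)
                    height = length / ratio
                    add_row(sid, sp.name, sex, "valve_area", side, area)
                    add_row(sid, sp.name, sex, "valve_length", side, length)
                    add_row(sid, sp.name, sex, "valve_height", side, height)
                    if landmarks:
                        outline = _ellipse_outline(area, ratio,
                                                   truth.outline_points,
                                                   truth.outline_noise_um,
                                                   lm_rng)
                        add_set(sid, "valve_outline", side,
                                _place(outline, lm_rng),
                                roles=["semilandmark"] * len(outline),
                                closed=True)

                # ---- limbs and hemipenis (per side) ----
                for var, tr in truth.traits.items():
                    if tr.male_only and not is_male:
                        continue
                    logv = tr.alpha + tr.slope * s + rng.normal(0.0, tr.resid_sd)
                    if is_male and tr.latent == "bc":
                        logv += tr.latent_sd * h_bc
                    elif is_male and tr.latent == "te":
                        logv += tr.latent_sd * h_te
                    left, right = _side_values(math.exp(logv), tr.asym,
                                               truth.side_noise_sd, rng)
                    for side, value in (("L", left), ("R", right)):
                        add_row(sid, sp.name, sex, var, side, value)

                # ---- first walking leg ----
                log_w = (math.log(truth.wl1_width_ref)
                         + truth.wl1_slope * (s - _S_REF))
                log_li = (math.log(truth.wl1_linear_ref)
                          + truth.wl1_slope * (s - _S_REF))
                for side in ("L", "R"):
                    w = math.exp(log_w + rng.normal(0.0, truth.wl1_resid_sd))
                    li = math.exp(log_li + rng.normal(0.0, truth.wl1_resid_sd))
                    kappa = max(rng.normal(truth.wl1_curv_female,
                                           truth.wl1_curv_sd), 0.005)
                    if is_male and side == "R":
                        w *= 1.0 + max(rng.normal(truth.wl1_male_width_factor,
                                                  truth.wl1_male_width_sd), 0.0)
                        kappa = max(rng.normal(truth.wl1_curv_male_right,
                                               truth.wl1_curv_male_sd), 0.01)
                    curve = li * (1.0 + kappa)
                    add_row(sid, sp.name, sex, "1WL_W", side, w)
                    add_row(sid, sp.name, sex, "1WL_Lc", side, curve)
                    add_row(sid, sp.name, sex, "1WL_Lli", side, li)
                    if landmarks:
                        wpts = np.array([[0.0, 0.0], [0.0, w]])
                        arc = _arc_points(curve, li) + np.array([10.0, 0.0])
                        pts = _place(np.vstack([wpts, arc]), lm_rng)
                        add_set(sid, "WL1", side, pts,
                                roles=["landmark"] * 2
                                + ["semilandmark"] * len(arc))

    # ---- landmark sets for the scalar structures ----
    df = pd.DataFrame(rows)
    wide = df.pivot_table(index=["specimen_id", "species", "sex"],
                          columns=["variable", "side"], values="value",
                          aggfunc="first")
    for (sid, species, sex), row in (wide.iterrows() if landmarks else ()):
        for side in ("L", "R"):
            for struct, var in (("A1", "1A"), ("A2", "2A"),
                                ("Md", "Md"), ("WL3", "3WL")):
                v = row.get((var, side))
                if v is None or not np.isfinite(v):
                    continue
                pts = _place(np.array([[0.0, 0.0], [v, 0.0]]), lm_rng)
                add_set(sid, struct, side, pts, roles=["landmark"] * 2)
            if sex == "M":
                bc12 = row.get(("HemiBC12_L", side))
                bc34 = row.get(("HemiBC34_L", side))
                bcd = row.get(("HemiBCd_L", side))
                if all(v is not None and np.isfinite(v)
                       for v in (bc12, bc34, bcd)):
                    lm = np.array([[0.0, 0.0], [bc12, 0.0],
                                   [0.0, 60.0], [bc34, 60.0]])
                    arc = _arc_points(bcd, 0.92 * bcd) + np.array([0.0, 120.0])
                    pts = _place(np.vstack([lm, arc]), lm_rng)
                    add_set(sid, "HemiBC", side, pts,
                            roles=["landmark"] * 4 + ["semilandmark"] * len(arc))
                te_l = row.get(("HemiTE_L", side))
                te_a = row.get(("HemiTE_A", side))
                if te_l is not None and np.isfinite(te_l):
                    pts = _place(np.array([[0.0, 0.0], [te_l, 0.0]]), lm_rng)
                    add_set(sid, "HemiTE", side, pts, roles=["landmark"] * 2)
                if te_a is not None and np.isfinite(te_a):
                    outline = _ellipse_outline(te_a, 1.6, 60, 0.2, lm_rng)
                    add_set(sid, "HemiTE", side, _place(outline, lm_rng),
                            roles=["semilandmark"] * 60, closed=True)

    # ---- degrade the measurement table ----
    df = _degrade(df, truth, rng)
    meta = pd.DataFrame(meta_rows)
    return SyntheticPopulation(landmark_sets=sets, metadata=meta,
                               structures=pd.DataFrame(struct_rows),
                               measurements=df, truth=truth)


def _degrade(df: pd.DataFrame, truth: SyntheticTruth, rng) -> pd.DataFrame:
    """Apply MCAR missingness, single-side loss, and side-label loss."""
    drop: set[tuple[str, str, str]] = set()  # (specimen, variable, side)

    # whole-variable MCAR deletion within each composite dataset
    for variables, rate in ((SOFTPART_VARS, truth.missing_rate_softpart),
                            (HEMIBC_VARS, truth.missing_rate_hemibc)):
        sub = df[df["variable"].isin(variables)]
        mat = sub.pivot_table(index="specimen_id", columns="variable",
                              values="value", aggfunc="first")
        mat = mat.reindex(columns=list(variables))
        degraded = apply_missingness(mat.to_numpy(), rate,
                                     rng.integers(2 ** 31))
        killed = np.isnan(degraded) & ~np.isnan(mat.to_numpy())
        for i, sid in enumerate(mat.index):
            for j, var in enumerate(mat.columns):
                if killed[i, j]:
                    drop.add((sid, var, "L"))
                    drop.add((sid, var, "R"))

    # single-side loss on soft-part and hemipenis variables
    soft_vars = SOFTPART_VARS + HEMIBC_VARS + HEMITE_VARS
    pairs = df[df["variable"].isin(soft_vars)][
        ["specimen_id", "variable"]].drop_duplicates()
    for sid, var in pairs.itertuples(index=False):
        if (sid, var, "L") in drop:
            continue
        if rng.random() < truth.single_side_rate:
            side = "L" if rng.random() < 0.5 else "R"
            drop.add((sid, var, side))

    key = list(zip(df["specimen_id"], df["variable"], df["side"]))
    df = df.loc[[k not in drop for k in key]].reset_index(drop=True)

    # side-label loss on reference limbs: larger value relabelled left
    out = df.copy()
    limb = out["variable"].isin(SOFTPART_VARS)
    grouped = out[limb].groupby(["specimen_id", "variable"])
    for (sid, var), idx in grouped.groups.items():
        if len(idx) != 2 or rng.random() >= truth.unknown_side_rate:
            continue
        vals = out.loc[idx, "value"].to_numpy()
        big, small = (vals.max(), vals.min())
        sides = out.loc[idx, "side"].to_list()
        out.loc[idx, "value"] = [big if s == "L" else small for s in sides]
        out.loc[idx, "side_known"] = False
    return out


def _combine_large_n(left: np.ndarray, right: np.ndarray) -> np.ndarray:
    """Side combination at large n: average of left and the left value
    predicted from right by the population left-on-right regression."""
    b = np.cov(left, right)[0, 1] / np.var(right)
    a = left.mean() - b * right.mean()
    return (left + a + b * right) / 2.0


def _population_valves(truth: SyntheticTruth, sp: SpeciesTruth, n: int, rng):
    """Large-n per-side valve values for both sexes, pooled F-then-M."""
    is_male = np.repeat([False, True], n)
    s = rng.normal(sp.mean_s_f, sp.s_sd, 2 * n)
    s[is_male] += sp.size_dimorphism / 2.0
    h_bc = np.where(is_male, rng.normal(size=2 * n), 0.0)
    h_te = np.where(is_male, rng.normal(size=2 * n), 0.0)
    log_area = 2.0 * s + is_male * (truth.gamma_bc_size * h_bc
                                    + truth.gamma_te_size * h_te)
    log_shape = rng.normal(sp.shape_mean_f, sp.shape_sd, 2 * n) \
        + is_male * (sp.shape_dimorphism + truth.gamma_bc_shape * h_bc
                     + truth.gamma_te_shape * h_te)
    sides = {}
    for side, sgn in (("L", 1.0), ("R", -1.0)):
        la = (log_area + sgn * truth.valve_area_asym / 2.0
              + rng.normal(0.0, truth.valve_side_noise_sd, 2 * n))
        lsh = (log_shape + sgn * truth.valve_shape_asym / 2.0
               + rng.normal(0.0, truth.valve_side_noise_sd, 2 * n))
        area, ratio = np.exp(la), np.exp(lsh)
        length = np.sqrt(4.0 * area * ratio / math.pi)
        sides[side] = (area, length, length / ratio)
    area_c = _combine_large_n(sides["L"][0], sides["R"][0])
    len_c = _combine_large_n(sides["L"][1], sides["R"][1])
    hgt_c = _combine_large_n(sides["L"][2], sides["R"][2])
    return is_male, s, h_bc, h_te, np.log(area_c), np.log(len_c / hgt_c)


def population_dimorphism(truth: SyntheticTruth, species: str,
                          trait: str = "log_shape", n: int = 400_000,
                          seed: int = 54321) -> float:
    """Large-n M-F dimorphism as measured by the full procedure.

    This is the estimand of the pipeline's dimorphism estimator: it
    includes the side-combination step, whose regression predictions
    shrink sex extremes slightly toward the pooled mean, so the
    procedure's large-n value sits a fraction of a percent below the
    generative offset.  Monte-Carlo, vectorized over ``n`` per sex.
    """
    sp = next(s for s in truth.species if s.name == species)
    rng = np.random.default_rng(seed)
    is_male, _, _, _, log_size, log_shape = _population_valves(
        truth, sp, n, rng)
    v = log_size if trait == "log_size" else log_shape
    return float(v[is_male].mean() - v[~is_male].mean())


def population_allometry_slope(truth: SyntheticTruth, species: str,
                               trait: str = "1A", n: int = 400_000,
                               seed: int = 98765) -> float:
    """Large-n static-allometry slope under the full procedure (side
    combination and per-side measurement noise included)."""
    sp = next(s for s in truth.species if s.name == species)
    rng = np.random.default_rng(seed)
    is_male, s, h_bc, h_te, log_size, _ = _population_valves(
        truth, sp, n, rng)
    tr = truth.traits[trait]
    logv = tr.alpha + tr.slope * s + rng.normal(0.0, tr.resid_sd, 2 * n)
    if tr.latent == "bc":
        logv += tr.latent_sd * h_bc
    elif tr.latent == "te":
        logv += tr.latent_sd * h_te
    half = math.log1p(tr.asym) / 2.0
    left = np.exp(logv + half + rng.normal(0.0, truth.side_noise_sd, 2 * n))
    right = np.exp(logv - half + rng.normal(0.0, truth.side_noise_sd, 2 * n))
    keep = slice(None) if not tr.male_only else is_male
    y = np.log(_combine_large_n(left[keep], right[keep]))
    x = (np.log(np.sqrt(np.exp(log_size[keep]))) if trait != "HemiTE_A"
         else log_size[keep])
    return float(np.cov(y, x)[0, 1] / np.var(x))


def population_partial_r(truth: SyntheticTruth, species: str,
                         male_trait: str = "HemiBC",
                         valve_trait: str = "log_size",
                         n: int = 200_000, seed: int = 12345) -> float:
    """Monte-Carlo population value of a male-trait x valve partial r.

    Simulates the male latent layer of the generative model at large n
    (no measurement-table degradation) and computes the partial
    correlation given the exact soft-part composite.  Serves as the
    ground truth for parameter-recovery checks.
    """
    sp = next(s for s in truth.species if s.name == species)
    rng = np.random.default_rng(seed)
    s = rng.normal(sp.mean_s_f + sp.size_dimorphism / 2.0, sp.s_sd, n)
    h_bc, h_te = rng.normal(size=n), rng.normal(size=n)
    log_area = (2.0 * s + truth.gamma_bc_size * h_bc
                + truth.gamma_te_size * h_te
                + rng.normal(0.0, truth.valve_side_noise_sd, n))
    log_shape = (sp.shape_mean_f + sp.shape_dimorphism
                 + truth.gamma_bc_shape * h_bc + truth.gamma_te_shape * h_te
                 + rng.normal(0.0, sp.shape_sd, n))
    soft_logs = []
    for var in SOFTPART_VARS:
        tr = truth.traits[var]
        soft_logs.append(tr.alpha + tr.slope * s
                         + rng.normal(0.0, tr.resid_sd, n)
                         + rng.normal(0.0, truth.side_noise_sd / 2.0, n))
    softpart = np.mean(soft_logs, axis=0)
    if male_trait == "HemiBC":
        logs = []
        for var in HEMIBC_VARS:
            tr = truth.traits[var]
            logs.append(tr.alpha + tr.slope * s + tr.latent_sd * h_bc
                        + rng.normal(0.0, tr.resid_sd, n)
                        + rng.normal(0.0, truth.side_noise_sd / 2.0, n))
        male = np.mean(logs, axis=0)
    else:
        tr = truth.traits[male_trait]
        latent = h_bc if tr.latent == "bc" else h_te
        male = (tr.alpha + tr.slope * s + tr.latent_sd * latent
                + rng.normal(0.0, tr.resid_sd, n)
                + rng.normal(0.0, truth.side_noise_sd / 2.0, n))
    valve = log_area if valve_trait == "log_size" else log_shape
    x = np.column_stack([np.ones(n), softpart])
    res_m = male - x @ np.linalg.lstsq(x, male, rcond=None)[0]
    res_v = valve - x @ np.linalg.lstsq(x, valve, rcond=None)[0]
    return float(np.corrcoef(res_m, res_v)[0, 1])
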