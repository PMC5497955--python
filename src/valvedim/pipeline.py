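"""End-to-end orchestration: measurements -> combined sides -> imputation
-> composites -> dimorphism, asymmetry, allometry and partial-correlation
tables.

The stages mirror how the analysis is assembled from its parts:

1. descriptive valve statistics and valve left-right asymmetry;
2. limb and hemipenis directional asymmetry (side-known pairs only);
3. left-on-right regressions per species and side combination into one
   left-equivalent value per specimen and variable;
4. per-species, per-dataset MVN imputation of the two composite-trait
   matrices (soft-part reference limbs; basal-capsule supports) on the
   log scale, with missingness reports and Royston normality checks;
5. composite sizes, valve dimorphism (Welch t), female-centered
   deviation coordinates, static and evolutionary allometry, soft-part
   vs valve correlation, and the headline partial correlations.

Every random element (bootstrap-EM draws) descends from one root seed
through ``numpy.random.SeedSequence`` spawning, so a rerun with the
same inputs and seed reproduces every number exactly.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import stats as vstats
from .bilateral import (BilateralPair, IDENTITY_REGRESSION, combine_sides,
                        directional_asymmetry, fit_left_on_right,
                        walking_leg_indices)
from .impute import MVNImputer, missingness_report, royston_test
from .synthetic import HEMIBC_VARS, SOFTPART_VARS

__all__ = ["RunConfig", "AnalysisResult", "run_full_analysis",
           "compare_to_reference", "write_outputs"]

VALVE_VARS = ("valve_area", "valve_length", "valve_height")
HEMI_SINGLE = ("HemiBCd_L", "HemiTE_L", "HemiTE_A")
ALLOMETRY_TRAITS = ("1A", "2A", "Md", "3WL", "HemiBCd_L", "HemiTE_L",
                    "HemiTE_A")
MALE_TRAITS = ("HemiBC", "HemiTE_A", "HemiTE_L", "1WL_W", "1WL_L")


@dataclass
class RunConfig:
    """Analysis settings; serialized with every result bundle."""

    draws: int = 500
    seed: int = 0
    bootstrap_em: bool = True
    holm: bool = False
    species: list[str] | None = None  # optional filter
    log_note: str = "natural logarithm throughout"


@dataclass
class AnalysisResult:
    tables: dict[str, pd.DataFrame]
    statistics: dict[str, float]
    missingness: dict[str, dict]
    royston: dict[str, tuple[float, float]]
    manifest: dict = field(default_factory=dict)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, exc: Exception):
        super().__init__(f"stage '{stage}' failed: {exc}")
        self.stage = stage


def _pairs_frame(df: pd.DataFrame) -> pd.DataFrame:
    """One row per (specimen, variable): left/right values + side_known."""
    wide = df.pivot_table(index=["species", "sex", "specimen_id", "variable"],
                          columns="side", values="value", aggfunc="first")
    for side in ("L", "R"):
        if side not in wide.columns:
            wide[side] = np.nan
    known = df.groupby(["species", "sex", "specimen_id", "variable"])[
        "side_known"].all()
    wide["side_known"] = known
    return wide.reset_index()


def _to_pairs(pframe: pd.DataFrame) -> list[BilateralPair]:
    out = []
    for r in pframe.itertuples(index=False):
        l = None if pd.isna(r.L) else float(r.L)
        rt = None if pd.isna(r.R) else float(r.R)
        if l is None and rt is None:
            continue
        out.append(BilateralPair(specimen_id=r.specimen_id,
                                 variable=r.variable, left=l, right=rt,
                                 side_known=bool(r.side_known)))
    return out


def _combine_variable(pframe: pd.DataFrame, species: str, variable: str
                      ) -> pd.Series:
    """One left-equivalent value per specimen for one species-variable."""
    pairs = _to_pairs(pframe)
    complete = [p for p in pairs if p.complete and p.side_known]
    if len(complete) >= 3:
        reg = fit_left_on_right(pairs, species, variable)
    else:
        warnings.warn(f"{species}/{variable}: <3 complete pairs; identity "
                      "left-on-right regression used", stacklevel=2)
        reg = IDENTITY_REGRESSION
    return pd.Series({p.specimen_id: combine_sides(p, reg) for p in pairs},
                     name=variable)


def _asymmetry_tables(pairs_df: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for (species, sex, variable), sub in pairs_df.groupby(
            ["species", "sex", "variable"]):
        pairs = _to_pairs(sub)
        if not pairs:
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            s = directional_asymmetry(pairs, species, sex, variable)
        rows.append(asdict(s) | {"significant": s.significant})
    return pd.DataFrame(rows)


def run_full_analysis(measurements: pd.DataFrame,
                      config: RunConfig | None = None) -> AnalysisResult:
    """Run every stage on a tidy measurement table.

    ``measurements`` columns: specimen_id, species, sex, variable, side,
    value and optionally side_known.  Returns tables keyed
    ``valve_summary``, ``asymmetry``, ``side_regressions``, ``combined``,
    ``dimorphism``, ``deviations``, ``allometry_static``,
    ``allometry_evolutionary``, ``softpart_valve_correlation``,
    ``partial_correlations``, ``secondary_indices`` plus missingness
    reports, Royston p-values, a flat statistics dict and a manifest.
    """
    config = config or RunConfig()
    df = measurements.copy()
    if "side_known" not in df.columns:
        df["side_known"] = True
    if config.species:
        df = df[df["species"].isin(config.species)]
    seeds = iter(np.random.SeedSequence(config.seed).spawn(64))

    tables: dict[str, pd.DataFrame] = {}
    stats_flat: dict[str, float] = {}
    missing: dict[str, dict] = {}
    royston: dict[str, tuple[float, float]] = {}

    # ---- stage: bilateral asymmetry ----------------------------------
    try:
        pairs_df = _pairs_frame(df)
        tables["asymmetry"] = _asymmetry_tables(pairs_df)
    except Exception as exc:  # pragma: no cover - stage diagnostics
        raise PipelineError("asymmetry", exc) from exc

    # ---- stage: side regressions + combination -----------------------
    try:
        combined_frames, reg_rows = [], []
        soft_vars = SOFTPART_VARS + HEMIBC_VARS + ("HemiTE_L", "HemiTE_A")
        for species, sub in pairs_df.groupby("species"):
            cols = {}
            for variable in soft_vars + VALVE_VARS:
                psub = sub[sub["variable"] == variable]
                if not len(psub):
                    continue
                pairs = _to_pairs(psub)
                complete = [p for p in pairs if p.complete and p.side_known]
                if len(complete) >= 3:
                    reg = fit_left_on_right(pairs, species, variable)
                    reg_rows.append(asdict(reg))
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    cols[variable] = _combine_variable(psub, species, variable)
            frame = pd.DataFrame(cols)
            frame.insert(0, "species", species)
            sex = sub.drop_duplicates("specimen_id").set_index(
                "specimen_id")["sex"]
            frame.insert(1, "sex", sex.reindex(frame.index))
            combined_frames.append(frame)
        combined = pd.concat(combined_frames)
        combined.index.name = "specimen_id"
        tables["side_regressions"] = pd.DataFrame(reg_rows)
        if len(tables["side_regressions"]):
            stats_flat["left_on_right_r2_min"] = float(
                tables["side_regressions"]["r_squared"].min())
            stats_flat["left_on_right_r2_max"] = float(
                tables["side_regressions"]["r_squared"].max())
    except Exception as exc:
        raise PipelineError("combine_sides", exc) from exc

    # ---- stage: valve descriptives -----------------------------------
    try:
        combined["log_size"] = np.log(combined["valve_area"])
        combined["log_shape"] = np.log(combined["valve_length"]
                                       / combined["valve_height"])
        rows = []
        left = df[(df["side"] == "L") & df["variable"].isin(VALVE_VARS)]
        for (species, sex, variable), sub in left.groupby(
                ["species", "sex", "variable"]):
            v = sub["value"].to_numpy()
            rows.append(dict(species=species, sex=sex, variable=variable,
                             mean_left=float(v.mean()),
                             cv_left=vstats.coefficient_of_variation(v),
                             n=len(v)))
        tables["valve_summary"] = pd.DataFrame(rows)
    except Exception as exc:
        raise PipelineError("valve_summary", exc) from exc

    # ---- stage: imputation + composites ------------------------------
    try:
        composites = {}
        for dataset, variables in (("softpart", list(SOFTPART_VARS)),
                                   ("hemibc", list(HEMIBC_VARS))):
            parts = []
            for species, grp in combined.groupby("species"):
                sel = grp
                if dataset == "hemibc":
                    sel = grp[grp["sex"] == "M"]
                have = [v for v in variables if v in sel.columns]
                mat = np.log(sel[have].to_numpy(dtype=float))
                key = f"{dataset}_{species}"
                rep = missingness_report(mat, have, dataset=key)
                missing[key] = {"fraction_missing": rep.fraction_missing,
                                "per_variable": rep.per_variable}
                complete_rows = mat[~np.isnan(mat).any(axis=1)]
                if len(complete_rows) >= 4:
                    royston[key] = royston_test(complete_rows)
                if np.isnan(mat).any():
                    imputer = MVNImputer(
                        n_draws=config.draws,
                        seed=int(next(seeds).generate_state(1)[0] % (2 ** 31)),
                        bootstrap=config.bootstrap_em)
                    mat = imputer.fit_transform(mat, have)
                parts.append(pd.DataFrame(mat, index=sel.index, columns=have))
            composites[dataset] = pd.concat(parts)
        soft = composites["softpart"]
        combined["softpart_size"] = pd.Series(
            vstats.composite_softpart_size(soft["1A"], soft["2A"],
                                           soft["Md"], soft["3WL"]),
            index=soft.index).reindex(combined.index)
        bc = composites["hemibc"]
        combined["HemiBC"] = pd.Series(
            vstats.composite_hemibc(bc["HemiBCd_L"], bc["HemiBC12_L"],
                                    bc["HemiBC34_L"]),
            index=bc.index).reindex(combined.index)
        overall_soft = missingness_report(
            np.log(combined[list(SOFTPART_VARS)].to_numpy(dtype=float)),
            SOFTPART_VARS, dataset="softpart")
        stats_flat["missing_pct_softpart"] = overall_soft.fraction_missing
        male_bc = combined.loc[combined["sex"] == "M", list(HEMIBC_VARS)]
        stats_flat["missing_pct_hemibc"] = missingness_report(
            male_bc.to_numpy(dtype=float), HEMIBC_VARS,
            dataset="hemibc").fraction_missing
    except Exception as exc:
        raise PipelineError("imputation", exc) from exc

    # ---- stage: dimorphism + deviations ------------------------------
    try:
        rows, dev_frames = [], []
        for species, grp in combined.groupby("species"):
            fem = grp["sex"] == "F"
            for trait in ("log_size", "log_shape"):
                est = vstats.dimorphism(grp.loc[fem, trait],
                                        grp.loc[~fem, trait],
                                        species=species, trait=trait)
                rows.append(asdict(est))
                stats_flat[f"welch_t_{trait}_{species}"] = est.t
                stats_flat[f"dimorphism_{trait}_{species}"] = est.diff
            dsize, dshape = vstats.female_centered_deviations(
                grp["log_size"], grp["log_shape"], fem)
            dev_frames.append(pd.DataFrame(
                {"species": species, "sex": grp["sex"],
                 "d_log_size": dsize, "d_log_shape": dshape},
                index=grp.index))
        tables["dimorphism"] = pd.DataFrame(rows)
        tables["deviations"] = pd.concat(dev_frames)
    except Exception as exc:
        raise PipelineError("dimorphism", exc) from exc

    # ---- stage: secondary sexual indices -----------------------------
    try:
        rows = []
        wl = df[df["variable"].isin(("1WL_W", "1WL_Lc", "1WL_Lli"))]
        wide = wl.pivot_table(index="specimen_id",
                              columns=["variable", "side"], values="value",
                              aggfunc="first")
        info = df.drop_duplicates("specimen_id").set_index("specimen_id")
        for sid, r in wide.iterrows():
            need = [("1WL_W", "L"), ("1WL_W", "R"), ("1WL_Lc", "L"),
                    ("1WL_Lli", "L"), ("1WL_Lc", "R"), ("1WL_Lli", "R")]
            vals = [r.get(k, np.nan) for k in need]
            if any(pd.isna(v) for v in vals):
                continue
            idx = walking_leg_indices(sid, vals[0], vals[1], vals[2],
                                      vals[3], vals[4], vals[5])
            rows.append(dict(specimen_id=sid,
                             species=info.at[sid, "species"],
                             sex=info.at[sid, "sex"],
                             width_asym=idx.width_asym,
                             curvature_asym=idx.curvature_asym))
        sec = pd.DataFrame(rows)
        tables["secondary_indices"] = sec
        if len(sec):
            sec = sec.set_index("specimen_id")
            combined["1WL_W"] = sec["width_asym"].reindex(combined.index)
            combined["1WL_L"] = sec["curvature_asym"].reindex(combined.index)
    except Exception as exc:
        raise PipelineError("secondary_indices", exc) from exc

    # ---- stage: allometry --------------------------------------------
    try:
        rows = []
        for species, grp in combined.groupby("species"):
            for trait in ALLOMETRY_TRAITS:
                if trait not in grp.columns:
                    continue
                sel = grp
                if trait in HEMI_SINGLE or trait in HEMIBC_VARS:
                    sel = grp[grp["sex"] == "M"]
                sub = sel[[trait, "valve_area"]].dropna()
                if len(sub) < 4:
                    continue
                fit = vstats.static_allometry(
                    sub[trait], sub["valve_area"], species=species,
                    trait=trait, same_dimensionality=(trait == "HemiTE_A"))
                rows.append(asdict(fit))
                stats_flat[f"allometry_slope_{trait}_{species}"] = fit.slope
        tables["allometry_static"] = pd.DataFrame(rows)

        evo_rows = []
        males = combined[combined["sex"] == "M"]
        means = males.groupby("species")[
            [t for t in HEMI_SINGLE if t in males.columns]
            + ["valve_area"]].mean()
        if len(means) >= 3:
            for trait in HEMI_SINGLE:
                if trait not in means.columns:
                    continue
                fit = vstats.evolutionary_allometry(
                    means[trait], means["valve_area"], trait=trait,
                    same_dimensionality=(trait == "HemiTE_A"))
                evo_rows.append(asdict(fit))
        tables["allometry_evolutionary"] = pd.DataFrame(evo_rows)
    except Exception as exc:
        raise PipelineError("allometry", exc) from exc

    # ---- stage: soft-part vs valve correlation -----------------------
    try:
        rows = []
        sub = combined[["softpart_size", "log_size", "species"]].dropna()
        r, dfree, p = vstats.pearson_correlation(sub["softpart_size"],
                                                 sub["log_size"])
        rows.append(dict(species="all", r=r, df=dfree, p=p))
        stats_flat["softpart_valve_r_all"] = r
        for species, grp in sub.groupby("species"):
            r, dfree, p = vstats.pearson_correlation(grp["softpart_size"],
                                                     grp["log_size"])
            rows.append(dict(species=species, r=r, df=dfree, p=p))
            stats_flat[f"softpart_valve_r_{species}"] = r
        tables["softpart_valve_correlation"] = pd.DataFrame(rows)
    except Exception as exc:
        raise PipelineError("softpart_valve_correlation", exc) from exc

    # ---- stage: partial correlations ---------------------------------
    try:
        rows = []
        males = combined[combined["sex"] == "M"].copy()
        for t in ("HemiTE_A", "HemiTE_L"):
            if t in males.columns:
                males[t] = np.log(males[t])
        for species, grp in males.groupby("species"):
            for male_trait in MALE_TRAITS:
                if male_trait not in grp.columns:
                    continue
                for valve_trait in ("log_size", "log_shape"):
                    sub = grp[[male_trait, valve_trait,
                               "softpart_size"]].dropna()
                    if len(sub) < 4:
                        continue
                    res = vstats.partial_correlation(
                        sub[male_trait], sub[valve_trait],
                        sub["softpart_size"], species=species,
                        male_name=male_trait, valve_name=valve_trait)
                    rows.append(asdict(res) | {
                        "significant": bool(res.p < 0.05)})
                    stats_flat[f"partial_r_{male_trait}_{valve_trait}"
                               f"_{species}"] = res.r_p
        part = pd.DataFrame(rows)
        if config.holm and len(part):
            from statsmodels.stats.multitest import multipletests
            part["p_holm"] = multipletests(part["p"], method="holm")[1]
        tables["partial_correlations"] = part
    except Exception as exc:
        raise PipelineError("partial_correlations", exc) from exc

    tables["combined"] = combined.reset_index()
    digest = hashlib.sha256(
        pd.util.hash_pandas_object(
            df[["specimen_id", "variable", "side", "value"]]
            .sort_values(["specimen_id", "variable", "side"])
            .reset_index(drop=True)).to_numpy().tobytes()).hexdigest()
    manifest = {"seed": config.seed, "draws": config.draws,
                "bootstrap_em": config.bootstrap_em,
                "n_specimens": int(df["specimen_id"].nunique()),
                "input_sha256": digest, "log_note": config.log_note,
                "package": "valvedim 0.1.0"}
    return AnalysisResult(tables=tables, statistics=stats_flat,
                          missingness=missing, royston=royston,
                          manifest=manifest)


def compare_to_reference(statistics: dict[str, float],
                         reference: pd.DataFrame) -> pd.DataFrame:
    """Check computed statistics against printed reference values.

    ``reference`` columns: statistic, value, tolerance.  Unmatched
    statistic names are listed with ``matched=False``, not fatal.
    """
    rows = []
    for r in reference.itertuples(index=False):
        name = str(r.statistic)
        if name in statistics:
            dev = abs(statistics[name] - float(r.value))
            rows.append(dict(statistic=name, computed=statistics[name],
                             printed=float(r.value), abs_deviation=dev,
                             tolerance=float(r.tolerance),
                             passed=bool(dev <= float(r.tolerance)),
                             matched=True))
        else:
            rows.append(dict(statistic=name, computed=np.nan,
                             printed=float(r.value), abs_deviation=np.nan,
                             tolerance=float(r.tolerance), passed=False,
                             matched=False))
    return pd.DataFrame(rows)


def write_outputs(result: AnalysisResult, outdir) -> None:
    """Write all tables as CSV and the scalar outputs as JSON."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    for name, table in result.tables.items():
        table.to_csv(out / f"{name}.csv", index=False)
    payload = {"statistics": result.statistics,
               "missingness": result.missingness,
               "royston": {k: {"H": v[0], "p": v[1]}
                           for k, v in result.royston.items()},
               "manifest": result.manifest}
    (out / "summary.json").write_text(json.dumps(payload, indent=2))
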