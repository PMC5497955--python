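"""Reading and writing TPS landmark/outline files and measurement tables.

The TPS dialect handled here is the one emitted by tpsDig: records start
with ``LM=n`` followed by ``n`` coordinate lines, optionally followed by
``CURVES=k`` blocks (each with ``POINTS=m``) holding semilandmarks,
``OUTLINES=k`` blocks holding closed outlines, and trailing ``IMAGE=``,
``ID=`` and ``SCALE=`` keys.  Keys are case-insensitive.  Coordinates
are multiplied by SCALE into um on read.

Side and structure codes are not part of TPS files; they live in the
specimen metadata table and are joined onto landmark sets by ID/IMAGE.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "LandmarkSet",
    "SpecimenRecord",
    "TPSParseError",
    "read_tps",
    "write_tps",
    "read_measurement_table",
    "read_metadata",
    "measurements_to_wide",
]

STRUCTURES = (
    "valve_outline", "A1", "A2", "Md", "WL1", "WL3", "HemiBC", "HemiTE",
)
SPECIES = ("MEXI", "SALE", "TORO")
SEXES = ("M", "F")
SIDES = ("L", "R", "unknown")


class TPSParseError(ValueError):
    """Raised for malformed TPS content; message names the record."""


@dataclass
class LandmarkSet:
    """One digitized structure: ordered 2-D points in um.

    ``point_roles`` flags each point as ``landmark`` or ``semilandmark``;
    ``closed`` marks outlines that close implicitly onto the first point.
    ``scale`` is the um-per-digitizer-unit factor already applied to
    ``points``.  ``meta`` preserves any unrecognized TPS keys verbatim.
    """

    specimen_id: str
    points: np.ndarray
    structure: str = "unknown"
    side: str = "unknown"
    point_roles: list[str] = field(default_factory=list)
    closed: bool = False
    scale: float = 1.0
    meta: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValueError("points must be an (n, 2) array")
        if len(self.points) < 2:
            raise ValueError("a LandmarkSet needs >= 2 points")
        if self.closed and len(self.points) < 3:
            raise ValueError("a closed outline needs >= 3 points")
        if not np.all(np.isfinite(self.points)):
            raise ValueError("coordinates must be finite")
        if self.scale <= 0:
            raise ValueError("scale must be positive")
        if self.side not in SIDES:
            raise ValueError(f"side must be one of {SIDES}, got {self.side!r}")
        if not self.point_roles:
            self.point_roles = ["landmark"] * len(self.points)
        if len(self.point_roles) != len(self.points):
            raise ValueError("point_roles length must match points")


@dataclass(frozen=True)
class SpecimenRecord:
    """Metadata for one specimen; only adults enter the analysis."""

    specimen_id: str
    species: str
    sex: str
    sample_id: str = ""
    adult: bool = True

    def __post_init__(self) -> None:
        if self.species not in SPECIES:
            raise ValueError(f"unknown species {self.species!r}")
        if self.sex not in SEXES:
            raise ValueError(f"unknown sex {self.sex!r}")


_KEY_RE = re.compile(r"^\s*([A-Za-z]+)\s*=\s*(.*?)\s*$")
_NUM_RE = re.compile(r"^\s*[-+0-9.]")


def _coord(line: str, record: int) -> tuple[float, float]:
    parts = line.split()
    if len(parts) != 2:
        raise TPSParseError(f"record {record}: bad coordinate line {line!r}")
    try:
        return float(parts[0]), float(parts[1])
    except ValueError as exc:
        raise TPSParseError(f"record {record}: bad coordinate line {line!r}") from exc


def read_tps(path, *, default_scale: float | None = 1.0,
             outline_key: str = "OUTLINES") -> list[LandmarkSet]:
    """Parse a TPS file into LandmarkSets, coordinates in um.

    Each ``LM=`` record with landmarks (plus any CURVES semilandmarks)
    yields one set; each outline in an ``OUTLINES=`` block yields one
    closed set.  A record whose declared point count disagrees with the
    coordinate lines found raises :class:`TPSParseError` naming the
    record.  A record with no ``SCALE=`` uses ``default_scale`` with a
    warning (pass ``None`` to make a missing scale an error).

    ``outline_key`` lets files that digitize the valve as a CURVES block
    be treated as outlines: pass ``"CURVES"`` to close curve blocks.
    """
    lines = Path(path).read_text().splitlines()
    # group physical lines into records: each starts at an LM= line
    starts = [i for i, ln in enumerate(lines)
              if (m := _KEY_RE.match(ln)) and m.group(1).upper() == "LM"]
    if not starts:
        raise TPSParseError("no LM= records found")
    out: list[LandmarkSet] = []
    close_curves = outline_key.upper() == "CURVES"
    for rec_no, start in enumerate(starts, start=1):
        end = starts[rec_no] if rec_no < len(starts) else len(lines)
        chunk = [ln for ln in lines[start:end] if ln.strip()]
        i = 0
        n_lm = int(_KEY_RE.match(chunk[0]).group(2))
        i = 1
        landmarks: list[tuple[float, float]] = []
        while i < len(chunk) and not _KEY_RE.match(chunk[i]):
            landmarks.append(_coord(chunk[i], rec_no))
            i += 1
        if len(landmarks) != n_lm:
            raise TPSParseError(
                f"record {rec_no}: LM={n_lm} but {len(landmarks)} "
                f"coordinate lines found")
        curves: list[list[tuple[float, float]]] = []
        outlines: list[list[tuple[float, float]]] = []
        specimen_id, image, scale = "", "", None
        meta: dict[str, str] = {}
        while i < len(chunk):
            m = _KEY_RE.match(chunk[i])
            if m is None:
                raise TPSParseError(
                    f"record {rec_no}: unexpected line {chunk[i]!r}")
            key, val = m.group(1).upper(), m.group(2)
            i += 1
            if key in ("CURVES", "OUTLINES"):
                n_blocks = int(val)
                target = outlines if (key == "OUTLINES" or
                                      (key == "CURVES" and close_curves)) else curves
                for b in range(n_blocks):
                    mm = _KEY_RE.match(chunk[i]) if i < len(chunk) else None
                    if mm is None or mm.group(1).upper() != "POINTS":
                        raise TPSParseError(
                            f"record {rec_no}: {key} block {b + 1} missing POINTS=")
                    n_pts = int(mm.group(2))
                    i += 1
                    pts: list[tuple[float, float]] = []
                    while i < len(chunk) and not _KEY_RE.match(chunk[i]):
                        pts.append(_coord(chunk[i], rec_no))
                        i += 1
                    if len(pts) != n_pts:
                        raise TPSParseError(
                            f"record {rec_no}: POINTS={n_pts} but "
                            f"{len(pts)} coordinate lines found")
                    target.append(pts)
            elif key == "SCALE":
                scale = float(val)
            elif key == "ID":
                specimen_id = val
            elif key == "IMAGE":
                image = val
            else:
                meta[key] = val
        if scale is None:
            if default_scale is None:
                raise TPSParseError(f"record {rec_no}: missing SCALE=")
            warnings.warn(f"record {rec_no}: missing SCALE=, using "
                          f"{default_scale}", stacklevel=2)
            scale = default_scale
        sid = specimen_id or image or f"record_{rec_no}"
        if image:
            meta.setdefault("IMAGE", image)
        if landmarks or curves:
            pts = landmarks + [p for c in curves for p in c]
            roles = (["landmark"] * len(landmarks)
                     + ["semilandmark"] * (len(pts) - len(landmarks)))
            out.append(LandmarkSet(
                specimen_id=sid, points=np.asarray(pts) * scale,
                point_roles=roles, closed=False, scale=scale,
                meta=dict(meta)))
        for o in outlines:
            out.append(LandmarkSet(
                specimen_id=sid, points=np.asarray(o) * scale,
                point_roles=["semilandmark"] * len(o), closed=True,
                scale=scale, meta=dict(meta)))
    return out


def _fmt(x: float) -> str:
    return np.format_float_positional(x, precision=6, unique=False, trim="0")


def write_tps(sets: list[LandmarkSet], path) -> None:
    """Write LandmarkSets in the tpsDig dialect.

    Coordinates are emitted in digitizer units (um divided by each set's
    scale) together with ``SCALE=``, so read -> write -> read preserves
    um values.  Closed outlines go into an OUTLINES block with the first
    point not repeated (closure is implicit).
    """
    if not sets:
        raise ValueError("no LandmarkSets to write")
    lines: list[str] = []
    for s in sets:
        raw = s.points / s.scale
        lm_idx = [k for k, r in enumerate(s.point_roles) if r == "landmark"]
        sl_idx = [k for k, r in enumerate(s.point_roles) if r == "semilandmark"]
        if s.closed:
            lines.append("LM=0")
            lines.append("OUTLINES=1")
            lines.append(f"POINTS={len(raw)}")
            lines.extend(f"{_fmt(x)} {_fmt(y)}" for x, y in raw)
        else:
            lines.append(f"LM={len(lm_idx)}")
            lines.extend(f"{_fmt(raw[k, 0])} {_fmt(raw[k, 1])}" for k in lm_idx)
            if sl_idx:
                lines.append("CURVES=1")
                lines.append(f"POINTS={len(sl_idx)}")
                lines.extend(f"{_fmt(raw[k, 0])} {_fmt(raw[k, 1])}"
                             for k in sl_idx)
        for key, val in s.meta.items():
            if key.upper() not in ("SCALE", "ID"):
                lines.append(f"{key.upper()}={val}")
        lines.append(f"ID={s.specimen_id}")
        lines.append(f"SCALE={_fmt(s.scale)}")
    Path(path).write_text("\n".join(lines) + "\n")


_META_COLS = ("specimen_id", "species", "sex")
_TABLE_COLS = ("specimen_id", "species", "sex", "variable", "side", "value")


def read_metadata(path) -> pd.DataFrame:
    """Read the specimen metadata CSV (specimen_id, species, sex, ...)."""
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in _META_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"metadata is missing columns {missing}")
    _check_codes(df)
    if "adult" in df.columns:
        df["adult"] = df["adult"].astype(str).str.lower().isin(
            ("1", "true", "yes"))
    else:
        df["adult"] = True
    return df


def _check_codes(df: pd.DataFrame) -> None:
    bad_sp = df.loc[~df["species"].isin(SPECIES)]
    bad_sex = df.loc[~df["sex"].isin(SEXES)]
    problems = []
    if len(bad_sp):
        problems.append(f"unknown species codes in rows "
                        f"{bad_sp.index.tolist()}: "
                        f"{sorted(bad_sp['species'].unique())}")
    if len(bad_sex):
        problems.append(f"unknown sex codes in rows "
                        f"{bad_sex.index.tolist()}: "
                        f"{sorted(bad_sex['sex'].unique())}")
    if problems:
        raise ValueError("; ".join(problems))


def read_measurement_table(path) -> pd.DataFrame:
    """Read a long-format measurement table (CSV or XLSX) into tidy form.

    Expected columns: specimen_id, species, sex, variable, side, value.
    Lengths are in um, areas in um^2.  Blank cells and "NA" are missing.
    Duplicate (specimen_id, variable, side) rows are an integrity error.
    """
    path = Path(path)
    if path.suffix.lower() in (".xlsx", ".xlsm"):
        df = pd.read_excel(path, dtype={"value": str})
    else:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in _TABLE_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"measurement table is missing columns {missing}")
    side_known = (df["side_known"].astype(str).str.lower().isin(
        ("1", "true", "yes", "1.0")) if "side_known" in df.columns
        else pd.Series(True, index=df.index))
    df = df.loc[:, list(_TABLE_COLS)].copy()
    df["side_known"] = side_known
    for c in _TABLE_COLS[:-1]:
        df[c] = df[c].astype(str).str.strip()
    _check_codes(df)
    bad_side = df.loc[~df["side"].isin(SIDES)]
    if len(bad_side):
        raise ValueError(f"unknown side codes in rows "
                         f"{bad_side.index.tolist()}: "
                         f"{sorted(bad_side['side'].unique())}")
    dupes = df.duplicated(subset=["specimen_id", "variable", "side"], keep=False)
    if dupes.any():
        raise ValueError(
            f"duplicated (specimen, variable, side) rows: "
            f"{df.index[dupes].tolist()}")
    val = df["value"].astype(str).str.strip()
    val = val.where(~val.str.upper().isin(("", "NA", "NAN")), other=np.nan)
    df["value"] = pd.to_numeric(val, errors="raise")
    return df


def measurements_to_wide(df: pd.DataFrame) -> pd.DataFrame:
    """Pivot a tidy measurement table to specimen x (variable, side)."""
    wide = df.pivot_table(index="specimen_id", columns=["variable", "side"],
                          values="value", aggfunc="first")
    wide.columns = [f"{v}_{s}" for v, s in wide.columns]
    return wide
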