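"""Extract the scalar measurement table from digitized landmark sets.

Maps each structure code to its measured variables:

============  =======================================================
structure     variables
============  =======================================================
valve_outline valve_area (shoelace), valve_length / valve_height
              (full axes of the direct least-squares ellipse fit)
A1, A2, Md,   1A, 2A, Md, 3WL: distance between the two landmarks
WL3
HemiBC        HemiBC12_L = dist(lm1, lm2); HemiBC34_L = dist(lm3, lm4);
              HemiBCd_L = curve length of the semilandmark run
HemiTE        open 2-landmark set -> HemiTE_L; closed outline ->
              HemiTE_A
WL1           1WL_W = dist(lm1, lm2); 1WL_Lc = curve length and
              1WL_Lli = chord of the semilandmark run
============  =======================================================
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import geometry
from .tps import LandmarkSet

__all__ = ["extract_measurements"]

_LIMB_VAR = {"A1": "1A", "A2": "2A", "Md": "Md", "WL3": "3WL"}


def _measure_one(s: LandmarkSet) -> dict[str, float]:
    roles = np.asarray(s.point_roles)
    lm = s.points[roles == "landmark"]
    sl = s.points[roles == "semilandmark"]
    if s.structure == "valve_outline":
        vm = geometry.valve_measurement(s)
        return {"valve_area": vm.area, "valve_length": vm.length,
                "valve_height": vm.height}
    if s.structure in _LIMB_VAR:
        return {_LIMB_VAR[s.structure]: geometry.landmark_distance(lm, 0, 1)}
    if s.structure == "HemiBC":
        out = {}
        if len(lm) >= 4:
            out["HemiBC12_L"] = geometry.landmark_distance(lm, 0, 1)
            out["HemiBC34_L"] = geometry.landmark_distance(lm, 2, 3)
        if len(sl) >= 2:
            out["HemiBCd_L"] = geometry.polyline_length(sl)
        return out
    if s.structure == "HemiTE":
        if s.closed:
            return {"HemiTE_A": geometry.polygon_area(s)}
        return {"HemiTE_L": geometry.landmark_distance(lm, 0, 1)}
    if s.structure == "WL1":
        out = {}
        if len(lm) >= 2:
            out["1WL_W"] = geometry.landmark_distance(lm, 0, 1)
        if len(sl) >= 2:
            out["1WL_Lc"] = geometry.polyline_length(sl)
            out["1WL_Lli"] = geometry.chord_length(sl)
        return out
    raise ValueError(f"unknown structure code {s.structure!r}")


def extract_measurements(sets: list[LandmarkSet],
                         metadata: pd.DataFrame,
                         structures: pd.DataFrame | None = None
                         ) -> pd.DataFrame:
    """Measure every landmark set and return the tidy long table.

    ``metadata`` supplies species/sex per specimen (adults only are
    kept).  If ``structures`` is given (columns image, specimen_id,
    structure, side) it overrides each set's own structure/side fields,
    joined on the set's IMAGE metadata — the digitization files
    themselves do not know sides.
    """
    lookup = {}
    if structures is not None:
        lookup = {r.image: (r.specimen_id, r.structure, r.side)
                  for r in structures.itertuples(index=False)}
    meta = metadata.set_index("specimen_id")
    rows = []
    for s in sets:
        sid, structure, side = s.specimen_id, s.structure, s.side
        image = s.meta.get("IMAGE", "")
        if image in lookup:
            sid, structure, side = lookup[image]
        if sid not in meta.index or not bool(meta.at[sid, "adult"]):
            continue
        work = s if (structure == s.structure and side == s.side) else \
            LandmarkSet(specimen_id=sid, points=s.points, structure=structure,
                        side=side, point_roles=list(s.point_roles),
                        closed=s.closed, scale=s.scale, meta=dict(s.meta))
        for var, value in _measure_one(work).items():
            rows.append(dict(specimen_id=sid,
                             species=meta.at[sid, "species"],
                             sex=meta.at[sid, "sex"], variable=var,
                             side=side, value=float(value), side_known=True))
    return pd.DataFrame(rows)
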