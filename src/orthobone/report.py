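"""Peri-implant ROI selection and model-comparison tables.

Replicates the reporting structure of peri-implant FE studies: maxima and
volume-weighted averages of six scalar measures (equivalent / tensile /
compressive, each for stress and strain) over the cortical and cancellous
bone bands surrounding the implant, for each material model, with percent
change against the isotropic baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .mesh import TetMesh, element_geometry, region_tag

QUANTITIES = (
    "equivalent_stress", "tensile_stress", "compressive_stress",
    "equivalent_strain", "tensile_strain", "compressive_strain",
)


class ReportError(ValueError):
    pass


def select_roi(
    mesh: TetMesh,
    around,
    distance: float,
    restrict_to,
) -> np.ndarray:
    """Elements of region ``restrict_to`` whose centroid lies within
    ``distance`` mm of the anchor ``around``.

    ``around`` may be a node-set name, a face-set name, or a region tag/name;
    anchor points are the corresponding nodes.  Deterministic (KD-tree over
    fixed coordinates).
    """
    if distance <= 0:
        raise ReportError("distance must be positive")
    if isinstance(around, str) and around in mesh.node_sets:
        anchor = mesh.node_sets[around]
    elif isinstance(around, str) and around in mesh.face_sets:
        anchor = np.unique(mesh.face_sets[around])
    else:
        tag = region_tag(around)
        anchor = np.unique(mesh.tets[mesh.region == tag])
        if not len(anchor):
            raise ReportError(f"region {around!r} has no elements")
    pts = mesh.nodes[anchor]
    elems = mesh.elements_of(restrict_to)
    if not len(elems):
        raise ReportError(f"restrict_to region {restrict_to!r} has no elements")
    d, _ = cKDTree(pts).query(mesh.centroids(elems))
    roi = elems[d <= distance]
    if not len(roi):
        raise ReportError(
            f"empty ROI: no {restrict_to!r} centroid within {distance} mm of "
            f"{around!r}; increase the distance")
    return roi


@dataclass
class RegionSummary:
    """Max and volume-weighted average of the six measures over one ROI.

    ``stats[(quantity, 'max')]`` for compressive quantities is the most
    negative (signed) value; ``*_magnitude`` keys carry |value| for display.
    """

    model: str
    region: str
    n_elements: int
    total_volume: float
    roi_distance: float
    stats: Dict[str, float] = field(default_factory=dict)

    def get(self, quantity: str, stat: str) -> float:
        return self.stats[f"{quantity}:{stat}"]


def summarize(
    measures: Mapping[str, np.ndarray],
    mesh: TetMesh,
    roi: np.ndarray,
    model: str,
    region: str,
    roi_distance: float = float("nan"),
) -> RegionSummary:
    """Summarize per-element measures over an ROI.

    ``measures`` maps the six quantity names to per-element arrays (stress in
    MPa, strain dimensionless).  Maxima of compressive quantities are the most
    negative values; averages are volume weighted.
    """
    roi = np.asarray(roi)
    if not len(roi):
        raise ReportError("empty ROI")
    vol, _ = element_geometry(mesh)
    V = vol[roi]
    out = RegionSummary(model=model, region=region, n_elements=int(len(roi)),
                        total_volume=float(V.sum()), roi_distance=roi_distance)
    for q in QUANTITIES:
        if q not in measures:
            raise ReportError(f"measures missing quantity {q!r}")
        v = np.asarray(measures[q], dtype=float)[roi]
        if not np.isfinite(v).all():
            raise ReportError(f"measure {q!r} undefined on ROI elements")
        if q.startswith("compressive"):
            mx = float(v.min())                  # most negative
        else:
            mx = float(v.max())
        avg = float(np.sum(v * V) / V.sum())
        out.stats[f"{q}:max"] = mx
        out.stats[f"{q}:avg"] = avg
        out.stats[f"{q}:max_magnitude"] = abs(mx)
        out.stats[f"{q}:avg_magnitude"] = abs(avg)
    return out


def compare_models(
    summaries: Sequence[RegionSummary],
    baseline: str = "isotropic",
) -> pd.DataFrame:
    """Long-form comparison table with percent change against the baseline model.

    One row per (region, quantity, statistic); one value column per model and
    a ``pct_change_<model>`` column for every non-baseline model, computed
    from unrounded values as 100 (x - x_iso) / x_iso.
    """
    models = sorted({s.model for s in summaries})
    if baseline not in models:
        raise ReportError(f"baseline model {baseline!r} missing; have {models}")
    regions = sorted({s.region for s in summaries})
    lut = {(s.model, s.region): s for s in summaries}
    for m in models:
        for r in regions:
            if (m, r) not in lut:
                raise ReportError(f"missing summary for model {m!r}, region {r!r}")

    rows: List[dict] = []
    for r in regions:
        for q in QUANTITIES:
            for stat in ("max", "avg"):
                row = {"region": r, "quantity": q, "statistic": stat}
                base = lut[(baseline, r)].get(q, stat)
                for m in models:
                    val = lut[(m, r)].get(q, stat)
                    row[m] = val
                    if m != baseline:
                        row[f"pct_change_{m}"] = (
                            100.0 * (val - base) / base if base != 0 else np.nan)
                rows.append(row)
    return pd.DataFrame(rows)


def write_comparison_csv(df: pd.DataFrame, path, metadata: Mapping[str, str] | None = None) -> None:
    """Write the comparison table with run metadata as leading comment lines."""
    lines = [f"# {k} = {v}" for k, v in (metadata or {}).items()]
    body = df.to_csv(index=False, float_format="%.10g")
    with open(path, "w") as fh:
        if lines:
            fh.write("\n".join(lines) + "\n")
        fh.write(body)
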