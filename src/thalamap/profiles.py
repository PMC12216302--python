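"""Connectivity fraction/density normalization and 2D hierarchical clustering.

Per case: fraction f_i = count_i / sum(counts) (shares summing to 1), and
density d_i = (f_i / area_i) / max_j(f_j / area_j) (peak exactly 1).  Case x
ROI density tables are clustered agglomeratively on rows and columns
independently for heatmap ordering.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

__all__ = [
    "CaseProjectionTable",
    "connectivity_fraction",
    "connectivity_density",
    "hierarchical_cluster",
    "ClusterResult",
]


def connectivity_fraction(roi_counts: Mapping[str, float]) -> dict[str, float]:
    """Per-ROI share of the case's total labeled signal; sums to 1."""
    counts = {k: float(v) for k, v in roi_counts.items()}
    if any(v < 0 for v in counts.values()):
        raise ValueError("counts must be non-negative")
    total = sum(counts.values())
    if total <= 0:
        raise ValueError("all counts are zero")
    return {k: v / total for k, v in counts.items()}


def connectivity_density(
    fractions: Mapping[str, float], roi_areas: Mapping[str, float]
) -> dict[str, float]:
    """Fraction per unit ROI area, rescaled so the maximum density is 1."""
    raw: dict[str, float] = {}
    for roi, f in fractions.items():
        area = roi_areas.get(roi)
        if area is None or area <= 0:
            if f > 0:
                raise ValueError(
                    f"ROI {roi!r} has fraction {f} but no positive area"
                )
            continue
        raw[roi] = float(f) / float(area)
    if not raw:
        raise ValueError("no ROI with a positive area")
    peak = max(raw.values())
    if peak <= 0:
        return {k: 0.0 for k in raw}
    return {k: v / peak for k, v in raw.items()}


@dataclass
class CaseProjectionTable:
    """Per-case ROI counts with derived fraction and density vectors."""

    case_id: str
    roi_counts: dict[str, float]
    roi_areas: dict[str, float]
    fractions: dict[str, float] = field(init=False)
    densities: dict[str, float] = field(init=False)

    def __post_init__(self) -> None:
        counts = dict(self.roi_counts)
        areas = dict(self.roi_areas)
        dropped = [
            roi
            for roi in counts
            if counts[roi] == 0 and areas.get(roi, 0) <= 0
        ]
        if dropped:
            warnings.warn(
                f"case {self.case_id!r}: dropping zero-count, zero-area "
                f"ROIs {dropped}",
                stacklevel=2,
            )
            for roi in dropped:
                counts.pop(roi)
                areas.pop(roi, None)
        self.roi_counts = counts
        self.roi_areas = areas
        self.fractions = connectivity_fraction(counts)
        self.densities = connectivity_density(self.fractions, areas)


@dataclass
class ClusterResult:
    row_order: list
    col_order: list
    row_linkage: np.ndarray | None
    col_linkage: np.ndarray | None


def _axis_cluster(data: np.ndarray, linkage: str, metric: str):
    """Linkage + deterministic leaf order along one axis; falls back to
    Euclidean when the requested metric is degenerate (constant rows) and to
    input order when all pairwise distances vanish."""
    if data.shape[0] < 2:
        return list(range(data.shape[0])), None
    dist = pdist(data, metric=metric)
    if not np.all(np.isfinite(dist)):
        dist = pdist(data, metric="euclidean")
    if np.allclose(dist, 0.0):
        return list(range(data.shape[0])), None
    link = hierarchy.linkage(dist, method=linkage)
    return list(hierarchy.leaves_list(link)), link


def hierarchical_cluster(
    density_table: pd.DataFrame,
    linkage: str = "average",
    metric: str = "correlation",
) -> ClusterResult:
    """Agglomerative 2D clustering of a cases x ROIs table.

    Rows and columns are clustered independently; default average linkage on
    correlation distance.  Returns the reordered labels plus both linkage
    trees (None where clustering degenerates).
    """
    if density_table.shape[0] < 2 or density_table.shape[1] < 2:
        raise ValueError("need at least a 2 x 2 table")
    data = density_table.to_numpy(dtype=float)
    if not np.all(np.isfinite(data)):
        raise ValueError("table contains non-finite values")
    row_idx, row_link = _axis_cluster(data, linkage, metric)
    col_idx, col_link = _axis_cluster(data.T, linkage, metric)
    return ClusterResult(
        row_order=[density_table.index[i] for i in row_idx],
        col_order=[density_table.columns[i] for i in col_idx],
        row_linkage=row_link,
        col_linkage=col_link,
    )
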