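"""Center-tropism statistics for dendritic arbors.

Each ~1 µm compartment of a resampled arbor is compared against its local
core vector — the straight line from the compartment's origin to the nucleus
center.  The per-neuron summary is the unweighted mean angular deviation
(radians, [0, pi]); an acute mean indicates an arbor oriented toward the
center.  A second statistic measures the length fraction of the arbor lying
closer to the center than the soma.  Somas are classified edge/non-edge from
their position relative to the nucleus boundary.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import LineString, Point, Polygon

from .stats import StatResult, pearson_correlation
from .swc import CompartmentSeries, NeuronReconstruction, resample_compartments

__all__ = [
    "RAD_TO_DEG",
    "NucleusGeometry",
    "TropismProfile",
    "compartment_deviation",
    "average_angular_deviation",
    "proportion_closer_than_soma",
    "classify_edge",
    "tropism_profile",
    "deviation_vs_distance",
    "tropism_frame",
]

#: Degrees per radian as used in all reports (prints as 57.3).
RAD_TO_DEG = 180.0 / math.pi

_EPS = 1e-9


@dataclass
class NucleusGeometry:
    """Nucleus center and (optional) boundary used for edge classification.

    ``boundary`` is a closed polygon in the section (x, y) plane, vertices in
    µm.  ``edge_threshold`` is either a fraction of the local center-to-
    boundary radius (``threshold_kind="fraction"``, default 0.2) or an
    absolute distance in µm (``threshold_kind="um"``).  Without a boundary, a
    spherical radius model ``radius_um`` may be supplied instead.
    """

    center: np.ndarray
    boundary: np.ndarray | None = None
    edge_threshold: float = 0.2
    threshold_kind: str = "fraction"
    radius_um: float | None = None

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float)
        if not np.all(np.isfinite(self.center)):
            raise ValueError("geometry center must be finite")
        if self.boundary is not None:
            self.boundary = np.asarray(self.boundary, dtype=float)
            poly = Polygon(self.boundary)
            if not poly.contains(Point(self.center[:2])):
                raise ValueError("center must lie inside the boundary polygon")
        if self.threshold_kind not in ("fraction", "um"):
            raise ValueError(f"unknown threshold_kind {self.threshold_kind!r}")

    @classmethod
    def from_json(cls, path: str | Path) -> "NucleusGeometry":
        data = json.loads(Path(path).read_text())
        return cls(
            center=np.asarray(data["center"], dtype=float),
            boundary=(
                np.asarray(data["boundary"], dtype=float)
                if data.get("boundary") is not None
                else None
            ),
            edge_threshold=float(data.get("edge_threshold", 0.2)),
            threshold_kind=data.get("threshold_kind", "fraction"),
            radius_um=data.get("radius_um"),
        )

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {
            "center": list(map(float, self.center)),
            "boundary": (
                [[float(x), float(y)] for x, y in self.boundary]
                if self.boundary is not None
                else None
            ),
            "edge_threshold": self.edge_threshold,
            "threshold_kind": self.threshold_kind,
            "radius_um": self.radius_um,
        }
        path.write_text(json.dumps(payload, indent=1))
        return path


@dataclass
class TropismProfile:
    neuron_label: str
    soma_center_distance: float
    average_angular_deviation: float
    proportion_closer: float
    edge_class: str
    n_compartments: int = 0
    n_excluded: int = 0


def compartment_deviation(
    origin: np.ndarray, endpoint: np.ndarray, center: np.ndarray
) -> float:
    """Angle (radians) between the compartment vector and its local core vector.

    The local core vector points from the compartment origin to the nucleus
    center.  Returns NaN when the origin coincides with the center (the core
    vector is undefined there); callers exclude those compartments.
    """
    v = np.asarray(endpoint, float) - np.asarray(origin, float)
    core = np.asarray(center, float) - np.asarray(origin, float)
    nv = np.linalg.norm(v)
    nc = np.linalg.norm(core)
    if nc < _EPS or nv < _EPS:
        return float("nan")
    cosang = float(v @ core) / (nv * nc)
    return float(math.acos(min(1.0, max(-1.0, cosang))))


def _deviations(series: CompartmentSeries, center: np.ndarray, planar: bool):
    center = np.asarray(center, dtype=float)
    out = []
    excluded = 0
    for c in series:
        o, e = c.origin, c.endpoint
        if planar:
            o = np.array([o[0], o[1], 0.0])
            e = np.array([e[0], e[1], 0.0])
            ctr = np.array([center[0], center[1], 0.0])
        else:
            ctr = center
        dev = compartment_deviation(o, e, ctr)
        if math.isnan(dev):
            excluded += 1
        else:
            out.append((dev, c.length))
    return out, excluded


def average_angular_deviation(
    series: CompartmentSeries,
    center: np.ndarray,
    weighted: bool = False,
    planar: bool = False,
) -> float:
    """Mean angular deviation over all (non-degenerate) compartments.

    Unweighted by default, matching averaging "across all compartments" of a
    ~1 µm resampled arbor; ``weighted=True`` weights by compartment length.
    """
    devs, excluded = _deviations(series, center, planar)
    if not devs:
        raise ValueError(
            f"no usable compartments ({excluded} excluded at the center)"
        )
    angles = np.array([d for d, _ in devs])
    if weighted:
        lengths = np.array([l for _, l in devs])
        return float(np.average(angles, weights=lengths))
    return float(angles.mean())


def proportion_closer_than_soma(
    series: CompartmentSeries, soma: np.ndarray, center: np.ndarray
) -> float:
    """Length fraction of the arbor lying closer to the center than the soma.

    A compartment counts as closer when its midpoint-to-center distance is
    strictly below the soma-to-center distance; contributions are weighted by
    compartment length.
    """
    soma = np.asarray(soma, float)
    center = np.asarray(center, float)
    soma_dist = float(np.linalg.norm(soma - center))
    total = series.total_length
    if total <= 0:
        raise ValueError("series has zero total length")
    closer = sum(
        c.length
        for c in series
        if float(np.linalg.norm(c.midpoint - center)) < soma_dist
    )
    return float(closer / total)


def _local_radius(geometry: NucleusGeometry, direction: np.ndarray) -> float:
    """Center-to-boundary distance along a 2D ray from the center."""
    if geometry.boundary is None:
        if geometry.radius_um is None:
            raise ValueError(
                "edge classification needs a boundary polygon or radius_um"
            )
        return float(geometry.radius_um)
    c2 = geometry.center[:2]
    span = float(np.abs(geometry.boundary - c2).max()) * 4.0 + 1.0
    ray = LineString([tuple(c2), tuple(c2 + direction * span)])
    hit = ray.intersection(Polygon(geometry.boundary).exterior)
    if hit.is_empty:
        raise ValueError("ray from center does not reach the boundary")
    origin = Point(c2)
    if hit.geom_type == "Point":
        return float(origin.distance(hit))
    return float(min(origin.distance(g) for g in getattr(hit, "geoms", [hit])))


def classify_edge(soma: np.ndarray, geometry: NucleusGeometry) -> str:
    """Classify a soma as ``"edge"`` or ``"non-edge"``.

    A soma is edge when its distance to the boundary along the center→soma
    ray is at most the threshold (default 20% of the local radius).  Somas on
    or outside the boundary classify as edge (outside additionally warns).
    """
    soma = np.asarray(soma, dtype=float)
    offset = soma[:2] - geometry.center[:2]
    dist = float(np.linalg.norm(offset))
    if dist < _EPS:
        return "non-edge"
    radius = _local_radius(geometry, offset / dist)
    if geometry.boundary is not None and not Polygon(geometry.boundary).covers(
        Point(soma[:2])
    ):
        warnings.warn(
            f"soma at {soma[:2]} lies outside the nucleus boundary; "
            "classifying as edge",
            stacklevel=2,
        )
        return "edge"
    margin = (
        geometry.edge_threshold * radius
        if geometry.threshold_kind == "fraction"
        else geometry.edge_threshold
    )
    return "edge" if radius - dist <= margin else "non-edge"


def tropism_profile(
    neuron: NeuronReconstruction,
    geometry: NucleusGeometry,
    step_um: float = 1.0,
    weighted: bool = False,
    planar: bool = False,
) -> TropismProfile:
    """Compute the full per-neuron tropism summary."""
    series = resample_compartments(neuron, step_um=step_um)
    soma = neuron.soma_position
    devs, excluded = _deviations(series, geometry.center, planar)
    if not devs:
        raise ValueError(f"neuron {neuron.label!r}: all compartments excluded")
    angles = np.array([d for d, _ in devs])
    if weighted:
        mean_dev = float(np.average(angles, weights=[l for _, l in devs]))
    else:
        mean_dev = float(angles.mean())
    return TropismProfile(
        neuron_label=neuron.label,
        soma_center_distance=float(np.linalg.norm(soma - geometry.center)),
        average_angular_deviation=mean_dev,
        proportion_closer=proportion_closer_than_soma(
            series, soma, geometry.center
        ),
        edge_class=classify_edge(soma, geometry),
        n_compartments=len(series),
        n_excluded=excluded,
    )


def deviation_vs_distance(profiles) -> StatResult:
    """Pearson correlation of soma-center distance vs mean angular deviation."""
    profiles = list(profiles)
    if len(profiles) < 3:
        raise ValueError("need at least 3 profiles")
    x = [p.soma_center_distance for p in profiles]
    y = [p.average_angular_deviation for p in profiles]
    return pearson_correlation(x, y)


def tropism_frame(profiles) -> pd.DataFrame:
    """CSV-ready table; deviations reported in both radians and degrees."""
    rows = [
        {
            "neuron_label": p.neuron_label,
            "soma_center_distance": p.soma_center_distance,
            "deviation_rad": p.average_angular_deviation,
            "deviation_deg": round(p.average_angular_deviation * RAD_TO_DEG, 4),
            "proportion_closer": p.proportion_closer,
            "edge_class": p.edge_class,
        }
        for p in profiles
    ]
    return pd.DataFrame(rows)
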