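"""Injection-by-grid matrices and connectional-domain detection.

Tracer label (binary masks for anterograde axon coverage, point lists for
retrograde cell counts) is tabulated into square pixel grids (default
105 x 105 px at 0.6 µm/px, i.e. ~63 µm per side).  Per-injection rows are
max-scaled to make the two tracer quantities commensurate, stacked into one
matrix, and communities are found by Louvain modularity maximization on the
weighted bipartite injection/grid graph (default resolution 0.75).
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "GridSpec",
    "InjectionGridRow",
    "ConnectivityGridMatrix",
    "DomainPartition",
    "tabulate_grid",
    "aggregate_matrix",
    "detect_domains",
    "reorder_matrix",
    "render_domain_map",
    "grid_label",
    "parse_grid_label",
]

_GRID_RE = re.compile(r"^r(\d+)c(\d+)$")


def grid_label(row: int, col: int) -> str:
    return f"r{row}c{col}"


def parse_grid_label(label: str) -> tuple[int, int]:
    m = _GRID_RE.match(label)
    if not m:
        raise ValueError(f"not a grid label: {label!r}")
    return int(m.group(1)), int(m.group(2))


@dataclass
class GridSpec:
    """Square-grid geometry over the section image (row-major, 0-based)."""

    grid_px: int = 105
    pixel_um: float = 0.6
    origin: tuple[int, int] = (0, 0)
    nucleus_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.grid_px <= 0:
            raise ValueError("grid_px must be positive")
        if self.pixel_um <= 0:
            raise ValueError("pixel_um must be positive")

    @property
    def grid_um(self) -> float:
        """Grid side length in µm (105 px at 0.6 µm/px -> 63 µm)."""
        return self.grid_px * self.pixel_um

    def compatible(self, other: "GridSpec") -> bool:
        return (
            self.grid_px == other.grid_px
            and self.pixel_um == other.pixel_um
            and self.origin == other.origin
        )

    def valid_grids(self, shape_px: tuple[int, int]) -> set[tuple[int, int]] | None:
        """Grid indices intersecting the nucleus mask (None = unrestricted)."""
        if self.nucleus_mask is None:
            return None
        valid: set[tuple[int, int]] = set()
        mask = np.asarray(self.nucleus_mask, dtype=bool)
        n_rows = -(-mask.shape[0] // self.grid_px)
        n_cols = -(-mask.shape[1] // self.grid_px)
        for r in range(n_rows):
            for c in range(n_cols):
                block = mask[
                    r * self.grid_px : (r + 1) * self.grid_px,
                    c * self.grid_px : (c + 1) * self.grid_px,
                ]
                if block.any():
                    valid.add((r + self.origin[0], c + self.origin[1]))
        return valid


@dataclass
class InjectionGridRow:
    """Per-injection grid quantities.

    Anterograde rows hold percent-of-grid-pixels-labeled in [0, 100];
    retrograde rows hold non-negative cell counts.
    """

    injection_id: str
    tracer_kind: str
    values: dict[tuple[int, int], float]
    spec: GridSpec = field(default_factory=GridSpec)

    def __post_init__(self) -> None:
        if self.tracer_kind not in ("anterograde", "retrograde"):
            raise ValueError(f"unknown tracer kind {self.tracer_kind!r}")
        for idx, v in self.values.items():
            if v < 0:
                raise ValueError(f"negative quantity at grid {idx}")
            if self.tracer_kind == "anterograde" and v > 100.0 + 1e-9:
                raise ValueError(
                    f"anterograde coverage {v} > 100% at grid {idx}"
                )


def tabulate_grid(label, spec: GridSpec, kind: str) -> InjectionGridRow:
    """Tabulate segmented label into per-grid quantities.

    ``label`` is a 2D binary mask (anterograde: percent pixel coverage per
    grid) or an (n, 2) array of (x_px, y_px) cell coordinates (retrograde:
    cells per grid).  Grids outside the nucleus mask are dropped.  An empty
    label produces an all-zero row with a warning.
    """
    values: dict[tuple[int, int], float] = {}
    if kind == "anterograde":
        mask = np.asarray(label, dtype=bool)
        if mask.ndim != 2:
            raise ValueError("anterograde label must be a 2D mask")
        valid = spec.valid_grids(mask.shape)
        g = spec.grid_px
        area = float(g * g)
        n_rows = -(-mask.shape[0] // g)
        n_cols = -(-mask.shape[1] // g)
        for r in range(n_rows):
            for c in range(n_cols):
                idx = (r + spec.origin[0], c + spec.origin[1])
                if valid is not None and idx not in valid:
                    continue
                count = int(mask[r * g : (r + 1) * g, c * g : (c + 1) * g].sum())
                values[idx] = 100.0 * count / area
    elif kind == "retrograde":
        pts = np.asarray(label, dtype=float).reshape(-1, 2)
        valid = spec.valid_grids((0, 0))
        for x_px, y_px in pts:
            idx = (
                int(y_px) // spec.grid_px + spec.origin[0],
                int(x_px) // spec.grid_px + spec.origin[1],
            )
            if valid is not None and idx not in valid:
                continue
            values[idx] = values.get(idx, 0.0) + 1.0
    else:
        raise ValueError(f"unknown tracer kind {kind!r}")
    if not values or all(v == 0 for v in values.values()):
        warnings.warn("empty label input: all-zero grid row", stacklevel=2)
    return InjectionGridRow("unnamed", kind, values, spec)


@dataclass
class ConnectivityGridMatrix:
    """Injections x grid-cells matrix after per-row max scaling."""

    frame: pd.DataFrame
    grid: GridSpec
    zero_columns: list[str] = field(default_factory=list)

    @property
    def injections(self) -> list[str]:
        return list(self.frame.index)

    @property
    def grid_columns(self) -> list[str]:
        return list(self.frame.columns)

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index_label="injection_id")

    @classmethod
    def from_csv(cls, path, grid: GridSpec | None = None):
        frame = pd.read_csv(path, index_col=0)
        zero = [c for c in frame.columns if (frame[c] == 0).all()]
        return cls(frame, grid or GridSpec(), zero)


def aggregate_matrix(rows) -> ConnectivityGridMatrix:
    """Stack injection rows into one matrix, rescaling each row by its max.

    The per-row scaling makes anterograde percentages and retrograde counts
    commensurate in [0, 1].  All-zero rows are dropped with a warning;
    all-zero columns are retained but flagged.
    """
    rows = list(rows)
    if not rows:
        raise ValueError("no injection rows supplied")
    spec = rows[0].spec
    for r in rows:
        if not r.spec.compatible(spec):
            raise ValueError(
                f"injection {r.injection_id!r} uses an inconsistent GridSpec"
            )
    all_grids = sorted({g for r in rows for g in r.values})
    columns = [grid_label(*g) for g in all_grids]
    data = {}
    for r in rows:
        vec = np.array([r.values.get(g, 0.0) for g in all_grids], dtype=float)
        peak = vec.max() if vec.size else 0.0
        if peak <= 0:
            warnings.warn(
                f"dropping all-zero injection row {r.injection_id!r}",
                stacklevel=2,
            )
            continue
        data[r.injection_id] = vec / peak
    if not data:
        raise ValueError("all injection rows are zero")
    frame = pd.DataFrame.from_dict(data, orient="index", columns=columns)
    zero = [c for c in frame.columns if (frame[c] == 0).all()]
    return ConnectivityGridMatrix(frame, spec, zero)


@dataclass
class DomainPartition:
    """Louvain community assignment over injections and grid cells."""

    community_of: dict[str, int]
    gamma: float
    modularity: float
    seed: int

    def injection_communities(self) -> dict[str, int]:
        return {
            k.removeprefix("inj:"): v
            for k, v in self.community_of.items()
            if k.startswith("inj:")
        }

    def grid_communities(self) -> dict[str, int]:
        return {
            k.removeprefix("grid:"): v
            for k, v in self.community_of.items()
            if k.startswith("grid:")
        }

    def domains(self) -> list[int]:
        """Community ids that contain at least one grid cell."""
        return sorted(set(self.grid_communities().values()))


def _bipartite_graph(matrix: ConnectivityGridMatrix) -> nx.Graph:
    """Weighted bipartite graph; nodes added in sorted order so the result
    is invariant to row/column permutations of the input matrix."""
    graph = nx.Graph()
    inj_nodes = sorted(f"inj:{i}" for i in matrix.injections)
    grid_nodes = sorted(f"grid:{c}" for c in matrix.grid_columns)
    graph.add_nodes_from(inj_nodes, bipartite=0)
    graph.add_nodes_from(grid_nodes, bipartite=1)
    for inj in sorted(matrix.injections):
        row = matrix.frame.loc[inj]
        for col in sorted(matrix.grid_columns):
            w = float(row[col])
            if w > 0:
                graph.add_edge(f"inj:{inj}", f"grid:{col}", weight=w)
    return graph


def detect_domains(
    matrix: ConnectivityGridMatrix, gamma: float = 0.75, seed: int = 0
) -> DomainPartition:
    """Louvain modularity maximization on the bipartite injection/grid graph.

    Deterministic given ``seed``.  Communities containing at least one grid
    cell define connectional domains.  Community ids are renumbered by the
    lexicographically smallest member so labels are stable across runs.
    """
    values = matrix.frame.to_numpy()
    if values.size == 0 or not np.any(values > 0):
        raise ValueError("all-zero matrix: nothing to partition")
    if np.any(values < 0):
        raise ValueError("matrix must be non-negative")
    graph = _bipartite_graph(matrix)
    communities = nx.community.louvain_communities(
        graph, weight="weight", resolution=gamma, seed=seed
    )
    communities = sorted(communities, key=lambda c: min(c))
    score = nx.community.modularity(
        graph, communities, weight="weight", resolution=gamma
    )
    community_of = {
        node: cid for cid, members in enumerate(communities) for node in members
    }
    return DomainPartition(community_of, gamma, float(score), seed)


def reorder_matrix(
    matrix: ConnectivityGridMatrix, partition: DomainPartition
) -> ConnectivityGridMatrix:
    """Permute rows/columns so same-community entries sit contiguously."""
    inj_comm = partition.injection_communities()
    grid_comm = partition.grid_communities()
    missing = (set(matrix.injections) - set(inj_comm)) | (
        set(matrix.grid_columns) - set(grid_comm)
    )
    if missing:
        raise ValueError(f"partition does not cover matrix labels: {sorted(missing)}")
    inj_order = sorted(
        matrix.injections,
        key=lambda i: (inj_comm[i], matrix.injections.index(i)),
    )
    col_order = sorted(
        matrix.grid_columns,
        key=lambda c: (grid_comm[c], matrix.grid_columns.index(c)),
    )
    return ConnectivityGridMatrix(
        matrix.frame.loc[inj_order, col_order],
        matrix.grid,
        matrix.zero_columns,
    )


def render_domain_map(
    partition: DomainPartition, spec: GridSpec
) -> pd.DataFrame:
    """Per-grid community-id table for plotting; -1 marks absent cells."""
    grid_comm = partition.grid_communities()
    if not grid_comm:
        raise ValueError("partition contains no grid cells")
    indices = [parse_grid_label(c) for c in grid_comm]
    rows = range(min(r for r, _ in indices), max(r for r, _ in indices) + 1)
    cols = range(min(c for _, c in indices), max(c for _, c in indices) + 1)
    table = pd.DataFrame(-1, index=list(rows), columns=list(cols), dtype=int)
    for label, cid in grid_comm.items():
        r, c = parse_grid_label(label)
        table.loc[r, c] = cid
    return table
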