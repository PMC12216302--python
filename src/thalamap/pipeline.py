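"""End-to-end orchestration of the two workflows.

``run_domain_pipeline``: tabulated grid rows (simulated or loaded) ->
aggregated matrix -> Louvain domains -> reordered matrix -> domain map.

``run_morphology_pipeline``: reconstructions (simulated cohort or an SWC
directory plus geometry JSON) -> per-neuron features and tropism -> K-means
typing -> group contrasts (pooled t for edge/non-edge, pairwise rank-sum for
nuclei) with BH-FDR per comparison family -> distance/deviation correlation.

Every run writes a manifest recording parameters, seed, package version, and
SHA-256 digests of all outputs, sufficient to reproduce the run exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import itertools
import json
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import __version__
from .domains import (
    ConnectivityGridMatrix,
    DomainPartition,
    GridSpec,
    InjectionGridRow,
    aggregate_matrix,
    detect_domains,
    render_domain_map,
    reorder_matrix,
)
from .morphometry import compute_profile, profiles_frame, sholl_frame
from .stats import bh_fdr, kmeans_two_types, pooled_t_test, rank_sum_test
from .swc import NeuronReconstruction, read_swc
from .synthetic import generate_cohort, generate_grid_cases
from .tropism import (
    NucleusGeometry,
    deviation_vs_distance,
    tropism_frame,
    tropism_profile,
)

__all__ = [
    "PipelineConfig",
    "DomainPipelineResult",
    "MorphologyPipelineResult",
    "run_domain_pipeline",
    "run_morphology_pipeline",
]

FEATURE_COLUMNS = [
    "total_length",
    "branch_count",
    "height",
    "max_path_distance",
    "average_branch_order",
    "partition_asymmetry",
]

TROPISM_COLUMNS = ["deviation_rad", "proportion_closer"]


@dataclass
class PipelineConfig:
    out_dir: str = "results"
    seed: int = 0
    simulate: bool = True
    preset: str = "amd-edge-study"
    swc_dir: str | None = None
    geometry_path: str | None = None
    input_dir: str | None = None
    gamma: float = 0.75
    grid_px: int = 105
    pixel_um: float = 0.6
    shell_um: float = 50.0
    step_um: float = 1.0
    edge_threshold: float = 0.2
    linkage: str = "average"
    metric: str = "correlation"
    restarts: int = 50
    n_injections: int = 19
    planted_domains: int = 4
    grid_shape: tuple[int, int] = (6, 10)
    noise_sd: float = 0.05

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        data = json.loads(Path(path).read_text())
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "grid_shape" in data:
            data["grid_shape"] = tuple(data["grid_shape"])
        return cls(**data)

    def as_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["grid_shape"] = list(d["grid_shape"])
        return d


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_manifest(out: Path, config: PipelineConfig, outputs: list[Path],
                    extra: dict | None = None) -> Path:
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config": config.as_dict(),
        "outputs": {p.name: _sha256(p) for p in sorted(outputs)},
    }
    if extra:
        manifest.update(extra)
    path = out / "manifest.json"
    path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return path


# ---------------------------------------------------------------------------
# Domain workflow


@dataclass
class DomainPipelineResult:
    matrix: ConnectivityGridMatrix
    partition: DomainPartition
    reordered: ConnectivityGridMatrix
    domain_map: pd.DataFrame
    manifest_path: Path


def _load_grid_rows(input_dir: Path, spec: GridSpec) -> list[InjectionGridRow]:
    """Read injection rows from CSVs: one matrix-style CSV with injection ids
    as row labels and r{row}c{col} column labels (see ConnectivityGridMatrix)."""
    from .domains import parse_grid_label

    files = sorted(input_dir.glob("*.csv"))
    if not files:
        raise FileNotFoundError(f"no CSV inputs in {input_dir}")
    rows: list[InjectionGridRow] = []
    for path in files:
        frame = pd.read_csv(path, index_col=0)
        kind_of = {}
        if "tracer_kind" in frame.columns:
            kind_of = frame.pop("tracer_kind").to_dict()
        for inj, rec in frame.iterrows():
            values = {
                parse_grid_label(col): float(v)
                for col, v in rec.items()
                if float(v) > 0
            }
            rows.append(
                InjectionGridRow(
                    str(inj),
                    kind_of.get(inj, "anterograde"),
                    values,
                    spec,
                )
            )
    return rows


def run_domain_pipeline(config: PipelineConfig) -> DomainPipelineResult:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    spec = GridSpec(grid_px=config.grid_px, pixel_um=config.pixel_um)
    if config.simulate:
        case_set = generate_grid_cases(
            n_injections=config.n_injections,
            planted_domains=config.planted_domains,
            grid_shape=config.grid_shape,
            noise_sd=config.noise_sd,
            seed=config.seed,
        )
        rows = case_set.rows
    else:
        if not config.input_dir:
            raise ValueError("input_dir required when simulate is off")
        rows = _load_grid_rows(Path(config.input_dir), spec)

    matrix = aggregate_matrix(rows)
    partition = detect_domains(matrix, gamma=config.gamma, seed=config.seed)
    reordered = reorder_matrix(matrix, partition)
    domain_map = render_domain_map(partition, spec)

    matrix_path = out / "matrix.csv"
    reordered_path = out / "matrix_reordered.csv"
    map_path = out / "domain_map.csv"
    partition_path = out / "partition.json"
    matrix.to_csv(matrix_path)
    reordered.to_csv(reordered_path)
    domain_map.to_csv(map_path, index_label="grid_row")
    partition_path.write_text(
        json.dumps(
            {
                "gamma": partition.gamma,
                "seed": partition.seed,
                "modularity": partition.modularity,
                "community_of": partition.community_of,
            },
            indent=1,
            sort_keys=True,
        )
    )
    manifest = _write_manifest(
        out,
        config,
        [matrix_path, reordered_path, map_path, partition_path],
        extra={"stage": "domains", "n_communities": len(set(partition.community_of.values()))},
    )
    return DomainPipelineResult(matrix, partition, reordered, domain_map, manifest)


# ---------------------------------------------------------------------------
# Morphology workflow


@dataclass
class MorphologyPipelineResult:
    features: pd.DataFrame
    tropism: pd.DataFrame
    types: pd.DataFrame
    stats: pd.DataFrame
    manifest_path: Path


def _load_neurons(swc_dir: Path) -> list[NeuronReconstruction]:
    files = sorted(swc_dir.glob("*.swc"))
    if not files:
        raise FileNotFoundError(f"no SWC files in {swc_dir}")
    return [read_swc(f) for f in files]


def _contrast_rows(label_prefix, pairs, samples, test):
    """Run a family of two-group contrasts and BH-adjust within the family."""
    rows = []
    for name, (a, b) in pairs.items():
        res = test(a, b)
        rows.append(
            {
                "comparison": f"{label_prefix}:{name}",
                "n_a": len(a),
                "n_b": len(b),
                "statistic": res.statistic,
                "df": res.df if res.df is not None else "",
                "p_value": res.p_value,
                "method": res.method,
            }
        )
    adjusted = bh_fdr([r["p_value"] for r in rows]) if rows else []
    for row, adj in zip(rows, adjusted):
        row["p_adjusted"] = adj
    return rows


def run_morphology_pipeline(config: PipelineConfig) -> MorphologyPipelineResult:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if config.simulate:
        cohort = generate_cohort(config.preset, seed=config.seed)
        neurons, geometry = cohort.neurons, cohort.geometry
    else:
        if not config.swc_dir:
            raise ValueError("swc_dir required when simulate is off")
        if not config.geometry_path:
            raise ValueError("geometry_path required for tropism analysis")
        neurons = _load_neurons(Path(config.swc_dir))
        geometry = NucleusGeometry.from_json(config.geometry_path)
    geometry.edge_threshold = config.edge_threshold

    profiles = [
        compute_profile(n, shell_um=config.shell_um, step_um=config.step_um)
        for n in neurons
    ]
    features = profiles_frame(profiles)
    sholl = sholl_frame(profiles)
    trop_profiles = [
        tropism_profile(n, geometry, step_um=config.step_um) for n in neurons
    ]
    tropism = tropism_frame(trop_profiles)

    assignment = kmeans_two_types(
        features.set_index("neuron_label")[["total_length", "branch_count"]],
        seed=config.seed,
        restarts=config.restarts,
    )
    types = pd.DataFrame(
        {
            "neuron_label": list(assignment.labels),
            "type": [assignment.labels[k] for k in assignment.labels],
        }
    )

    merged = features.merge(
        tropism[["neuron_label", "deviation_rad", "proportion_closer",
                 "soma_center_distance", "edge_class"]],
        on="neuron_label",
    )
    stat_rows: list[dict] = []
    by_edge = dict(tuple(merged.groupby("edge_class")))
    if {"edge", "non-edge"} <= set(by_edge) and all(
        len(g) >= 2 for g in by_edge.values()
    ):
        pairs = {
            col: (
                by_edge["edge"][col].dropna().to_numpy(),
                by_edge["non-edge"][col].dropna().to_numpy(),
            )
            for col in FEATURE_COLUMNS + TROPISM_COLUMNS
        }
        stat_rows += _contrast_rows(
            "edge-vs-non-edge", pairs, merged, pooled_t_test
        )
    nuclei = [n for n, g in merged.groupby("nucleus") if len(g) >= 2]
    if len(nuclei) >= 2:
        for col in ("total_length", "branch_count"):
            pairs = {
                f"{a}-vs-{b}:{col}": (
                    merged.loc[merged.nucleus == a, col].to_numpy(),
                    merged.loc[merged.nucleus == b, col].to_numpy(),
                )
                for a, b in itertools.combinations(nuclei, 2)
            }
            stat_rows += _contrast_rows("nuclei", pairs, merged, rank_sum_test)
    if len(merged) >= 3 and merged["soma_center_distance"].std() > 0:
        corr = deviation_vs_distance(trop_profiles)
        stat_rows.append(
            {
                "comparison": "pearson:distance-vs-deviation",
                "n_a": len(merged),
                "n_b": len(merged),
                "statistic": corr.statistic,
                "df": corr.df,
                "p_value": corr.p_value,
                "method": corr.method,
                "p_adjusted": "",
            }
        )
    stats = pd.DataFrame(
        stat_rows,
        columns=[
            "comparison", "n_a", "n_b", "statistic", "df",
            "p_value", "p_adjusted", "method",
        ],
    )

    paths = {
        "features.csv": features,
        "sholl.csv": sholl,
        "tropism.csv": tropism,
        "types.csv": types,
        "stats.csv": stats,
    }
    written = []
    for name, frame in paths.items():
        p = out / name
        frame.to_csv(p, index=False)
        written.append(p)
    manifest = _write_manifest(
        out, config, written, extra={"stage": "morphology", "n_neurons": len(neurons)}
    )
    return MorphologyPipelineResult(features, tropism, types, stats, manifest)
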