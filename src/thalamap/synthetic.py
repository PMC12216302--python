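"""Synthetic inputs for every pipeline stage.

Neuron trees are grown stochastically: segment directions are drawn from a
von-Mises-Fisher-like distribution (a concentration-scaled mean direction
plus an isotropic Gaussian, renormalized) whose mean points from the current
position toward the nucleus center.  Concentration 0 gives isotropic growth
(mean angular deviation pi/2); larger concentrations bias arbors toward the
center.  Grid matrices carry planted block communities plus clipped Gaussian
noise; feature mixtures and ROI count tables follow the distributions the
analysis stages assume.  Every generator is a pure function of its
configuration and seed.
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .domains import GridSpec, InjectionGridRow
from .swc import SOMA, BASAL_DENDRITE, NeuronReconstruction, SWCNode
from .tropism import NucleusGeometry

__all__ = [
    "NeuronGenConfig",
    "CohortPreset",
    "Cohort",
    "GridCaseSet",
    "generate_neuron",
    "generate_cohort",
    "generate_type_mixture",
    "generate_grid_cases",
    "generate_case_counts",
    "circular_boundary",
    "COHORT_PRESETS",
]

# Printed cohort structure the loaders reproduce: 109 reconstructions split
# 10 AD + 17 AV + 82 AM, the AM comprising 72 AMd (five domain groups of
# 12/12/11/20/17) plus 10 AMv.
PAPER_COHORT_GROUPS: list[tuple[str, str | None, int]] = [
    ("AD", None, 10),
    ("AV", None, 17),
    ("AMv", None, 10),
    ("AMd", "core", 12),
    ("AMd", "dorsal", 12),
    ("AMd", "dorsomedial", 11),
    ("AMd", "lateral", 20),
    ("AMd", "medial", 17),
]

# Two-component feature mixture: (count, mean length, sd length,
# mean branches, sd branches) for Type 1 and Type 2.
TYPE_MIXTURE_COMPONENTS = [
    (84, 3645.0, 1428.0, 51.0, 16.0),
    (25, 8976.0, 1998.0, 126.0, 27.0),
]


@dataclass
class NeuronGenConfig:
    """Parameters of the stochastic center-tropic tree generator."""

    soma_position: tuple[float, float, float] = (0.0, 0.0, 0.0)
    center: tuple[float, float, float] = (0.0, 0.0, 0.0)
    tropism_kappa: float = 0.0
    target_branches: int = 20
    mean_segment_um: float = 3.0
    branch_prob: float = 0.25
    seed: int = 0
    min_steps: int = 2
    max_steps: int = 40

    def __post_init__(self) -> None:
        if self.tropism_kappa < 0:
            raise ValueError("tropism_kappa must be >= 0")
        if self.target_branches < 1:
            raise ValueError("target_branches must be >= 1")
        if self.mean_segment_um <= 0:
            raise ValueError("mean_segment_um must be positive")
        if not (0.0 < self.branch_prob <= 1.0):
            raise ValueError("branch_prob must be in (0, 1]")


def _sample_direction(
    rng: np.random.Generator, kappa: float, mu: np.ndarray
) -> np.ndarray:
    """Unit direction from a vMF-like distribution around ``mu``.

    Implemented as normalize(kappa * mu + g) with isotropic Gaussian g; at
    kappa = 0 this is exactly uniform on the sphere, and the angular spread
    shrinks monotonically as kappa grows.
    """
    while True:
        v = kappa * mu + rng.standard_normal(3)
        norm = float(np.linalg.norm(v))
        if norm > 1e-12:
            return v / norm


def generate_neuron(
    config: NeuronGenConfig,
    label: str = "synthetic",
    nucleus: str = "synthetic",
    domain: str | None = None,
) -> NeuronReconstruction:
    """Grow one reconstruction; passes SWC validation by construction.

    Unbranched segments extend node by node (~mean_segment_um steps) and
    terminate with probability ``branch_prob`` per step (after ``min_steps``);
    a terminating segment bifurcates while the branch budget allows, so the
    finished tree has exactly ``target_branches`` unbranched segments
    (parity permitting via the stem count).
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    soma = np.asarray(cfg.soma_position, dtype=float)
    center = np.asarray(cfg.center, dtype=float)
    nodes = [SWCNode(1, SOMA, *soma, radius=6.0, parent_id=-1)]
    next_id = 2

    def center_dir(pos: np.ndarray) -> np.ndarray:
        d = center - pos
        n = float(np.linalg.norm(d))
        return d / n if n > 1e-9 else np.array([1.0, 0.0, 0.0])

    n_stems = 1 if cfg.target_branches % 2 else 2
    n_stems = min(n_stems, cfg.target_branches)
    segments_made = n_stems
    queue: deque[tuple[int, np.ndarray]] = deque(
        (1, soma.copy()) for _ in range(n_stems)
    )
    while queue:
        parent_id, pos = queue.popleft()
        pos = pos.copy()
        steps = 0
        while True:
            direction = _sample_direction(
                rng, cfg.tropism_kappa, center_dir(pos)
            )
            step_len = cfg.mean_segment_um * (0.8 + 0.4 * rng.random())
            pos = pos + direction * step_len
            nodes.append(
                SWCNode(
                    next_id, BASAL_DENDRITE, *pos, radius=0.5,
                    parent_id=parent_id,
                )
            )
            parent_id = next_id
            next_id += 1
            steps += 1
            if steps >= cfg.max_steps:
                break
            if steps >= cfg.min_steps and rng.random() < cfg.branch_prob:
                break
        if segments_made + 2 <= cfg.target_branches:
            segments_made += 2
            queue.append((parent_id, pos))
            queue.append((parent_id, pos))
    return NeuronReconstruction(
        nodes, label=label, nucleus=nucleus, domain=domain
    )


def circular_boundary(
    center: np.ndarray | tuple[float, float],
    radius: float,
    n_vertices: int = 64,
) -> np.ndarray:
    """Regular-polygon approximation of a circular nucleus boundary."""
    c = np.asarray(center, dtype=float)[:2]
    theta = np.linspace(0.0, 2.0 * math.pi, n_vertices, endpoint=False)
    return np.column_stack(
        [c[0] + radius * np.cos(theta), c[1] + radius * np.sin(theta)]
    )


@dataclass
class CohortPreset:
    """Named synthetic-population recipe."""

    name: str
    nucleus_radius_um: float = 250.0
    # (group label, n, soma radial range as fraction of nucleus radius,
    #  branch range (lo, hi), nucleus, domain)
    groups: list[tuple] = field(default_factory=list)
    kappa_scale: float = 8.0
    # tropism concentration grows as kappa_scale * (r/R)**kappa_power, so
    # central somas grow near-isotropically and peripheral ones center-biased
    kappa_power: float = 3.0

    def total(self) -> int:
        return sum(g[1] for g in self.groups)


def _edge_study_preset() -> CohortPreset:
    return CohortPreset(
        name="amd-edge-study",
        groups=[
            ("edge", 27, (0.84, 0.97), (20, 32), "AMd", None),
            ("non-edge", 45, (0.15, 0.72), (36, 56), "AMd", None),
        ],
    )


def _paper_cohort_preset() -> CohortPreset:
    groups = []
    for nucleus, domain, n in PAPER_COHORT_GROUPS:
        # AM neurons drawn larger than AD/AV, echoing the reported contrast
        branches = (24, 48) if nucleus.startswith("AM") else (12, 28)
        groups.append(
            (
                f"{nucleus}" + (f".{domain}" if domain else ""),
                n,
                (0.2, 0.9),
                branches,
                nucleus,
                domain,
            )
        )
    return CohortPreset(name="paper-cohort", groups=groups)


COHORT_PRESETS = {
    "amd-edge-study": _edge_study_preset,
    "paper-cohort": _paper_cohort_preset,
}


@dataclass
class Cohort:
    """A generated population plus the geometry its tropism is measured in."""

    name: str
    neurons: list[NeuronReconstruction]
    geometry: NucleusGeometry
    table: pd.DataFrame  # label, group, nucleus, domain, soma xyz, kappa

    @property
    def n_total(self) -> int:
        return len(self.neurons)

    @property
    def n_amd(self) -> int:
        return int(sum(1 for n in self.neurons if n.nucleus == "AMd"))


def generate_cohort(preset: str | CohortPreset, seed: int = 0) -> Cohort:
    """Generate a cohort under a named preset.

    ``amd-edge-study``: 27 edge somas (radius >= 0.84 R, classifying edge
    under the default 20%-of-local-radius rule) and 45 non-edge somas, with
    tropism concentration increasing as a power law of soma distance and
    edge arbors drawn smaller.  ``paper-cohort``: the printed per-nucleus /
    per-domain group sizes (109 total, 72 AMd).
    """
    if isinstance(preset, str):
        try:
            preset = COHORT_PRESETS[preset]()
        except KeyError:
            raise ValueError(
                f"unknown preset {preset!r}; "
                f"available: {sorted(COHORT_PRESETS)}"
            ) from None
    rng = np.random.default_rng(seed)
    radius = preset.nucleus_radius_um
    center = np.zeros(3)
    geometry = NucleusGeometry(
        center=center, boundary=circular_boundary(center, radius)
    )
    neurons: list[NeuronReconstruction] = []
    records: list[dict] = []
    counter = 0
    for group, n, (lo, hi), (b_lo, b_hi), nucleus, domain in preset.groups:
        for _ in range(n):
            counter += 1
            r_frac = float(rng.uniform(lo, hi))
            theta = float(rng.uniform(0.0, 2.0 * math.pi))
            soma = np.array(
                [
                    r_frac * radius * math.cos(theta),
                    r_frac * radius * math.sin(theta),
                    float(rng.normal(0.0, 5.0)),
                ]
            )
            kappa = preset.kappa_scale * r_frac**preset.kappa_power
            branches = int(rng.integers(b_lo // 2, b_hi // 2 + 1)) * 2
            label = f"{preset.name}-{counter:03d}"
            cfg = NeuronGenConfig(
                soma_position=tuple(soma),
                center=tuple(center),
                tropism_kappa=kappa,
                target_branches=max(2, branches),
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            neurons.append(
                generate_neuron(cfg, label=label, nucleus=nucleus, domain=domain)
            )
            records.append(
                {
                    "neuron_label": label,
                    "group": group,
                    "nucleus": nucleus,
                    "domain": domain or "",
                    "soma_x": soma[0],
                    "soma_y": soma[1],
                    "soma_z": soma[2],
                    "kappa": kappa,
                }
            )
    return Cohort(preset.name, neurons, geometry, pd.DataFrame(records))


def generate_type_mixture(seed: int = 0) -> pd.DataFrame:
    """109-row two-component (length, branch count) feature mixture.

    84 rows from the small/simple component and 25 from the large/complex
    one, each feature normal with the component mean/SD, redrawn on negative
    values.  Branch counts are rounded to integers >= 1.
    """
    rng = np.random.default_rng(seed)

    def truncated_normal(mean: float, sd: float, n: int) -> np.ndarray:
        out = rng.normal(mean, sd, size=n)
        while np.any(out <= 0):
            bad = out <= 0
            out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        return out

    frames = []
    for planted, (n, len_mu, len_sd, br_mu, br_sd) in enumerate(
        TYPE_MIXTURE_COMPONENTS, start=1
    ):
        frames.append(
            pd.DataFrame(
                {
                    "total_length": truncated_normal(len_mu, len_sd, n),
                    "branch_count": np.maximum(
                        1, np.round(truncated_normal(br_mu, br_sd, n))
                    ).astype(int),
                    "planted_type": planted,
                }
            )
        )
    table = pd.concat(frames, ignore_index=True)
    table.index = [f"neuron-{i:03d}" for i in range(len(table))]
    return table


@dataclass
class GridCaseSet:
    rows: list[InjectionGridRow]
    planted_domain_of: dict[str, int]
    spec: GridSpec


def generate_grid_cases(
    n_injections: int = 19,
    planted_domains: int = 4,
    grid_shape: tuple[int, int] = (6, 10),
    noise_sd: float = 0.05,
    seed: int = 0,
    repeats: int = 2,
) -> GridCaseSet:
    """Injection rows with planted block/community structure plus noise.

    Grid columns are split into ``planted_domains`` contiguous blocks; each
    injection targets one block with high coverage plus clipped Gaussian
    noise of SD ``noise_sd`` (on the unit scale).  The first ``repeats``
    injections replicate the first ROI, mimicking repeated injections for a
    single region, and tracer kinds alternate anterograde/retrograde.
    """
    n_rows, n_cols = grid_shape
    n_grids = n_rows * n_cols
    if planted_domains > min(n_injections, n_grids):
        raise ValueError("more planted domains than injections or grids")
    if n_injections < 1:
        raise ValueError("need at least one injection")
    rng = np.random.default_rng(seed)
    spec = GridSpec()
    grids = [(r, c) for r in range(n_rows) for c in range(n_cols)]
    blocks = np.array_split(np.arange(n_grids), planted_domains)
    rows: list[InjectionGridRow] = []
    planted: dict[str, int] = {}
    for k in range(n_injections):
        if k < repeats:
            roi, domain = "ROI00", 0
            injection_id = f"ROI00-rep{k + 1}"
        else:
            domain = k % planted_domains
            injection_id = f"ROI{k:02d}"
        kind = "anterograde" if k % 2 == 0 else "retrograde"
        signal = np.zeros(n_grids)
        signal[blocks[domain]] = rng.uniform(0.6, 1.0, size=len(blocks[domain]))
        noisy = np.clip(signal + rng.normal(0.0, noise_sd, size=n_grids), 0, None)
        if kind == "anterograde":
            quantities = np.minimum(100.0, 100.0 * noisy)
        else:
            quantities = np.round(40.0 * noisy)
        values = {
            grids[g]: float(quantities[g])
            for g in range(n_grids)
            if quantities[g] > 0
        }
        rows.append(InjectionGridRow(injection_id, kind, values, spec))
        planted[injection_id] = domain
    return GridCaseSet(rows, planted, spec)


def generate_case_counts(
    n_rois: int,
    profile_shape: str = "lognormal",
    seed: int = 0,
) -> tuple[dict[str, float], dict[str, float]]:
    """ROI count and area tables for one case (fraction/density inputs)."""
    if n_rois < 1:
        raise ValueError("need at least one ROI")
    rng = np.random.default_rng(seed)
    rois = [f"ROI{i:03d}" for i in range(n_rois)]
    if profile_shape == "lognormal":
        counts = rng.lognormal(mean=5.0, sigma=1.5, size=n_rois)
    elif profile_shape == "uniform":
        counts = rng.uniform(1.0, 1000.0, size=n_rois)
    elif profile_shape == "sparse":
        counts = rng.lognormal(mean=5.0, sigma=1.5, size=n_rois)
        counts[rng.random(n_rois) < 0.5] = 0.0
        if counts.max() <= 0:
            counts[0] = 1.0
    else:
        raise ValueError(f"unknown profile shape {profile_shape!r}")
    areas = rng.uniform(0.5, 5.0, size=n_rois)
    rounded = np.round(counts)
    if rounded.max() <= 0:  # guard against all-zero rounding
        rounded[int(np.argmax(counts))] = 1.0
    return (
        {roi: float(c) for roi, c in zip(rois, rounded)},
        {roi: float(a) for roi, a in zip(rois, areas)},
    )
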