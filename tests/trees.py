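"""Hand-built reconstructions and small helpers shared across test modules."""

from __future__ import annotations

import numpy as np

from thalamap.swc import (
    BASAL_DENDRITE,
    SOMA,
    NeuronReconstruction,
    SWCNode,
)
from thalamap.synthetic import NeuronGenConfig, generate_neuron


def build(rows, **meta) -> NeuronReconstruction:
    """rows: (id, type, x, y, z, radius, parent) tuples."""
    return NeuronReconstruction([SWCNode(*r) for r in rows], **meta)


def straight_dendrite(length: float, axis: int = 1) -> NeuronReconstruction:
    """Soma at origin with a single straight dendrite along ``axis``."""
    tip = [0.0, 0.0, 0.0]
    mid = [0.0, 0.0, 0.0]
    tip[axis] = length
    mid[axis] = length / 2.0
    return build(
        [
            (1, SOMA, 0.0, 0.0, 0.0, 5.0, -1),
            (2, BASAL_DENDRITE, *mid, 1.0, 1),
            (3, BASAL_DENDRITE, *tip, 1.0, 2),
        ]
    )


def y_tree(
    stem: float = 10.0, left: float = 5.0, right: float = 5.0
) -> NeuronReconstruction:
    """Stem along +x then two daughters along ±y (lengths exact)."""
    return build(
        [
            (1, SOMA, 0.0, 0.0, 0.0, 5.0, -1),
            (2, BASAL_DENDRITE, stem, 0.0, 0.0, 1.0, 1),
            (3, BASAL_DENDRITE, stem, left, 0.0, 1.0, 2),
            (4, BASAL_DENDRITE, stem, -right, 0.0, 1.0, 2),
        ]
    )


def binary_tree(depth: int, edge: float = 10.0) -> NeuronReconstruction:
    """Perfect binary dendritic tree: one stem plus depth-1 bifurcation levels.

    Unbranched segment count is 2**depth - 1; tips 2**(depth-1).
    """
    rows = [(1, SOMA, 0.0, 0.0, 0.0, 5.0, -1)]
    next_id = 2

    def grow(parent_id: int, x: float, y: float, level: int) -> None:
        nonlocal next_id
        nid = next_id
        next_id += 1
        rows.append((nid, BASAL_DENDRITE, x, y + edge, 0.0, 1.0, parent_id))
        if level < depth:
            spread = edge / (2.0**level)
            grow(nid, x - spread, y + edge, level + 1)
            grow(nid, x + spread, y + edge, level + 1)

    grow(1, 0.0, 0.0, 1)
    return build(rows)


def random_neuron(seed: int, kappa: float = 0.0, soma=(300.0, 0.0, 0.0),
                  branches: int = 16) -> NeuronReconstruction:
    cfg = NeuronGenConfig(
        soma_position=soma,
        center=(0.0, 0.0, 0.0),
        tropism_kappa=kappa,
        target_branches=branches,
        seed=seed,
    )
    return generate_neuron(cfg, label=f"rand-{seed}")


def rotate_z(neuron: NeuronReconstruction, angle: float) -> NeuronReconstruction:
    """Rigidly rotate all nodes about the z axis through the origin."""
    c, s = np.cos(angle), np.sin(angle)
    rot = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
    rows = []
    for n in neuron.nodes:
        x, y, z = rot @ n.position
        rows.append((n.id, n.type_code, x, y, z, n.radius, n.parent_id))
    return build(rows)


def translate(neuron: NeuronReconstruction, offset) -> NeuronReconstruction:
    off = np.asarray(offset, dtype=float)
    rows = []
    for n in neuron.nodes:
        x, y, z = n.position + off
        rows.append((n.id, n.type_code, x, y, z, n.radius, n.parent_id))
    return build(rows)


def set_partitions(items: list):
    """Yield all set partitions of ``items`` (for exhaustive modularity)."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [part[i] | {first}] + part[i + 1 :]
        yield part + [{first}]
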