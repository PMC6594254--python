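"""Seeded generators for synthetic sequences, terrains and labelled datasets.

These provide controlled inputs for every pipeline stage without any
external download: i.i.d. random sequences, uniform random integer
terrains, and a two-class dataset that mirrors the reference/SNP-variant
pairing of the real experiment (one single-base edit per reference
sequence) with a controllable class separation injected into one named
feature.
"""

from __future__ import annotations

from typing import Optional, Sequence as Seq, Tuple

import numpy as np

from .embedding import (
    BASES,
    Lattice3D,
    LatticeNode,
    Sequence,
    apply_edit,
    encode_sequence,
    rank_function,
    spiral_embed,
)
from .hybrid import LabeledDataset
from .triads import FEATURE_LAYOUT, feature_vector
from .visibility import BuildConfig, build_visibility_graph_3d

__all__ = ["random_sequence", "random_lattice", "two_class_dataset", "sequence_features"]

#: Elevation -> base used when synthesizing terrains directly (the inverse
#: of the canonical rank map f(A)=4, f(C)=3, f(G)=2, f(T)=1).
_Z_TO_BASE = {4: "A", 3: "C", 2: "G", 1: "T"}


def random_sequence(
    length: int,
    probabilities: Seq[float] = (0.25, 0.25, 0.25, 0.25),
    seed: int = 0,
    id: str = "random",
) -> Sequence:
    """I.i.d. random sequence over A, C, G, T; deterministic per seed."""
    p = np.asarray(probabilities, dtype=float)
    if p.min() < 0 or abs(p.sum() - 1.0) > 1e-12:
        raise ValueError("probabilities must be non-negative and sum to 1")
    if length < 1:
        raise ValueError("length must be positive")
    rng = np.random.default_rng(seed)
    residues = "".join(rng.choice(list(BASES), size=length, p=p))
    return Sequence(id=id, residues=residues)


def random_lattice(
    side: int, z_range: Tuple[int, int] = (1, 4), seed: int = 0
) -> Lattice3D:
    """Full side x side terrain with uniform integer elevations.

    Sequence positions run boustrophedon (so consecutive positions stay
    4-adjacent, as on a spiral) and bases are back-filled from elevations.
    """
    if side < 1:
        raise ValueError("side must be >= 1")
    lo, hi = z_range
    rng = np.random.default_rng(seed)
    nodes = {}
    pos = 1
    for y in range(side):
        xs = range(side) if y % 2 == 0 else range(side - 1, -1, -1)
        for x in xs:
            z = int(rng.integers(lo, hi + 1))
            nodes[(x, y)] = LatticeNode(z=z, seq_pos=pos, base=_Z_TO_BASE.get(z, "A"))
            pos += 1
    return Lattice3D(side=side, nodes=nodes, meta={"generator": "random_lattice", "seed": seed})


def sequence_features(
    seq: Sequence, config: Optional[BuildConfig] = None
) -> np.ndarray:
    """End-to-end features of one sequence: rank -> spiral -> 3D visibility
    graph -> triad/chi-square/digit features."""
    rmap = rank_function(seq)
    lattice = spiral_embed(seq, rmap)
    graph = build_visibility_graph_3d(lattice, config)
    return feature_vector(graph, encode_sequence(seq, rmap))


def two_class_dataset(
    n_per_class: int = 10,
    effect: float = 5.0,
    feature: str = "TP1",
    seed: int = 0,
    length: int = 99,
    config: Optional[BuildConfig] = None,
) -> LabeledDataset:
    """Labelled dataset of reference/variant sequence pairs.

    For each of ``n_per_class`` random reference sequences (label 0) a
    variant (label 1) is derived by one random single-base substitution,
    mirroring the SNP design of the real data.  Features are extracted by
    the full pipeline; the positive class then receives a mean shift of
    ``effect`` population standard deviations on the named feature, giving
    a dataset whose class separation is known by construction.
    """
    if n_per_class < 2:
        raise ValueError("n_per_class must be >= 2")
    if feature not in FEATURE_LAYOUT:
        raise ValueError(f"unknown feature {feature!r}; see FEATURE_LAYOUT")
    rng = np.random.default_rng(seed)
    rows, labels = [], []
    for i in range(n_per_class):
        ref = random_sequence(length, seed=int(rng.integers(2**31)), id=f"ref{i}")
        pos = int(rng.integers(1, length + 1))
        alt = str(rng.choice([b for b in BASES if b != ref.residues[pos - 1]]))
        var = apply_edit(ref, pos, alt)
        rows.append(sequence_features(ref, config))
        labels.append(0)
        rows.append(sequence_features(var, config))
        labels.append(1)
    X = np.vstack(rows)
    y = np.asarray(labels)
    if effect:
        j = FEATURE_LAYOUT.index(feature)
        sd = float(X[:, j].std()) or 1.0
        X[y == 1, j] += effect * sd
    return LabeledDataset(X=X, y=y, feature_names=FEATURE_LAYOUT)
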