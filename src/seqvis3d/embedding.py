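"""Sequence validation, frequency ranking, and spiral embedding onto a 3D lattice.

A nucleotide sequence is mapped to a terrain-like integer lattice in three
steps: (1) each base receives an integer rank in {1..4} determined by how
often it occurs in the sequence (the most frequent base ranks highest);
(2) successive sequence positions are laid out on a square grid along a
spiral curve; (3) the rank of the base at each grid cell becomes that cell's
elevation ``z``.  The resulting lattice is the input terrain for the 3D
visibility-graph construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, Iterator, List, Optional, Tuple

__all__ = [
    "BASES",
    "Edit",
    "Sequence",
    "RankMap",
    "Lattice3D",
    "LatticeNode",
    "SpiralConfig",
    "normalize_sequence",
    "apply_edit",
    "rank_function",
    "encode_sequence",
    "decode_digits",
    "spiral_embed",
    "spiral_path",
]

BASES = ("A", "C", "G", "T")

Cell = Tuple[int, int]


class SequenceError(ValueError):
    """Raised when a sequence fails validation."""


@dataclass(frozen=True)
class Edit:
    """A single-nucleotide substitution at a 1-based sequence position."""

    position: int
    ref: str
    alt: str


@dataclass(frozen=True)
class Sequence:
    """A validated nucleotide string over {A, C, G, T} with provenance.

    ``edits`` records substitutions applied via :func:`apply_edit`, mirroring
    the SNP-variant bookkeeping used when comparing a reference precursor
    miRNA with its polymorphic form.
    """

    id: str
    residues: str
    edits: Tuple[Edit, ...] = ()

    def __len__(self) -> int:
        return len(self.residues)

    def __post_init__(self) -> None:
        bad = [i for i, b in enumerate(self.residues) if b not in BASES]
        if not self.residues:
            raise SequenceError(f"sequence {self.id!r} is empty")
        if bad:
            raise SequenceError(
                f"sequence {self.id!r}: invalid residue {self.residues[bad[0]]!r} "
                f"at position {bad[0] + 1}"
            )


def normalize_sequence(raw: str, id: str = "seq") -> Sequence:
    """Validate and normalize a raw nucleotide string.

    Whitespace is stripped, letters are uppercased and uracil is mapped to
    thymine so that RNA and DNA inputs share one alphabet.  Any other
    character raises :class:`SequenceError` naming the offending (1-based)
    position.
    """
    stripped = "".join(raw.split())
    if not stripped:
        raise SequenceError(f"sequence {id!r} is empty")
    out = []
    for i, ch in enumerate(stripped):
        up = ch.upper()
        if up == "U":
            up = "T"
        if up not in BASES:
            raise SequenceError(
                f"sequence {id!r}: invalid character {ch!r} at position {i + 1}"
            )
        out.append(up)
    return Sequence(id=id, residues="".join(out))


def apply_edit(seq: Sequence, position: int, alt: str) -> Sequence:
    """Return a copy of ``seq`` with the residue at ``position`` (1-based)
    replaced by ``alt``; the edit is recorded in provenance.

    Applying an edit whose ``alt`` equals the current residue is the
    identity on the residue string (but is still recorded).
    """
    if not 1 <= position <= len(seq):
        raise SequenceError(
            f"edit position {position} out of range 1..{len(seq)} for {seq.id!r}"
        )
    alt = alt.upper().replace("U", "T")
    if alt not in BASES:
        raise SequenceError(f"invalid alternate base {alt!r}")
    ref = seq.residues[position - 1]
    residues = seq.residues[: position - 1] + alt + seq.residues[position:]
    return replace(
        seq, residues=residues, edits=seq.edits + (Edit(position, ref, alt),)
    )


@dataclass(frozen=True)
class RankMap:
    """The frequency-rank function f : {A,C,G,T} -> {1,2,3,4}.

    The most frequent base receives rank 4, the least frequent rank 1; ties
    are broken by ``tie order`` (the earlier base takes the larger value).
    """

    value: Dict[str, int]
    counts: Dict[str, int]

    def __post_init__(self) -> None:
        if sorted(self.value) != sorted(BASES) or sorted(self.value.values()) != [1, 2, 3, 4]:
            raise ValueError("rank map must be a bijection {A,C,G,T} -> {1,2,3,4}")

    def __getitem__(self, base: str) -> int:
        return self.value[base]

    def inverse(self) -> Dict[int, str]:
        return {v: k for k, v in self.value.items()}


def rank_function(seq: Sequence, tie_order: str = "ACGT") -> RankMap:
    """Compute the rank map of a sequence from its base counts.

    Bases are sorted by count descending; equal counts are ordered by their
    position in ``tie_order`` (earlier base ranks higher).  With counts
    n_A > n_C > n_G > n_T this yields f(A)=4, f(C)=3, f(G)=2, f(T)=1.
    """
    if sorted(tie_order) != sorted(BASES):
        raise ValueError("tie_order must be a permutation of ACGT")
    counts = {b: seq.residues.count(b) for b in BASES}
    ordered = sorted(BASES, key=lambda b: (-counts[b], tie_order.index(b)))
    value = {b: 4 - i for i, b in enumerate(ordered)}
    return RankMap(value=value, counts=counts)


def encode_sequence(seq: Sequence, rank_map: RankMap) -> str:
    """Substitute every base by its rank digit, e.g. TGCCAATCGTTGT -> 1233441231121
    under f(A)=4, f(C)=3, f(G)=2, f(T)=1."""
    return "".join(str(rank_map[b]) for b in seq.residues)


def decode_digits(digits: str, rank_map: RankMap) -> str:
    """Invert :func:`encode_sequence` (the rank map is a bijection)."""
    inv = rank_map.inverse()
    return "".join(inv[int(d)] for d in digits)


@dataclass(frozen=True)
class LatticeNode:
    z: int
    seq_pos: int
    base: str


@dataclass(frozen=True)
class SpiralConfig:
    """Convention for the spiral curve filling the grid.

    origin ``center``: Ulam-style outward spiral starting at the central
    cell; ``corner``: inward spiral starting at cell (0, 0).  ``turn`` is the
    handedness of the walk and ``first_step`` its initial direction.
    """

    origin: str = "center"
    turn: str = "ccw"
    first_step: str = "+x"

    def __post_init__(self) -> None:
        if self.origin not in ("center", "corner"):
            raise ValueError("origin must be 'center' or 'corner'")
        if self.turn not in ("ccw", "cw"):
            raise ValueError("turn must be 'ccw' or 'cw'")
        if self.first_step not in ("+x", "-x", "+y", "-y"):
            raise ValueError("first_step must be one of +x,-x,+y,-y")


@dataclass(frozen=True)
class Lattice3D:
    """Integer terrain: grid cells (x, y) with elevation z = f(base).

    ``nodes`` maps each occupied cell to its elevation, 1-based sequence
    position and base.  Cells beyond the sequence length are simply absent.
    """

    side: int
    nodes: Dict[Cell, LatticeNode]
    meta: Dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for (x, y) in self.nodes:
            if not (0 <= x < self.side and 0 <= y < self.side):
                raise ValueError(f"cell {(x, y)} outside {self.side}x{self.side} grid")

    def __len__(self) -> int:
        return len(self.nodes)

    def cells(self) -> List[Cell]:
        return sorted(self.nodes)

    def z(self, cell: Cell) -> int:
        return self.nodes[cell].z


_DIRS = {"+x": (1, 0), "-x": (-1, 0), "+y": (0, 1), "-y": (0, -1)}


def _turn(d: Cell, turn: str) -> Cell:
    dx, dy = d
    # ccw: (1,0)->(0,1)->(-1,0)->(0,-1); cw is the inverse
    return (-dy, dx) if turn == "ccw" else (dy, -dx)


def _ulam_walk(config: SpiralConfig) -> Iterator[Cell]:
    """Unbounded outward spiral from (0, 0): runs of length 1,1,2,2,3,3,..."""
    x, y = 0, 0
    d = _DIRS[config.first_step]
    run = 1
    yield (x, y)
    while True:
        for _ in range(2):
            for _ in range(run):
                x, y = x + d[0], y + d[1]
                yield (x, y)
            d = _turn(d, config.turn)
        run += 1


def _corner_walk(side: int, config: SpiralConfig) -> List[Cell]:
    """Inward boundary spiral over the side x side grid starting at (0, 0)."""
    d = _DIRS[config.first_step]
    visited: set = set()
    out: List[Cell] = []
    x, y = 0, 0
    for _ in range(side * side):
        out.append((x, y))
        visited.add((x, y))
        nx_, ny_ = x + d[0], y + d[1]
        if not (0 <= nx_ < side and 0 <= ny_ < side) or (nx_, ny_) in visited:
            d = _turn(d, config.turn)
            nx_, ny_ = x + d[0], y + d[1]
        x, y = nx_, ny_
    return out


def spiral_path(length: int, side: int, config: Optional[SpiralConfig] = None) -> List[Cell]:
    """The first ``length`` cells of the spiral walk on a side x side grid."""
    config = config or SpiralConfig()
    if config.origin == "corner":
        return _corner_walk(side, config)[:length]
    # center: take side**2 cells of the unbounded walk, shift into the grid
    walk = []
    gen = _ulam_walk(config)
    for _ in range(side * side):
        walk.append(next(gen))
    minx = min(c[0] for c in walk)
    miny = min(c[1] for c in walk)
    return [(x - minx, y - miny) for (x, y) in walk[:length]]


def spiral_embed(
    seq: Sequence,
    rank_map: Optional[RankMap] = None,
    config: Optional[SpiralConfig] = None,
) -> Lattice3D:
    """Embed a sequence on a square grid along a spiral curve.

    The grid side is ceil(sqrt(length)); position 1 sits at the spiral
    origin and successive positions follow the walk, so consecutive
    positions always occupy 4-adjacent cells.  Each node's elevation is the
    rank of its base.  When ``rank_map`` is omitted it is computed from the
    sequence itself.
    """
    config = config or SpiralConfig()
    rank_map = rank_map or rank_function(seq)
    n = len(seq)
    side = math.isqrt(n - 1) + 1  # ceil(sqrt(n))
    path = spiral_path(n, side, config)
    nodes = {
        cell: LatticeNode(z=rank_map[b], seq_pos=i + 1, base=b)
        for i, (cell, b) in enumerate(zip(path, seq.residues))
    }
    meta = {
        "sequence_id": seq.id,
        "spiral": {"origin": config.origin, "turn": config.turn, "first_step": config.first_step},
        "rank_map": dict(rank_map.value),
    }
    return Lattice3D(side=side, nodes=nodes, meta=meta)
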