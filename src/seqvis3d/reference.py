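"""Slow, definition-level reference implementations used for validation.

Everything here re-evaluates the defining statements of the pipeline
directly — all-pairs/all-intermediates visibility checks, per-cell argmax
diagonals, dense-sampled line-of-sight against the terrain, and a
per-triple triad classifier — independently of the optimized code paths in
:mod:`seqvis3d.visibility` and :mod:`seqvis3d.triads`.  They exist so that
the fast implementations can be checked against first principles on small
inputs; they are not meant for production-size data.
"""

from __future__ import annotations

import itertools
from fractions import Fraction
from typing import Dict, List, Optional, Sequence as Seq, Set, Tuple

from .embedding import Lattice3D
from .visibility import BuildConfig, TerrainSurface, _cell_corners

Cell = Tuple[int, int]

TRIAD_ORDER = (
    "003", "012", "102", "021D", "021U", "021C", "111D", "111U",
    "030T", "030C", "201", "120D", "120U", "120C", "210", "300",
)


# ---------------------------------------------------------------------------
# Triads: per-triple classifier (Mutual-Asymmetric-Null scheme)
# ---------------------------------------------------------------------------


def classify_triple(arcs: Set[Tuple], triple: Seq) -> str:
    """Classify the directed triad induced on ``triple`` by ``arcs``.

    ``arcs`` is a set of ordered pairs.  Dyads are first typed as mutual,
    asymmetric or null; the suffix (D/U/C/T) then distinguishes orientation:
    D = the distinguishing arcs fan out of one node, U = they fan into one
    node, C = cyclic/path arrangement, T = transitive.
    """
    a, b, c = triple
    pairs = [(a, b), (a, c), (b, c)]
    mutual, asym, null = [], [], []
    for u, v in pairs:
        fwd, bwd = (u, v) in arcs, (v, u) in arcs
        if fwd and bwd:
            mutual.append((u, v))
        elif fwd:
            asym.append((u, v))
        elif bwd:
            asym.append((v, u))
        else:
            null.append((u, v))
    m, s, n = len(mutual), len(asym), len(null)
    if (m, s, n) == (0, 0, 3):
        return "003"
    if (m, s, n) == (0, 1, 2):
        return "012"
    if (m, s, n) == (1, 0, 2):
        return "102"
    if (m, s, n) == (2, 0, 1):
        return "201"
    if (m, s, n) == (3, 0, 0):
        return "300"
    if (m, s, n) == (2, 1, 0):
        return "210"
    if (m, s, n) == (0, 2, 1):
        (s1, t1), (s2, t2) = asym
        if s1 == s2:
            return "021D"
        if t1 == t2:
            return "021U"
        return "021C"
    if (m, s, n) == (1, 1, 1):
        pair = set(mutual[0])
        src, dst = asym[0]
        return "111D" if dst in pair else "111U"
    if (m, s, n) == (0, 3, 0):
        sources = [u for u, _ in asym]
        if any(sources.count(u) == 2 for u in set(sources)):
            return "030T"
        return "030C"
    if (m, s, n) == (1, 2, 0):
        third = ({a, b, c} - set(mutual[0])).pop()
        outs = sum(1 for u, _ in asym if u == third)
        if outs == 2:
            return "120D"
        if outs == 0:
            return "120U"
        return "120C"
    raise AssertionError(f"unclassifiable dyad counts {(m, s, n)}")


def graph_arcs(vg) -> Set[Tuple]:
    """Ordered arc set of a VisibilityGraph (mutual -> both directions)."""
    arcs = set()
    for d in vg.dyads.values():
        arcs.add((d.u, d.v))
        if d.mode == "mutual":
            arcs.add((d.v, d.u))
    return arcs


def triad_census_bruteforce(vg) -> Dict[str, int]:
    """Census by exhaustive classification of every unordered node triple."""
    arcs = graph_arcs(vg)
    counts = {t: 0 for t in TRIAD_ORDER}
    for triple in itertools.combinations(vg.nodes, 3):
        counts[classify_triple(arcs, triple)] += 1
    return counts


# ---------------------------------------------------------------------------
# Natural visibility: literal all-pairs / all-intermediates evaluation
# ---------------------------------------------------------------------------


def natural_visibility_pairs_bruteforce(series: Seq[Tuple]) -> Set[Tuple[int, int]]:
    """Index pairs (i, k), i < k, visible under the literal chord criterion
    y_c < y_b + (y_a - y_b)(x_b - x_c)/(x_b - x_a), evaluated with rational
    division exactly as printed."""
    pts = [(Fraction(x), Fraction(y)) for x, y in series]
    out = set()
    for i, k in itertools.combinations(range(len(pts)), 2):
        xa, ya = pts[i]
        xb, yb = pts[k]
        ok = True
        for mth in range(i + 1, k):
            xc, yc = pts[mth]
            if not yc < yb + (ya - yb) * (xb - xc) / (xb - xa):
                ok = False
                break
        if ok:
            out.add((i, k))
    return out


# ---------------------------------------------------------------------------
# Lattice steps, re-derived from their definitions
# ---------------------------------------------------------------------------


def adjacency_pairs_bruteforce(lattice: Lattice3D) -> Set[Tuple[Cell, Cell]]:
    out = set()
    for (x, y) in lattice.nodes:
        for nb in ((x - 1, y), (x + 1, y), (x, y - 1), (x, y + 1)):
            if nb in lattice.nodes:
                out.add(tuple(sorted(((x, y), nb))))
    return out


def diagonal_pairs_bruteforce(lattice: Lattice3D) -> Set[Tuple[Cell, Cell]]:
    """Per complete unit cell: argmax-z corner (lexicographic tie-break)
    joined to the opposite corner."""
    out = set()
    for cx in range(lattice.side - 1):
        for cy in range(lattice.side - 1):
            corners = _cell_corners(cx, cy)
            if any(c not in lattice.nodes for c in corners):
                continue
            zmax = max(lattice.z(c) for c in corners)
            top = sorted(c for c in corners if lattice.z(c) == zmax)[0]
            opposite = corners[(corners.index(top) + 2) % 4]
            out.add(tuple(sorted((top, opposite))))
    return out


def axis_pairs_bruteforce(lattice: Lattice3D, axis: str) -> Set[Tuple[Cell, Cell]]:
    """Literal evaluation of the per-line elevation-profile criterion over
    all node pairs of each row (axis 'x') or column (axis 'y') and all
    intermediate nodes of the same line."""
    out = set()
    coord = (lambda c: c[0]) if axis == "x" else (lambda c: c[1])
    line_of = (lambda c: c[1]) if axis == "x" else (lambda c: c[0])
    for line in range(lattice.side):
        cells = sorted((c for c in lattice.nodes if line_of(c) == line), key=coord)
        for ci, ck in itertools.combinations(cells, 2):
            xi, zi = Fraction(coord(ci)), Fraction(lattice.z(ci))
            xk, zk = Fraction(coord(ck)), Fraction(lattice.z(ck))
            ok = True
            for cm in cells:
                if not coord(ci) < coord(cm) < coord(ck):
                    continue
                xm, zm = Fraction(coord(cm)), Fraction(lattice.z(cm))
                if not zm < zk + (zi - zk) * (xk - xm) / (xk - xi):
                    ok = False
                    break
            if ok:
                out.add(tuple(sorted((ci, ck))))
    return out


# ---------------------------------------------------------------------------
# Line of sight: dense sampling with exact surface-height evaluation
# ---------------------------------------------------------------------------


def surface_heights_at(surface: TerrainSurface, x: Fraction, y: Fraction) -> List[Fraction]:
    """Exact terrain height(s) at a 2D point: triangle heights from every
    complete cell containing the point, plus wireframe heights where the
    point lies on a node or on an edge between adjacent nodes (all values
    agree where they overlap)."""
    lat = surface.lattice
    heights: List[Fraction] = []
    if x.denominator == 1 and y.denominator == 1:
        node = lat.nodes.get((int(x), int(y)))
        if node is not None:
            heights.append(Fraction(node.z))
    if y.denominator == 1:  # horizontal edges
        ex = x.numerator // x.denominator
        for x0 in {ex, ex - 1} if x.denominator == 1 else {ex}:
            a, b = (x0, int(y)), (x0 + 1, int(y))
            if a in lat.nodes and b in lat.nodes and x0 <= x <= x0 + 1:
                heights.append(lat.z(a) + (x - x0) * (lat.z(b) - lat.z(a)))
    if x.denominator == 1:  # vertical edges
        ey = y.numerator // y.denominator
        for y0 in {ey, ey - 1} if y.denominator == 1 else {ey}:
            a, b = (int(x), y0), (int(x), y0 + 1)
            if a in lat.nodes and b in lat.nodes and y0 <= y <= y0 + 1:
                heights.append(lat.z(a) + (y - y0) * (lat.z(b) - lat.z(a)))
    xcands = {x.numerator // x.denominator}
    if x.denominator == 1:
        xcands.add(int(x) - 1)
    ycands = {y.numerator // y.denominator}
    if y.denominator == 1:
        ycands.add(int(y) - 1)
    for cx in xcands:
        for cy in ycands:
            kind = surface.triangulation.get((cx, cy))
            if kind is None:
                continue
            fx, fy = x - cx, y - cy
            if not (0 <= fx <= 1 and 0 <= fy <= 1):
                continue
            c00, c10, c11, c01 = _cell_corners(cx, cy)
            z00, z10 = lat.z(c00), lat.z(c10)
            z11, z01 = lat.z(c11), lat.z(c01)
            if kind == "main":  # diagonal c00-c11
                if fx >= fy:  # triangle c00, c10, c11
                    h = z00 + fx * (z10 - z00) + fy * (z11 - z10)
                else:  # triangle c00, c11, c01
                    h = z00 + fy * (z01 - z00) + fx * (z11 - z01)
            else:  # diagonal c10-c01
                if fx + fy <= 1:  # triangle c00, c10, c01
                    h = z00 + fx * (z10 - z00) + fy * (z01 - z00)
                else:  # triangle c10, c11, c01
                    h = z11 + (1 - fx) * (z01 - z11) + (1 - fy) * (z10 - z11)
            heights.append(h)
    return heights


def _breakpoints(u: Cell, v: Cell) -> List[Fraction]:
    """Interior parameter values where the projected segment crosses a grid
    line or a cell diagonal (the terrain is planar between these)."""
    ts: Set[Fraction] = set()
    for u0, d in (
        (u[0], v[0] - u[0]),                           # x(t) integer
        (u[1], v[1] - u[1]),                           # y(t) integer
        (u[0] - u[1], (v[0] - v[1]) - (u[0] - u[1])),  # x - y integer (main diagonals)
        (u[0] + u[1], (v[0] + v[1]) - (u[0] + u[1])),  # x + y integer (anti diagonals)
    ):
        if d == 0:
            continue
        lo, hi = sorted((u0, u0 + d))
        for k in range(lo, hi + 1):
            t = Fraction(k - u0, d)
            if 0 < t < 1:
                ts.add(t)
    return sorted(ts)


def segment_clears_surface_bruteforce(
    surface: TerrainSurface, u: Cell, v: Cell, samples: int = 1009
) -> bool:
    """Dense-sampling line-of-sight oracle with exact height evaluation.

    Tests the open segment at >= ``samples`` evenly spaced interior points
    plus every surface breakpoint (grid-line and diagonal crossings).  The
    clearance function is piecewise linear with breakpoints only at those
    crossings, so including them makes the test exact despite sampling.
    """
    lat = surface.lattice
    uz, vz = lat.z(u), lat.z(v)
    ts = [Fraction(i, samples + 1) for i in range(1, samples + 1)]
    ts.extend(_breakpoints(u, v))
    for t in ts:
        x = u[0] + t * (v[0] - u[0])
        y = u[1] + t * (v[1] - u[1])
        z = uz + t * (vz - uz)
        for h in surface_heights_at(surface, x, y):
            if z <= h:
                return False
    return True


def node_blocked_bruteforce(lattice: Lattice3D, u: Cell, v: Cell) -> bool:
    """Node policy: a third node blocks when its column meets the sightline
    (it projects onto the open 2D segment and its elevation is at or above
    the sight height there).  Evaluated with rational arithmetic."""
    uz, vz = lattice.z(u), lattice.z(v)
    dx, dy = v[0] - u[0], v[1] - u[1]
    for w, rec in lattice.nodes.items():
        if w in (u, v):
            continue
        bx, by = w[0] - u[0], w[1] - u[1]
        if dx * by - dy * bx != 0:
            continue
        t = Fraction(dx * bx + dy * by, dx * dx + dy * dy)
        if not 0 < t < 1:
            continue
        if rec.z >= uz + t * (vz - uz):
            return True
    return False


# ---------------------------------------------------------------------------
# End-to-end build oracle
# ---------------------------------------------------------------------------


def build_pairs_bruteforce(
    lattice: Lattice3D, config: Optional[BuildConfig] = None, samples: int = 200
) -> Dict[Tuple[Cell, Cell], Tuple[str, str, Optional[Tuple[Cell, Cell]]]]:
    """Independent five-step build.

    Returns pair -> (step, mode, direction) with first-step-wins provenance,
    where direction is the ordered (source, target) for asymmetric dyads and
    None for mutual ones.
    """
    config = config or BuildConfig()
    result: Dict[Tuple[Cell, Cell], str] = {}
    for pair in sorted(adjacency_pairs_bruteforce(lattice)):
        result.setdefault(pair, "2")
    for pair in sorted(diagonal_pairs_bruteforce(lattice)):
        result.setdefault(pair, "3")
    for axis, tag in (("x", "4x"), ("y", "4y")):
        for pair in sorted(axis_pairs_bruteforce(lattice, axis)):
            result.setdefault(pair, tag)
    surface = TerrainSurface.from_lattice(lattice)
    for u, v in itertools.combinations(lattice.cells(), 2):
        pair = tuple(sorted((u, v)))
        if pair in result:
            continue
        if config.blocking == "surface":
            clear = segment_clears_surface_bruteforce(surface, u, v, samples)
        else:
            clear = not node_blocked_bruteforce(lattice, u, v)
        if clear:
            result[pair] = "5"
    out = {}
    for pair, step in result.items():
        u, v = pair
        mode, direction = _orient_bruteforce(lattice, u, v, step, config.orientation)
        out[pair] = (step, mode, direction)
    return out


def _orient_bruteforce(lattice, u, v, step, orientation):
    if orientation == "all-mutual" or (orientation == "default" and step == "2"):
        return "mutual", None
    if orientation == "temporal":
        pu, pv = lattice.nodes[u].seq_pos, lattice.nodes[v].seq_pos
        return "asym", ((u, v) if pu < pv else (v, u))
    zu, zv = lattice.z(u), lattice.z(v)
    if zu == zv:
        return "mutual", None
    return "asym", ((u, v) if zu > zv else (v, u))


def graph_pair_view(vg) -> Dict[Tuple, Tuple[str, str, Optional[Tuple]]]:
    """The comparable pair -> (step, mode, direction) view of a built graph."""
    out = {}
    for k, d in vg.dyads.items():
        out[k] = (d.step, d.mode, ((d.u, d.v) if d.mode == "asym" else None))
    return out
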