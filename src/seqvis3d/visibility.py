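"""Natural visibility graphs in 1D/2D and the five-step 3D lattice construction.

The 3D construction treats the embedded sequence lattice as an integer
terrain and connects nodes that can "see" each other:

  step 2   grid adjacency (4-neighbours),
  step 3   one diagonal per complete unit cell, through its highest corner,
  step 4   natural visibility along every row (4x) and column (4y) profile,
  step 5   general line of sight: the open 3D segment between two nodes must
           stay strictly above the triangulated terrain (surface policy), or
           merely avoid passing through a third node (node policy).

All geometric comparisons on integer lattices are carried out in exact
rational arithmetic; no floating-point tolerances are involved.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Dict, FrozenSet, Iterable, List, Optional, Sequence as Seq, Tuple

from .embedding import Lattice3D

__all__ = [
    "Dyad",
    "VisibilityGraph",
    "TerrainSurface",
    "BuildConfig",
    "natural_visibility_2d",
    "lattice_adjacency",
    "quadrilateral_diagonals",
    "axis_profile_visibility",
    "line_of_sight_visibility",
    "build_visibility_graph_3d",
]

Cell = Tuple[int, int]
Pair = Tuple[Cell, Cell]

ORIENTATIONS = ("default", "all-mutual", "z-descending", "temporal")


@dataclass(frozen=True)
class Dyad:
    """A connected node pair.  For ``mode == 'asym'`` the direction is u -> v."""

    u: object
    v: object
    mode: str  # "mutual" | "asym"
    step: str  # "2" | "3" | "4x" | "4y" | "5" | "2D"

    def key(self) -> Tuple:
        return tuple(sorted((self.u, self.v)))


@dataclass
class VisibilityGraph:
    """Node set plus dyads, each tagged with the construction step that
    produced it (first step wins; later steps never duplicate a pair)."""

    nodes: Tuple
    dyads: Dict[Tuple, Dyad] = field(default_factory=dict)
    meta: Dict[str, object] = field(default_factory=dict)

    @property
    def edge_count(self) -> int:
        """Unordered connected pairs; a mutual dyad counts once."""
        return len(self.dyads)

    def pairs(self) -> FrozenSet[Tuple]:
        return frozenset(self.dyads)

    def add(self, dyad: Dyad) -> bool:
        """Insert unless the pair is already present; returns True if added."""
        k = dyad.key()
        if dyad.u == dyad.v:
            raise ValueError("self-dyads are not allowed")
        if k in self.dyads:
            return False
        self.dyads[k] = dyad
        return True

    def to_networkx(self):
        """Directed view: mutual dyads become reciprocal arc pairs."""
        import networkx as nx

        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        for d in self.dyads.values():
            g.add_edge(d.u, d.v, step=d.step, mode=d.mode)
            if d.mode == "mutual":
                g.add_edge(d.v, d.u, step=d.step, mode=d.mode)
        return g

    @classmethod
    def from_networkx(cls, g) -> "VisibilityGraph":
        """Build from a directed graph; reciprocal arc pairs become mutual dyads."""
        vg = cls(nodes=tuple(sorted(g.nodes())))
        for u, v in g.edges():
            if tuple(sorted((u, v))) in vg.dyads:
                continue
            if g.has_edge(v, u):
                vg.add(Dyad(u, v, "mutual", "2D"))
            else:
                vg.add(Dyad(u, v, "asym", "2D"))
        return vg


# ---------------------------------------------------------------------------
# 1D / 2D natural visibility
# ---------------------------------------------------------------------------


def _visible_1d(points: Seq[Tuple], i: int, k: int) -> bool:
    """Exact natural-visibility test between profile points i < k.

    Points are (x, y) with x strictly increasing; every intermediate point
    must lie strictly below the chord from i to k.
    """
    xi, yi = points[i]
    xk, yk = points[k]
    for m in range(i + 1, k):
        xm, ym = points[m]
        # y_m < y_k + (y_i - y_k) (x_k - x_m) / (x_k - x_i), with x_k > x_i
        lhs = Fraction(ym - yk) * Fraction(xk - xi)
        rhs = Fraction(yi - yk) * Fraction(xk - xm)
        if lhs >= rhs:
            return False
    return True


def _nv_pairs(points: Seq[Tuple]) -> List[Tuple[int, int]]:
    out = []
    for i in range(len(points)):
        for k in range(i + 1, len(points)):
            if _visible_1d(points, i, k):
                out.append((i, k))
    return out


def natural_visibility_2d(series: Seq[Tuple[float, float]]) -> VisibilityGraph:
    """Natural visibility graph of a series of (x, y) data points.

    Nodes are the point indices 0..n-1; consecutive points are always
    connected.  Comparisons are exact (floats are converted to rationals).
    """
    xs = [p[0] for p in series]
    if any(b <= a for a, b in zip(xs, xs[1:])):
        raise ValueError("x coordinates must be strictly increasing")
    if not series:
        raise ValueError("series must be non-empty")
    pts = [(Fraction(x), Fraction(y)) for x, y in series]
    vg = VisibilityGraph(nodes=tuple(range(len(series))))
    for i, k in _nv_pairs(pts):
        vg.add(Dyad(i, k, "mutual", "2D"))
    return vg


# ---------------------------------------------------------------------------
# Step 2: lattice adjacency
# ---------------------------------------------------------------------------


def lattice_adjacency(lattice: Lattice3D) -> List[Dyad]:
    """4-neighbour adjacency dyads (mutual).  Border nodes have degree 2-3;
    absent cells contribute nothing."""
    out = []
    for (x, y) in lattice.cells():
        for nb in ((x + 1, y), (x, y + 1)):
            if nb in lattice.nodes:
                out.append(Dyad((x, y), nb, "mutual", "2"))
    return out


# ---------------------------------------------------------------------------
# Step 3: quadrilateral diagonals and the terrain triangulation
# ---------------------------------------------------------------------------


def _cell_corners(cx: int, cy: int) -> Tuple[Cell, Cell, Cell, Cell]:
    return ((cx, cy), (cx + 1, cy), (cx + 1, cy + 1), (cx, cy + 1))


def _choose_diagonal(lattice: Lattice3D, cx: int, cy: int) -> Optional[Tuple[Pair, str]]:
    """Diagonal of a complete unit cell through its maximum-z corner.

    Ties are broken by the lexicographically smallest (x, y) corner.
    Returns ((corner, opposite), 'main'|'anti') or None for incomplete cells.
    """
    corners = _cell_corners(cx, cy)
    if any(c not in lattice.nodes for c in corners):
        return None
    top = max(sorted(corners), key=lambda c: lattice.z(c))
    # sorted() puts lexicographically smaller corners first; max keeps the
    # first maximal element, implementing the tie rule.
    idx = corners.index(top)
    opposite = corners[(idx + 2) % 4]
    kind = "main" if top in ((cx, cy), (cx + 1, cy + 1)) else "anti"
    return (top, opposite), kind


def quadrilateral_diagonals(lattice: Lattice3D) -> List[Dyad]:
    """One diagonal dyad per complete unit cell (from the highest corner)."""
    out = []
    for cx in range(lattice.side - 1):
        for cy in range(lattice.side - 1):
            chosen = _choose_diagonal(lattice, cx, cy)
            if chosen is None:
                continue
            (a, b), _ = chosen
            out.append(Dyad(a, b, "mutual", "3"))
    return out


@dataclass(frozen=True)
class TerrainSurface:
    """Triangulated terrain over the lattice: each complete unit cell is split
    by its step-3 diagonal ('main' = low-left/high-right, 'anti' = the other)."""

    lattice: Lattice3D
    triangulation: Dict[Cell, str]

    @classmethod
    def from_lattice(cls, lattice: Lattice3D) -> "TerrainSurface":
        tri = {}
        for cx in range(lattice.side - 1):
            for cy in range(lattice.side - 1):
                chosen = _choose_diagonal(lattice, cx, cy)
                if chosen is not None:
                    tri[(cx, cy)] = chosen[1]
        return cls(lattice=lattice, triangulation=tri)

    def triangles(self) -> List[Tuple[Tuple[int, int, int], ...]]:
        """All surface triangles as 3-tuples of (x, y, z) integer vertices."""
        out = []
        lat = self.lattice
        for (cx, cy), kind in self.triangulation.items():
            p = {c: (c[0], c[1], lat.z(c)) for c in _cell_corners(cx, cy)}
            c00, c10, c11, c01 = _cell_corners(cx, cy)
            if kind == "main":  # diagonal c00-c11
                out.append((p[c00], p[c10], p[c11]))
                out.append((p[c00], p[c11], p[c01]))
            else:  # diagonal c10-c01
                out.append((p[c00], p[c10], p[c01]))
                out.append((p[c10], p[c11], p[c01]))
        return out


# ---------------------------------------------------------------------------
# Step 4: per-row / per-column profile visibility
# ---------------------------------------------------------------------------


def axis_profile_visibility(lattice: Lattice3D, axis: str) -> List[Dyad]:
    """Natural visibility applied to the elevation profile of every grid line.

    ``axis == 'x'``: within each row (fixed y) the profile is (x, z) over the
    existing nodes; two nodes connect iff every intermediate node of the row
    lies strictly below their chord.  ``axis == 'y'`` is the column analogue.
    """
    if axis not in ("x", "y"):
        raise ValueError("axis must be 'x' or 'y'")
    step = "4x" if axis == "x" else "4y"
    out = []
    for line in range(lattice.side):
        if axis == "x":
            cells = sorted(c for c in lattice.nodes if c[1] == line)
            pts = [(c[0], lattice.z(c)) for c in cells]
        else:
            cells = sorted((c for c in lattice.nodes if c[0] == line), key=lambda c: c[1])
            pts = [(c[1], lattice.z(c)) for c in cells]
        for i, k in _nv_pairs(pts):
            out.append(Dyad(cells[i], cells[k], "mutual", step))
    return out


# ---------------------------------------------------------------------------
# Step 5: general line of sight
# ---------------------------------------------------------------------------


def _clip_interval(P0: Cell, P1: Cell, tri2d: Tuple[Cell, Cell, Cell]):
    """Parameter interval [lo, hi] of t where P0 + t (P1 - P0) lies in the
    closed 2D triangle, intersected with [0, 1]; None when empty."""
    lo, hi = Fraction(0), Fraction(1)
    A, B, C = tri2d
    for (E0, E1, other) in ((A, B, C), (B, C, A), (C, A, B)):
        ex, ey = E1[0] - E0[0], E1[1] - E0[1]
        s = ex * (other[1] - E0[1]) - ey * (other[0] - E0[0])  # inward sign
        c0 = ex * (P0[1] - E0[1]) - ey * (P0[0] - E0[0])
        c1 = ex * (P1[1] - E0[1]) - ey * (P1[0] - E0[0])
        a, b = s * c0, s * c1  # need a + t (b - a) >= 0
        if a == b:
            if a < 0:
                return None
            continue
        bound = Fraction(-a, b - a)
        if b - a > 0:
            lo = max(lo, bound)
        else:
            hi = min(hi, bound)
        if lo > hi:
            return None
    return lo, hi


def _plane_height(tri3d, x: Fraction, y: Fraction) -> Fraction:
    (ax, ay, az), (bx, by, bz), (cx, cy, cz) = tri3d
    ux, uy, uz = bx - ax, by - ay, bz - az
    vx, vy, vz = cx - ax, cy - ay, cz - az
    nx_, ny_, nz_ = uy * vz - uz * vy, uz * vx - ux * vz, ux * vy - uy * vx
    # nz is nonzero for any non-degenerate lattice triangle
    return az - (Fraction(nx_) * (x - ax) + Fraction(ny_) * (y - ay)) / nz_


def _interval_clear(lo: Fraction, hi: Fraction, d) -> bool:
    """d is linear on [lo, hi] (a sub-interval of [0, 1]); require d > 0 on
    the open part excluding the sight endpoints t = 0, 1 where d vanishes by
    construction."""
    if lo == hi:
        return not (0 < lo < 1 and d(lo) <= 0)
    if lo == 0 and hi == 1:
        return False  # the whole sight lies in the obstacle's plane/line
    if lo > 0 and d(lo) <= 0:
        return False
    if hi < 1 and d(hi) <= 0:
        return False
    if lo == 0 and d(hi) <= 0:
        return False
    if hi == 1 and d(lo) <= 0:
        return False
    return True


def _node_blocks(u: Cell, uz: int, v: Cell, vz: int, w: Cell, wz: int) -> bool:
    """Exact test: does node w's column reach up to the open sight segment
    u -> v (i.e. w projects onto the open 2D segment and z_w is at or above
    the sight height there)?"""
    dx, dy = v[0] - u[0], v[1] - u[1]
    bx, by = w[0] - u[0], w[1] - u[1]
    if dx * by - dy * bx != 0:
        return False
    dot = dx * bx + dy * by
    length2 = dx * dx + dy * dy
    if not 0 < dot < length2:
        return False
    # sight height at t = dot / length2 is uz + (vz - uz) t
    return wz * length2 >= uz * length2 + (vz - uz) * dot


def _edge_blocks(u: Cell, uz: int, v: Cell, vz: int, edge) -> bool:
    """Exact test: does the terrain edge (a unit segment between adjacent
    nodes) rise to or above the open sight segment where their projections
    meet?"""
    (ax, ay, az), (bx, by, bz) = edge
    dx, dy = v[0] - u[0], v[1] - u[1]
    ex, ey = bx - ax, by - ay
    denom = dx * ey - dy * ex
    wx, wy = ax - u[0], ay - u[1]
    if denom != 0:
        t = Fraction(wx * ey - wy * ex, denom)
        s = Fraction(wx * dy - wy * dx, denom)
        if not (0 < t < 1 and 0 <= s <= 1):
            return False
        sight_z = uz + t * (vz - uz)
        edge_z = az + s * (bz - az)
        return sight_z <= edge_z
    # parallel: only collinear overlap can obstruct
    if wx * dy - wy * dx != 0:
        return False
    length2 = dx * dx + dy * dy
    ta = Fraction(wx * dx + wy * dy, length2)
    tb = Fraction((bx - u[0]) * dx + (by - u[1]) * dy, length2)
    (ta, za), (tb, zb) = sorted(((ta, az), (tb, bz)))
    lo, hi = max(ta, Fraction(0)), min(tb, Fraction(1))
    if lo > hi:
        return False

    def d(t: Fraction) -> Fraction:
        sight_z = uz + t * (vz - uz)
        edge_z = za + (t - ta) * (zb - za) / (tb - ta) if tb != ta else za
        return sight_z - edge_z

    return not _interval_clear(lo, hi, d)


def _segment_above_surface(surface: TerrainSurface, u: Cell, v: Cell,
                           cells_tris, edges) -> bool:
    """True iff the open segment between lattice nodes u, v stays strictly
    above the terrain wireframe and surface: every other node, every edge
    between adjacent nodes, and every cell triangle (the endpoints, which
    lie on the terrain, are exempt)."""
    lat = surface.lattice
    uz, vz = lat.z(u), lat.z(v)
    for w, rec in lat.nodes.items():
        if w != u and w != v and _node_blocks(u, uz, v, vz, w, rec.z):
            return False
    for edge in edges:
        if (edge[0][:2], edge[1][:2]) in ((u, v), (v, u)):
            continue
        if _edge_blocks(u, uz, v, vz, edge):
            return False
    P0, P1 = u, v
    dx, dy = P1[0] - P0[0], P1[1] - P0[1]
    for tri2d, tri3d, bbox in cells_tris:
        # cheap rejection: bounding boxes, then line straddle
        if max(P0[0], P1[0]) < bbox[0] or min(P0[0], P1[0]) > bbox[1]:
            continue
        if max(P0[1], P1[1]) < bbox[2] or min(P0[1], P1[1]) > bbox[3]:
            continue
        sides = [dx * (q[1] - P0[1]) - dy * (q[0] - P0[0]) for q in tri2d]
        if all(s > 0 for s in sides) or all(s < 0 for s in sides):
            continue
        iv = _clip_interval(P0, P1, tri2d)
        if iv is None:
            continue
        lo, hi = iv

        def d(t: Fraction) -> Fraction:
            x = P0[0] + t * dx
            y = P0[1] + t * dy
            z = uz + t * (vz - uz)
            return z - _plane_height(tri3d, x, y)

        if not _interval_clear(lo, hi, d):
            return False
    return True


def _terrain_edges(lattice: Lattice3D):
    """All wireframe edges (between 4-adjacent nodes) as 3D endpoint pairs."""
    out = []
    for (x, y) in lattice.cells():
        for nb in ((x + 1, y), (x, y + 1)):
            if nb in lattice.nodes:
                out.append(((x, y, lattice.z((x, y))), (*nb, lattice.z(nb))))
    return out


def _surface_tris(surface: TerrainSurface):
    """Precompute (2D triangle, 3D triangle, bbox) for every surface triangle."""
    out = []
    for tri3d in surface.triangles():
        tri2d = tuple((p[0], p[1]) for p in tri3d)
        xs = [p[0] for p in tri2d]
        ys = [p[1] for p in tri2d]
        out.append((tri2d, tri3d, (min(xs), max(xs), min(ys), max(ys))))
    return out


def line_of_sight_visibility(
    surface: TerrainSurface,
    policy: str = "surface",
    exclude: Iterable[Tuple] = (),
) -> List[Dyad]:
    """Step-5 dyads: every remaining node pair with a clear line of sight.

    ``policy='surface'`` (default) blocks a pair when its open 3D segment
    fails to stay strictly above the terrain (nodes, wireframe edges and
    cell triangles); ``policy='node'`` blocks only when a third node's
    column reaches up to the segment (a node exactly on, or poking above,
    the sightline).  Pairs listed in ``exclude`` (already produced by
    earlier steps) are not re-emitted.
    """
    if policy not in ("surface", "node"):
        raise ValueError("policy must be 'surface' or 'node'")
    lat = surface.lattice
    cells = lat.cells()
    excluded = set(exclude)
    out = []
    if policy == "surface":
        cells_tris = _surface_tris(surface)
        edges = _terrain_edges(lat)
    for u, v in itertools.combinations(cells, 2):
        if tuple(sorted((u, v))) in excluded:
            continue
        if policy == "surface":
            ok = _segment_above_surface(surface, u, v, cells_tris, edges)
        else:
            uz, vz = lat.z(u), lat.z(v)
            ok = not any(
                _node_blocks(u, uz, v, vz, w, lat.z(w))
                for w in cells
                if w != u and w != v
            )
        if ok:
            out.append(Dyad(u, v, "mutual", "5"))
    return out


# ---------------------------------------------------------------------------
# Full build
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BuildConfig:
    """Configuration of the 3D visibility-graph build.

    ``blocking`` selects the step-5 policy.  ``orientation`` decides dyad
    modes for the directed triad census:

      default      adjacency dyads mutual; step 3/4/5 dyads directed from the
                   higher to the lower endpoint, mutual on equal elevation
      all-mutual   every dyad mutual
      z-descending every dyad directed higher -> lower (equal -> mutual)
      temporal     every dyad directed from the earlier to the later
                   sequence position
    """

    blocking: str = "surface"
    orientation: str = "default"

    def __post_init__(self) -> None:
        if self.blocking not in ("surface", "node"):
            raise ValueError("blocking must be 'surface' or 'node'")
        if self.orientation not in ORIENTATIONS:
            raise ValueError(f"orientation must be one of {ORIENTATIONS}")


def _orient(dyad: Dyad, lattice: Lattice3D, orientation: str) -> Dyad:
    u, v = dyad.u, dyad.v
    if orientation == "all-mutual":
        return Dyad(u, v, "mutual", dyad.step)
    if orientation == "temporal":
        pu, pv = lattice.nodes[u].seq_pos, lattice.nodes[v].seq_pos
        return Dyad(u, v, "asym", dyad.step) if pu < pv else Dyad(v, u, "asym", dyad.step)
    zu, zv = lattice.z(u), lattice.z(v)
    if orientation == "default" and dyad.step == "2":
        return Dyad(u, v, "mutual", dyad.step)
    # z-descending (and default for steps 3/4/5)
    if zu == zv:
        return Dyad(u, v, "mutual", dyad.step)
    return Dyad(u, v, "asym", dyad.step) if zu > zv else Dyad(v, u, "asym", dyad.step)


def build_visibility_graph_3d(
    lattice: Lattice3D, config: Optional[BuildConfig] = None
) -> VisibilityGraph:
    """Union of construction steps 2, 3, 4x, 4y, 5 with first-step-wins
    provenance, oriented according to the configured policy."""
    config = config or BuildConfig()
    vg = VisibilityGraph(nodes=tuple(lattice.cells()))
    for dyad in lattice_adjacency(lattice):
        vg.add(_orient(dyad, lattice, config.orientation))
    for dyad in quadrilateral_diagonals(lattice):
        vg.add(_orient(dyad, lattice, config.orientation))
    for axis in ("x", "y"):
        for dyad in axis_profile_visibility(lattice, axis):
            vg.add(_orient(dyad, lattice, config.orientation))
    surface = TerrainSurface.from_lattice(lattice)
    for dyad in line_of_sight_visibility(surface, config.blocking, exclude=vg.pairs()):
        vg.add(_orient(dyad, lattice, config.orientation))
    vg.meta = {
        "blocking": config.blocking,
        "orientation": config.orientation,
        **({"lattice": dict(lattice.meta)} if lattice.meta else {}),
    }
    return vg
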