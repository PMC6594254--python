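"""Triad census, dyad-conditioned triad expectations, chi-square, features.

The census counts the 16 directed three-node isomorphism classes in the
Mutual-Asymmetric-Null labelling (003 ... 300).  The chi-square statistic
sums squared deviations of the observed counts from their expectations,
scaled by the variances, under a null model that holds the observed dyad
census (numbers of mutual, asymmetric and null pairs) fixed and treats all
graphs with that dyad census as equally likely.  Means and variances under
that null are computed exactly by enumerating the possible dyad-type
assignments of one triple (64 states), of two triples sharing a dyad (4^5)
and of two dyad-disjoint triples (4^6), with hypergeometric weights.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from fractions import Fraction
from functools import lru_cache
from typing import Dict, Sequence as Seq, Tuple

import numpy as np

from .visibility import VisibilityGraph

__all__ = [
    "TRIAD_TYPES",
    "TP_COLUMNS",
    "FEATURE_LAYOUT",
    "TriadCensus",
    "DyadCensus",
    "ExpectedTriadModel",
    "triad_census",
    "dyad_census",
    "expected_triads",
    "chi_square_statistic",
    "chi_square",
    "summary_stats",
    "feature_vector",
]

TRIAD_TYPES = (
    "003", "012", "102", "021D", "021U", "021C", "111D", "111U",
    "030T", "030C", "201", "120D", "120U", "120C", "210", "300",
)

#: The six census columns reported for sequence networks (TP1..TP6) and the
#: triad type each one counts.
TP_COLUMNS = (
    ("TP1", "102"),
    ("TP2", "003"),
    ("TP3", "012"),
    ("TP4", "021C"),
    ("TP5", "111D"),
    ("TP6", "111U"),
)


@dataclass(frozen=True)
class TriadCensus:
    """Counts over the 16 directed triad classes; sums to C(n, 3)."""

    counts: Dict[str, int]
    n_nodes: int

    def __post_init__(self) -> None:
        if set(self.counts) != set(TRIAD_TYPES):
            raise ValueError("census must cover exactly the 16 triad types")
        total = sum(self.counts.values())
        if total != math.comb(self.n_nodes, 3):
            raise ValueError(
                f"census sums to {total}, expected C({self.n_nodes},3)"
            )

    def __getitem__(self, t: str) -> int:
        return self.counts[t]

    def vector(self) -> np.ndarray:
        return np.array([self.counts[t] for t in TRIAD_TYPES], dtype=float)


@dataclass(frozen=True)
class DyadCensus:
    mutual: int
    asymmetric: int
    null: int

    @property
    def total(self) -> int:
        return self.mutual + self.asymmetric + self.null


def dyad_census(graph: VisibilityGraph) -> DyadCensus:
    n = len(graph.nodes)
    mutual = sum(1 for d in graph.dyads.values() if d.mode == "mutual")
    asym = len(graph.dyads) - mutual
    return DyadCensus(mutual, asym, math.comb(n, 2) - mutual - asym)


def triad_census(graph: VisibilityGraph) -> TriadCensus:
    """Classify every unordered node triple into its directed triad class."""
    import networkx as nx

    if len(graph.nodes) < 3:
        raise ValueError("triad census requires at least 3 nodes")
    counts = nx.triadic_census(graph.to_networkx())
    return TriadCensus(counts={t: int(counts[t]) for t in TRIAD_TYPES},
                       n_nodes=len(graph.nodes))


# ---------------------------------------------------------------------------
# Expected triad counts under the dyad-census-conditional null
# ---------------------------------------------------------------------------

# Slot states for one dyad slot between an ordered node pair (i, j):
#   0 null, 1 mutual, 2 arc i->j, 3 arc j->i
_SLOT_STATES = (0, 1, 2, 3)


@lru_cache(maxsize=None)
def _triple_type(states: Tuple[int, int, int]) -> str:
    """Triad type of a 3-node digraph given the slot states of pairs
    (1,2), (1,3), (2,3)."""
    import networkx as nx

    g = nx.DiGraph()
    g.add_nodes_from((1, 2, 3))
    for (i, j), s in zip(((1, 2), (1, 3), (2, 3)), states):
        if s == 1:
            g.add_edge(i, j)
            g.add_edge(j, i)
        elif s == 2:
            g.add_edge(i, j)
        elif s == 3:
            g.add_edge(j, i)
    census = nx.triadic_census(g)
    return next(t for t, c in census.items() if c == 1)


def _falling(x: int, k: int) -> int:
    out = 1
    for i in range(k):
        out *= x - i
    return out


def _state_weight(states: Tuple[int, ...], dc: DyadCensus, null: str) -> Fraction:
    """Probability that specific dyad slots carry the given states."""
    m = sum(1 for s in states if s == 1)
    a = sum(1 for s in states if s >= 2)
    nn = len(states) - m - a
    if null == "dyad":
        num = _falling(dc.mutual, m) * _falling(dc.asymmetric, a) * _falling(dc.null, nn)
        den = _falling(dc.total, len(states))
    else:  # "uniform": dyad types i.i.d. with the observed proportions
        num = dc.mutual ** m * dc.asymmetric ** a * dc.null ** nn
        den = dc.total ** len(states)
    if num == 0:
        return Fraction(0)
    return Fraction(num, den) / 2 ** a


@dataclass(frozen=True)
class ExpectedTriadModel:
    """Exact means and variances of the 16 triad counts under the null."""

    mu: Dict[str, Fraction]
    sigma2: Dict[str, Fraction]
    null: str
    n_nodes: int
    dyads: DyadCensus

    def mu_vector(self) -> np.ndarray:
        return np.array([float(self.mu[t]) for t in TRIAD_TYPES])

    def sigma2_vector(self) -> np.ndarray:
        return np.array([float(self.sigma2[t]) for t in TRIAD_TYPES])


def expected_triads(graph: VisibilityGraph, null: str = "dyad") -> ExpectedTriadModel:
    """Expectations and variances of each triad count under the chosen null.

    ``null='dyad'`` (default) conditions on the observed dyad census: the
    dyad types are a random permutation of the observed multiset, with each
    asymmetric dyad oriented uniformly.  ``null='uniform'`` draws each dyad
    type independently with the observed proportions.

    Both moments are exact rational numbers: the mean enumerates the 64
    states of one triple's dyad slots; the second moment additionally
    enumerates triple pairs sharing one dyad (4^5 states) and dyad-disjoint
    triple pairs (4^6 states).
    """
    if null not in ("dyad", "uniform"):
        raise ValueError("null must be 'dyad' or 'uniform'")
    n = len(graph.nodes)
    if n < 3:
        raise ValueError("expected_triads requires at least 3 nodes")
    dc = dyad_census(graph)
    n_triples = math.comb(n, 3)

    # per-triple type probabilities
    p = {t: Fraction(0) for t in TRIAD_TYPES}
    for states in itertools.product(_SLOT_STATES, repeat=3):
        p[_triple_type(states)] += _state_weight(states, dc, null)
    mu = {t: n_triples * p[t] for t in TRIAD_TYPES}

    # ordered pairs of distinct triples: sharing one dyad vs dyad-disjoint
    n_share = math.comb(n, 2) * (n - 2) * (n - 3)
    n_disjoint = n_triples * (n_triples - 1) - n_share

    q_share = {t: Fraction(0) for t in TRIAD_TYPES}
    if n_share:
        for states in itertools.product(_SLOT_STATES, repeat=5):
            w = _state_weight(states, dc, null)
            if w == 0:
                continue
            t1 = _triple_type(states[:3])       # shared slot + two own slots
            t2 = _triple_type((states[0],) + states[3:])
            if t1 == t2:
                q_share[t1] += w

    q_disj = {t: Fraction(0) for t in TRIAD_TYPES}
    if n_disjoint:
        for states in itertools.product(_SLOT_STATES, repeat=6):
            w = _state_weight(states, dc, null)
            if w == 0:
                continue
            t1 = _triple_type(states[:3])
            t2 = _triple_type(states[3:])
            if t1 == t2:
                q_disj[t1] += w

    sigma2 = {}
    for t in TRIAD_TYPES:
        second = mu[t] + n_share * q_share[t] + n_disjoint * q_disj[t]
        sigma2[t] = second - mu[t] ** 2
    return ExpectedTriadModel(mu=mu, sigma2=sigma2, null=null, n_nodes=n, dyads=dc)


# ---------------------------------------------------------------------------
# Chi-square
# ---------------------------------------------------------------------------


def chi_square_statistic(observed: Seq, mu: Seq, sigma2: Seq) -> float:
    """Sum of (x_i - mu_i)^2 / sigma_i^2.

    Cells with zero variance and x == mu are skipped (they carry no
    information under the null); zero variance with x != mu is an error.
    """
    if not (len(observed) == len(mu) == len(sigma2)):
        raise ValueError("observed, mu and sigma2 must have equal length")
    total = Fraction(0)
    for x, m, s2 in zip(observed, mu, sigma2):
        x, m, s2 = Fraction(x), Fraction(m), Fraction(s2)
        if s2 < 0:
            raise ValueError("negative variance")
        if s2 == 0:
            if x != m:
                raise ValueError(
                    f"zero variance with observed {float(x)} != expected {float(m)}"
                )
            continue
        total += (x - m) ** 2 / s2
    return float(total)


def chi_square(
    observed: TriadCensus, model: ExpectedTriadModel, variant: str = "variance"
) -> float:
    """Chi-square of a triad census against its expected model.

    ``variant='variance'`` uses the model variances as denominators (the
    triadic z-score tradition); ``variant='pearson'`` replaces them by the
    expected counts (zero-mean cells skipped).
    """
    x = [observed[t] for t in TRIAD_TYPES]
    mu = [model.mu[t] for t in TRIAD_TYPES]
    if variant == "variance":
        return chi_square_statistic(x, mu, [model.sigma2[t] for t in TRIAD_TYPES])
    if variant == "pearson":
        total = Fraction(0)
        for xi, mi in zip(x, mu):
            if mi == 0:
                continue
            total += (Fraction(xi) - mi) ** 2 / mi
        return float(total)
    raise ValueError("variant must be 'variance' or 'pearson'")


# ---------------------------------------------------------------------------
# Summaries and feature vectors
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SummaryStats:
    """Edge count (unordered pairs), triad census and chi-square of a graph."""

    edge_count: int
    census: TriadCensus
    chi_square: float


def summary_stats(
    graph: VisibilityGraph, null: str = "dyad", variant: str = "variance"
) -> SummaryStats:
    if len(graph.nodes) < 3:
        # no triples exist: the census is identically zero and so is chi-square
        census = TriadCensus(counts={t: 0 for t in TRIAD_TYPES},
                             n_nodes=len(graph.nodes))
        return SummaryStats(edge_count=graph.edge_count, census=census,
                            chi_square=0.0)
    census = triad_census(graph)
    model = expected_triads(graph, null=null)
    return SummaryStats(
        edge_count=graph.edge_count,
        census=census,
        chi_square=chi_square(census, model, variant=variant),
    )


#: Documented feature layout, version 1: the six reported triad counts, the
#: edge count, the chi-square, the four rank-digit counts and the length.
FEATURE_LAYOUT = (
    "TP1", "TP2", "TP3", "TP4", "TP5", "TP6",
    "S2_edges", "S3_chi_square",
    "n_digit_1", "n_digit_2", "n_digit_3", "n_digit_4",
    "length",
)


def feature_vector(
    graph: VisibilityGraph,
    encoding: str,
    null: str = "dyad",
    variant: str = "variance",
) -> np.ndarray:
    """Numeric feature vector of a sequence network for classification.

    Concatenates the six TP triad counts, the edge count, the chi-square and
    summary features of the rank-digit encoding (digit counts and length),
    in the order of :data:`FEATURE_LAYOUT`.
    """
    stats = summary_stats(graph, null=null, variant=variant)
    tp = [float(stats.census[t]) for _, t in TP_COLUMNS]
    digits = [float(encoding.count(d)) for d in "1234"]
    vec = np.array(
        tp + [float(stats.edge_count), stats.chi_square] + digits + [float(len(encoding))]
    )
    assert vec.shape == (len(FEATURE_LAYOUT),)
    return vec
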