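"""Readers and writers: FASTA, lattice TSV, Pajek, GraphML, edge lists, CSV.

All writers are deterministic byte-for-byte for fixed inputs and embed the
tool version plus the effective configuration as comment/metadata lines
where the format permits.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import pandas as pd

from . import __version__
from .embedding import Lattice3D, LatticeNode, Sequence, normalize_sequence
from .triads import FEATURE_LAYOUT
from .visibility import Dyad, VisibilityGraph

__all__ = [
    "read_fasta",
    "read_edits_csv",
    "write_lattice_tsv",
    "read_lattice_tsv",
    "write_pajek",
    "read_pajek",
    "write_graphml",
    "write_edgelist_tsv",
    "read_edgelist_tsv",
    "features_to_frame",
]


def read_fasta(path) -> List[Sequence]:
    """Read a multi-record FASTA file into validated, normalized sequences
    (uppercase, U -> T).  Raises on empty files and invalid residues."""
    from Bio import SeqIO

    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return [normalize_sequence(str(r.seq), id=r.id) for r in records]


def read_edits_csv(path) -> List[Tuple[str, int, str]]:
    """Read a 3-column CSV (id, position, alt) of single-base edits."""
    df = pd.read_csv(path, comment="#")
    cols = [c.lower() for c in df.columns]
    df.columns = cols
    missing = {"id", "position", "alt"} - set(cols)
    if missing:
        raise ValueError(f"edits CSV is missing columns: {sorted(missing)}")
    return [
        (str(r.id), int(r.position), str(r.alt)) for r in df.itertuples(index=False)
    ]


def _meta_lines(meta: Dict, comment: str) -> List[str]:
    lines = [f"{comment} seqvis3d {__version__}"]
    if meta:
        lines.append(f"{comment} config {json.dumps(meta, sort_keys=True)}")
    return lines


def write_lattice_tsv(lattice: Lattice3D, path) -> None:
    lines = _meta_lines(dict(lattice.meta), "#")
    lines.append(f"# side {lattice.side}")
    lines.append("x\ty\tz\tseq_pos\tbase")
    for cell in lattice.cells():
        node = lattice.nodes[cell]
        lines.append(f"{cell[0]}\t{cell[1]}\t{node.z}\t{node.seq_pos}\t{node.base}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_lattice_tsv(path) -> Lattice3D:
    side = None
    meta: Dict = {}
    rows = []
    for line in Path(path).read_text().splitlines():
        if line.startswith("# side"):
            side = int(line.split()[-1])
        elif line.startswith("# config"):
            meta = json.loads(line[len("# config") :])
        elif line.startswith("#") or line.startswith("x\t"):
            continue
        elif line.strip():
            rows.append(line.split("\t"))
    if side is None:
        raise ValueError(f"{path}: missing '# side' header")
    nodes = {
        (int(x), int(y)): LatticeNode(z=int(z), seq_pos=int(p), base=b)
        for x, y, z, p, b in rows
    }
    return Lattice3D(side=side, nodes=nodes, meta=meta)


def _node_label(node) -> str:
    if isinstance(node, tuple):
        return "_".join(str(c) for c in node)
    return str(node)


def _parse_label(label: str):
    parts = label.split("_")
    if len(parts) == 2 and all(p.lstrip("-").isdigit() for p in parts):
        return (int(parts[0]), int(parts[1]))
    return label


def write_pajek(graph: VisibilityGraph, path) -> None:
    """Pajek .net: 1-based vertex ids with quoted "x_y" labels; mutual dyads
    under *Edges, asymmetric under *Arcs."""
    nodes = sorted(graph.nodes)
    index = {v: i + 1 for i, v in enumerate(nodes)}
    lines = _meta_lines(dict(graph.meta), "%")
    lines.append(f"*Vertices {len(nodes)}")
    for v in nodes:
        lines.append(f'{index[v]} "{_node_label(v)}"')
    arcs = [d for d in graph.dyads.values() if d.mode == "asym"]
    edges = [d for d in graph.dyads.values() if d.mode == "mutual"]
    lines.append("*Arcs")
    for d in sorted(arcs, key=lambda d: (index[d.u], index[d.v])):
        lines.append(f"{index[d.u]} {index[d.v]} 1")
    lines.append("*Edges")
    for d in sorted(edges, key=lambda d: d.key()):
        a, b = sorted((index[d.u], index[d.v]))
        lines.append(f"{a} {b} 1")
    Path(path).write_text("\n".join(lines) + "\n")


def read_pajek(path) -> VisibilityGraph:
    """Read the Pajek dialect written by :func:`write_pajek`.  Step tags are
    not stored in .net files; dyads come back tagged 'pajek'."""
    nodes: Dict[int, object] = {}
    section = None
    dyads: List[Tuple[int, int, str]] = []
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("%"):
            continue
        low = line.lower()
        if low.startswith("*vertices"):
            section = "vertices"
            continue
        if low.startswith("*arcs"):
            section = "arcs"
            continue
        if low.startswith("*edges"):
            section = "edges"
            continue
        if section == "vertices":
            idx, label = line.split(maxsplit=1)
            nodes[int(idx)] = _parse_label(label.strip().strip('"'))
        elif section in ("arcs", "edges"):
            a, b = line.split()[:2]
            dyads.append((int(a), int(b), section))
    vg = VisibilityGraph(nodes=tuple(sorted(nodes.values())))
    for a, b, section in dyads:
        mode = "asym" if section == "arcs" else "mutual"
        vg.add(Dyad(nodes[a], nodes[b], mode, "pajek"))
    return vg


def write_graphml(graph: VisibilityGraph, path) -> None:
    import networkx as nx

    g = nx.DiGraph()
    for v in sorted(graph.nodes):
        g.add_node(_node_label(v))
    for d in graph.dyads.values():
        g.add_edge(_node_label(d.u), _node_label(d.v), step=d.step, mode=d.mode)
        if d.mode == "mutual":
            g.add_edge(_node_label(d.v), _node_label(d.u), step=d.step, mode=d.mode)
    g.graph["generator"] = f"seqvis3d {__version__}"
    g.graph["config"] = json.dumps(graph.meta, sort_keys=True)
    nx.write_graphml(g, str(path))


def write_edgelist_tsv(graph: VisibilityGraph, path) -> None:
    lines = _meta_lines(dict(graph.meta), "#")
    lines.append("u\tv\tmode\tstep")
    for key in sorted(graph.dyads):
        d = graph.dyads[key]
        lines.append(f"{_node_label(d.u)}\t{_node_label(d.v)}\t{d.mode}\t{d.step}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_edgelist_tsv(path) -> VisibilityGraph:
    meta: Dict = {}
    dyads = []
    for line in Path(path).read_text().splitlines():
        if line.startswith("# config"):
            meta = json.loads(line[len("# config") :])
        elif line.startswith("#") or line.startswith("u\t") or not line.strip():
            continue
        else:
            u, v, mode, step = line.split("\t")
            dyads.append(Dyad(_parse_label(u), _parse_label(v), mode, step))
    nodes = sorted({d.u for d in dyads} | {d.v for d in dyads})
    vg = VisibilityGraph(nodes=tuple(nodes), meta=meta)
    for d in dyads:
        vg.add(d)
    return vg


def features_to_frame(
    ids: List[str],
    vectors,
    labels: Optional[List[int]] = None,
) -> pd.DataFrame:
    """Feature matrix as a DataFrame with the documented column layout
    (TP1..TP6, S2/S3, digit counts, length) plus id and optional Y."""
    df = pd.DataFrame(vectors, columns=list(FEATURE_LAYOUT))
    df.insert(0, "id", ids)
    if labels is not None:
        df["Y"] = labels
    return df
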