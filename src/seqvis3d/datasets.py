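"""Packaged fixtures: the printed prediction table and SNP-edit metadata.

``table4.csv`` carries the experimental labels (row E) and the 0/1
predictions of each method (NN1..NN3, H1..H3, and the hyper-hybrid rows) on
the ten reference/variant networks, exactly as printed; agreement between a
method row and row E is the reported precision of that method.
``snp_edits.csv`` carries the five reference miRNA polymorphisms (mark,
rs number, 1-based position, reference and alternate base) used to pair
each reference sequence with its cancer-associated variant.
"""

from __future__ import annotations

from importlib import resources
from typing import Dict

import pandas as pd

from .hybrid import percent_agreement

__all__ = ["load_table4", "load_snp_edits", "table4_agreement"]


def _data_path(name: str):
    return resources.files("seqvis3d") / "data" / name


def load_table4() -> pd.DataFrame:
    """The prediction table, indexed by method row ('E' first), columns in
    the printed order D1, C1, D2, C2, D3, C3, C4, D4, C5, D5."""
    with resources.as_file(_data_path("table4.csv")) as p:
        df = pd.read_csv(p)
    return df.set_index("method")


def load_snp_edits() -> pd.DataFrame:
    """Reference miRNA polymorphism metadata (one single-base edit each)."""
    with resources.as_file(_data_path("snp_edits.csv")) as p:
        return pd.read_csv(p)


def table4_agreement() -> Dict[str, float]:
    """Percent agreement of every prediction row against the experimental
    row E, computed positionally over the ten printed columns."""
    df = load_table4()
    reference = df.loc["E"].to_numpy()
    return {
        method: percent_agreement(df.loc[method].to_numpy(), reference)
        for method in df.index
        if method != "E"
    }
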