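"""Published worked-example data: differentially expressed wheat miRNAs and
fungal (Clonostachys rosea) milRNAs from a biocontrol-fungus / wheat-root
interaction experiment.

The packaged table carries, per small RNA, the mature sequence, the total
read count, and the reported log2 fold changes with their FDR-significance
flags for three contrasts: wildtype interaction versus the respective
mono-culture control (``crwr``), and the two Dicer-deletion interactions
versus the wildtype interaction (``ddcl1``, ``ddcl2``).  It serves as a
fixed input for exercising the differential-expression call rule and the
approximate-matching quantifier on real printed sequences.
"""

from __future__ import annotations

from importlib import resources
from typing import Dict

import pandas as pd

CONTRASTS = ("crwr", "ddcl1", "ddcl2")


def load_mirna_de_table() -> pd.DataFrame:
    """The packaged miRNA/milRNA differential-expression table."""
    ref = resources.files("xksilence").joinpath("data/mirna_de_table.tsv")
    with ref.open() as fh:
        table = pd.read_csv(fh, sep="\t", index_col="id")
    for c in CONTRASTS:
        table[f"sig_{c}"] = table[f"sig_{c}"].astype(bool)
    return table


def de_call(log2fc: float, significant: bool, fc_threshold: float = 1.5) -> str:
    """The thresholded call rule: up/down needs |log2FC| >= threshold AND
    FDR significance, otherwise ns."""
    if significant and abs(log2fc) >= fc_threshold:
        return "up" if log2fc > 0 else "down"
    return "ns"


def call_counts(
    table: pd.DataFrame,
    contrast: str,
    group: str | None = None,
    fc_threshold: float = 1.5,
) -> Dict[str, int]:
    """Numbers of up/down/ns calls for one contrast, optionally one group
    (``wheat`` miRNAs or ``fungal`` milRNAs)."""
    if contrast not in CONTRASTS:
        raise ValueError(f"contrast must be one of {CONTRASTS}")
    sub = table if group is None else table[table["group"] == group]
    calls = [
        de_call(lfc, sig, fc_threshold)
        for lfc, sig in zip(sub[f"log2fc_{contrast}"], sub[f"sig_{contrast}"])
    ]
    return {
        "up": calls.count("up"),
        "down": calls.count("down"),
        "ns": calls.count("ns"),
    }


def mature_sequences(table: pd.DataFrame | None = None) -> Dict[str, str]:
    """id -> mature sequence mapping from the packaged table."""
    if table is None:
        table = load_mirna_de_table()
    return dict(table["mature_seq"])
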