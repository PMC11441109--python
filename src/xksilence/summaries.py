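"""Descriptive analytics: sRNA length and 5' base profiles, antisense
percentile-rank expression analysis, and qPCR-derived quantities.

The percentile-rank analysis asks whether transcripts attracting many
antisense small RNAs are, on average, less expressed: genes are ranked by
antisense sRNA count (genes with zero antisense counts are excluded),
binned into quintiles of the percentile rank, and per-bin mean normalized
expression is compared by one-way ANOVA with Tukey HSD; bins sharing a
compact-display letter are not significantly different.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .reads import SmallRNARead

LENGTH_RANGE = range(18, 33)
BASES = ("A", "C", "G", "U")


@dataclass
class DistributionSummary:
    """Multiplicity-weighted read fractions by length and 5' nucleotide."""

    length_fractions: Dict[int, float]
    base5_fractions: Dict[str, float]
    label: str = ""
    n_reads: int = 0


def length_and_5p_distribution(
    reads: Iterable[SmallRNARead], label: str = ""
) -> DistributionSummary:
    """Fractions of reads per length and per 5' base; fractions sum to 1."""
    length_counts: Dict[int, float] = {}
    base_counts: Dict[str, float] = {b: 0.0 for b in BASES}
    total = 0
    for read in reads:
        m = read.multiplicity
        total += m
        length_counts[len(read)] = length_counts.get(len(read), 0.0) + m
        base_counts[read.sequence[0]] += m
    if total == 0:
        raise ValueError("empty read set")
    return DistributionSummary(
        length_fractions={k: v / total for k, v in sorted(length_counts.items())},
        base5_fractions={b: v / total for b, v in base_counts.items()},
        label=label,
        n_reads=total,
    )


# ---------------------------------------------------------------------------
# percentile-rank analysis
# ---------------------------------------------------------------------------

@dataclass
class PercentileBinReport:
    """Per-quintile mean expression with Tukey compact letter display."""

    table: pd.DataFrame  # index: bin label; columns: n_genes, mean_expression, letters
    anova_p: float
    gene_bins: pd.Series = field(repr=False, default=None)


def compact_letter_display(
    groups: Sequence[str], significant: Mapping[Tuple[str, str], bool]
) -> Dict[str, str]:
    """Insert-and-absorb letter assignment.

    Groups sharing a letter are not significantly different; every
    significantly different pair shares no letter.
    """
    letter_sets: List[set] = [set(groups)]
    for (g1, g2), sig in significant.items():
        if not sig:
            continue
        for s in [s for s in letter_sets if g1 in s and g2 in s]:
            letter_sets.remove(s)
            a, b = s - {g2}, s - {g1}
            for candidate in (a, b):
                if not any(candidate <= other for other in letter_sets):
                    letter_sets.append(candidate)
    # deterministic letter order: by first (in group order) member
    order = {g: i for i, g in enumerate(groups)}
    letter_sets.sort(key=lambda s: min(order[g] for g in s))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out: Dict[str, str] = {g: "" for g in groups}
    for letter, s in zip(alphabet, letter_sets):
        for g in groups:
            if g in s:
                out[g] += letter
    return out


def percentile_rank_analysis(
    antisense_counts: pd.Series,
    expression: pd.Series,
    n_bins: int = 5,
    alpha: float = 0.05,
) -> PercentileBinReport:
    """Bin genes by percentile rank of antisense sRNA counts and compare
    mean expression between bins.

    Genes with zero antisense counts are excluded up front.  Percentile
    ranks use mean ranks for ties, scaled to (0, 100]; bin edges are
    right-closed ((0,20], (20,40], ...).  Tukey HSD at ``alpha`` produces
    the letter display.
    """
    genes = antisense_counts.index.intersection(expression.index)
    counts = antisense_counts.loc[genes]
    counts = counts[counts > 0]
    if counts.empty:
        raise ValueError("no gene has a positive antisense count")
    expr = expression.loc[counts.index].astype(float)
    pct = pd.Series(
        stats.rankdata(counts.to_numpy()) / len(counts) * 100.0, index=counts.index
    )
    edges = np.linspace(0, 100, n_bins + 1)
    labels = [f"{int(lo) + 1}-{int(hi)}" for lo, hi in zip(edges[:-1], edges[1:])]
    bins = pd.cut(pct, bins=edges, labels=labels, right=True, include_lowest=False)
    occupied = [lab for lab in labels if (bins == lab).any()]
    if len(occupied) < 2:
        raise ValueError("fewer than 2 non-empty percentile bins; cannot compare")

    table = pd.DataFrame(
        {
            "n_genes": bins.value_counts().reindex(labels).fillna(0).astype(int),
            "mean_expression": expr.groupby(bins, observed=True).mean().reindex(labels),
        }
    )
    anova_groups = [expr[bins == lab].to_numpy() for lab in occupied]
    anova_p = float(stats.f_oneway(*anova_groups).pvalue)

    if all(len(g) > 1 for g in anova_groups) and expr.var() > 0:
        tukey = pairwise_tukeyhsd(
            expr.to_numpy(), np.asarray(bins.astype(str)), alpha=alpha
        )
        res = pd.DataFrame(
            tukey.summary().data[1:], columns=tukey.summary().data[0]
        )
        significant = {
            (r["group1"], r["group2"]): bool(r["reject"]) for _, r in res.iterrows()
        }
    else:
        significant = {}
    letters = compact_letter_display(occupied, significant)
    table["letters"] = [letters.get(lab, "") for lab in labels]
    return PercentileBinReport(table=table, anova_p=anova_p, gene_bins=bins)


# ---------------------------------------------------------------------------
# qPCR-derived quantities
# ---------------------------------------------------------------------------

def ddct(measurements: pd.DataFrame) -> float:
    """Relative expression by the 2^-ddCt method.

    ``measurements`` needs columns target_ct, reference_ct and condition
    (values "treatment" / "calibrator"); replicate Ct values are averaged
    per condition before the double difference.
    """
    required = {"target_ct", "reference_ct", "condition"}
    if not required <= set(measurements.columns):
        raise ValueError(f"measurements need columns {sorted(required)}")
    if (measurements[["target_ct", "reference_ct"]] <= 0).any().any():
        raise ValueError("Ct values must be positive")
    dct = measurements["target_ct"] - measurements["reference_ct"]
    by_cond = dct.groupby(measurements["condition"]).mean()
    for cond in ("treatment", "calibrator"):
        if cond not in by_cond.index:
            raise ValueError(f"missing {cond} measurements")
    return float(2.0 ** -(by_cond["treatment"] - by_cond["calibrator"]))


def quantity_from_ct(ct: float) -> float:
    """Relative DNA quantity 2^-Ct against an implicit shared baseline."""
    if ct <= 0:
        raise ValueError("Ct must be positive")
    return 2.0**-ct


def colonization_ratio(fungal_quantity: float, plant_quantity: float) -> float:
    """Fungal / plant marker DNA ratio (root-colonization proxy).

    Both quantities must be positive and on a common relative scale
    (2^-Ct against a shared baseline, or standard-curve quantities).
    """
    if fungal_quantity <= 0 or plant_quantity <= 0:
        raise ValueError("marker quantities must be positive")
    return fungal_quantity / plant_quantity
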