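"""Quantification of mature miRNAs by approximate matching in clean reads.

A read contributes its multiplicity when the mature sequence occurs within
it at edit distance <= max_errors (substitutions, insertions and deletions,
the default error model of agrep-style matching); a substitution-only
Hamming mode is available as the alternative reading of "one mismatch".
Counting is strand-specific (catalogs are oriented) and each read is
counted at most once per miRNA, but a read may legitimately count towards
several near-identical catalog entries (isomiR families), matching
independent per-miRNA searches.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence

import pandas as pd

from .expression import differential_expression, library_size_factors
from .reads import SmallRNARead
from .seq import hamming_window_match, infix_match, normalize_rna

DETECTION_MIN_COPIES = 50


@dataclass
class MiRNARecord:
    """A catalog miRNA with its per-sample approximate-match counts."""

    id: str
    mature_seq: str
    species: str = ""
    per_sample_counts: Dict[str, int] = field(default_factory=dict)
    detected: bool = False

    def __post_init__(self):
        self.mature_seq = normalize_rna(self.mature_seq)
        if not 18 <= len(self.mature_seq) <= 32:
            raise ValueError(
                f"mature sequence of {self.id} has length {len(self.mature_seq)}, "
                "outside the small-RNA bounds [18, 32]"
            )

    @property
    def total_count(self) -> int:
        return sum(self.per_sample_counts.values())


def approximate_count(
    mature: str,
    reads: Iterable[SmallRNARead],
    max_errors: int = 1,
    mode: str = "edit",
) -> Dict[str, int]:
    """Per-sample multiplicity-weighted counts of a mature sequence.

    ``mode="edit"`` allows indels (edit distance); ``mode="hamming"``
    restricts to substitutions within equal-length read windows.
    """
    mature = normalize_rna(mature)
    match = infix_match if mode == "edit" else hamming_window_match
    if mode not in ("edit", "hamming"):
        raise ValueError("mode must be 'edit' or 'hamming'")
    counts: Dict[str, int] = {}
    cache: Dict[str, bool] = {}
    any_long_enough = False
    for read in reads:
        # with indels a shorter read can still host the pattern via deletions
        if len(read) >= len(mature) - (max_errors if mode == "edit" else 0):
            any_long_enough = True
        hit = cache.get(read.sequence)
        if hit is None:
            hit = match(mature, read.sequence, max_errors)
            cache[read.sequence] = hit
        if hit:
            counts[read.sample_id] = counts.get(read.sample_id, 0) + read.multiplicity
    if not any_long_enough:
        warnings.warn(
            f"mature sequence ({len(mature)} nt) is longer than every read; "
            "counts are zero"
        )
    return counts


def quantify_catalog(
    catalog: Mapping[str, str],
    reads_by_sample: Mapping[str, Sequence[SmallRNARead]],
    max_errors: int = 1,
    mode: str = "edit",
    species: Optional[Mapping[str, str]] = None,
) -> List[MiRNARecord]:
    """Count every catalog mature sequence in every sample's clean reads."""
    records = []
    samples = list(reads_by_sample)
    for mid in catalog:
        rec = MiRNARecord(
            id=mid,
            mature_seq=catalog[mid],
            species="" if species is None else species.get(mid, ""),
        )
        rec.per_sample_counts = {s: 0 for s in samples}
        for sample in samples:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                hits = approximate_count(
                    rec.mature_seq, reads_by_sample[sample], max_errors, mode
                )
            rec.per_sample_counts[sample] = sum(hits.values())
        records.append(rec)
    return records


def detect_expressed(
    mirnas: Iterable[MiRNARecord], min_copies: int = DETECTION_MIN_COPIES
) -> List[MiRNARecord]:
    """Flag miRNAs whose summed counts reach ``min_copies`` (inclusive)."""
    out = []
    for rec in mirnas:
        rec.detected = rec.total_count >= min_copies
        out.append(rec)
    return out


def counts_table(mirnas: Iterable[MiRNARecord]) -> pd.DataFrame:
    """miRNA x sample integer count matrix from quantified records."""
    records = list(mirnas)
    return pd.DataFrame(
        {rec.id: rec.per_sample_counts for rec in records}
    ).T.fillna(0).astype(int)


def mirna_differential_expression(
    counts: pd.DataFrame,
    condition_a: Sequence[str],
    condition_b: Sequence[str],
    fc_threshold: float = 1.5,
    alpha: float = 0.05,
    factors: Optional[pd.Series] = None,
) -> pd.DataFrame:
    """NB Wald differential expression on a miRNA count table.

    Same thresholds as the transcript-level test; normalization defaults to
    library-size factors because miRNA tables routinely contain features
    that are structurally absent from one condition, which breaks
    median-of-ratios.
    """
    if factors is None:
        factors = library_size_factors(counts[list(condition_a) + list(condition_b)])
    return differential_expression(
        counts, condition_a, condition_b, fc_threshold, alpha, factors
    )
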