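"""Small-RNA read triage: length filtering, structural-RNA removal,
collapsing, and partitioning between two interacting species.

The triage contract mirrors standard dual sRNA-seq practice: reads are kept
when 18-32 nt long, cleaned of rRNA/tRNA/sn(o)RNA fragments, collapsed to
unique sequences per sample, and assigned to the species whose transcriptome
they match (either orientation) within a configurable edit tolerance; reads
matching both transcriptomes are ambiguous and excluded downstream, reads
matching neither are unmapped.  Matching is approximate substring search
against transcriptomes (not spliced genome alignment).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple

from .seq import infix_locations, infix_match, normalize_rna, reverse_complement

#: cap on recorded placements per read within one species
MAX_PLACEMENTS = 200


@dataclass(frozen=True)
class SmallRNARead:
    """A (possibly collapsed) small-RNA read."""

    sequence: str
    multiplicity: int = 1
    sample_id: str = ""

    def __post_init__(self):
        object.__setattr__(self, "sequence", normalize_rna(self.sequence))
        if self.multiplicity < 1:
            raise ValueError("multiplicity must be >= 1")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class ReadHit:
    """One placement of a read on a transcript.

    ``strand`` is "sense" when the read matches the transcript as-is and
    "antisense" when its reverse complement does.  Coordinates are 0-based,
    half-open, on the transcript; ties between equal-distance placements are
    broken leftmost-lowest (transcript id, then position).
    """

    transcript_id: str
    strand: str
    start: int
    end: int
    edit_distance: int


@dataclass
class PartitionResult:
    """Reads split into the four disjoint triage classes.

    ``hits_a``/``hits_b`` record placements (per read sequence) on the
    respective transcriptome for reads that map to that species at all;
    ambiguous reads have hits on both, unmapped reads on neither.
    """

    unique_to_a: List[SmallRNARead] = field(default_factory=list)
    unique_to_b: List[SmallRNARead] = field(default_factory=list)
    ambiguous: List[SmallRNARead] = field(default_factory=list)
    unmapped: List[SmallRNARead] = field(default_factory=list)
    hits_a: Dict[str, List[ReadHit]] = field(default_factory=dict)
    hits_b: Dict[str, List[ReadHit]] = field(default_factory=dict)

    def tallies(self) -> Dict[str, int]:
        """Multiplicity-weighted read totals per class."""
        return {
            "unique_to_a": sum(r.multiplicity for r in self.unique_to_a),
            "unique_to_b": sum(r.multiplicity for r in self.unique_to_b),
            "ambiguous": sum(r.multiplicity for r in self.ambiguous),
            "unmapped": sum(r.multiplicity for r in self.unmapped),
        }

    def total(self) -> int:
        return sum(self.tallies().values())


# ---------------------------------------------------------------------------
# filtering and collapsing
# ---------------------------------------------------------------------------

def length_filter(
    reads: Iterable[SmallRNARead], min_len: int = 18, max_len: int = 32
) -> List[SmallRNARead]:
    """Keep reads with ``min_len <= length <= max_len`` (boundaries inclusive)."""
    if min_len > max_len:
        raise ValueError(f"min_len {min_len} > max_len {max_len}")
    return [r for r in reads if min_len <= len(r) <= max_len]


def remove_structural(
    reads: Iterable[SmallRNARead],
    structural_ref: Sequence[str],
    max_errors: int = 0,
) -> List[SmallRNARead]:
    """Drop reads occurring inside any structural reference within
    ``max_errors`` edits; survivors keep their multiplicities."""
    refs = [normalize_rna(s) for s in structural_ref]
    if not refs:
        warnings.warn("empty structural reference set: passing all reads through")
        return list(reads)
    kept = []
    cache: Dict[str, bool] = {}
    for read in reads:
        seq = read.sequence
        hit = cache.get(seq)
        if hit is None:
            hit = any(infix_match(seq, ref, max_errors) for ref in refs)
            cache[seq] = hit
        if not hit:
            kept.append(read)
    return kept


def collapse_reads(reads: Iterable[SmallRNARead]) -> List[SmallRNARead]:
    """Merge identical sequences within a sample, summing multiplicities.

    Total multiplicity is conserved; output order follows first occurrence.
    """
    merged: Dict[Tuple[str, str], int] = {}
    for read in reads:
        key = (read.sample_id, read.sequence)
        merged[key] = merged.get(key, 0) + read.multiplicity
    return [
        SmallRNARead(sequence=seq, multiplicity=mult, sample_id=sample)
        for (sample, seq), mult in merged.items()
    ]


# ---------------------------------------------------------------------------
# species partitioning
# ---------------------------------------------------------------------------

def _scan_reference(
    seq: str, reference: Mapping[str, str], max_errors: int
) -> List[ReadHit]:
    """All transcript placements of ``seq`` (either orientation) within
    ``max_errors`` edits, capped at MAX_PLACEMENTS, leftmost-lowest order."""
    rc = reverse_complement(seq)
    hits: List[ReadHit] = []
    for tid in sorted(reference):
        transcript = reference[tid]
        for strand, probe in (("sense", seq), ("antisense", rc)):
            d, locs = infix_locations(probe, transcript, max_errors)
            if d < 0:
                continue
            start, end = locs[0]
            hits.append(ReadHit(tid, strand, start, end, d))
        if len(hits) >= MAX_PLACEMENTS:
            break
    return hits[:MAX_PLACEMENTS]


def partition_by_species(
    reads: Iterable[SmallRNARead],
    ref_a: Mapping[str, str],
    ref_b: Mapping[str, str],
    max_errors: int = 1,
) -> PartitionResult:
    """Assign each read to {unique_to_a, unique_to_b, ambiguous, unmapped}.

    A read "maps" to a species iff it or its reverse complement occurs as a
    substring of any transcript of that species within ``max_errors`` edits.
    The four classes partition the input exactly.
    """
    if not ref_a or not ref_b:
        raise ValueError("both references must be non-empty")
    norm_a = {t: normalize_rna(s) for t, s in ref_a.items()}
    norm_b = {t: normalize_rna(s) for t, s in ref_b.items()}

    result = PartitionResult()
    seen: Dict[str, Tuple[str, List[ReadHit], List[ReadHit]]] = {}
    for read in reads:
        seq = read.sequence
        if seq in seen:
            cls, hits_a, hits_b = seen[seq]
        else:
            hits_a = _scan_reference(seq, norm_a, max_errors)
            hits_b = _scan_reference(seq, norm_b, max_errors)
            if hits_a and hits_b:
                cls = "ambiguous"
            elif hits_a:
                cls = "unique_to_a"
            elif hits_b:
                cls = "unique_to_b"
            else:
                cls = "unmapped"
            seen[seq] = (cls, hits_a, hits_b)
        getattr(result, cls).append(read)
        if hits_a:
            result.hits_a[seq] = hits_a
        if hits_b:
            result.hits_b[seq] = hits_b
    return result


def strand_counts(
    partition: PartitionResult, species: str = "a"
) -> Dict[str, Dict[str, float]]:
    """Per-transcript multiplicity-weighted read counts by orientation.

    Only reads unique to the requested species contribute.  A read with
    several placements within the species is counted once per transcript
    hit, each weighted 1/n_placements, so total counts are conserved.
    Returns ``{"sense": {tid: count}, "antisense": {tid: count}}``.
    """
    if species == "a":
        unique, hits = partition.unique_to_a, partition.hits_a
    elif species == "b":
        unique, hits = partition.unique_to_b, partition.hits_b
    else:
        raise ValueError("species must be 'a' or 'b'")
    counts: Dict[str, Dict[str, float]] = {"sense": {}, "antisense": {}}
    for read in unique:
        placements = hits[read.sequence]
        weight = read.multiplicity / len(placements)
        for hit in placements:
            bucket = counts[hit.strand]
            bucket[hit.transcript_id] = bucket.get(hit.transcript_id, 0.0) + weight
    return counts
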