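"""File-format glue: FASTA/FASTQ via Biopython, TSV tables via pandas.

Collapsed reads are written in the ``>seq{i}_x{multiplicity}`` FASTA
dialect; count tables are TSV with the feature id in the first column and
sample ids as the header row.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Dict, Iterable, List, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .reads import SmallRNARead
from .seq import normalize_rna

_X_SUFFIX = re.compile(r"_x(\d+)$")


def read_fasta(path) -> Dict[str, str]:
    """FASTA records as an id -> RNA-normalized sequence mapping."""
    return {rec.id: normalize_rna(str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fastq(path, sample_id: str = "") -> List[SmallRNARead]:
    sample = sample_id or Path(str(path)).stem
    return [
        SmallRNARead(str(rec.seq), 1, sample) for rec in SeqIO.parse(str(path), "fastq")
    ]


def write_fastq(reads: Iterable[SmallRNARead], path) -> None:
    """Uniform-quality FASTQ (the pipeline ignores qualities)."""
    records = []
    for i, read in enumerate(reads, 1):
        for copy in range(read.multiplicity):
            rec = SeqRecord(Seq(read.sequence), id=f"read{i}_{copy + 1}", description="")
            rec.letter_annotations["phred_quality"] = [40] * len(read)
            records.append(rec)
    SeqIO.write(records, str(path), "fastq")


def write_collapsed_fasta(reads: Iterable[SmallRNARead], path) -> None:
    """Collapsed reads as ``>seq{i}_x{multiplicity}`` FASTA."""
    seqs = {
        f"seq{i}_x{read.multiplicity}": read.sequence
        for i, read in enumerate(reads, 1)
    }
    write_fasta(seqs, path)


def read_collapsed_fasta(path, sample_id: str = "") -> List[SmallRNARead]:
    """Inverse of ``write_collapsed_fasta``; headers without an ``_x``
    suffix count as multiplicity 1."""
    sample = sample_id or Path(str(path)).stem
    reads = []
    for rec in SeqIO.parse(str(path), "fasta"):
        m = _X_SUFFIX.search(rec.id)
        mult = int(m.group(1)) if m else 1
        reads.append(SmallRNARead(str(rec.seq), mult, sample))
    return reads


def read_counts_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_counts_tsv(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t")
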