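"""Heterochromatic repeat quantification via H3K9me2-enriched 12-mers.

Short tandem and satellite repeats that nucleate heterochromatin are
invisible to assembly-based TE annotation.  Instead they are quantified
directly from reads: k-mers (k = 12) counted in the H3K9me2 IP and its
matching input library, normalized by each library's uniquely-mapped read
count, identify 'heterochromatic' k-mers (at least threefold IP/input
enrichment); their summed abundance in a PCR-free whole-genome library,
normalized by total reads, measures a genome's heterochromatic repeat
content.  Counting collapses each k-mer with its reverse complement to a
canonical form, so results are strand-symmetric.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO

DEFAULT_K = 12
DEFAULT_FOLD = 3.0

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def canonical(kmer: str) -> str:
    """Lexicographically smaller of a k-mer and its reverse complement."""
    rc = kmer.translate(_COMPLEMENT)[::-1]
    return kmer if kmer <= rc else rc


@dataclass
class KmerTable:
    k: int
    counts: Counter = field(default_factory=Counter)
    normalizer: float = 0.0  # uniquely-mapped reads (MAPQ >= 30) or total reads

    def normalized(self, kmer: str) -> float:
        if self.normalizer <= 0:
            raise ZeroDivisionError("normalizer must be positive")
        return self.counts.get(kmer, 0) / self.normalizer


def _iter_seqs(reads, fmt: str | None) -> Iterable[str]:
    if isinstance(reads, (str, Path)):
        path = Path(reads)
        if fmt is None:
            fmt = "fastq" if path.suffix.lower() in (".fastq", ".fq") else "fasta"
        for rec in SeqIO.parse(str(path), fmt):
            yield str(rec.seq).upper()
    else:
        for s in reads:
            yield str(s).upper()


def count_kmers(
    reads, k: int = DEFAULT_K, fmt: str | None = None, normalizer: float | None = None
) -> KmerTable:
    """Canonical k-mer counts from reads (FASTA/FASTQ path or sequences).

    Reads shorter than k are skipped; a read of length L contributes
    L - k + 1 k-mers.  k-mers containing non-ACGT characters are ignored.
    ``normalizer`` defaults to the number of reads processed (replace it
    with the uniquely-mapped MAPQ>=30 count when alignment statistics are
    available).
    """
    if k <= 0:
        raise ValueError("k must be positive")
    counts: Counter = Counter()
    n_reads = 0
    for seq in _iter_seqs(reads, fmt):
        n_reads += 1
        for i in range(len(seq) - k + 1):
            kmer = seq[i : i + k]
            if set(kmer) <= {"A", "C", "G", "T"}:
                counts[canonical(kmer)] += 1
    return KmerTable(k, counts, float(normalizer if normalizer is not None else n_reads))


def enriched_kmers(
    ip: KmerTable, input_table: KmerTable, fold: float = DEFAULT_FOLD
) -> set[str]:
    """k-mers with normalized IP/input ratio >= fold (inclusive).

    A k-mer present in the IP but absent from the input is treated as
    infinitely enriched and included.
    """
    if ip.normalizer <= 0 or input_table.normalizer <= 0:
        raise ZeroDivisionError("both tables need a positive normalizer")
    if ip.k != input_table.k:
        raise ValueError("k differs between tables")
    out = set()
    for kmer, c in ip.counts.items():
        c_in = input_table.counts.get(kmer, 0)
        if c_in == 0:
            out.add(kmer)
        # cross-multiplied form keeps the inclusive boundary exact for
        # integer counts (no float-division rounding at ratio == fold)
        elif c * input_table.normalizer >= fold * c_in * ip.normalizer:
            out.add(kmer)
    return out


def repeat_abundance(
    wgs_reads, het_kmers: set[str], normalizer: float, k: int = DEFAULT_K, fmt: str | None = None
) -> float:
    """Summed counts of the heterochromatic k-mer set per normalizing read."""
    if not het_kmers:
        raise ValueError("heterochromatic k-mer set is empty")
    if normalizer <= 0:
        raise ZeroDivisionError("normalizer must be positive")
    table = count_kmers(wgs_reads, k=k, fmt=fmt)
    total = sum(table.counts.get(km, 0) for km in het_kmers)
    return total / normalizer
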