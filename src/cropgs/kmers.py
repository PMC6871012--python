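"""K-mer counting and genome-size estimation from a depth histogram.

Genome size is estimated as total_kmers / peak_depth, where peak_depth is
the mode of the k-mer depth distribution after excluding the low-depth
error peak. With error-free coverage c, k-mer depths are ~Poisson(c), the
histogram peaks near c, and the ratio recovers the number of distinct
genomic k-mers (~ genome length for k = 17 on a non-repetitive genome).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _canonical(kmer: str) -> str:
    rc = kmer.translate(_COMPLEMENT)[::-1]
    return kmer if kmer <= rc else rc


@dataclass
class KmerHistogram:
    """Depth -> number of distinct k-mers observed at that depth."""

    k: int
    counts: dict  # depth -> count of distinct k-mers

    def __post_init__(self):
        self.counts = {int(d): int(c) for d, c in self.counts.items() if c > 0}
        if any(d < 1 for d in self.counts):
            raise ValueError("k-mer depths must be >= 1")

    @property
    def total_kmers(self) -> int:
        """Total k-mer occurrences: sum over depth * count(depth)."""
        return int(sum(d * c for d, c in self.counts.items()))

    @property
    def n_distinct(self) -> int:
        return int(sum(self.counts.values()))


def kmer_histogram(sequences, k: int) -> KmerHistogram:
    """Count canonical k-mers (1-bp slide) across FASTA records or strings.

    ``sequences`` may be an iterable of strings or of Biopython SeqRecords.
    Windows containing N (or any non-ACGT character) are skipped. Forward
    and reverse-complement forms are collapsed to the lexicographic minimum.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    tally: Counter = Counter()
    for rec in sequences:
        seq = str(getattr(rec, "seq", rec)).upper()
        for i in range(len(seq) - k + 1):
            kmer = seq[i:i + k]
            if any(b not in "ACGT" for b in kmer):
                continue
            tally[_canonical(kmer)] += 1
    depth_counts = Counter(tally.values())
    return KmerHistogram(k=k, counts=dict(depth_counts))


def estimate_genome_size(hist: KmerHistogram,
                         error_depth_cutoff: int = 3) -> float:
    """Genome size = total_kmers / peak_depth.

    peak_depth is the depth with the largest distinct-k-mer count among
    depths >= error_depth_cutoff; the cutoff excludes the low-depth peak of
    sequencing-error k-mers.
    """
    eligible = {d: c for d, c in hist.counts.items() if d >= error_depth_cutoff}
    if not eligible:
        raise ValueError(
            f"no k-mer depth >= error cutoff {error_depth_cutoff}"
        )
    peak_depth = max(eligible, key=lambda d: (eligible[d], -d))
    return hist.total_kmers / peak_depth
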