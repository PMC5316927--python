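"""k-mer frequency histograms and genome-size estimation.

Genome size is estimated from shotgun reads as

    total genome size = total k-mer frequency / primary peak depth,

where the total frequency is the number of k-mer occurrences counted across
all reads and the primary peak depth is the multiplicity at the main mode of
the k-mer frequency histogram (the low-multiplicity error region, populated
by k-mers carrying sequencing errors, is excluded before the peak search).
k-mers are counted canonically: each occurrence is recorded under the
lexicographic minimum of the k-mer and its reverse complement, since shotgun
sequencing samples both strands.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from ._seq import revcomp


class UnresolvablePeakError(ValueError):
    """No coverage peak exists above the low-multiplicity error region."""


@dataclass
class KmerHistogram:
    """counts maps multiplicity -> number of distinct k-mers at that multiplicity."""

    k: int
    counts: dict[int, int]
    skipped_reads: int = 0  # reads shorter than k

    @property
    def total_frequency(self) -> int:
        """Total k-mer occurrences: sum of multiplicity * count."""
        return sum(m * c for m, c in self.counts.items())

    def to_frame(self) -> pd.DataFrame:
        mults = sorted(self.counts)
        return pd.DataFrame(
            {"multiplicity": mults, "n_kmers": [self.counts[m] for m in mults]}
        )


_ACGT = frozenset("ACGT")


def count_kmers(reads, k: int = 17, canonical: bool = True) -> KmerHistogram:
    """Count k-mers over reads (iterable of sequences or (id, seq) pairs).

    k must be odd (a canonical k-mer is then never its own reverse
    complement) and <= 31.  Reads shorter than k are skipped and counted;
    k-mers containing non-ACGT characters are ignored.
    """
    if k % 2 == 0 or not 1 < k <= 31:
        raise ValueError("k must be odd and in (1, 31]")
    table: Counter[str] = Counter()
    skipped = 0
    n_reads = 0
    for read in reads:
        seq = read[1] if isinstance(read, tuple) else str(read)
        seq = seq.upper()
        n_reads += 1
        if len(seq) < k:
            skipped += 1
            continue
        for i in range(len(seq) - k + 1):
            kmer = seq[i : i + k]
            if not _ACGT.issuperset(kmer):
                continue
            if canonical:
                rc = revcomp(kmer)
                if rc < kmer:
                    kmer = rc
            table[kmer] += 1
    if n_reads == 0:
        raise ValueError("no reads supplied")
    hist: Counter[int] = Counter(table.values())
    return KmerHistogram(k, dict(hist), skipped)


def primary_peak(hist: KmerHistogram) -> int:
    """Multiplicity of the main histogram mode beyond the error region.

    Scanning multiplicities in ascending order, the error region ends at the
    first local minimum of the counts; the peak is the global maximum from
    there on.  A histogram that only decreases has no resolvable peak.
    """
    if not hist.counts:
        raise ValueError("empty histogram")
    max_mult = max(hist.counts)
    counts = [hist.counts.get(m, 0) for m in range(1, max_mult + 1)]
    valley = None
    for i in range(1, len(counts) - 1):
        if counts[i] <= counts[i - 1] and counts[i] <= counts[i + 1]:
            valley = i
            break
    if valley is None:
        raise UnresolvablePeakError(
            "histogram decreases monotonically: no peak above the error region"
        )
    tail = counts[valley:]
    peak_idx = valley + max(range(len(tail)), key=tail.__getitem__)
    if counts[peak_idx] == 0:
        raise UnresolvablePeakError("no nonzero counts beyond the error region")
    return peak_idx + 1  # multiplicities are 1-based


def estimate_genome_size(hist_or_total, peak_depth: int) -> int:
    """round(total k-mer frequency / primary peak depth), in bases."""
    if peak_depth < 1:
        raise ZeroDivisionError("peak_depth must be >= 1")
    total = (
        hist_or_total.total_frequency
        if isinstance(hist_or_total, KmerHistogram)
        else int(hist_or_total)
    )
    return round(total / peak_depth)


def write_summary(hist: KmerHistogram, peak: int, path) -> None:
    summary = {
        "k": hist.k,
        "peak": peak,
        "total_frequency": hist.total_frequency,
        "genome_size": estimate_genome_size(hist, peak),
    }
    Path(path).write_text(json.dumps(summary, indent=2) + "\n")
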