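"""Collapsed/repeat region detection from three-mode read-mapping coverage.

Reads are mapped to an assembly in three reporting modes: r0 counts only
uniquely mapping reads, r1 places each multi-mapping read at one randomly
chosen locus, and r2 places it at every locus.  At every base r0 <= r1 <= r2.
Two per-position signatures then separate assembly pathologies:

* collapsed ("coll"): a multi-copy locus assembled as one copy.  Reads from
  every true copy pile onto the single assembled copy, so coverage in all
  three modes exceeds twice its overall median.
* repeated, non-collapsed ("rnc"): a multi-copy locus correctly assembled in
  all copies.  Unique-mode coverage drops to ~0 (no read maps uniquely),
  random-one coverage stays near the sequencing depth, and all-hits coverage
  is inflated; the signature is r0 in [0, 2], r1 >= 2 and r2 at least half
  its overall median.

Flagged positions are merged into regions (same-kind regions within
merge_gap bases are joined) and each region's copy number is estimated as
the ratio of its median all-hits coverage to the overall all-hits median.

The exact-match mapping emulator below substitutes for a short-read aligner
on the error-free synthetic reads this package generates; real-data users
supply the five-column per-base coverage table instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._seq import revcomp


class InvalidTrackError(ValueError):
    """Track ordering r0 <= r1 <= r2 violated."""


class DegenerateInputError(ValueError):
    """Coverage is all zero or the unique-mode median is zero."""


@dataclass
class CoverageTrackSet:
    """Per-base integer coverage in the three mapping modes, per sequence."""

    tracks: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]
    unmapped: int = 0

    def validate(self) -> None:
        for name, (r0, r1, r2) in self.tracks.items():
            if not (len(r0) == len(r1) == len(r2)):
                raise InvalidTrackError(f"{name}: track lengths differ")
            if np.any(r0 > r1) or np.any(r1 > r2):
                raise InvalidTrackError(f"{name}: mode ordering r0<=r1<=r2 violated")

    def overall_medians(self) -> tuple[float, float, float]:
        """Genome-wide medians of the three tracks."""
        cat = [
            np.concatenate([t[i] for t in self.tracks.values()]) for i in range(3)
        ]
        return tuple(float(np.median(c)) for c in cat)

    def sequence_medians(self, name: str) -> tuple[float, float, float]:
        r0, r1, r2 = self.tracks[name]
        return float(np.median(r0)), float(np.median(r1)), float(np.median(r2))

    def to_frame(self) -> pd.DataFrame:
        """Five-column table (sequence, 1-based position, r0, r1, r2)."""
        parts = []
        for name, (r0, r1, r2) in self.tracks.items():
            parts.append(
                pd.DataFrame(
                    {
                        "sequence": name,
                        "position": np.arange(1, len(r0) + 1),
                        "r0": r0,
                        "r1": r1,
                        "r2": r2,
                    }
                )
            )
        return pd.concat(parts, ignore_index=True)

    def to_table(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def coverage_from_table(path) -> CoverageTrackSet:
    """Read the five-column per-base coverage table (1-based positions).

    Missing positions become coverage 0; any row with r0 > r1 or r1 > r2 is
    rejected as violating the mapping-mode semantics.
    """
    df = pd.read_csv(path, sep="\t")
    needed = ["sequence", "position", "r0", "r1", "r2"]
    if list(df.columns[:5]) != needed:
        df.columns = needed + list(df.columns[5:])
    if (df["r0"] > df["r1"]).any() or (df["r1"] > df["r2"]).any():
        raise InvalidTrackError("table violates r0 <= r1 <= r2")
    tracks = {}
    for name, grp in df.groupby("sequence", sort=False):
        length = int(grp["position"].max())
        arrs = [np.zeros(length, dtype=np.int64) for _ in range(3)]
        pos = grp["position"].to_numpy() - 1
        for arr, colname in zip(arrs, ("r0", "r1", "r2")):
            arr[pos] = grp[colname].to_numpy()
        tracks[str(name)] = tuple(arrs)
    ts = CoverageTrackSet(tracks)
    ts.validate()
    return ts


# ---------------------------------------------------------------------------
# Exact-match mapping emulator
# ---------------------------------------------------------------------------


def coverage_from_reads(
    reads: list[tuple[str, str]],
    assembly: dict[str, str],
    seed: int = 0,
) -> CoverageTrackSet:
    """Map error-free reads to an assembly by exact full-length matching.

    Every locus (on either strand) where the read matches exactly is found.
    A read with one locus increments r0, r1 and r2 there; with several loci
    it increments r2 at all of them and r1 at one chosen uniformly (seeded);
    with none it is counted as unmapped.
    """
    if not assembly:
        raise ValueError("assembly is empty")
    rng = np.random.default_rng(seed)
    # index all assembly substrings of each read length present
    index: dict[int, dict[str, list[tuple[str, int]]]] = {}
    read_lengths = sorted({len(s) for _, s in reads})
    for L in read_lengths:
        idx: dict[str, list[tuple[str, int]]] = {}
        for name, seq in assembly.items():
            for i in range(len(seq) - L + 1):
                idx.setdefault(seq[i : i + L], []).append((name, i))
        index[L] = idx
    diffs = {
        name: [np.zeros(len(seq) + 1, dtype=np.int64) for _ in range(3)]
        for name, seq in assembly.items()
    }
    unmapped = 0
    for _, seq in reads:
        idx = index[len(seq)]
        loci = list(idx.get(seq, ()))
        for name, i in idx.get(revcomp(seq), ()):
            if (name, i) not in loci:  # palindromic reads hit one interval once
                loci.append((name, i))
        if not loci:
            unmapped += 1
            continue
        L = len(seq)
        if len(loci) == 1:
            targets = {0: loci, 1: loci, 2: loci}
        else:
            chosen = [loci[int(rng.integers(len(loci)))]]
            targets = {0: [], 1: chosen, 2: loci}
        for mode, hits in targets.items():
            for name, i in hits:
                diffs[name][mode][i] += 1
                diffs[name][mode][i + L] -= 1
    tracks = {
        name: tuple(np.cumsum(d[:-1]) for d in ds) for name, ds in diffs.items()
    }
    ts = CoverageTrackSet(tracks, unmapped)
    ts.validate()
    return ts


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------


@dataclass
class CorefindParams:
    coll_factor: float = 2.0  # x overall median, all three tracks
    rnc_r0_max: int = 2
    rnc_r1_min: int = 2
    rnc_r2_factor: float = 0.5  # x overall median of r2
    merge_gap: int = 100
    min_region: int = 1
    per_sequence: bool = False  # medians per sequence instead of genome-wide

    def __post_init__(self):
        if min(self.coll_factor, self.rnc_r2_factor) <= 0 or self.merge_gap < 0:
            raise ValueError("thresholds must be positive")


@dataclass
class FlaggedRegion:
    sequence: str
    start: int  # 0-based half-open
    end: int
    kind: str  # "coll" | "rnc"
    copy_number: float | None = None


def _merge_runs(flags: np.ndarray, value: int, merge_gap: int, min_region: int):
    """Maximal runs of `value` in flags, merged across gaps <= merge_gap."""
    hits = np.flatnonzero(flags == value)
    if hits.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(hits) > merge_gap + 1)
    starts = np.concatenate([[0], breaks + 1])
    ends = np.concatenate([breaks, [hits.size - 1]])
    return [
        (int(hits[s]), int(hits[e]) + 1)
        for s, e in zip(starts, ends)
        if hits[e] + 1 - hits[s] >= min_region
    ]


def classify_regions(
    tracks: CoverageTrackSet, params: CorefindParams | None = None
) -> list[FlaggedRegion]:
    """Flag collapsed and repeated-non-collapsed regions.

    Per-position predicates (medians per track, genome-wide by default):
      coll: r0 > f*med(r0) and r1 > f*med(r1) and r2 > f*med(r2)  (f = 2)
      rnc:  0 <= r0 <= 2 and r1 >= 2 and r2 >= 0.5*med(r2)
    Runs of equal flag become regions; same-kind regions separated by at
    most merge_gap bases are merged.  When med(r0) >= 2 the two predicates
    are mutually exclusive (coll requires r0 > 4); if both ever hold (only
    possible at low unique-mode median) coll takes precedence.
    """
    params = params or CorefindParams()
    tracks.validate()
    regions: list[FlaggedRegion] = []
    genome_med = tracks.overall_medians()
    if all(m == 0 for m in genome_med):
        raise DegenerateInputError("all coverage tracks are zero")
    for name in tracks.tracks:
        m0, m1, m2 = (
            tracks.sequence_medians(name) if params.per_sequence else genome_med
        )
        if m0 <= 0:
            raise DegenerateInputError(
                "unique-mode median coverage is zero: classification meaningless"
            )
        r0, r1, r2 = tracks.tracks[name]
        coll = (
            (r0 > params.coll_factor * m0)
            & (r1 > params.coll_factor * m1)
            & (r2 > params.coll_factor * m2)
        )
        rnc = (
            (r0 <= params.rnc_r0_max)
            & (r1 >= params.rnc_r1_min)
            & (r2 >= params.rnc_r2_factor * m2)
        )
        if m0 >= 2:
            assert not np.any(coll & rnc)
        flags = np.zeros(len(r0), dtype=np.int8)
        flags[rnc] = 2
        flags[coll] = 1  # coll wins where both hold
        for start, end in _merge_runs(flags, 1, params.merge_gap, params.min_region):
            regions.append(FlaggedRegion(name, start, end, "coll"))
        for start, end in _merge_runs(flags, 2, params.merge_gap, params.min_region):
            regions.append(FlaggedRegion(name, start, end, "rnc"))
    for reg in regions:
        reg.copy_number = estimate_copy_number(reg, tracks, params)
    regions.sort(key=lambda r: (r.sequence, r.start))
    return regions


def estimate_copy_number(
    region: FlaggedRegion,
    tracks: CoverageTrackSet,
    params: CorefindParams | None = None,
) -> float:
    """median(r2 over the region) / overall median(r2), rounded to 2 decimals."""
    params = params or CorefindParams()
    r2 = tracks.tracks[region.sequence][2]
    if not 0 <= region.start < region.end <= len(r2):
        raise ValueError("region outside track bounds")
    m2 = (
        tracks.sequence_medians(region.sequence)[2]
        if params.per_sequence
        else tracks.overall_medians()[2]
    )
    if m2 == 0:
        raise ZeroDivisionError("overall median of r2 is zero")
    return round(float(np.median(r2[region.start : region.end])) / m2, 2)


# ---------------------------------------------------------------------------
# BED output
# ---------------------------------------------------------------------------


def write_bed(regions: list[FlaggedRegion], path) -> None:
    """BED6: chrom, start, end, kind, score = min(round(100*copy_number), 1000)."""
    with open(path, "w") as fh:
        fh.write("# wgdkit corefind regions (BED6)\n")
        for r in regions:
            score = min(int(round(100 * (r.copy_number or 0))), 1000)
            fh.write(f"{r.sequence}\t{r.start}\t{r.end}\t{r.kind}\t{score}\t.\n")


def read_bed(path) -> list[FlaggedRegion]:
    regions = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            chrom, start, end, kind, score, _ = line.rstrip("\n").split("\t")
            regions.append(
                FlaggedRegion(chrom, int(start), int(end), kind, int(score) / 100)
            )
    return regions
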