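"""In-silico PCR placement of sequence-based markers.

A marker assay is a primer pair (optionally with a known amplicon).  Each
primer may match a template site with up to two mismatches and two gaps
(unit-cost edit operations, capped separately and summed for ranking); a
candidate placement is a pair of primer sites on opposite strands facing
inward whose product length falls in the platform's size range (10-1000 bp
for Fluidigm assays, 10-5000 bp otherwise).  A marker is placed by in-silico
PCR when exactly one candidate attains the minimum combined distance; when
PCR yields nothing, the location of an unambiguous best sequence-similarity
hit of the known amplicon is used instead; otherwise the marker is reported
ambiguous or unplaced.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._seq import revcomp

SIZE_RANGES = {"fluidigm": (10, 1000), "other": (10, 5000)}


@dataclass
class MarkerAssay:
    name: str
    forward: str
    reverse: str
    platform: str = "other"  # "fluidigm" | "other"
    amplicon: str | None = None

    def __post_init__(self):
        if min(len(self.forward), len(self.reverse)) < 15:
            raise ValueError("primers must be >= 15 bases")
        if self.platform not in SIZE_RANGES:
            raise ValueError(f"unknown platform {self.platform!r}")


@dataclass
class PrimerSite:
    sequence: str
    start: int  # 0-based half-open footprint on the forward strand
    end: int
    strand: str  # "+" | "-"
    mismatches: int
    gaps: int

    @property
    def distance(self) -> int:
        return self.mismatches + self.gaps


@dataclass
class Candidate:
    sequence: str
    start: int  # amplicon interval, half-open
    end: int
    forward_site: PrimerSite
    reverse_site: PrimerSite

    @property
    def distance(self) -> int:
        return self.forward_site.distance + self.reverse_site.distance


@dataclass
class MarkerPlacement:
    name: str
    status: str  # "placed" | "ambiguous" | "unplaced"
    method: str | None = None  # "epcr" | "sequence_hit"
    sequence: str | None = None
    start: int | None = None
    end: int | None = None
    distance: int | None = None
    reason: str | None = None


def _site_costs(pattern: str, window: str) -> set[tuple[int, int]]:
    """Feasible (mismatches, gaps) pairs aligning pattern to a suffix-anchored
    substring of window (semi-global: free start, fixed end)."""
    m, n = len(pattern), len(window)
    # states[i][j] = set of (mm, gaps) reaching pattern[:i] vs window[..j] ending at j
    states = [[set() for _ in range(n + 1)] for _ in range(m + 1)]
    for j in range(n + 1):
        states[0][j] = {(0, 0)}
    for i in range(1, m + 1):
        for j in range(n + 1):
            here = set()
            if j > 0:
                for mm, g in states[i - 1][j - 1]:
                    cost = pattern[i - 1] != window[j - 1]
                    if mm + cost <= 2:
                        here.add((mm + cost, g))
                for mm, g in states[i][j - 1]:  # gap in pattern (insertion in text)
                    if g + 1 <= 2:
                        here.add((mm, g + 1))
            for mm, g in states[i - 1][j]:  # gap in text (deletion)
                if g + 1 <= 2:
                    here.add((mm, g + 1))
            states[i][j] = here
    return states[m][n]


def find_primer_sites(
    primer: str,
    sequences: dict[str, str],
    max_mismatch: int = 2,
    max_gap: int = 2,
) -> list[PrimerSite]:
    """All sites where the primer (or its reverse complement) matches.

    A "+" site means the primer anneals to the minus strand and extends
    rightward along the plus strand (primer sequence equals the plus
    strand); a "-" site extends leftward.
    """
    sites: list[PrimerSite] = []
    max_dist = max_mismatch + max_gap
    for strand, pat in (("+", primer), ("-", revcomp(primer))):
        for name, seq in sequences.items():
            ends = _semiglobal_dp_ends(pat, seq, max_dist)
            for end in ends:
                window_start = max(0, end - len(pat) - max_gap)
                feasible = _site_costs(pat, seq[window_start:end])
                feasible = {
                    (mm, g)
                    for mm, g in feasible
                    if mm <= max_mismatch and g <= max_gap
                }
                if not feasible:
                    continue
                mm, g = min(feasible, key=lambda x: (x[0] + x[1], x[1]))
                start = max(0, end - len(pat))  # nominal footprint
                sites.append(PrimerSite(name, start, end, strand, mm, g))
    return sites


def _semiglobal_dp_ends(pattern: str, text: str, max_dist: int) -> list[int]:
    """End positions (exclusive) where pattern matches with distance <= max_dist."""
    t = np.frombuffer(text.encode(), dtype=np.uint8)
    n = len(t)
    prev = np.zeros(n + 1, dtype=np.int32)
    for ch in pattern.encode():
        sub = prev[:-1] + (t != ch).astype(np.int32)
        dele = prev[1:] + 1
        cand = np.minimum(sub, dele)
        # insertion: row[j] = min(cand[j], row[j-1] + 1) -> prefix-min trick
        idx = np.arange(1, n + 1, dtype=np.int32)
        base = np.minimum.accumulate(cand - idx)
        row = np.empty(n + 1, dtype=np.int32)
        row[0] = prev[0] + 1
        row[1:] = np.minimum(cand, base + idx)
        row[1:] = np.minimum(row[1:], row[0] + idx)  # runs of leading insertions
        prev = row
    return [int(j) for j in np.flatnonzero(prev[1:] <= max_dist) + 1]


def insilico_pcr(
    assay: MarkerAssay,
    sequences: dict[str, str],
    max_mismatch: int = 2,
    max_gap: int = 2,
    size_range: tuple[int, int] | None = None,
) -> list[Candidate]:
    """Candidate amplicons: inward-facing primer sites within the size range.

    Either primer may prime either end; candidates are returned sorted by
    combined distance (mismatches + gaps over both primers).
    """
    size_range = size_range or SIZE_RANGES[assay.platform]
    fwd = find_primer_sites(assay.forward, sequences, max_mismatch, max_gap)
    rev = find_primer_sites(assay.reverse, sequences, max_mismatch, max_gap)
    candidates: list[Candidate] = []
    # left primer on "+" paired with right primer on "-", both orderings
    for left_sites, right_sites in ((fwd, rev), (rev, fwd)):
        for ls in left_sites:
            if ls.strand != "+":
                continue
            for rs in right_sites:
                if rs.strand != "-" or rs.sequence != ls.sequence:
                    continue
                length = rs.end - ls.start
                if rs.start < ls.start or not size_range[0] <= length <= size_range[1]:
                    continue
                candidates.append(Candidate(ls.sequence, ls.start, rs.end, ls, rs))
    # deduplicate identical amplicon intervals (swap-symmetric assays)
    seen = {}
    for c in candidates:
        key = (c.sequence, c.start, c.end)
        if key not in seen or c.distance < seen[key].distance:
            seen[key] = c
    return sorted(seen.values(), key=lambda c: (c.distance, c.sequence, c.start))


@dataclass
class FallbackHit:
    sequence: str
    start: int
    end: int
    score: float


def amplicon_hits(
    amplicon: str, sequences: dict[str, str], seed_length: int = 21
) -> list[FallbackHit]:
    """Ungapped seed-chain hits of a known amplicon sequence.

    Exact seed matches (seed_length-mers stepped every seed) are grouped by
    diagonal; the score of a hit is its matched seed count.  A lightweight
    stand-in for an external similarity search, sufficient for placements
    where the amplicon is present near-verbatim.
    """
    hits: dict[tuple[str, int], list[int]] = {}
    for template_name, strand_seq in (("+", amplicon), ("-", revcomp(amplicon))):
        for off in range(0, max(1, len(strand_seq) - seed_length + 1), seed_length):
            seed = strand_seq[off : off + seed_length]
            if len(seed) < seed_length:
                continue
            for name, seq in sequences.items():
                pos = seq.find(seed)
                while pos != -1:
                    hits.setdefault((name, pos - off), []).append(off)
                    pos = seq.find(seed, pos + 1)
    out = []
    for (name, diag), offs in hits.items():
        start = max(0, diag)
        out.append(FallbackHit(name, start, start + len(amplicon), float(len(offs))))
    out.sort(key=lambda h: -h.score)
    return out


def place_marker(
    assay: MarkerAssay,
    candidates: list[Candidate],
    fallback_hits: list[FallbackHit] | None = None,
) -> MarkerPlacement:
    """Decide a placement: unique best PCR candidate, else unique top
    similarity hit of the known amplicon, else ambiguous/unplaced."""
    if candidates:
        best = min(c.distance for c in candidates)
        winners = [c for c in candidates if c.distance == best]
        if len(winners) == 1:
            c = winners[0]
            return MarkerPlacement(
                assay.name, "placed", "epcr", c.sequence, c.start, c.end, c.distance
            )
        return MarkerPlacement(
            assay.name,
            "ambiguous",
            reason=f"{len(winners)} amplicons at minimum distance {best}",
        )
    fallback_hits = fallback_hits or []
    if fallback_hits:
        top = fallback_hits[0]
        runner = fallback_hits[1].score if len(fallback_hits) > 1 else None
        if runner is None or top.score - runner >= 1:
            return MarkerPlacement(
                assay.name, "placed", "sequence_hit", top.sequence, top.start, top.end
            )
        return MarkerPlacement(
            assay.name, "ambiguous", reason="tied top similarity hits"
        )
    return MarkerPlacement(assay.name, "unplaced", reason="no candidates and no hits")
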