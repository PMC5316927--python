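"""Pairwise Ka/Ks estimation and synteny-block Ks analysis.

The estimator is the Nei-Gojobori (1986) counting method with the
Jukes-Cantor multiple-hit correction d = -(3/4) ln(1 - (4/3) p), applied to
in-frame codon alignments.  Synonymous/nonsynonymous site fractions are
computed per codon from the standard genetic code; codons that differ at more
than one position are resolved by averaging synonymous/nonsynonymous
difference counts over all orderings of single-step mutational pathways,
excluding pathways that pass through a stop codon.

Gene anchors between two genomes are chained into collinear synteny blocks by
a sparse dynamic program (the standard DAG-chaining recurrence), blocks are
summarised by their median Ks, and the distribution of block medians is
binned and scanned for modal peaks -- the signature used to recognise and
date whole-genome duplications.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from ._seq import CODON_AA, STOP_CODONS


class KsSaturationError(ValueError):
    """Raised when an observed proportion p >= 3/4 (JC correction undefined)."""


class EmptyAlignmentError(ValueError):
    """Raised when no codon pair is countable."""


# ---------------------------------------------------------------------------
# Nei-Gojobori (1986) with Jukes-Cantor correction
# ---------------------------------------------------------------------------

_BASES = "ACGT"


def _codon_site_fractions(codon: str) -> float:
    """Number of synonymous sites in one codon (0..3).

    Each of the nine single-base changes is synonymous or not; changes that
    create a stop codon count as nonsynonymous.  The per-position synonymous
    fraction is (synonymous changes)/3 and sites sum over the 3 positions.
    """
    aa = CODON_AA[codon]
    s = 0.0
    for pos in range(3):
        syn = 0
        for b in _BASES:
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1 :]
            if CODON_AA[alt] == aa:
                syn += 1
        s += syn / 3.0
    return s


_SITE_CACHE: dict[str, float] = {}


def syn_sites(codon: str) -> float:
    if codon not in _SITE_CACHE:
        _SITE_CACHE[codon] = _codon_site_fractions(codon)
    return _SITE_CACHE[codon]


def _pathway_counts(ca: str, cb: str) -> tuple[float, float]:
    """Average (synonymous, nonsynonymous) difference counts between codons.

    Averaged over all orderings of single-step pathways from ca to cb;
    pathways whose intermediate codons are stops are excluded.  If every
    pathway is blocked by a stop, all pathways are used (with a warning) so
    the difference count is still conserved.
    """
    diff_pos = [i for i in range(3) if ca[i] != cb[i]]
    if not diff_pos:
        return 0.0, 0.0

    def walk(order: tuple[int, ...], allow_stops: bool) -> tuple[float, float] | None:
        sd = nd = 0
        cur = ca
        for step, pos in enumerate(order):
            nxt = cur[:pos] + cb[pos] + cur[pos + 1 :]
            if nxt in STOP_CODONS and step < len(order) - 1 and not allow_stops:
                return None
            if CODON_AA[cur] == CODON_AA[nxt]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        return sd, nd

    results = [r for o in itertools.permutations(diff_pos) if (r := walk(o, False))]
    if not results:
        warnings.warn(
            f"all mutational pathways {ca}->{cb} pass through stop codons; "
            "averaging over all pathways",
            stacklevel=2,
        )
        results = [walk(o, True) for o in itertools.permutations(diff_pos)]
    sd = sum(r[0] for r in results) / len(results)
    nd = sum(r[1] for r in results) / len(results)
    return sd, nd


def jukes_cantor(p: float) -> float:
    """JC69 distance d = -(3/4) ln(1 - (4/3) p); undefined for p >= 3/4."""
    if p < 0:
        raise ValueError(f"proportion must be >= 0, got {p}")
    if p >= 0.75:
        raise KsSaturationError(f"proportion {p:.4f} >= 3/4: correction saturates")
    return -0.75 * math.log1p(-4.0 * p / 3.0)


_VALID = frozenset("ACGT")


def countable_codons(seq_a: str, seq_b: str) -> list[tuple[str, str]]:
    """Aligned codon pairs eligible for counting.

    Codons containing gaps or ambiguity codes in either sequence, and stop
    codons in either sequence, are excluded.
    """
    a, b = seq_a.upper(), seq_b.upper()
    if len(a) != len(b):
        raise ValueError("aligned sequences must have equal length")
    if len(a) % 3:
        raise ValueError("alignment length must be a multiple of 3")
    pairs = []
    for i in range(0, len(a), 3):
        ca, cb = a[i : i + 3], b[i : i + 3]
        if not (_VALID.issuperset(ca) and _VALID.issuperset(cb)):
            continue
        if ca in STOP_CODONS or cb in STOP_CODONS:
            continue
        pairs.append((ca, cb))
    return pairs


def ng86_pairwise(seq_a: str, seq_b: str) -> dict[str, float]:
    """NG86 Ka/Ks for one aligned coding-sequence pair.

    Returns S, N (sites, averaged over both sequences), ps, pn (proportions
    of synonymous/nonsynonymous differences), and the JC-corrected Ks, Ka
    and their ratio (NaN when Ks == 0).  Symmetric under sequence swap.
    """
    pairs = countable_codons(seq_a, seq_b)
    if not pairs:
        raise EmptyAlignmentError("no countable codon pairs in alignment")
    s_a = sum(syn_sites(ca) for ca, _ in pairs)
    s_b = sum(syn_sites(cb) for _, cb in pairs)
    n_codons = len(pairs)
    S = (s_a + s_b) / 2.0
    N = 3.0 * n_codons - S
    sd = nd = 0.0
    for ca, cb in pairs:
        d_s, d_n = _pathway_counts(ca, cb)
        sd += d_s
        nd += d_n
    ps = sd / S if S > 0 else 0.0
    pn = nd / N if N > 0 else 0.0
    Ks = jukes_cantor(ps)
    Ka = jukes_cantor(pn)
    return {
        "S": S,
        "N": N,
        "ps": ps,
        "pn": pn,
        "Ks": Ks,
        "Ka": Ka,
        "Ka_Ks": Ka / Ks if Ks > 0 else float("nan"),
        "n_codons": n_codons,
    }


# ---------------------------------------------------------------------------
# Anchor chaining (DAG chaining dynamic program)
# ---------------------------------------------------------------------------

ANCHOR_COLUMNS = [
    "gene_a",
    "chr_a",
    "start_a",
    "end_a",
    "gene_b",
    "chr_b",
    "start_b",
    "end_b",
    "score",
]


@dataclass
class SyntenyBlock:
    """A chained run of collinear gene anchors between two genomic regions."""

    chr_a: str
    chr_b: str
    orientation: str  # "+" (B increasing) or "-" (B decreasing)
    anchors: pd.DataFrame
    chain_score: float
    median_ks: float | None = None

    @property
    def span_a(self) -> tuple[int, int]:
        return int(self.anchors["start_a"].min()), int(self.anchors["end_a"].max())

    @property
    def span_b(self) -> tuple[int, int]:
        return int(self.anchors["start_b"].min()), int(self.anchors["end_b"].max())

    def __len__(self) -> int:
        return len(self.anchors)


@dataclass
class ChainParams:
    max_gap: int = 100_000
    gap_penalty: float = 0.0005  # per base of gap on both genomes
    min_block: int = 5


def top_matches_per_chromosome(anchors: pd.DataFrame) -> pd.DataFrame:
    """Retain each query gene's best-scoring match per target chromosome.

    Allows one hit per (gene_a, chr_b) pair, so a query may anchor several
    target chromosomes (as multiple WGD-derived homoeologs do) without
    flooding any one of them with secondary hits.
    """
    idx = anchors.groupby(["gene_a", "chr_b"])["score"].idxmax()
    return anchors.loc[sorted(idx)].reset_index(drop=True)


def _best_chain(sub: pd.DataFrame, sign: int, params: ChainParams):
    """DP over one chromosome pair / orientation; returns (score, row indices)."""
    n = len(sub)
    a_start = sub["start_a"].to_numpy()
    a_end = sub["end_a"].to_numpy()
    if sign == 1:
        b_start = sub["start_b"].to_numpy()
        b_end = sub["end_b"].to_numpy()
    else:  # reflect the B axis so intervals stay (start < end)
        b_start = -sub["end_b"].to_numpy()
        b_end = -sub["start_b"].to_numpy()
    score = sub["score"].to_numpy(dtype=float)
    best = score.copy()
    back = np.full(n, -1)
    order = np.argsort(a_start, kind="stable")
    pos = {int(o): k for k, o in enumerate(order)}
    for oi in range(n):
        i = int(order[oi])
        for oj in range(oi):
            j = int(order[oj])
            if not (a_start[i] > a_start[j] and b_start[i] > b_start[j]):
                continue
            gap_a = a_start[i] - a_end[j]
            gap_b = b_start[i] - b_end[j]
            if gap_a > params.max_gap or gap_b > params.max_gap:
                continue
            gap = max(gap_a, 0) + max(gap_b, 0)
            cand = score[i] + best[j] - params.gap_penalty * gap
            if cand > best[i]:
                best[i] = cand
                back[i] = j
    del pos
    i = int(np.argmax(best))
    chain = []
    while i != -1:
        chain.append(i)
        i = int(back[i])
    chain.reverse()
    return float(best[chain[-1]]), chain


def chain_anchors(
    anchors: pd.DataFrame, params: ChainParams | None = None
) -> list[SyntenyBlock]:
    """Chain anchors into synteny blocks.

    Per chromosome pair and orientation, the best chain under the scoring
    recurrence  chain(i) = score(i) + max_j [chain(j) - gap_penalty * gap(i,j)]
    (j collinear with i within max_gap on both genomes) is extracted
    repeatedly, removing its anchors, until no chain reaches min_block
    anchors -- mirroring best-first extraction without anchor reuse.
    """
    params = params or ChainParams()
    blocks: list[SyntenyBlock] = []
    if len(anchors) == 0:
        return blocks
    anchors = anchors.reset_index(drop=True)
    for (ca, cb), group in anchors.groupby(["chr_a", "chr_b"], sort=True):
        for sign, orient in ((1, "+"), (-1, "-")):
            sub = group.sort_values("start_a").reset_index(drop=True)
            while len(sub) >= params.min_block:
                _, chain = _best_chain(sub, sign, params)
                if len(chain) < params.min_block:
                    break
                rows = sub.iloc[chain].reset_index(drop=True)
                chain_score = float(
                    _chain_score(rows, sign, params)
                )
                blocks.append(
                    SyntenyBlock(str(ca), str(cb), orient, rows, chain_score)
                )
                sub = sub.drop(sub.index[chain]).reset_index(drop=True)
    blocks.sort(key=lambda b: (b.chr_a, b.chr_b, b.span_a))
    return blocks


def _chain_score(rows: pd.DataFrame, sign: int, params: ChainParams) -> float:
    total = float(rows["score"].sum())
    for k in range(1, len(rows)):
        gap_a = rows["start_a"].iat[k] - rows["end_a"].iat[k - 1]
        if sign == 1:
            gap_b = rows["start_b"].iat[k] - rows["end_b"].iat[k - 1]
        else:
            gap_b = rows["start_b"].iat[k - 1] - rows["end_b"].iat[k]
        total -= params.gap_penalty * (max(gap_a, 0) + max(gap_b, 0))
    return total


# ---------------------------------------------------------------------------
# Block medians, histograms, modal peaks
# ---------------------------------------------------------------------------


def block_median_ks(ks_values) -> float | None:
    """Median of the finite per-anchor Ks values of a block.

    Saturated anchors (NaN/None) are excluded; a block with no finite value
    is dropped (None) with a warning.
    """
    vals = np.asarray([v for v in ks_values if v is not None], dtype=float)
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        warnings.warn("block has no finite Ks values; dropped", stacklevel=2)
        return None
    return float(np.median(vals))


def annotate_block_medians(
    blocks: list[SyntenyBlock], pair_ks: dict[tuple[str, str], float]
) -> list[SyntenyBlock]:
    """Attach per-anchor Ks (keyed by gene pair) and the block median."""
    kept = []
    for b in blocks:
        vals = [
            pair_ks.get((ga, gb))
            for ga, gb in zip(b.anchors["gene_a"], b.anchors["gene_b"])
        ]
        med = block_median_ks([v for v in vals if v is not None] or [None])
        if med is None:
            continue
        b.anchors = b.anchors.assign(ks=vals)
        b.median_ks = med
        kept.append(b)
    return kept


@dataclass
class KsHistogram:
    """Proportions of Ks values per half-open bin [i*w, (i+1)*w)."""

    bin_width: float
    proportions: np.ndarray
    label: str = ""
    n_values: int = 0

    @property
    def bin_centers(self) -> np.ndarray:
        return (np.arange(len(self.proportions)) + 0.5) * self.bin_width

    bin_edges = property(
        lambda self: np.arange(len(self.proportions) + 1) * self.bin_width
    )


def ks_histogram(values, bin_width: float = 0.01, label: str = "") -> KsHistogram:
    vals = np.asarray(list(values), dtype=float)
    if vals.size == 0:
        raise ValueError("no Ks values to bin")
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    if np.any(vals < 0):
        raise ValueError("negative Ks values are invalid")
    n_bins = int(np.floor(vals.max() / bin_width)) + 1
    edges = np.arange(n_bins + 1) * bin_width
    counts, _ = np.histogram(vals, bins=edges)
    return KsHistogram(bin_width, counts / counts.sum(), label, int(vals.size))


@dataclass
class ModalPeak:
    ks_mode: float
    height: float


def find_modal_peaks(
    hist: KsHistogram, smooth_window: int = 5, min_prominence: float = 0.002
) -> list[ModalPeak]:
    """Local maxima of the smoothed histogram, ascending in Ks.

    Smoothing is a centred moving average over `smooth_window` bins (odd);
    peaks must have prominence >= min_prominence (proportion units).  The
    mode is reported at the bin centre.
    """
    y = np.asarray(hist.proportions, dtype=float)
    if smooth_window % 2 == 0 or smooth_window < 1:
        raise ValueError("smooth_window must be odd and >= 1")
    if smooth_window > len(y):
        raise ValueError("smooth_window larger than histogram")
    kernel = np.ones(smooth_window) / smooth_window
    pad = smooth_window // 2
    smoothed = np.convolve(np.pad(y, pad, mode="edge"), kernel, mode="valid")
    idx, props = find_peaks(smoothed, prominence=min_prominence)
    centers = hist.bin_centers
    return [ModalPeak(float(centers[i]), float(smoothed[i])) for i in idx]


# ---------------------------------------------------------------------------
# Tabular I/O
# ---------------------------------------------------------------------------


def read_anchors(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in ANCHOR_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"anchor table missing columns: {missing}")
    return df


def blocks_to_frame(blocks: list[SyntenyBlock]) -> pd.DataFrame:
    rows = []
    for i, b in enumerate(blocks):
        sa, sb = b.span_a, b.span_b
        rows.append(
            {
                "block": i,
                "chr_a": b.chr_a,
                "start_a": sa[0],
                "end_a": sa[1],
                "chr_b": b.chr_b,
                "start_b": sb[0],
                "end_b": sb[1],
                "orientation": b.orientation,
                "n_anchors": len(b),
                "chain_score": b.chain_score,
                "median_ks": b.median_ks,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "block",
            "chr_a",
            "start_a",
            "end_a",
            "chr_b",
            "start_b",
            "end_b",
            "orientation",
            "n_anchors",
            "chain_score",
            "median_ks",
        ],
    )
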