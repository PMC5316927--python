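"""Per-base synteny coverage depth and depth-proportion summaries.

The depth at each reference base is the number of synteny-block footprints
covering it; the fraction of the genome at each depth level is the ploidy
signature of paleopolyploidy (a whole-genome triplication leaves large
fractions at depth three in cross-species comparisons).  Implemented by
interval stacking on a difference array with run-length encoded output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class DepthProfile:
    """Run-length encoded depth per sequence plus genome-wide fractions."""

    runs: dict[str, list[tuple[int, int]]]  # sequence -> [(run_length, depth), ...]
    summary: dict[int, float]  # depth -> fraction of genome
    total_length: int

    def fraction_at(self, depth: int) -> float:
        return self.summary.get(depth, 0.0)


def _as_intervals(blocks) -> list[tuple[str, int, int]]:
    if isinstance(blocks, pd.DataFrame):
        cols = (
            ("chrom", "start", "end")
            if "chrom" in blocks.columns
            else ("chr_a", "start_a", "end_a")
        )
        return [
            (str(c), int(s), int(e))
            for c, s, e in zip(blocks[cols[0]], blocks[cols[1]], blocks[cols[2]])
        ]
    return [(str(c), int(s), int(e)) for c, s, e in blocks]


def exclude_self_blocks(blocks: pd.DataFrame) -> pd.DataFrame:
    """Drop trivial self-match blocks (same chromosome, identical spans).

    In a genome self-comparison every region matches itself perfectly on the
    main diagonal; those blocks carry no duplication evidence and would
    inflate every depth level by one.
    """
    mask = (blocks["chr_a"] == blocks["chr_b"]) & (
        (blocks["start_a"] == blocks["start_b"]) & (blocks["end_a"] == blocks["end_b"])
    )
    return blocks.loc[~mask].reset_index(drop=True)


def depth_profile(blocks, genome_lengths: dict[str, int]) -> DepthProfile:
    """Depth at each base = number of covering block intervals.

    `blocks` is a DataFrame with chrom/start/end (or chr_a/start_a/end_a)
    columns or an iterable of (chrom, start, end) half-open intervals.
    Fractions in the summary are over the total genome length.
    """
    intervals = _as_intervals(blocks)
    total = sum(genome_lengths.values())
    if total <= 0:
        raise ValueError("genome_lengths must be positive")
    diffs = {name: np.zeros(L + 1, dtype=np.int64) for name, L in genome_lengths.items()}
    for chrom, start, end in intervals:
        if chrom not in diffs:
            raise ValueError(f"interval on unknown sequence {chrom!r}")
        if not 0 <= start <= end <= genome_lengths[chrom]:
            raise ValueError(
                f"interval [{start}, {end}) beyond sequence {chrom!r} bounds"
            )
        diffs[chrom][start] += 1
        diffs[chrom][end] -= 1
    runs: dict[str, list[tuple[int, int]]] = {}
    counts: dict[int, int] = {}
    for name, diff in diffs.items():
        depth = np.cumsum(diff[:-1])
        change = np.flatnonzero(np.diff(depth)) + 1
        starts = np.concatenate([[0], change])
        ends = np.concatenate([change, [len(depth)]])
        seq_runs = []
        for s, e in zip(starts, ends):
            d = int(depth[s])
            seq_runs.append((int(e - s), d))
            counts[d] = counts.get(d, 0) + int(e - s)
        runs[name] = seq_runs
    summary = {d: c / total for d, c in sorted(counts.items())}
    assert abs(sum(summary.values()) - 1.0) < 1e-9
    return DepthProfile(runs, summary, total)


def depth_table(profiles: dict[str, DepthProfile]) -> pd.DataFrame:
    """Depth levels x comparisons table of percentages (1 decimal).

    Rows cover every depth from 0 to the maximum seen in any profile;
    columns follow the input order; each column sums to 100.0 +- 0.1.
    """
    if not profiles:
        raise ValueError("at least one profile required")
    max_depth = max(max(p.summary) for p in profiles.values())
    rows = list(range(max_depth + 1))
    data = {
        label: [round(100.0 * p.fraction_at(d), 1) for d in rows]
        for label, p in profiles.items()
    }
    out = pd.DataFrame(data, index=pd.Index(rows, name="depth"))
    return out
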