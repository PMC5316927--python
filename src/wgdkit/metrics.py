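"""Assembly, genetic-map and sliding-window summary statistics.

N50 follows the cumulative-half convention: sequences are sorted by
decreasing length and the N50 length is the length of the sequence at which
the running total first reaches half the assembly total; the N50 count is
that sequence's 1-based rank.  Presentation rounding is half-up; full
precision is kept internally.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from ._seq import gc_fraction


def round_half_up(x: float, decimals: int = 0) -> float:
    q = Decimal(1).scaleb(-decimals)
    v = float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))
    return int(v) if decimals <= 0 else v


# ---------------------------------------------------------------------------
# N-statistics and filtering
# ---------------------------------------------------------------------------


def nstats(lengths) -> dict[str, int]:
    """Total, count, mean (rounded), max, min, N50 rank and N50 length."""
    ls = sorted((int(x) for x in lengths), reverse=True)
    if not ls:
        raise ValueError("empty sequence set")
    total = sum(ls)
    half = total / 2
    cum = 0
    for rank, L in enumerate(ls, start=1):
        cum += L
        if cum >= half:
            n50_count, n50_length = rank, L
            break
    return {
        "total": total,
        "count": len(ls),
        "mean": round_half_up(total / len(ls)),
        "max": ls[0],
        "min": ls[-1],
        "N50_count": n50_count,
        "N50_length": n50_length,
    }


def filter_sequences(
    sequences: dict[str, str] | dict[str, int],
    masked_fraction: dict[str, float] | None = None,
    min_length: int = 200,
    max_masked: float = 0.5,
) -> tuple[list[str], pd.DataFrame]:
    """Drop sequences shorter than min_length or >= max_masked masked.

    `sequences` maps name -> sequence (N bases count toward the masked
    fraction) or name -> length with masked fractions supplied separately.
    Returns (kept names, drop report with a reason per dropped sequence).
    """
    masked_fraction = masked_fraction or {}
    kept, dropped = [], []
    for name, seq in sequences.items():
        if isinstance(seq, str):
            length = len(seq)
            n_frac = seq.upper().count("N") / length if length else 0.0
            masked = max(masked_fraction.get(name, 0.0), n_frac)
        else:
            length = int(seq)
            masked = masked_fraction.get(name, 0.0)
        if not 0 <= masked <= 1:
            raise ValueError(f"masked fraction for {name!r} outside [0, 1]")
        if length < min_length:
            dropped.append({"sequence": name, "length": length, "reason": "length"})
        elif masked >= max_masked:
            dropped.append({"sequence": name, "length": length, "reason": "mask"})
        else:
            kept.append(name)
    report = pd.DataFrame(dropped, columns=["sequence", "length", "reason"])
    return kept, report


def ratio_percent(part: float, whole: float, decimals: int = 1) -> float:
    """100 * part / whole, rounded half-up to `decimals`."""
    if whole <= 0:
        raise ZeroDivisionError("whole must be > 0")
    return round_half_up(100.0 * part / whole, decimals)


# ---------------------------------------------------------------------------
# Genetic map
# ---------------------------------------------------------------------------


def interval_mean(total_cm: float, n_loci: int, n_groups: int) -> float:
    """Mean marker interval: total map length over (loci - groups) intervals."""
    n_intervals = n_loci - n_groups
    if n_intervals <= 0:
        raise ValueError("no intervals: every group has at most one locus")
    return round_half_up(total_cm / n_intervals, 2)


def map_summary(map_table: pd.DataFrame) -> dict[str, float]:
    """Summary of a genetic map table (columns: marker, group, position_cm).

    Total length is the sum over linkage groups of the maximum position;
    each group with k loci contributes k - 1 intervals (a single-locus
    group contributes none, with a warning).
    """
    import warnings

    needed = {"marker", "group", "position_cm"}
    if not needed.issubset(map_table.columns):
        raise ValueError(f"map table needs columns {sorted(needed)}")
    if (map_table["position_cm"] < 0).any():
        raise ValueError("positions must be >= 0")
    total_cm = 0.0
    n_intervals = 0
    groups = map_table.groupby("group")
    for name, grp in groups:
        if len(grp) == 1:
            warnings.warn(f"linkage group {name!r} has a single locus", stacklevel=2)
        total_cm += float(grp["position_cm"].max())
        n_intervals += len(grp) - 1
    loci = int(len(map_table))
    return {
        "total_cM": round_half_up(total_cm, 1),
        "groups": int(groups.ngroups),
        "loci": loci,
        "mean_interval": round_half_up(total_cm / n_intervals, 2)
        if n_intervals
        else float("nan"),
    }


# ---------------------------------------------------------------------------
# 100-kb window tracks
# ---------------------------------------------------------------------------


def window_density(
    positions, seq_length: int, window: int = 100_000, per_mb: bool = True
) -> pd.DataFrame:
    """Feature counts in non-overlapping windows tiled from position 0.

    The last partial window is scaled by its true width when converting to
    per-Mb density, so total counts are conserved across windows.
    """
    if window <= 0:
        raise ValueError("window must be > 0")
    pos = np.asarray(list(positions), dtype=np.int64)
    if pos.size and (pos.min() < 0 or pos.max() >= seq_length):
        raise ValueError("positions outside sequence bounds")
    n_windows = max(1, -(-seq_length // window))
    counts = np.bincount(pos // window, minlength=n_windows).astype(float)
    starts = np.arange(n_windows) * window
    widths = np.minimum(starts + window, seq_length) - starts
    out = pd.DataFrame({"start": starts, "end": starts + widths, "count": counts})
    if per_mb:
        out["per_mb"] = counts / widths * 1e6
    return out


def window_gc(seq: str, window: int = 100_000) -> pd.DataFrame:
    """GC percentage over non-N bases in non-overlapping windows."""
    if window <= 0:
        raise ValueError("window must be > 0")
    rows = []
    for start in range(0, max(len(seq), 1), window):
        chunk = seq[start : start + window]
        rows.append(
            {
                "start": start,
                "end": start + len(chunk),
                "gc_percent": round_half_up(100.0 * gc_fraction(chunk), 1),
            }
        )
    return pd.DataFrame(rows)
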