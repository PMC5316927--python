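"""Independent brute-force oracles used to verify the package's fast paths.

Each oracle recomputes a quantity by direct enumeration or per-base counting
and is deliberately written without reference to the implementation it
checks.
"""

from __future__ import annotations

import itertools

import numpy as np
from Bio.Data.CodonTable import standard_dna_table

_AA = dict(standard_dna_table.forward_table)
for _s in standard_dna_table.stop_codons:
    _AA[_s] = "*"


def ng86_oracle(seq_a: str, seq_b: str) -> dict[str, float]:
    """Nei-Gojobori site/pathway enumeration done longhand.

    Sites: every one of the nine single-base changes per codon is classified
    from the code table (changes to stops are nonsynonymous).  Differences:
    recursive enumeration of all single-step pathways between each codon
    pair, discarding pathways with stop intermediates, averaging the
    synonymous/nonsynonymous step counts.
    """
    codons = [
        (seq_a[i : i + 3].upper(), seq_b[i : i + 3].upper())
        for i in range(0, len(seq_a), 3)
    ]
    codons = [
        (ca, cb)
        for ca, cb in codons
        if set(ca + cb) <= set("ACGT") and _AA[ca] != "*" and _AA[cb] != "*"
    ]

    def sites(codon):
        syn = 0.0
        for pos, base in enumerate(codon):
            for alt in "ACGT":
                if alt == base:
                    continue
                mutant = codon[:pos] + alt + codon[pos + 1 :]
                if _AA[mutant] != "*" and _AA[mutant] == _AA[codon]:
                    syn += 1.0 / 3.0
        return syn

    def pathways(ca, cb):
        """All (syn_steps, nonsyn_steps) over stop-free orderings."""
        positions = [i for i in range(3) if ca[i] != cb[i]]
        results = []
        for order in itertools.permutations(positions):
            cur, sd, nd, ok = ca, 0, 0, True
            for step_no, pos in enumerate(order):
                nxt = cur[:pos] + cb[pos] + cur[pos + 1 :]
                if _AA[nxt] == "*" and step_no < len(order) - 1:
                    ok = False
                    break
                if _AA[nxt] == _AA[cur]:
                    sd += 1
                else:
                    nd += 1
                cur = nxt
            if ok:
                results.append((sd, nd))
        return results

    S = (sum(sites(ca) for ca, _ in codons) + sum(sites(cb) for _, cb in codons)) / 2
    N = 3 * len(codons) - S
    sd_total = nd_total = 0.0
    for ca, cb in codons:
        if ca == cb:
            continue
        paths = pathways(ca, cb)
        if not paths:  # every ordering blocked; fall back to all orderings
            paths = []
            for order in itertools.permutations(
                [i for i in range(3) if ca[i] != cb[i]]
            ):
                cur, sd, nd = ca, 0, 0
                for pos in order:
                    nxt = cur[:pos] + cb[pos] + cur[pos + 1 :]
                    sd, nd = (
                        (sd + 1, nd) if _AA[nxt] == _AA[cur] else (sd, nd + 1)
                    )
                    cur = nxt
                paths.append((sd, nd))
        sd_total += sum(p[0] for p in paths) / len(paths)
        nd_total += sum(p[1] for p in paths) / len(paths)
    ps = sd_total / S if S else 0.0
    pn = nd_total / N if N else 0.0

    def jc(p):
        return -0.75 * np.log(1 - 4 * p / 3)

    return {"S": S, "N": N, "ps": ps, "pn": pn, "Ks": float(jc(ps)), "Ka": float(jc(pn))}


def best_chain_bruteforce(anchors, max_gap: int, gap_penalty: float) -> float:
    """Exhaustive search over all collinear chains of an anchor list.

    anchors: list of (start_a, end_a, start_b, end_b, score); compatibility
    of consecutive anchors = strictly increasing starts on both genomes and
    gaps at most max_gap on both.  Returns the maximum chain score.
    """

    def extend(last, remaining, score_so_far):
        best = score_so_far
        for idx, a in enumerate(remaining):
            if last is not None:
                if not (a[0] > last[0] and a[2] > last[2]):
                    continue
                gap_a = a[0] - last[1]
                gap_b = a[2] - last[3]
                if gap_a > max_gap or gap_b > max_gap:
                    continue
                penalty = gap_penalty * (max(gap_a, 0) + max(gap_b, 0))
            else:
                penalty = 0.0
            best = max(
                best,
                extend(a, remaining[idx + 1 :], score_so_far + a[4] - penalty),
            )
        return best

    ordered = sorted(anchors, key=lambda a: a[0])
    return extend(None, ordered, 0.0)


def naive_depth_fractions(intervals, lengths: dict[str, int]) -> dict[int, float]:
    """Per-base interval stacking by explicit counting."""
    counts: dict[int, int] = {}
    for name, L in lengths.items():
        base = np.zeros(L, dtype=int)
        for chrom, s, e in intervals:
            if chrom == name:
                base[s:e] += 1
        for d in base:
            counts[int(d)] = counts.get(int(d), 0) + 1
    total = sum(lengths.values())
    return {d: c / total for d, c in counts.items()}


def naive_nstats(lengths):
    """Cumulative scan for N50 done directly."""
    ls = sorted(lengths, reverse=True)
    total = sum(ls)
    cum = 0
    for i, L in enumerate(ls):
        cum += L
        if cum * 2 >= total:
            return {"N50_count": i + 1, "N50_length": L}
    raise AssertionError("unreachable")


def naive_coverage(reads, assembly: dict[str, str]):
    """All-hits per-base coverage by brute-force string scanning."""

    def rc(s):
        return s.translate(str.maketrans("ACGT", "TGCA"))[::-1]

    cov = {name: np.zeros(len(seq), dtype=int) for name, seq in assembly.items()}
    n_loci = []
    for _, read in reads:
        L = len(read)
        loci = []
        for name, seq in assembly.items():
            for i in range(len(seq) - L + 1):
                window = seq[i : i + L]
                if window == read or window == rc(read):
                    loci.append((name, i))
        for name, i in loci:
            cov[name][i : i + L] += 1
        n_loci.append(len(loci))
    return cov, n_loci
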