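"""NG86+JC estimator, anchor chaining, block medians, histograms, peaks."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import best_chain_bruteforce, ng86_oracle
from wgdkit import ks
from wgdkit._seq import SENSE_CODONS


def random_codon_seq(rng, n_codons):
    return "".join(rng.choice(SENSE_CODONS, size=n_codons))


class TestNg86:
    def test_identical_sequences(self):
        seq = "ATGGCTAAAGGT"
        r = ks.ng86_pairwise(seq, seq)
        assert r["Ks"] == 0 and r["Ka"] == 0

    def test_single_synonymous_change_worked_example(self):
        r = ks.ng86_pairwise("TTTGGTGGTGGTGGT", "TTCGGTGGTGGTGGT")
        assert r["S"] == pytest.approx(13 / 3)
        assert r["ps"] == pytest.approx(3 / 13)
        assert r["Ks"] == pytest.approx(-0.75 * np.log(1 - 4 / 3 * 3 / 13))
        assert r["Ka"] == 0

    def test_saturation_raises(self):
        with pytest.raises(ks.KsSaturationError):
            ks.ng86_pairwise("TTT", "TTC")  # ps = 1 on a single codon

    def test_empty_alignment_rejected(self):
        with pytest.raises(ks.EmptyAlignmentError):
            ks.ng86_pairwise("---", "---")

    def test_gap_and_ambiguity_codons_excluded(self):
        r = ks.ng86_pairwise("ATG---GGT", "ATGGCTGGT")
        assert r["n_codons"] == 2

    def test_symmetry_on_random_pairs(self, rng):
        for _ in range(30):
            a = random_codon_seq(rng, 40)
            b = random_codon_seq(rng, 40)
            try:
                fwd = ks.ng86_pairwise(a, b)
                rev = ks.ng86_pairwise(b, a)
            except ks.KsSaturationError:
                continue
            for key in ("S", "N", "ps", "pn", "Ks", "Ka"):
                assert fwd[key] == pytest.approx(rev[key], abs=1e-12)

    def test_site_conservation(self, rng):
        for _ in range(20):
            a = random_codon_seq(rng, 50)
            b = random_codon_seq(rng, 50)
            try:
                r = ks.ng86_pairwise(a, b)
            except ks.KsSaturationError:
                continue
            assert r["S"] + r["N"] == pytest.approx(3 * r["n_codons"], abs=1e-9)

    def test_agrees_with_enumeration_oracle(self, rng):
        for _ in range(100):
            a = random_codon_seq(rng, 30)
            b = random_codon_seq(rng, 30)
            try:
                mine = ks.ng86_pairwise(a, b)
            except ks.KsSaturationError:
                continue
            ref = ng86_oracle(a, b)
            for key in ("S", "N", "ps", "pn", "Ks", "Ka"):
                assert mine[key] == pytest.approx(ref[key], abs=1e-12)

    @given(st.floats(0.001, 0.74))
    @settings(max_examples=50, deadline=None)
    def test_jc_monotone_in_p(self, p):
        assert ks.jukes_cantor(p) > ks.jukes_cantor(p * 0.99)

    @pytest.mark.parametrize("target", [0.1, 0.3, 0.6])
    def test_cross_check_against_biopython_ng86(self, target):
        """Independent library cross-check on synonymously diverged pairs
        (conventions for stop-adjacent pathways only matter near saturation,
        so agreement is exact at realistic divergence)."""
        from Bio.Align import Alignment
        from Bio.Align.analysis import calculate_dn_ds
        from Bio.Seq import Seq

        from wgdkit import simulate

        pairs, _ = simulate.simulate_codon_pairs(10, target, 200, seed=1)
        for a, b in pairs:
            mine = ks.ng86_pairwise(a, b)
            aln = Alignment(
                [Seq(a), Seq(b)], np.array([[0, len(a)], [0, len(b)]])
            )
            dn, ds = calculate_dn_ds(aln, method="NG86")
            assert mine["Ks"] == pytest.approx(ds, abs=1e-12)
            assert mine["Ka"] == pytest.approx(dn, abs=1e-12)


def make_anchor_frame(rows):
    return pd.DataFrame(
        rows,
        columns=["gene_a", "chr_a", "start_a", "end_a",
                 "gene_b", "chr_b", "start_b", "end_b", "score"],
    )


def collinear_anchors(n, start=0, chr_b="b1", spacing=2000, score=10.0):
    rows = []
    for i in range(n):
        s = start + i * spacing
        rows.append((f"ga{start}_{i}", "a1", s, s + 1000,
                     f"gb{start}_{i}", chr_b, s, s + 1000, score))
    return rows


class TestChaining:
    def test_collinear_run_forms_one_block(self):
        df = make_anchor_frame(collinear_anchors(10))
        blocks = ks.chain_anchors(df, ks.ChainParams(max_gap=5000, min_block=5))
        assert len(blocks) == 1 and len(blocks[0]) == 10

    def test_large_gap_splits_blocks(self):
        rows = collinear_anchors(6) + collinear_anchors(6, start=200_000)
        df = make_anchor_frame(rows)
        blocks = ks.chain_anchors(df, ks.ChainParams(max_gap=50_000, min_block=5))
        assert len(blocks) == 2

    def test_min_block_threshold(self):
        df = make_anchor_frame(collinear_anchors(4))
        blocks = ks.chain_anchors(df, ks.ChainParams(max_gap=5000, min_block=5))
        assert blocks == []

    def test_reverse_orientation_chained(self):
        rows = []
        for i in range(8):
            s = i * 2000
            rows.append((f"ga{i}", "a1", s, s + 1000,
                         f"gb{i}", "b1", 100_000 - s, 101_000 - s, 10.0))
        blocks = ks.chain_anchors(
            make_anchor_frame(rows), ks.ChainParams(max_gap=5000, min_block=5)
        )
        assert len(blocks) == 1 and blocks[0].orientation == "-"

    def test_empty_input(self):
        assert ks.chain_anchors(make_anchor_frame([])) == []

    def test_dp_matches_bruteforce_on_random_sets(self, rng):
        params = ks.ChainParams(max_gap=3000, gap_penalty=0.001, min_block=1)
        for trial in range(60):
            n = int(rng.integers(4, 13))
            rows = []
            for i in range(n):
                sa = int(rng.integers(0, 10_000))
                sb = int(rng.integers(0, 10_000))
                rows.append((f"g{i}", "a", sa, sa + 500,
                             f"h{i}", "b", sb, sb + 500, float(rng.integers(1, 20))))
            df = make_anchor_frame(rows)
            blocks = ks.chain_anchors(df, params)
            dp_best = max((b.chain_score for b in blocks), default=0.0)
            fwd = best_chain_bruteforce(
                [(r[2], r[3], r[6], r[7], r[8]) for r in rows],
                params.max_gap,
                params.gap_penalty,
            )
            rev = best_chain_bruteforce(
                [(r[2], r[3], -r[7], -r[6], r[8]) for r in rows],
                params.max_gap,
                params.gap_penalty,
            )
            assert dp_best == pytest.approx(max(fwd, rev), abs=1e-9)


class TestBlockMedian:
    @pytest.mark.parametrize(
        "values,expected",
        [([0.1, 0.3, 0.2], 0.2), ([0.1, 0.2, 0.3, 0.4], 0.25)],
    )
    def test_median(self, values, expected):
        assert ks.block_median_ks(values) == pytest.approx(expected)

    def test_saturated_anchors_excluded(self):
        assert ks.block_median_ks([0.2, float("nan"), 0.4]) == pytest.approx(0.3)

    def test_all_saturated_dropped(self):
        with pytest.warns(UserWarning):
            assert ks.block_median_ks([float("nan")]) is None


class TestHistogram:
    def test_single_value(self):
        h = ks.ks_histogram([0.25], 0.1)
        assert h.proportions[2] == 1.0

    def test_uniform_values(self):
        vals = np.linspace(0, 0.999, 1000)
        h = ks.ks_histogram(vals, 0.1)
        assert np.allclose(h.proportions, 0.1, atol=0.005)

    def test_proportions_sum_to_one(self, rng):
        h = ks.ks_histogram(rng.random(500) * 2, 0.01)
        assert h.proportions.sum() == pytest.approx(1.0, abs=1e-9)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            ks.ks_histogram([-0.1, 0.2], 0.1)


class TestModalPeaks:
    def test_unimodal_recovery(self, rng):
        vals = rng.normal(0.3, 0.05, 10_000).clip(0)
        h = ks.ks_histogram(vals, 0.01)
        peaks = ks.find_modal_peaks(h, min_prominence=0.002)
        assert any(abs(p.ks_mode - 0.30) <= 0.01 for p in peaks)

    def test_bimodal_recovery(self, rng):
        vals = np.concatenate(
            [rng.normal(0.12, 0.03, 5000), rng.normal(0.68, 0.08, 5000)]
        ).clip(0)
        h = ks.ks_histogram(vals, 0.01)
        modes = [p.ks_mode for p in ks.find_modal_peaks(h)]
        assert any(abs(m - 0.12) <= 0.01 for m in modes)
        assert any(abs(m - 0.68) <= 0.01 for m in modes)

    def test_flat_histogram_no_peaks(self):
        h = ks.KsHistogram(0.1, np.full(10, 0.1))
        assert ks.find_modal_peaks(h) == []

    def test_window_too_large(self):
        h = ks.KsHistogram(0.1, np.full(3, 1 / 3))
        with pytest.raises(ValueError):
            ks.find_modal_peaks(h, smooth_window=5)


class TestTopMatches:
    def test_best_per_target_chromosome_kept(self):
        df = make_anchor_frame(
            [
                ("g1", "a", 0, 10, "x1", "b1", 0, 10, 5.0),
                ("g1", "a", 0, 10, "x2", "b1", 50, 60, 9.0),
                ("g1", "a", 0, 10, "x3", "b2", 0, 10, 3.0),
            ]
        )
        out = ks.top_matches_per_chromosome(df)
        assert len(out) == 2
        assert set(out["gene_b"]) == {"x2", "x3"}
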