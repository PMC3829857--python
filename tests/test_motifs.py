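"""Motif dictionary, masking, scanning, GAM enrichment, hotspots."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from psormod.datatypes import MotifModel, iupac_complement
from psormod.motifs import (
    MaskedSequence,
    apply_masks,
    conservation_mask,
    count_occurrences,
    dedupe_dictionary,
    gam_motif_test,
    hotspot_scan,
    naive_logistic_z,
    occurrence_positions,
    screen_module,
)
from psormod.synthetic import gen_sequences
from tests.conftest import motif_from_consensus, naive_scan_count


class TestDedupe:
    def test_exact_duplicate_removed(self):
        m = motif_from_consensus("GATTACA", "m1")
        m2 = motif_from_consensus("GATTACA", "m2")
        kept = dedupe_dictionary([m, m2])
        assert [k.motif_id for k in kept] == ["m1"]

    def test_same_consensus_divergent_ppm_both_kept(self):
        m1 = motif_from_consensus("RRRR", "m1")
        ppm = m1.ppm.copy()
        # shift every A/G entry by ±0.06: same consensus, mean |Δ| over all
        # 16 PPM entries = 0.03, above the 0.02 redundancy threshold
        ppm[0, :] += 0.06
        ppm[2, :] -= 0.06
        m2 = MotifModel("m2", ppm)
        assert m2.consensus == "RRRR"
        assert np.abs(m2.ppm - m1.ppm).mean() == pytest.approx(0.03, abs=1e-9)
        kept = dedupe_dictionary([m1, m2])
        assert len(kept) == 2

    def test_short_motif_removed(self):
        kept = dedupe_dictionary([motif_from_consensus("ACG", "short"),
                                  motif_from_consensus("ACGT", "ok")])
        assert [k.motif_id for k in kept] == ["ok"]

    def test_first_occurrence_retained(self):
        a = motif_from_consensus("ACGTAC", "first")
        b = motif_from_consensus("ACGTAC", "second")
        assert dedupe_dictionary([a, b])[0].motif_id == "first"


class TestMasking:
    def test_empty_intervals_identity(self):
        ms = apply_masks("ACGTACGT", [], gene_id="g")
        assert ms.bases == "ACGTACGT"
        assert ms.scanned_length == 8

    def test_full_cover_masks_all(self):
        ms = apply_masks("ACGTACGT", [(0, 8)])
        assert ms.bases == "N" * 8
        assert ms.scanned_length == 0

    def test_scanned_length_matches_per_base_coverage(self, rng):
        seq = "".join(rng.choice(list("ACGT"), 200))
        intervals = [
            (int(s), int(s) + int(w))
            for s, w in zip(rng.integers(0, 180, 10), rng.integers(1, 20, 10))
        ]
        ms = apply_masks(seq, intervals)
        covered = np.zeros(200, dtype=bool)
        for s, e in intervals:
            covered[s:e] = True
        assert ms.scanned_length == int((~covered).sum())

    def test_out_of_bounds_clipped_with_warning(self):
        with pytest.warns(UserWarning, match="clipped"):
            ms = apply_masks("ACGT", [(2, 99)])
        assert ms.bases == "ACNN"

    def test_conservation_median_rule(self):
        seq = MaskedSequence("g", "ACGTACGTA")
        scores = np.array([0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9])
        out = conservation_mask(seq, scores)
        assert out.bases.count("N") == 4  # bases scoring < median 0.5

    def test_conservation_cap_at_070(self):
        seq = MaskedSequence("g", "ACGTACGTA")
        out = conservation_mask(seq, np.full(9, 0.9))
        # median 0.9 > 0.70 -> threshold 0.70; nothing scores below it
        assert out.bases.count("N") == 0

    def test_all_equal_scores_mask_nothing(self):
        seq = MaskedSequence("g", "ACGTAC")
        out = conservation_mask(seq, np.full(6, 0.3))
        assert out.bases == "ACGTAC"

    def test_median_over_unmasked_bases_only(self):
        seq = apply_masks("ACGTACGTA", [(0, 4)])
        scores = np.array([0.9, 0.9, 0.9, 0.9, 0.1, 0.2, 0.3, 0.4, 0.5])
        out = conservation_mask(seq, scores)
        # median over unmasked five = 0.3; 0.1 and 0.2 masked
        assert out.bases == "NNNNNNGTA"

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            conservation_mask(MaskedSequence("g", "ACGT"), np.ones(3))


class TestScanner:
    def test_two_planted_copies(self):
        motif = motif_from_consensus("GAAACT")
        assert count_occurrences("GAAACTGAAACT", motif) == naive_scan_count(
            "GAAACTGAAACT", "GAAACT"
        )
        assert set(occurrence_positions("GAAACTGAAACT", motif)) >= {0, 6}

    def test_isre_like_worked_match(self):
        motif = motif_from_consensus("GRAANNGAAAST")
        assert count_occurrences("GGAATTGAAAGT", motif) >= 1

    def test_matches_naive_two_strand_oracle(self, rng):
        for _ in range(60):
            L = int(rng.integers(20, 150))
            seq = "".join(
                rng.choice(list("ACGTN"), L, p=[0.24, 0.24, 0.24, 0.24, 0.04])
            )
            cons = "".join(
                rng.choice(list("ACGTRYSWKMBDHVN"), rng.integers(4, 10))
            )
            motif = motif_from_consensus(cons)
            assert count_occurrences(seq, motif) == naive_scan_count(seq, cons)

    @given(st.text(alphabet="ACGT", min_size=10, max_size=60),
           st.text(alphabet="ACGTRY", min_size=4, max_size=6))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_reverse_complement_symmetry(self, seq, cons):
        motif = motif_from_consensus(cons)
        assert count_occurrences(seq, motif) == count_occurrences(
            iupac_complement(seq), motif
        )

    def test_masking_monotonicity(self, rng):
        seq = "".join(rng.choice(list("ACGT"), 300))
        motif = motif_from_consensus("RYSW")
        base = count_occurrences(seq, motif)
        masked = apply_masks(seq, [(50, 80), (150, 200)])
        assert count_occurrences(masked, motif) <= base

    def test_n_window_never_matches(self):
        motif = motif_from_consensus("NNNN")
        assert count_occurrences("ACGN", motif) == 0
        assert count_occurrences("ACGT", motif) == 1


class TestGam:
    def test_constant_x2_degenerate(self, rng):
        n = 100
        y = np.zeros(n)
        y[:10] = 1
        res = gam_motif_test(y, rng.normal(7, 1, n), np.zeros(n))
        assert res.z == 0.0 and res.p == 1.0

    def test_null_calibration_small(self, rng):
        zs = []
        for _ in range(120):
            n = 300
            length = np.exp(rng.normal(7, 0.5, n))
            counts = rng.poisson(1.0 * length / 1000)
            y = np.zeros(n)
            y[rng.choice(n, 30, replace=False)] = 1
            zs.append(gam_motif_test(y, np.log(length), np.log1p(counts)).z)
        zs = np.array(zs)
        assert 0.6 < zs.var() < 1.5
        assert np.mean(np.abs(zs) > 1.96) < 0.12

    def test_planted_enrichment_strong_positive_z(self, rng):
        medians = []
        for _ in range(10):
            n = 550
            y = np.zeros(n)
            y[:50] = 1
            length = np.exp(rng.normal(7.5, 0.5, n))
            counts = rng.poisson(np.where(y == 1, 3.0, 1.0) * length / 1000)
            res = gam_motif_test(y, np.log(length), np.log1p(counts))
            medians.append(res.z)
            assert res.beta > 0
        assert np.median(medians) > 3.0

    def test_length_confound_controlled(self, rng):
        gam_z, naive_z = [], []
        for _ in range(40):
            n = 400
            length = np.exp(rng.normal(7.5, 0.6, n))
            rank_frac = np.argsort(np.argsort(length)) / n
            y = (rng.random(n) < 0.3 * rank_frac**2).astype(float)
            if y.sum() < 5:
                continue
            counts = rng.poisson(1.0 * length / 1000)
            x1, x2 = np.log(length), np.log1p(counts)
            gam_z.append(abs(gam_motif_test(y, x1, x2).z))
            naive_z.append(abs(naive_logistic_z(y, x2)))
        assert np.median(gam_z) < np.median(naive_z)

    def test_argument_validation(self):
        with pytest.raises(ValueError):
            gam_motif_test(np.array([1, 0]), np.ones(2), np.ones(2))


class TestScreenAndHotspots:
    def test_single_motif_q_equals_p(self, rng):
        motif = motif_from_consensus("GATTACA")
        seqs, _, _ = gen_sequences(80, (600, 50), motif,
                                   {f"G{i:05d}" for i in range(15)},
                                   rate_in=3.0, rate_out=0.5, seed=1)
        masked = {g: MaskedSequence(g, s) for g, s in seqs.items()}
        members = {f"G{i:05d}" for i in range(15)}
        results = screen_module(members, [motif], masked)
        assert len(results) == 1
        assert results[0].q == pytest.approx(results[0].p)

    def test_planted_motif_ranks_first_among_decoys(self):
        planted = motif_from_consensus("GRAANNGAAAST", "planted")
        decoys = [
            motif_from_consensus(cons, f"decoy{i}")
            for i, cons in enumerate(
                ["GATTACAT", "CCCGGGAA", "TTTTACGT", "ACACACAC", "GGCCGGCC"]
            )
        ]
        wins = 0
        for seed in range(5):
            members = {f"G{i:05d}" for i in range(40)}
            seqs, _, _ = gen_sequences(240, (800, 80), planted, members,
                                       rate_in=3.0, rate_out=0.3, seed=seed)
            masked = {g: MaskedSequence(g, s) for g, s in seqs.items()}
            results = screen_module(members, [planted] + decoys, masked)
            if results[0].motif_id == "planted":
                wins += 1
        assert wins >= 4

    def test_reportable_needs_five_percent_carriers(self):
        from psormod.motifs import GamResult
        from psormod.stats import bh_adjust

        # construct directly: strong q but carriers below 5%
        res = GamResult(motif_id="m", z=4.0, p=1e-5, beta=1.0,
                        frac_with_site=0.04, converged=True)
        res.q = 0.01
        res.reportable = (res.q < 0.10 and res.frac_with_site >= 0.05)
        assert res.reportable is False

    def test_hotspot_single_site(self):
        seq = MaskedSequence("g", "A" * 500)
        motif = motif_from_consensus("GATTACAT")
        bases = list(seq.bases)
        bases[220:228] = "GATTACAT"
        seq = MaskedSequence("g", "".join(bases))
        best = hotspot_scan(seq, [motif])
        for w, (start, end, count) in best.items():
            assert count == 1
            assert start <= 220 < end

    def test_hotspot_prefers_denser_cluster(self):
        length = 1000
        bases = ["A"] * length
        motif = motif_from_consensus("GGGTACCC")
        for pos in (100, 110, 120):  # 3-site cluster
            bases[pos : pos + 8] = "GGGTACCC"
        for pos in (700, 760):  # 2-site cluster
            bases[pos : pos + 8] = "GGGTACCC"
        seq = MaskedSequence("g", "".join(bases))
        best = hotspot_scan(seq, [motif], window_sizes=(50,))
        start, end, count = best[50]
        assert count == 3
        # left-most 50 bp window containing all three site starts
        assert start <= 100 and end > 120

    def test_no_sites_leftmost_zero(self):
        seq = MaskedSequence("g", "A" * 500)
        best = hotspot_scan(seq, [motif_from_consensus("GGGGCCCC")])
        for w, (start, end, count) in best.items():
            assert (start, count) == (0, 0)

    def test_oversized_window_skipped(self):
        seq = MaskedSequence("g", "ACGT" * 20)
        with pytest.warns(UserWarning, match="skipped"):
            best = hotspot_scan(seq, [motif_from_consensus("ACGTA")],
                                window_sizes=(400, 50))
        assert 400 not in best and 50 in best

    def test_tss_proximal_narrowing_strengthens_enrichment(self, rng):
        # sites planted near the sequence start: narrowing the scanned
        # region toward the start should monotonically strengthen the signal
        motif = motif_from_consensus("GGGTACCC")
        n = 300
        members = {f"G{i:05d}" for i in range(40)}
        genes = [f"G{i:05d}" for i in range(n)]
        seqs = {}
        for g in genes:
            bases = rng.choice(list("ACGT"), 2000)
            seq = "".join(bases)
            # diffuse background sites everywhere, for every gene
            for _ in range(rng.poisson(1.0)):
                pos = int(rng.integers(0, 1990))
                seq = seq[:pos] + "GGGTACCC" + seq[pos + 8 :]
            if g in members:
                # extra sites concentrated near the start (TSS-proximal end)
                for _ in range(rng.poisson(1.5)):
                    pos = int(rng.integers(0, 400))
                    seq = seq[:pos] + "GGGTACCC" + seq[pos + 8 :]
            seqs[g] = seq
        pvals = []
        for region in (2000, 1000, 500):
            masked = {
                g: MaskedSequence(g, s[:region]) for g, s in seqs.items()
            }
            res = screen_module(members, [motif], masked)[0]
            pvals.append(res.p)
        assert pvals[2] <= pvals[0]
        assert pvals[2] < 1e-3
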