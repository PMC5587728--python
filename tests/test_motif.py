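"""Motif scoring: information content, window scores, profiles, group tests."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from apakit.motif import (
    Pfm,
    build_meta_profile,
    example_pfm,
    extract_flank,
    kmer_enrichment,
    mean_upstream_score,
    percentile_group_ks,
    position_information_content,
    scan_flank,
    score_7mer,
    signal_composition_test,
)
from apakit._util import revcomp

UNIFORM = Pfm(np.full((7, 4), 0.25))


def conserved_pfm(consensus="AAUAAAA"):
    freqs = np.zeros((7, 4))
    for p, b in enumerate(consensus):
        freqs[p, "ACGU".index(b)] = 1.0
    return Pfm(freqs)


class TestInformationContent:
    @pytest.mark.parametrize(
        "freqs, expected",
        [
            ((0.25, 0.25, 0.25, 0.25), 0.0),
            ((1.0, 0.0, 0.0, 0.0), 2.0),
            ((0.5, 0.5, 0.0, 0.0), 1.0),
        ],
    )
    def test_closed_forms(self, freqs, expected):
        assert position_information_content(freqs) == pytest.approx(expected)

    def test_rejects_negative_and_unnormalised(self):
        with pytest.raises(ValueError):
            position_information_content((-0.1, 0.5, 0.3, 0.3))
        with pytest.raises(ValueError):
            position_information_content((0.5, 0.5, 0.5, 0.5))

    @given(st.lists(st.floats(0.01, 1.0), min_size=4, max_size=4))
    @settings(derandomize=True, max_examples=50)
    def test_bounded_between_0_and_2(self, raw):
        freqs = np.array(raw) / np.sum(raw)
        value = position_information_content(freqs)
        assert -1e-12 <= value <= 2.0 + 1e-12


class TestWindowScore:
    def test_uniform_pfm_scores_zero(self):
        assert score_7mer("ACGUACG", UNIFORM) == pytest.approx(0.0)

    def test_conserved_consensus_scores_14(self):
        pfm = conserved_pfm()
        assert score_7mer("AATAAAA", pfm) == pytest.approx(14.0)

    def test_conserved_single_mismatch_scores_12(self):
        pfm = conserved_pfm()
        assert score_7mer("CATAAAA", pfm) == pytest.approx(12.0)

    def test_ambiguous_base_contributes_zero(self):
        pfm = conserved_pfm()
        assert score_7mer("NATAAAA", pfm) == pytest.approx(12.0)

    @given(st.text(alphabet="ACGU", min_size=7, max_size=7))
    @settings(derandomize=True, max_examples=100)
    def test_score_bounded_by_total_information(self, window):
        pfm = example_pfm()
        total = pfm.information_content.sum()
        assert 0.0 <= score_7mer(window, pfm) <= total + 1e-12


class TestScan:
    def test_full_flank_yields_195_scores(self, rng):
        flank = "".join(rng.choice(list("ACGT"), 201))
        offsets, scores = scan_flank(flank, example_pfm())
        assert len(scores) == 195
        assert offsets[0] == -100 and offsets[-1] == 94

    def test_all_n_flank_scores_zero(self):
        _, scores = scan_flank("N" * 201, example_pfm())
        assert np.allclose(scores, 0.0)

    def test_planted_consensus_maximises_at_its_offset(self, rng):
        pfm = conserved_pfm()
        flank = list("".join(rng.choice(list("CG"), 201)))
        flank[20:27] = list("AATAAAA")  # offset -80
        offsets, scores = scan_flank("".join(flank), pfm)
        assert offsets[int(np.argmax(scores))] == -80

    def test_score_invariant_to_sequence_outside_window(self, rng):
        pfm = example_pfm()
        core = "".join(rng.choice(list("ACGT"), 7))
        a = "C" * 40 + core + "G" * 40
        b = "A" * 40 + core + "T" * 40
        sa = scan_flank(a, pfm, upstream=40)[1][40]
        sb = scan_flank(b, pfm, upstream=40)[1][40]
        assert sa == pytest.approx(sb)

    def test_short_flank_yields_empty(self):
        offsets, scores = scan_flank("ACG", example_pfm())
        assert len(offsets) == 0 and len(scores) == 0


class TestMeanUpstreamScore:
    def test_uniform_pfm_gives_zero(self, rng):
        flank = "".join(rng.choice(list("ACGT"), 201))
        assert mean_upstream_score(flank, UNIFORM) == pytest.approx(0.0)

    def test_planted_consensus_matches_positionwise_oracle(self):
        # Independent oracle: for a fully conserved PFM a window scores 2
        # per base agreeing with the consensus; average the 54 fully
        # contained windows by direct counting.
        pfm = conserved_pfm()
        consensus = "AATAAAA"
        flank = list("GC" * 101)[:201]
        flank[20:27] = list(consensus)
        seq = "".join(flank)
        expected = np.mean(
            [
                2.0
                * sum(a == b for a, b in zip(seq[start : start + 7], consensus))
                for start in range(0, 54)
            ]
        )
        assert mean_upstream_score(seq, pfm) == pytest.approx(expected)
        # the planted window itself scores the full 7 x 2 bits
        _, scores = scan_flank(seq, pfm)
        assert scores[20] == pytest.approx(14.0)

    def test_region_shorter_than_width_errors(self):
        with pytest.raises(ValueError):
            mean_upstream_score("A" * 201, example_pfm(), region=(-10, -5))

    def test_strand_symmetric_flank_extraction(self):
        # A minus-strand PAS must score identically to the plus-strand
        # version of the reverse-complemented construction.
        rng = np.random.default_rng(5)
        genome_plus = "".join(rng.choice(list("ACGT"), 401))
        genome_minus = revcomp(genome_plus)
        pfm = example_pfm()
        flank_plus = extract_flank({"c": genome_plus}, "c", 200, "+")
        flank_minus = extract_flank({"c": genome_minus}, "c", 200, "-")
        assert flank_plus == flank_minus
        assert mean_upstream_score(flank_plus, pfm) == pytest.approx(
            mean_upstream_score(flank_minus, pfm)
        )


class TestMetaProfile:
    def test_single_flank_profile_equals_its_scan(self, rng):
        flank = "".join(rng.choice(list("ACGT"), 201))
        pfm = example_pfm()
        profile = build_meta_profile([flank], pfm)
        _, scores = scan_flank(flank, pfm)
        assert np.allclose(profile.raw, scores)

    def test_constant_scores_unchanged_by_smoothing(self):
        profile = build_meta_profile(["A" * 201], conserved_pfm(consensus="CCCCCCC"))
        assert np.allclose(profile.smoothed, profile.raw)

    def test_smoothing_preserves_mean_within_5_percent(self, rng):
        flanks = ["".join(rng.choice(list("ACGT"), 201)) for _ in range(40)]
        profile = build_meta_profile(flanks, example_pfm())
        assert profile.smoothed.mean() == pytest.approx(
            profile.raw.mean(), rel=0.05
        )

    def test_planted_offset_recovered_in_smoothed_peak(self, rng):
        # Motifs planted at -60 with the same +/-2 nt heterogeneity real
        # cleavage sites show; the smoothed meta-profile must peak there.
        pfm = example_pfm()
        consensus = pfm.consensus.replace("U", "T")
        flanks = []
        for _ in range(100):
            f = list("".join(rng.choice(list("ACGT"), 201)))
            start = 40 + int(rng.integers(-2, 3))
            f[start : start + 7] = list(consensus)
            flanks.append("".join(f))
        profile = build_meta_profile(flanks, pfm)
        raw_peak = profile.offsets[int(np.argmax(profile.raw))]
        smooth_peak = profile.offsets[int(np.argmax(profile.smoothed))]
        assert abs(raw_peak - (-60)) <= 2
        assert abs(smooth_peak - (-60)) <= 3


class TestPercentileGroups:
    def test_identical_values_give_p_one(self, rng):
        scores = rng.normal(size=100)
        values = np.ones(100)
        result = percentile_group_ks(scores, values)
        assert result.pvalue == pytest.approx(1.0)

    def test_degenerate_scores_flagged(self):
        with pytest.warns(UserWarning):
            result = percentile_group_ks(np.ones(30), np.arange(30.0))
        assert result.degenerate and result.pvalue is None

    def test_ties_at_cutoff_fall_in_lower_group(self):
        # Half zeros, half ones: the interpolated 90th percentile is 1.0 and
        # scores tied with the cutoff belong to the lower group, leaving the
        # high group empty (flagged degenerate).
        scores = np.array([0.0] * 50 + [1.0] * 50)
        with pytest.warns(UserWarning):
            result = percentile_group_ks(scores, np.arange(100.0))
        assert result.high.sum() == 0 and result.degenerate

    def test_shifted_top_decile_detected(self, rng):
        scores = rng.normal(size=500)
        values = rng.normal(0, 0.3, 500)
        values[scores > np.percentile(scores, 90)] -= 1.0
        result = percentile_group_ks(scores, values)
        assert result.pvalue < 1e-6

    def test_ten_ninety_cut_compares_extremes(self, rng):
        scores = np.arange(100.0)
        values = np.where(scores >= 90, 1.0, 0.0)
        result = percentile_group_ks(scores, values, cut="10th/90th")
        assert result.high.sum() == result.low.sum()
        assert result.pvalue < 1e-3

    def test_too_few_units_rejected(self):
        with pytest.raises(ValueError):
            percentile_group_ks(np.arange(10.0), np.arange(10.0))


class TestKmerEnrichment:
    def test_256_rows_for_k4(self, rng):
        seqs = ["".join(rng.choice(list("ACGT"), 60)) for _ in range(5)]
        frame = kmer_enrichment(seqs, seqs, k=4)
        assert len(frame) == 256

    def test_identical_groups_all_p_one(self, rng):
        seqs = ["".join(rng.choice(list("ACGT"), 60)) for _ in range(8)]
        frame = kmer_enrichment(seqs, list(seqs), k=4)
        assert (frame["p_value"] == 1.0).all()

    def test_perfect_separation_matches_hypergeometric(self):
        # group of 10 all contain AUAA, background of 10 none: the 2x2 is
        # (10,0;0,10) and the two-sided exact p is 2/C(20,10).
        group = ["CCATAACC" + "G" * 20] * 10
        background = ["C" * 28] * 10
        frame = kmer_enrichment(group, background, k=4)
        row = frame[frame["kmer"] == "AUAA"].iloc[0]
        from scipy.stats import hypergeom

        expected = 2 * hypergeom.pmf(10, 20, 10, 10)
        assert row["p_value"] == pytest.approx(expected, rel=1e-9)
        assert row["group_with"] == 10 and row["background_with"] == 0

    def test_empty_group_errors(self):
        with pytest.raises(ValueError):
            kmer_enrichment([], ["ACGT"], k=4)


class TestSignalComposition:
    def test_identical_distributions_not_significant(self):
        classes = ["AAUAAA"] * 30 + ["variant"] * 15 + ["none"] * 15
        result = signal_composition_test({"a": classes, "b": list(classes)})
        assert result.pvalue > 0.99

    def test_disjoint_compositions_highly_significant(self):
        result = signal_composition_test(
            {"a": ["AAUAAA"] * 50, "b": ["none"] * 50}
        )
        assert result.pvalue < 1e-10

    def test_proportions_sum_to_one(self):
        result = signal_composition_test(
            {"a": ["AAUAAA", "variant", "none"], "b": ["A_rich", "none", "none"]}
        )
        assert np.allclose(result.proportions.sum(axis=1), 1.0)


class TestPfmIO:
    def test_tsv_roundtrip(self, tmp_path):
        pfm = example_pfm()
        path = tmp_path / "pfm.tsv"
        pfm.to_tsv(path)
        again = Pfm.from_tsv(path)
        assert np.allclose(pfm.freqs, again.freqs)

    def test_invalid_rows_rejected(self):
        with pytest.raises(ValueError):
            Pfm(np.full((7, 4), 0.3))
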