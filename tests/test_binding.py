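"""PSSM predictor tests: scoring arithmetic, IC50/rank transforms, binder calls."""

import math

import numpy as np
import pandas as pd
import pytest

from ligandsweep import (
    AlleleSpec,
    SimConfig,
    build_profile,
    build_profiles,
    call_binders,
    binder_peptides,
    ic50_from_score,
    percent_rank,
    score_peptide,
    simulate_experiment,
)
from ligandsweep.alphabet import AA_INDEX
from ligandsweep.binding import AlleleProfile
from ligandsweep.errors import (
    AlphabetError,
    ConfigurationError,
    InvalidArgumentError,
    LengthError,
)


def flat_profile(score_min=-100.0, score_max=100.0, bg=None):
    """Hand-built profile with an all-zero 9mer PSSM and a controllable background."""
    if bg is None:
        bg = np.linspace(50, 1, 1000)
    return AlleleProfile(
        "TEST",
        {9: np.zeros((9, 20))},
        {9: np.sort(np.asarray(bg, dtype=float))[::-1]},
        {9: (score_min, score_max)},
    )


class TestRawScore:
    def test_zero_matrix_scores_zero(self):
        assert score_peptide(flat_profile(), "ALAKAAAAV") == 0.0

    def test_two_anchor_weights_sum(self):
        mat = np.zeros((9, 20))
        mat[1, AA_INDEX["L"]] = 1.0
        mat[8, AA_INDEX["V"]] = 1.0
        prof = AlleleProfile("T", {9: mat}, {9: np.linspace(5, 0, 1000)}, {9: (0.0, 2.0)})
        assert score_peptide(prof, "ALAAAAAAV") == pytest.approx(2.0)

    def test_matches_per_position_lookup_oracle(self, matched_profiles):
        prof = matched_profiles[0]
        for peptide in ["PEPTIDEKL", "KLMNPQRSTV", "ACDEFGHIKLM"]:
            expected = sum(
                prof.pssm_by_length[len(peptide)][pos, AA_INDEX[res]]
                for pos, res in enumerate(peptide)
            )
            assert score_peptide(prof, peptide) == pytest.approx(expected)

    def test_unsupported_length_and_alphabet_rejected(self, matched_profiles):
        with pytest.raises(LengthError):
            score_peptide(matched_profiles[0], "SHORT")
        with pytest.raises(AlphabetError):
            score_peptide(matched_profiles[0], "ACDEFGHIX")

    def test_swapping_equal_weight_positions_preserves_score(self):
        # scoring is position-local: permuting residues across positions with
        # identical weight columns cannot change the sum
        mat = np.tile(np.arange(20, dtype=float), (9, 1))
        prof = AlleleProfile("T", {9: mat}, {9: np.linspace(5, 0, 1000)}, {9: (0.0, 1.0)})
        assert score_peptide(prof, "ACDEFGHIK") == pytest.approx(score_peptide(prof, "KIHGFEDCA"))


class TestIc50:
    def test_endpoints(self):
        assert ic50_from_score(1.0, 0.0, 1.0) == pytest.approx(1.0)
        assert ic50_from_score(0.0, 0.0, 1.0) == pytest.approx(50000.0)

    def test_500nm_at_closed_form_normalised_score(self):
        s = 1 - math.log(500) / math.log(50000)
        assert s == pytest.approx(0.4256, abs=1e-4)
        assert ic50_from_score(s, 0.0, 1.0) == pytest.approx(500.0)

    def test_clamped_above_maximum(self):
        assert ic50_from_score(99.0, 0.0, 1.0) == pytest.approx(1.0)

    def test_antitone_in_raw_score(self):
        raws = np.linspace(-2, 3, 50)
        out = ic50_from_score(raws, 0.0, 1.0)
        assert (np.diff(out) <= 0).all()

    def test_degenerate_range_rejected(self):
        with pytest.raises(InvalidArgumentError):
            ic50_from_score(0.5, 1.0, 1.0)


class TestPercentRank:
    def test_score_above_all_background_ranks_zero(self):
        prof = flat_profile(bg=np.linspace(-10, -1, 1000))
        assert percent_rank(prof, "ACDEFGHIK") == 0.0

    def test_median_background_score_ranks_fifty(self):
        bg = np.linspace(-5, 5, 2000)  # median straddles 0 = the flat PSSM score
        prof = flat_profile(bg=bg)
        assert percent_rank(prof, "ACDEFGHIK") == pytest.approx(50.0, abs=100 / 2000)

    def test_missing_background_length_is_configuration_error(self):
        with pytest.raises((ConfigurationError, LengthError)):
            percent_rank(flat_profile(), "ACDEFGHIKL")

    def test_rank_is_antitone_in_score(self, matched_profiles):
        prof = matched_profiles[0]
        from ligandsweep.binding import _percent_rank_scores

        raws = np.linspace(-3, 8, 100)
        ranks = _percent_rank_scores(prof, 9, raws)
        assert (np.diff(ranks) <= 0).all()

    def test_fresh_background_peptides_rank_uniformly(self, matched_profiles):
        # probability-integral transform: rank of a background-distributed
        # peptide is Uniform(0, 100), so P(rank <= 2%) = 2%
        from ligandsweep.binding import _percent_rank_scores, _score_codes

        prof = matched_profiles[0]
        rng = np.random.default_rng(123)
        codes = rng.integers(0, 20, size=(10000, 9))
        ranks = _percent_rank_scores(prof, 9, _score_codes(prof.pssm_by_length[9], codes))
        assert abs((ranks <= 2.0).mean() - 0.02) < 0.005


class TestBinderCalls:
    def test_ic50_arm_inclusive_at_500(self):
        # raw score placed exactly at IC50 = 500 nM, rank far above 2%
        prof = flat_profile(score_min=-100.0, score_max=100.0,
                            bg=np.linspace(200, 100, 1000))
        s500 = 1 - math.log(500) / math.log(50000)
        raw = -100 + s500 * 200.0
        mat = np.zeros((9, 20))
        mat[0, AA_INDEX["A"]] = raw
        prof.pssm_by_length[9] = mat
        calls = call_binders([prof], ["ACDEFGHIK"])
        row = calls.iloc[0]
        assert row.ic50 == pytest.approx(500.0)
        assert row.percent_rank == 100.0
        assert bool(row.is_binder)

    def test_rank_arm_inclusive_at_two_percent(self):
        # rank exactly 2.0%, IC50 kept > 500 by a huge score range
        bg = np.linspace(1000, 1, 1000)  # score 981 -> 20 of 1000 >= it
        prof = flat_profile(score_min=0.0, score_max=1e7, bg=bg)
        mat = np.zeros((9, 20))
        mat[0, AA_INDEX["A"]] = 981.0
        prof.pssm_by_length[9] = mat
        calls = call_binders([prof], ["ACDEFGHIK"])
        row = calls.iloc[0]
        assert row.percent_rank == pytest.approx(2.0)
        assert row.ic50 > 500.0
        assert bool(row.is_binder)

    def test_failing_both_arms_is_not_a_binder(self):
        prof = flat_profile(score_min=0.0, score_max=1e7, bg=np.linspace(1000, 1, 1000))
        calls = call_binders([prof], ["ACDEFGHIK"])  # raw 0: rank 100, ic50 huge
        assert not calls["is_binder"].any()

    def test_out_of_range_lengths_excluded_before_calling(self, matched_profiles):
        calls = call_binders(matched_profiles, ["ACDEFGHI", "ACDEFGHIK", "ACDEFGHIKLMN"])
        assert set(calls["peptide"]) == {"ACDEFGHIK"}

    def test_empty_profile_list_rejected(self):
        with pytest.raises(InvalidArgumentError):
            call_binders([], ["ACDEFGHIK"])

    def test_multi_allele_or_semantics(self, matched_profiles):
        # an A*02:01-style double-anchor peptide binds the panel even though
        # it misses the B*07:02 motif
        peptide = "GLDKAWQEV"
        binders = binder_peptides(matched_profiles, [peptide])
        per_allele = call_binders(matched_profiles, [peptide])
        assert peptide in binders
        assert per_allele["is_binder"].sum() >= 1

    def test_recovers_simulated_binder_fraction(self, proteome_and_abundance):
        # parameter recovery: the called-binder fraction among true 9-11mers
        # tracks the generating true_binder_fraction within 5 points
        proteome, abundance = proteome_and_abundance
        fractions = []
        for seed in range(5):
            cfg = SimConfig(seed=100 + seed, n_true_psms=1000, false_match_rate=0.0)
            exp = simulate_experiment(cfg, proteome, abundance)
            profiles = build_profiles(cfg.alleles, seed=11)
            mers = [p for p in exp.truth["peptide"] if len(p) in (9, 10, 11)]
            binders = binder_peptides(profiles, mers)
            fractions.append(len(binders) / len(set(mers)))
        assert abs(np.mean(fractions) - 0.85) < 0.05


class TestProfileBuild:
    def test_anchor_residues_get_anchor_weight(self):
        spec = AlleleSpec(name="X*01:01", p2="L", cterm="V")
        prof = build_profile(spec, seed=1)
        mat = prof.pssm_by_length[9]
        assert mat[1, AA_INDEX["L"]] > 2.0
        assert mat[8, AA_INDEX["V"]] > 2.0
        assert abs(mat[4, AA_INDEX["A"]]) < 1.5  # non-anchor stays small

    def test_background_sorted_descending_and_large_enough(self, matched_profiles):
        for prof in matched_profiles:
            for ln, bg in prof.background_by_length.items():
                assert bg.size >= 1000
                assert (np.diff(bg) <= 0).all()

    def test_small_background_rejected(self):
        with pytest.raises(InvalidArgumentError):
            build_profile(AlleleSpec(name="X", p2="L", cterm="V"), seed=1, n_background=10)
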