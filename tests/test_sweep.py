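"""Sweep assembly, protein-of-interest filtering and rescue set algebra."""

import math

import numpy as np
import pandas as pd
import pytest

from ligandsweep import (
    build_sweep,
    collapse_to_peptides,
    filter_by_source,
    rescue_analysis,
    threshold_for_fdr,
)
from ligandsweep.binding import binder_peptides
from ligandsweep.errors import InvalidArgumentError

from _oracles import brute_rescue_sets


def psm_frame(rows, sample="s"):
    return pd.DataFrame(
        [
            {"peptide": p, "score": s, "is_decoy": d, "protein": prot, "sample": sample}
            for p, s, d, prot in rows
        ]
    )


class TestBuildSweep:
    def test_single_point_matches_manual_composition(self, default_experiment, matched_profiles):
        psms = default_experiment.psms
        result = build_sweep(psms, matched_profiles, [0.05])
        point = result.points.iloc[0]
        cutoff, accepted = threshold_for_fdr(collapse_to_peptides(psms), 0.05)
        mers = {p for p in accepted["peptide"] if len(p) in (9, 10, 11)}
        binders = binder_peptides(matched_profiles, mers)
        assert point.score_cutoff == cutoff
        assert point.n_total_peptides == len(set(accepted["peptide"]))
        assert point.n_9_11 == len(mers)
        assert point.n_binders == len(binders)
        assert point.pct_binders == pytest.approx(100 * len(binders) / len(mers))

    def test_counts_monotone_and_sets_nested(self, default_experiment, matched_profiles):
        result = build_sweep(default_experiment.psms, matched_profiles, [0.001, 0.01, 0.05])
        pts = result.points
        for col in ["n_total_peptides", "n_9_11", "n_binders"]:
            assert (pts[col].diff().dropna() >= 0).all()
        a1, a2, a3 = [set(result.accepted_by_alpha[a]["peptide"]) for a in [0.001, 0.01, 0.05]]
        assert a1 <= a2 <= a3
        b1, b2, b3 = [result.binders_by_alpha[a] for a in [0.001, 0.01, 0.05]]
        assert b1 <= b2 <= b3

    def test_no_9_11mers_yields_tagged_missing_pct(self, matched_profiles):
        psms = psm_frame([("ACDEFGHI", 10.0, False, "P1"), ("ACDEFGHW", 1.0, True, "")])
        result = build_sweep(psms, matched_profiles, [0.5])
        point = result.points.iloc[0]
        assert point.n_9_11 == 0
        assert math.isnan(point.pct_binders)


class TestFilterBySource:
    def _sweep_with_proteins(self, matched_profiles):
        # five accepted binder-motif peptides from four proteins, no decoys
        peptides = ["GLDKAWQEV", "KLFEQWNSV", "MLYARDTGV", "ALWEKNQSV", "SLGERYTAV"]
        proteins = ["P1", "P1", "P2", "P3", "P4"]
        psms = psm_frame([(p, 10.0, False, prot) for p, prot in zip(peptides, proteins)])
        return build_sweep(psms, matched_profiles, [1.0]), peptides

    def test_hand_counted_subset(self, matched_profiles):
        sweep, peptides = self._sweep_with_proteins(matched_profiles)
        assert sweep.points.iloc[0].n_binders == 5  # sanity: implanted motifs all bind
        out = filter_by_source(sweep, ["P1", "P3"])
        assert out.iloc[0].n_poi_binders == 3

    def test_full_accession_list_recovers_all_binders(self, matched_profiles):
        sweep, _ = self._sweep_with_proteins(matched_profiles)
        out = filter_by_source(sweep, ["P1", "P2", "P3", "P4"])
        assert out.iloc[0].n_poi_binders == sweep.points.iloc[0].n_binders

    def test_disjoint_accession_list_yields_zero(self, matched_profiles):
        sweep, _ = self._sweep_with_proteins(matched_profiles)
        assert filter_by_source(sweep, ["OTHER"]).iloc[0].n_poi_binders == 0

    def test_empty_accession_list_rejected(self, matched_profiles):
        sweep, _ = self._sweep_with_proteins(matched_profiles)
        with pytest.raises(InvalidArgumentError):
            filter_by_source(sweep, [])


class TestRescue:
    BINDERS = ["GLDKAWQEV", "KLFEQWNSV", "MLYARDTGV"]  # p1, p2, p3

    def _filler(self, n=100):
        rng = np.random.default_rng(7)
        from ligandsweep.alphabet import decode

        # unique non-motif 9mers at high score: accepted at every threshold
        out = set()
        while len(out) < n:
            pep = decode(rng.integers(0, 20, size=9))
            if pep[1] not in "LMPA":
                out.add(pep)
        return sorted(out)

    def test_hand_built_recovery_counts(self, matched_profiles):
        filler = self._filler()
        low = psm_frame(
            [(p, 10.0, False, "P") for p in filler]
            + [(p, 5.0, False, "P") for p in self.BINDERS]
            + [("WWWWDDDDK", 5.5, True, ""), ("WWWWDDDDR", 5.5, True, "")]
        )
        # high input: p1 climbs to the strict set, p2 stays in the band, p3 sinks
        high = psm_frame(
            [(p, 10.0, False, "P") for p in filler]
            + [("GLDKAWQEV", 10.0, False, "P"), ("KLFEQWNSV", 5.0, False, "P"),
               ("MLYARDTGV", 0.5, False, "P")]
            + [("WWWWDDDDK", 5.5, True, ""), ("WWWWDDDDR", 5.5, True, "")]
            + [("WWWWDDDK" + "ACDEFGHIKL"[i], 0.6, True, "") for i in range(10)]
        )
        report = rescue_analysis(low, high, matched_profiles, 0.01, 0.05)
        assert report.band_binders == set(self.BINDERS)
        assert report.n_recovered_strict == 1
        assert report.n_recovered_relaxed_extra == 1
        assert report.recovery_fraction == pytest.approx(1 / 3)

    def test_identical_samples_recover_nothing_at_strict(self, matched_profiles):
        filler = self._filler()
        low = psm_frame(
            [(p, 10.0, False, "P") for p in filler]
            + [(p, 5.0, False, "P") for p in self.BINDERS]
            + [("WWWWDDDDK", 5.5, True, ""), ("WWWWDDDDR", 5.5, True, "")]
        )
        report = rescue_analysis(low, low.copy(), matched_profiles, 0.01, 0.05)
        assert report.n_recovered_strict == 0
        assert report.n_recovered_relaxed_extra == report.n_band > 0

    def test_set_identities_match_brute_force_oracle(self, matched_profiles):
        rng = np.random.default_rng(99)
        universe = self._filler(40)
        for _ in range(200):
            band = set(rng.choice(universe, size=rng.integers(0, 15), replace=False))
            strict = set(rng.choice(universe, size=rng.integers(0, 25), replace=False))
            relaxed = strict | set(rng.choice(universe, size=rng.integers(0, 10), replace=False))
            o_strict, o_extra = brute_rescue_sets(band, strict, relaxed)
            got_strict = len(band & strict)
            got_extra = len(band & (relaxed - strict))
            assert (got_strict, got_extra) == (o_strict, o_extra)
            assert got_strict + got_extra <= len(band)

    def test_misordered_thresholds_rejected(self, matched_profiles):
        psms = psm_frame([("GLDKAWQEV", 1.0, False, "P")])
        with pytest.raises(InvalidArgumentError):
            rescue_analysis(psms, psms, matched_profiles, 0.05, 0.01)
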