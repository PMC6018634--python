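"""The manual filtering ledger, site-level FDR and co-modification scoring."""

import math
import random

import pytest

from sumosite.evidence import Modification
from sumosite.filtering import (
    FilterParams,
    filter_sites,
    find_comod,
    site_level_fdr,
)


class TestFilterLedger:
    def _ten_rows(self, make):
        """Hand fixture: 5 clean rows + one violation of five rules each."""
        clean = [
            make(scans=(i,), sample=s, condition=c, replicate=r)
            for i, (s, c, r) in enumerate(
                [
                    ("control_r1", "control", 1),
                    ("control_r2", "control", 2),
                    ("control_r3", "control", 3),
                    ("heat_r1", "heat", 1),
                ],
                start=1,
            )
        ]
        clean.append(
            make(peptide="AQWLKDSTRGHPLMNEY", mods=(Modification("sumo", 5, 30.0),),
                 protein="P2", scans=(5,))
        )
        bad = [
            make(reverse=True, scans=(11,)),
            make(mods=(Modification("sumo", 9, 30.0),
                       Modification("phospho", 3, 30.0)),
                 delta=35.0, scans=(12,), sample="heat_r2", condition="heat",
                 replicate=2),
            make(mods=(Modification("sumo", 9, 5.0),), scans=(13,),
                 sample="heat_r3", condition="heat", replicate=3),
            # trypsin-derived SUMO site on the peptide C-terminal lysine
            make(peptide="DLGHWRFAK", mods=(Modification("sumo", 9, 30.0),),
                 protease="trypsin", scans=(14,), sample="heat_r1",
                 condition="heat", replicate=1),
            # duplicate window of clean[0] in the same sample, lower delta
            make(delta=50.0, scans=(15,)),
        ]
        return clean + bad

    def test_hand_fixture_counts(self, tiny_proteins, row_factory):
        rows = self._ten_rows(row_factory)
        survivors, report = filter_sites(rows, FilterParams(), tiny_proteins)
        assert report.counts_dropped == {
            "reverse": 1, "delta_multi": 1, "loc": 1, "cterm": 1, "duplicate": 1,
        }
        assert report.survivors == len(survivors) == 5
        assert report.fraction_discarded == pytest.approx(0.5)

    def test_all_rows_passing(self, tiny_proteins, row_factory):
        rows = [row_factory(scans=(i,), sample=s, condition=c, replicate=r)
                for i, (s, c, r) in enumerate(
                    [("control_r1", "control", 1), ("control_r2", "control", 2)],
                    start=1)]
        _, report = filter_sites(rows, FilterParams(), tiny_proteins)
        assert report.fraction_discarded == 0.0
        assert report.counts_dropped == {}

    def test_aspn_cterminal_lysine_kept_when_next_residue_acidic(
        self, tiny_proteins, row_factory
    ):
        # P2 = AQWLKDST...: peptide ending at K5 is followed by D
        row = row_factory(
            peptide="AQWLK", mods=(Modification("sumo", 5, 30.0),),
            protein="P2", protease="aspn",
        )
        params = FilterParams(min_peptide_length=5)
        survivors, report = filter_sites([row], params, tiny_proteins)
        assert len(survivors) == 1

    def test_aspn_cterminal_lysine_dropped_otherwise(self, row_factory):
        proteins = {"P3": "AQWLKSTRGHPLMNEY"}  # K5 followed by S
        row = row_factory(
            peptide="AQWLK", mods=(Modification("sumo", 5, 30.0),),
            protein="P3", protease="aspn",
        )
        params = FilterParams(min_peptide_length=5)
        _, report = filter_sites([row], params, proteins)
        assert report.counts_dropped == {"cterm": 1}

    def test_aspn_cterminal_lysine_needs_protein_sequences(self, row_factory):
        row = row_factory(
            peptide="AQWLK", mods=(Modification("sumo", 5, 30.0),),
            protein="P2", protease="aspn",
        )
        with pytest.raises(ValueError, match="protein sequences"):
            filter_sites([row], FilterParams(min_peptide_length=5), None)

    def test_diagnostic_ion_requirement_per_protease(self, tiny_proteins,
                                                     row_factory):
        rows = [
            row_factory(diagnostic=False, scans=(1,)),  # aspn: dropped
            row_factory(diagnostic=False, protease="lysc", scans=(2,),
                        sample="control_r2", replicate=2),  # lysc: kept
        ]
        survivors, report = filter_sites(rows, FilterParams(), tiny_proteins)
        assert report.counts_dropped == {"diagnostic": 1}
        assert survivors[0].protease == "lysc"

    def test_attribution_completeness(self, tiny_proteins, row_factory):
        rows = self._ten_rows(row_factory)
        survivors, report = filter_sites(rows, FilterParams(), tiny_proteins)
        assert sum(report.counts_dropped.values()) + len(survivors) == len(rows)

    def test_order_independence(self, tiny_proteins, row_factory):
        rows = self._ten_rows(row_factory)
        shuffled = rows[:]
        random.Random(7).shuffle(shuffled)
        a, ra = filter_sites(rows, FilterParams(), tiny_proteins)
        b, rb = filter_sites(shuffled, FilterParams(), tiny_proteins)
        assert a == b
        assert ra.counts_dropped == rb.counts_dropped

    def test_raising_thresholds_never_adds_survivors(self, tiny_proteins,
                                                     row_factory):
        rows = self._ten_rows(row_factory)
        base = FilterParams()
        n_base = len(filter_sites(rows, base, tiny_proteins)[0])
        for stricter in (
            FilterParams(min_andromeda=150),
            FilterParams(min_delta_single=55),
            FilterParams(min_delta_multi=70),
            FilterParams(min_loc_delta=25),
            FilterParams(min_peptide_length=12),
        ):
            n = len(filter_sites(rows, stricter, tiny_proteins)[0])
            assert n <= n_base


class TestSiteLevelFdr:
    def test_separable_targets(self):
        # 98 targets above both decoys: the most permissive feasible
        # threshold still admits one decoy (1/98 ~ 1% <= 2%)
        cands = [(s, False) for s in range(10, 108)] + [(1.0, True), (2.0, True)]
        threshold = site_level_fdr(cands, 0.02)
        assert threshold == 2.0
        strict = site_level_fdr(cands, 0.005)
        assert 2.0 < strict <= 10.0

    def test_unattainable_returns_infinity(self):
        cands = [(99.0, True), (98.0, True), (1.0, False)]
        assert site_level_fdr(cands, 0.1) == math.inf

    def test_target_one_accepts_everything(self):
        cands = [(5.0, False), (1.0, True), (0.5, False)]
        assert site_level_fdr(cands, 1.0) == 0.5

    def test_matches_brute_force(self):
        rng = random.Random(0)
        cands = [(rng.uniform(0, 100), rng.random() < 0.2) for _ in range(200)]
        got = site_level_fdr(cands, 0.05)
        feasible = []
        for t, _ in cands:
            n_t = sum(1 for s, d in cands if not d and s >= t)
            n_d = sum(1 for s, d in cands if d and s >= t)
            if n_t and n_d / n_t <= 0.05:
                feasible.append(t)
        assert got == min(feasible)

    def test_no_targets_raises(self):
        with pytest.raises(ValueError):
            site_level_fdr([(1.0, True)], 0.05)


class TestComod:
    def _row(self, make, **kw):
        defaults = dict(
            mods=(Modification("sumo", 9, 10.0), Modification("phospho", 3, 10.0)),
            delta=50.0,
        )
        defaults.update(kw)
        return make(**defaults)

    def test_passing_row_scores_half_delta(self, tiny_proteins, row_factory):
        (rec,) = find_comod([self._row(row_factory)], tiny_proteins)
        assert rec.combined_score == 25.0
        assert rec.sumo_position == 9
        assert rec.phospho_position == 3
        assert len(rec.sumo_window) == len(rec.phospho_window) == 51
        assert rec.sumo_window[25] == "K"

    def test_delta_forty_is_rejected(self, tiny_proteins, row_factory):
        # combined score of exactly 20 does not pass the > 20 cutoff
        assert find_comod([self._row(row_factory, delta=40.0)], tiny_proteins) == []

    def test_matched_rows_excluded(self, tiny_proteins, row_factory):
        row = self._row(row_factory, id_type="matched", delta=90.0)
        assert find_comod([row], tiny_proteins) == []

    def test_low_localization_excluded(self, tiny_proteins, row_factory):
        row = self._row(
            row_factory,
            mods=(Modification("sumo", 9, 10.0), Modification("phospho", 3, 5.0)),
        )
        assert find_comod([row], tiny_proteins) == []

    def test_best_record_per_modified_peptide(self, tiny_proteins, row_factory):
        rows = [
            self._row(row_factory, delta=50.0, scans=(1,)),
            self._row(row_factory, delta=70.0, scans=(2,),
                      sample="control_r2", replicate=2),
        ]
        (rec,) = find_comod(rows, tiny_proteins)
        assert rec.combined_score == 35.0

    def test_comod_is_subset_of_filter_survivors(self, tiny_proteins,
                                                 row_factory):
        rows = [
            self._row(row_factory, scans=(1,)),
            self._row(row_factory, delta=35.0, scans=(2,),
                      sample="control_r2", replicate=2),
            row_factory(scans=(3,), sample="control_r3", replicate=3),
        ]
        survivors, _ = filter_sites(rows, FilterParams(), tiny_proteins)
        surviving_peptides = {
            (r.peptide_sequence, tuple(r.modifications)) for r in survivors
        }
        for rec in find_comod(rows, tiny_proteins):
            matching = [
                r for r in rows
                if r.peptide_sequence == rec.peptide_sequence
                and r.delta_score == rec.delta
            ]
            assert any(
                (m.peptide_sequence, tuple(m.modifications)) in surviving_peptides
                for m in matching
            )
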