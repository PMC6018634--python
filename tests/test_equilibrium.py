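"""SUMO pool classification, equilibrium fractions and chain topology."""

import numpy as np
import pytest
from scipy import stats

from sumosite.equilibrium import (
    HUMAN_CONSTANTS,
    SUMO2_HUMAN,
    ChainProfile,
    chain_topology,
    classify_row,
    compare_organ_fraction,
    equilibrium_fractions,
    EquilibriumResult,
)
from sumosite.evidence import Modification, StudyDesign
from sumosite.synthetic import make_design


def sumo_row(make, **kw):
    defaults = dict(protein="SUMO2", peptide="DVFQQQTGG", mods=())
    defaults.update(kw)
    return make(**defaults)


class TestClassification:
    def test_free_mature(self, row_factory):
        assert classify_row(sumo_row(row_factory)) == "free_mature"

    def test_longer_qqtgg_peptide_is_also_free(self, row_factory):
        row = sumo_row(row_factory, peptide="TIDVFQQQTGG")
        assert classify_row(row) == "free_mature"

    def test_immature_sumo2(self, row_factory):
        row = sumo_row(row_factory, peptide="DVFQQQTGGVY")
        assert classify_row(row) == "immature_sumo2"

    def test_immature_sumo3(self, row_factory):
        row = sumo_row(row_factory, peptide="DVFQQQTGGVP", protein="SUMO3")
        assert classify_row(row) == "immature_sumo3"

    def test_internal_peptide_excluded(self, row_factory):
        row = sumo_row(row_factory, peptide="DGSVVQFKIK")
        assert classify_row(row) == "internal_excluded"

    def test_enzyme_precedence(self, row_factory):
        mods = (Modification("sumo", 1, 30.0),)
        cases = [
            ("SUMO2", "KVAGQDGSVV", "chain"),
            ("UBC9", "KAAAAAA", "e2"),
            ("SAE1", "KAAAAAA", "e1"),
            ("UBA2", "KAAAAAA", "e1"),
            ("P0001", "KAAAAAA", "other_target"),
        ]
        for protein, peptide, expected in cases:
            row = sumo_row(row_factory, protein=protein, peptide=peptide,
                           mods=mods)
            assert classify_row(row) == expected

    def test_e3_by_descriptive_name(self, row_factory):
        row = sumo_row(
            row_factory, protein="Q12345", peptide="KAAAAAA",
            mods=(Modification("sumo", 1, 30.0),),
        )
        names = {"Q12345": "E3 SUMO ligase PIAS1"}
        assert classify_row(row, HUMAN_CONSTANTS, names) == "e3"

    def test_non_sumo_unmodified_row_rejected(self, row_factory):
        row = sumo_row(row_factory, protein="P0001", peptide="AAAAQA")
        with pytest.raises(ValueError):
            classify_row(row)


class TestEquilibriumFractions:
    def test_direct_ratio(self, row_factory):
        design = StudyDesign((("s1", "c", 1),))
        mods = (Modification("sumo", 1, 30.0),)
        rows = [
            sumo_row(row_factory, protein="SUMO2", peptide="KVAGQDGSVV",
                     mods=mods, intensity=60.0, sample="s1", condition="c"),
            sumo_row(row_factory, protein="P0001", peptide="KAAAAAA",
                     mods=mods, intensity=30.0, sample="s1", condition="c"),
            sumo_row(row_factory, intensity=10.0, sample="s1", condition="c"),
        ]
        result = equilibrium_fractions(rows, design)
        fr = result.per_replicate[("c", 1)]
        assert fr["chain"] == pytest.approx(0.6)
        assert fr["other_target"] == pytest.approx(0.3)
        assert fr["free_mature"] == pytest.approx(0.1)
        assert sum(fr.values()) == pytest.approx(1.0, abs=1e-9)

    def test_internal_peptides_absent_from_denominator(self, row_factory):
        design = StudyDesign((("s1", "c", 1),))
        rows = [
            sumo_row(row_factory, intensity=10.0, sample="s1", condition="c"),
            sumo_row(row_factory, peptide="DGSVVQFKIK", intensity=1e9,
                     sample="s1", condition="c"),
        ]
        result = equilibrium_fractions(rows, design)
        assert result.per_replicate[("c", 1)]["free_mature"] == pytest.approx(1.0)

    def test_non_lysc_aspn_rows_ignored(self, row_factory):
        design = StudyDesign((("s1", "c", 1),))
        rows = [
            sumo_row(row_factory, intensity=10.0, sample="s1", condition="c"),
            sumo_row(row_factory, peptide="TIDVFQQQTGG", intensity=1e9,
                     protease="trypsin", sample="s1", condition="c"),
        ]
        result = equilibrium_fractions(rows, design)
        assert result.per_replicate[("c", 1)]["free_mature"] == pytest.approx(1.0)

    def test_scaling_invariance(self, row_factory):
        design = StudyDesign((("s1", "c", 1),))
        mods = (Modification("sumo", 1, 30.0),)
        base = [
            sumo_row(row_factory, protein="P0001", peptide="KAAAAAA",
                     mods=mods, intensity=30.0, sample="s1", condition="c"),
            sumo_row(row_factory, intensity=10.0, sample="s1", condition="c"),
        ]
        scaled = [
            r.__class__(**{**r.__dict__, "intensity": r.intensity * 7.5})
            for r in base
        ]
        a = equilibrium_fractions(base, design).per_replicate[("c", 1)]
        b = equilibrium_fractions(scaled, design).per_replicate[("c", 1)]
        assert a == pytest.approx(b)

    def test_zero_intensity_replicate_excluded(self, row_factory):
        design = StudyDesign((("s1", "c", 1), ("s2", "c", 2)))
        rows = [
            sumo_row(row_factory, intensity=10.0, sample="s1", condition="c"),
            sumo_row(row_factory, intensity=None, sample="s2", condition="c",
                     replicate=2),
        ]
        result = equilibrium_fractions(rows, design)
        assert ("c", 2) not in result.per_replicate

    def test_dual_free_totals_reported(self, row_factory):
        design = StudyDesign((("s1", "c", 1),))
        rows = [
            sumo_row(row_factory, intensity=90.0, sample="s1", condition="c"),
            sumo_row(row_factory, peptide="TIDVFQQQTGG", intensity=10.0,
                     sample="s1", condition="c"),
        ]
        result = equilibrium_fractions(rows, design)
        assert result.per_replicate[("c", 1)]["free_mature"] == pytest.approx(1.0)
        assert result.free_dvfqqqtgg_fraction[("c", 1)] == pytest.approx(0.9)


class TestChainTopology:
    def test_multiply_modified_peptide_counts_toward_each_site(self, row_factory):
        design = StudyDesign((("s1", "c", 1),))
        proteins = {"SUMO2": SUMO2_HUMAN}
        # KEGVK at SUMO2 positions 7-11: K7 and K11 both modified
        peptide = SUMO2_HUMAN[4:14]  # KPKEGVKTEN
        row = row_factory(
            peptide=peptide, protein="SUMO2",
            mods=(Modification("sumo", 3, 30.0), Modification("sumo", 7, 30.0)),
            intensity=100.0, sample="s1", condition="c",
        )
        profile = chain_topology([row], design, "SUMO2", proteins)
        fr = profile.per_replicate[("c", 1)]
        assert fr[7] == pytest.approx(0.5)
        assert fr[11] == pytest.approx(0.5)

    def test_single_replicate_fractions(self, row_factory):
        design = StudyDesign((("s1", "c", 1),))
        proteins = {"SUMO2": SUMO2_HUMAN}
        rows = [
            row_factory(peptide=SUMO2_HUMAN[4:14], protein="SUMO2",
                        mods=(Modification("sumo", 7, 30.0),), intensity=300.0,
                        sample="s1", condition="c", scans=(1,)),
            row_factory(peptide=SUMO2_HUMAN[15:25], protein="SUMO2",
                        mods=(Modification("sumo", 6, 30.0),), intensity=100.0,
                        sample="s1", condition="c", scans=(2,)),
        ]
        profile = chain_topology(rows, design, "SUMO2", proteins)
        fr = profile.per_replicate[("c", 1)]
        assert fr[11] == pytest.approx(0.75)
        assert fr[21] == pytest.approx(0.25)
        assert sum(fr.values()) == pytest.approx(1.0, abs=1e-9)

    def test_empty_profile_for_unseen_isoform(self, row_factory):
        design = StudyDesign((("s1", "c", 1),))
        proteins = {"SUMO1": "MSDQEAKPSTEDLGDKK"}
        profile = chain_topology([], design, "SUMO1", proteins)
        assert profile.per_replicate == {}


class TestOrganComparison:
    def _result(self, organ_values, n_organs=8, reps=5, seed=0):
        rng = np.random.default_rng(seed)
        per_rep = {}
        for o in range(n_organs):
            name = f"organ{o}"
            values = (
                organ_values if name == "organ0"
                else rng.normal(0.5, 0.01, size=reps)
            )
            for r, v in enumerate(values, start=1):
                per_rep[(name, r)] = {"chain": float(v)}
        return EquilibriumResult(
            per_replicate=per_rep, summary={}, error_type="sem"
        )

    def test_null_organ_not_significant(self):
        rng = np.random.default_rng(1)
        result = self._result(rng.normal(0.5, 0.01, size=5))
        t, p = compare_organ_fraction(result, "organ0", "chain")
        assert p > 0.05

    def test_shifted_organ_significant(self):
        result = self._result(np.full(5, 0.8))
        t, p = compare_organ_fraction(result, "organ0", "chain")
        assert p < 0.001
        assert t > 0

    def test_matches_textbook_two_sample_t(self):
        result = self._result(np.array([0.52, 0.54, 0.53, 0.55, 0.51]))
        t, p = compare_organ_fraction(result, "organ0", "chain")
        organ = result.condition_fractions("organ0", "chain")
        others = [f"organ{o}" for o in range(1, 8)]
        means = {o: result.condition_fractions(o, "chain").mean() for o in others}

        def z(c):
            rest = np.array([means[o] for o in others if o != c])
            return abs(means[c] - rest.mean()) / rest.std(ddof=1)

        drop = max(others, key=lambda c: (z(c), c))
        ref = np.concatenate(
            [result.condition_fractions(o, "chain") for o in others if o != drop]
        )
        t_ref, p_ref = stats.ttest_ind(organ, ref)
        assert t == pytest.approx(float(t_ref))
        assert p == pytest.approx(float(p_ref))

    def test_too_few_conditions_rejected(self):
        result = self._result(np.full(5, 0.5), n_organs=4)
        with pytest.raises(ValueError, match="8 conditions"):
            compare_organ_fraction(result, "organ0", "chain")


class TestParameterRecovery:
    def test_pool_and_chain_recovery(self):
        from sumosite.synthetic import (
            PROTEIN_NAMES, GeneratorConfig, generate_evidence, generate_proteome,
        )

        cfg = GeneratorConfig(seed=11, replicates=5)
        proteome = generate_proteome(cfg)
        rows, design, truth = generate_evidence(cfg, proteome)
        result = equilibrium_fractions(rows, design, protein_names=PROTEIN_NAMES)
        conjugated_truth = sum(
            truth.pool_fractions[k] for k in ("chain", "e1", "e2", "e3",
                                              "other_target")
        )
        for condition, summary in result.summary.items():
            conjugated = sum(
                summary[k][0] for k in ("chain", "e1", "e2", "e3", "other_target")
            )
            assert conjugated == pytest.approx(conjugated_truth, abs=0.02)
        profile = chain_topology(rows, design, "SUMO2", proteome[0])
        for condition, summary in profile.summary.items():
            for lysine, frac in truth.chain_profile["SUMO2"].items():
                assert summary[lysine][0] == pytest.approx(frac, abs=0.03)
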