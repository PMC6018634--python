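"""LFQ filters, normalization, imputation and permutation-FDR tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from sumosite.quantstats import (
    QuantMatrix,
    impute_downshift,
    median_normalize,
    perm_anova,
    perm_two_sample,
    quant_filter,
    rank_entities,
)
from sumosite.synthetic import (
    generate_null_matrix,
    generate_shifted_matrix,
    make_design,
)

DESIGN = make_design(("control", "heat"), 3)
DESIGN5 = make_design(("a", "b"), 5)


def matrix_from(values, columns, **kw):
    frame = pd.DataFrame(
        values, columns=columns,
        index=[f"e{i}" for i in range(len(values))],
    )
    return QuantMatrix(frame, log2_transformed=True, **kw)


class TestQuantFilter:
    def test_detection_rule(self):
        nan = float("nan")
        m = matrix_from(
            [
                [1, 1, 1, nan, nan, nan],  # 3/3 in control: kept
                [1, 1, nan, 1, 1, nan],  # 2/3 everywhere: dropped at 3
                [nan, nan, nan, 1, 1, 1],  # 3/3 in heat: kept
            ],
            DESIGN.sample_ids,
        )
        kept = quant_filter(m, DESIGN, min_detected=3)
        assert list(kept.values.index) == ["e0", "e2"]

    def test_protein_peptide_rule(self):
        m = matrix_from(
            [[1, 1, 1, 1, 1, 1], [1, 1, 1, 1, 1, 1]],
            DESIGN.sample_ids,
            peptide_counts={"e0": 1, "e1": 2},
        )
        kept = quant_filter(m, DESIGN, min_detected=3, min_peptides=2)
        assert list(kept.values.index) == ["e1"]

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        data = rng.normal(size=(50, 6))
        data[rng.random(size=data.shape) < 0.4] = np.nan
        m = matrix_from(data, DESIGN.sample_ids)
        once = quant_filter(m, DESIGN, min_detected=3)
        twice = quant_filter(once, DESIGN, min_detected=3)
        pd.testing.assert_frame_equal(once.values, twice.values)


class TestMedianNormalize:
    def test_equalizes_column_medians(self):
        rng = np.random.default_rng(1)
        m = matrix_from(rng.normal(20, 2, size=(200, 6)) +
                        rng.normal(0, 1, size=6), DESIGN.sample_ids)
        out = median_normalize(m)
        medians = out.values.median(axis=0)
        assert np.allclose(medians, medians.iloc[0])

    def test_identity_when_already_equal(self):
        m = matrix_from(
            np.array([[1, 2, 3, 1, 2, 3], [3, 2, 1, 3, 2, 1]], dtype=float),
            DESIGN.sample_ids,
        )
        out = median_normalize(m)
        pd.testing.assert_frame_equal(out.values, m.values)

    def test_idempotent(self):
        rng = np.random.default_rng(2)
        m = matrix_from(rng.normal(20, 2, size=(100, 6)), DESIGN.sample_ids)
        once = median_normalize(m)
        twice = median_normalize(once)
        pd.testing.assert_frame_equal(once.values, twice.values)

    def test_requires_log_scale(self):
        m = QuantMatrix(pd.DataFrame([[1.0]], columns=["s"]), False)
        with pytest.raises(ValueError):
            median_normalize(m)


class TestImputation:
    def _with_missing(self, seed=3, frac=0.2):
        rng = np.random.default_rng(seed)
        data = rng.normal(20, 1, size=(500, 6))
        data[rng.random(size=data.shape) < frac] = np.nan
        return matrix_from(data, DESIGN.sample_ids)

    def test_no_missing_is_identity(self):
        m = matrix_from(np.ones((3, 6)), DESIGN.sample_ids)
        out = impute_downshift(m, seed=0)
        pd.testing.assert_frame_equal(out.values, m.values)

    def test_deterministic_per_seed(self):
        m = self._with_missing()
        a = impute_downshift(m, seed=42)
        b = impute_downshift(m, seed=42)
        pd.testing.assert_frame_equal(a.values, b.values)
        c = impute_downshift(m, seed=43)
        assert not a.values.equals(c.values)

    def test_imputed_values_follow_downshifted_normal(self):
        m = self._with_missing(seed=4, frac=0.3)
        observed = m.values.to_numpy()
        mask = np.isnan(observed)
        mu = np.nanmean(observed)
        sd = np.nanstd(observed, ddof=1)
        out = impute_downshift(m, width=0.3, shift=1.8, seed=5)
        imputed = out.values.to_numpy()[mask]
        se = 0.3 * sd / np.sqrt(mask.sum())
        assert abs(imputed.mean() - (mu - 1.8 * sd)) < 3 * se
        assert not out.has_missing

    def test_all_missing_rejected(self):
        m = matrix_from(np.full((2, 6), np.nan), DESIGN.sample_ids)
        with pytest.raises(ValueError):
            impute_downshift(m)


class TestPermTwoSample:
    def test_null_data_yields_no_flags(self):
        frame = generate_null_matrix(300, DESIGN, seed=0)
        m = QuantMatrix(frame, True)
        res = perm_two_sample(
            m, DESIGN.samples_of("control"), DESIGN.samples_of("heat"),
            s0=1.0, fdr=0.05, seed=0,
        )
        assert len(res.significant) == 0

    def test_statistic_matches_pooled_t_at_zero_s0(self):
        frame = generate_null_matrix(40, DESIGN5, seed=1)
        m = QuantMatrix(frame, True)
        a = DESIGN5.samples_of("a")
        b = DESIGN5.samples_of("b")
        res = perm_two_sample(m, a, b, s0=0.0, seed=0)
        t_ref, _ = stats.ttest_ind(
            frame[a].to_numpy(), frame[b].to_numpy(), axis=1
        )
        assert np.allclose(res.table["statistic"].to_numpy(), t_ref)

    def test_group_relabel_flips_sign_keeps_q(self):
        frame = generate_null_matrix(100, DESIGN5, seed=2)
        m = QuantMatrix(frame, True)
        a, b = DESIGN5.samples_of("a"), DESIGN5.samples_of("b")
        r1 = perm_two_sample(m, a, b, s0=1.0, seed=3)
        r2 = perm_two_sample(m, b, a, s0=1.0, seed=3)
        assert np.allclose(r1.table["statistic"], -r2.table["statistic"])
        assert np.allclose(r1.table["q_value"], r2.table["q_value"])

    def test_shifted_entities_detected(self):
        # 5% of entities shifted by 4 sigma, 3 vs 3, aggregated over 20
        # generator seeds
        tp = fp = n_shift = n_flag = 0
        for seed in range(20):
            frame, shifted = generate_shifted_matrix(
                400, DESIGN, "heat", fraction_shifted=0.05, effect_sd=4.0,
                seed=seed,
            )
            res = perm_two_sample(
                QuantMatrix(frame, True),
                DESIGN.samples_of("heat"), DESIGN.samples_of("control"),
                s0=1.0, fdr=0.05, seed=0,
            )
            flagged, truth = set(res.significant), set(shifted)
            tp += len(flagged & truth)
            fp += len(flagged - truth)
            n_shift += len(truth)
            n_flag += len(flagged)
        assert tp / n_shift >= 0.9
        assert fp / max(n_flag, 1) <= 0.07

    def test_overlapping_groups_rejected(self):
        frame = generate_null_matrix(10, DESIGN, seed=0)
        m = QuantMatrix(frame, True)
        with pytest.raises(ValueError):
            perm_two_sample(m, ["control_r1"], ["control_r1", "heat_r1"])

    def test_missing_values_rejected(self):
        frame = generate_null_matrix(10, DESIGN, seed=0)
        frame.iloc[0, 0] = np.nan
        with pytest.raises(ValueError, match="missing"):
            perm_two_sample(
                QuantMatrix(frame, True),
                DESIGN.samples_of("control"), DESIGN.samples_of("heat"),
            )


class TestPermAnova:
    def test_single_condition_rejected(self):
        design1 = make_design(("only",), 3)
        frame = generate_null_matrix(10, design1, seed=0)
        with pytest.raises(ValueError):
            perm_anova(QuantMatrix(frame, True), design1)

    def test_null_yields_few_flags(self):
        design = make_design(("a", "b", "c"), 3)
        frame = generate_null_matrix(300, design, seed=5)
        res = perm_anova(QuantMatrix(frame, True), design, s0=1.0, fdr=0.05,
                         n_perm=200, seed=0)
        assert len(res.significant) <= 6  # ~2% of entities

    def test_two_condition_ranking_matches_two_sample(self):
        frame = generate_null_matrix(60, DESIGN, seed=6)
        m = QuantMatrix(frame, True)
        res_a = perm_anova(m, DESIGN, s0=0.0, n_perm=50, seed=0)
        res_t = perm_two_sample(
            m, DESIGN.samples_of("control"), DESIGN.samples_of("heat"),
            s0=0.0, n_perm=50, seed=0,
        )
        order_a = list(res_a.table["statistic"].abs().sort_values().index)
        order_t = list(res_t.table["statistic"].abs().sort_values().index)
        assert order_a == order_t

    def test_shifted_condition_enriched_among_flags(self):
        design = make_design(("a", "b", "c"), 3)
        frame, shifted = generate_shifted_matrix(
            300, design, "c", fraction_shifted=0.05, effect_sd=4.0, seed=7
        )
        res = perm_anova(QuantMatrix(frame, True), design, s0=0.5, fdr=0.05,
                         n_perm=300, seed=0)
        flagged = set(res.significant)
        assert len(flagged & set(shifted)) / len(shifted) >= 0.8


class TestRanking:
    def test_max_component_entity_ranks_first(self):
        comps = {
            "top": {"msms": 10.0, "score": 100.0},
            "mid": {"msms": 5.0, "score": 50.0},
            "low": {"msms": 0.0, "score": 0.0},
        }
        ranks = rank_entities(comps)
        assert [r.entity_id for r in ranks] == ["top", "mid", "low"]
        assert ranks[0].score == pytest.approx(1.0)

    def test_ties_broken_by_id(self):
        comps = {"b": {"x": 1.0}, "a": {"x": 1.0}}
        ranks = rank_entities(comps)
        assert [r.entity_id for r in ranks] == ["a", "b"]

    def test_hand_computed_normalized_means(self):
        comps = {
            "e1": {"x": 0.0, "y": 10.0},
            "e2": {"x": 5.0, "y": 0.0},
            "e3": {"x": 10.0, "y": 5.0},
        }
        ranks = {r.entity_id: r.score for r in rank_entities(comps)}
        assert ranks["e1"] == pytest.approx(0.5)
        assert ranks["e2"] == pytest.approx(0.25)
        assert ranks["e3"] == pytest.approx(0.75)

    def test_empty_input(self):
        assert rank_entities({}) == []
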