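"""SAHR panel selection, delta coefficients, scoring, transfer, stratification."""

import logging

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sahr import (
    SAHREntry,
    SAHRModel,
    SAHRScorer,
    ValidationError,
    assign_delta,
    score_matrix,
    score_sample,
    stratify,
    train_sahr,
    transfer_model,
)


def _catalog_frame(rows):
    return pd.DataFrame(
        rows,
        columns=["gene_id", "direction", "cutoff", "hr", "cox_p", "category",
                 "zero_rule_applied", "unsplittable", "flagged"],
    )


def _row(gene, cat, p, hr=2.0, cutoff=1.0, flagged=False):
    direction = "up" if cat in ("oncogene_like", "up_regulated_saver") else "down"
    return (gene, direction, cutoff, hr, p, cat, False, False, flagged)


class TestTrainSAHR:
    def test_top_twenty_by_p_selected(self):
        rows = [_row(f"G{i:02d}", "oncogene_like", p=0.001 * (i + 1)) for i in range(25)]
        model = train_sahr(_catalog_frame(rows))
        assert len(model) == 20
        assert model.gene_ids == [f"G{i:02d}" for i in range(20)]

    def test_hr_above_cap_excluded_regardless_of_p(self):
        rows = [_row("GBAD", "oncogene_like", p=1e-10, hr=25.0)]
        rows += [_row(f"G{i:02d}", "oncogene_like", p=0.01) for i in range(5)]
        model = train_sahr(_catalog_frame(rows))
        assert "GBAD" not in model.gene_ids
        assert len(model) == 5

    def test_flagged_fits_excluded(self):
        rows = [_row("GFLAG", "oncogene_like", p=1e-10, hr=19.0, flagged=True)]
        rows += [_row("GOK", "oncogene_like", p=0.01)]
        model = train_sahr(_catalog_frame(rows))
        assert model.gene_ids == ["GOK"]

    def test_scarce_category_keeps_all_with_warning(self, caplog):
        rows = [_row(f"S{i}", "suppressor_like", p=0.01) for i in range(5)]
        with caplog.at_level(logging.WARNING, logger="sahr"):
            model = train_sahr(_catalog_frame(rows))
        assert len(model) == 5
        assert any("5/20 suppressor_like" in r.message for r in caplog.records)

    def test_p_ties_broken_by_larger_hr_then_gene_id(self):
        rows = [
            _row("GB", "oncogene_like", p=0.01, hr=3.0),
            _row("GA", "oncogene_like", p=0.01, hr=2.0),
            _row("GC", "oncogene_like", p=0.01, hr=3.0),
        ]
        model = train_sahr(_catalog_frame(rows), limits=(2, 20, 10, 10))
        assert model.gene_ids == ["GB", "GC"]

    def test_uncategorized_genes_never_selected(self):
        rows = [("GN", "up", 1.0, 2.0, 1e-9, "none", False, False, False)]
        model = train_sahr(_catalog_frame(rows))
        assert len(model) == 0  # "none" rows carry no category slot
        with pytest.raises(ValidationError, match="empty model"):
            score_matrix(pd.DataFrame({"S1": [1.0]}, index=["GN"]), model)

    def test_empty_catalog_rejected(self):
        with pytest.raises(ValidationError, match="empty catalog"):
            train_sahr(_catalog_frame([]))


class TestAssignDelta:
    @pytest.mark.parametrize(
        "category,above,expected",
        [
            ("oncogene_like", True, 1),
            ("oncogene_like", False, -1),
            ("down_regulated_saver", True, 1),
            ("down_regulated_saver", False, -1),
            ("up_regulated_saver", True, -1),
            ("up_regulated_saver", False, 1),
            ("suppressor_like", True, -1),
            ("suppressor_like", False, 1),
        ],
    )
    def test_coefficient_table(self, category, above, expected):
        entry = SAHREntry("G", category, cutoff=5.0, hr=2.0)
        value = 6.0 if above else 4.0
        assert assign_delta(value, entry) == expected

    def test_value_equal_to_cutoff_counts_as_lower(self):
        entry = SAHREntry("G", "oncogene_like", cutoff=5.0, hr=2.0)
        assert assign_delta(5.0, entry) == -1


class TestScoring:
    def _model3(self):
        return SAHRModel(
            "demo",
            [
                SAHREntry("GA", "oncogene_like", 1.0, 2.0),
                SAHREntry("GB", "up_regulated_saver", 1.0, 1.5),
                SAHREntry("GC", "oncogene_like", 1.0, 3.0),
            ],
        )

    def test_stated_formula_arithmetic(self):
        # deltas (+1, -1, +1) on hr (2, 1.5, 3) -> 3.5
        values = pd.Series({"GA": 2.0, "GB": 2.0, "GC": 2.0})
        s = score_sample(values, self._model3())
        assert s.deltas == (1, -1, 1)
        assert s.score == pytest.approx(3.5)
        assert s.group == "positive"

    def test_all_unit_hr_above_cutoffs_scores_n(self):
        entries = [SAHREntry(f"G{i}", "oncogene_like", 0.5, 1.0) for i in range(7)]
        model = SAHRModel("demo", entries, {})
        values = pd.Series({f"G{i}": 1.0 for i in range(7)})
        assert score_sample(values, model).score == pytest.approx(7.0)

    def test_negated_deltas_negate_score(self):
        model = self._model3()
        above = pd.Series({"GA": 2.0, "GB": 0.5, "GC": 2.0})
        below = pd.Series({"GA": 0.5, "GB": 2.0, "GC": 0.5})
        assert score_sample(above, model).score == pytest.approx(
            -score_sample(below, model).score
        )

    def test_score_bounded_by_sum_of_hrs(self):
        model = self._model3()
        rng = np.random.default_rng(0)
        bound = sum(e.hr for e in model.entries)
        for _ in range(20):
            values = pd.Series(rng.uniform(0, 2, 3), index=["GA", "GB", "GC"])
            assert abs(score_sample(values, model).score) <= bound + 1e-12

    def test_missing_gene_directs_to_transfer(self):
        with pytest.raises(ValidationError, match="transfer_model"):
            score_sample(pd.Series({"GA": 1.0}), self._model3())

    def test_empty_model_refused(self):
        with pytest.raises(ValidationError, match="empty model"):
            score_sample(pd.Series({"GA": 1.0}), SAHRModel("x", []))

    def test_score_matrix_matches_per_sample_scoring(self):
        model = self._model3()
        rng = np.random.default_rng(1)
        mat = pd.DataFrame(
            rng.uniform(0, 2, (3, 5)), index=["GA", "GB", "GC"],
            columns=[f"S{i}" for i in range(5)],
        )
        frame = score_matrix(mat, model)
        for sid in mat.columns:
            assert frame.loc[sid, "score"] == pytest.approx(
                score_sample(mat[sid], model, sid).score
            )


class TestTransfer:
    def _model(self):
        return SAHRModel(
            "train",
            [
                SAHREntry("GA", "oncogene_like", 10.0, 2.0),
                SAHREntry("GB", "suppressor_like", 20.0, 4.0),
                SAHREntry("GC", "up_regulated_saver", 30.0, 1.5),
            ],
        )

    def test_intersection_with_reanchored_cutoffs(self):
        rng = np.random.default_rng(2)
        target = pd.DataFrame(
            rng.uniform(0, 100, (2, 9)), index=["GA", "GB"],
            columns=[f"S{i}" for i in range(9)],
        )
        out = transfer_model(self._model(), target)
        assert out.gene_ids == ["GA", "GB"]
        np.testing.assert_allclose(
            [e.cutoff for e in out.entries],
            [np.median(target.loc["GA"]), np.median(target.loc["GB"])],
        )
        assert [e.hr for e in out.entries] == [2.0, 4.0]
        assert out.provenance["intersection_size"] == 2

    def test_small_intersection_warns(self, caplog):
        rng = np.random.default_rng(5)
        target = pd.DataFrame(
            rng.uniform(0, 100, (1, 9)), index=["GA"],
            columns=[f"S{i}" for i in range(9)],
        )
        with caplog.at_level(logging.WARNING, logger="sahr"):
            out = transfer_model(self._model(), target)
        assert out.gene_ids == ["GA"]
        assert any("1/3 model genes" in r.message for r in caplog.records)

    def test_empty_intersection_rejected(self):
        target = pd.DataFrame(np.ones((1, 4)), index=["GZ"], columns=list("abcd"))
        with pytest.raises(ValidationError, match="no model gene"):
            transfer_model(self._model(), target)

    def test_scaling_target_tenfold_preserves_scores(self):
        rng = np.random.default_rng(3)
        target = pd.DataFrame(
            rng.uniform(0, 100, (3, 11)), index=["GA", "GB", "GC"],
            columns=[f"S{i}" for i in range(11)],
        )
        m1 = transfer_model(self._model(), target)
        m2 = transfer_model(self._model(), target * 10.0)
        s1 = score_matrix(target, m1)
        s2 = score_matrix(target * 10.0, m2)
        pd.testing.assert_series_equal(s1["score"], s2["score"])

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        seed=st.integers(0, 10_000),
        scale=st.floats(min_value=0.01, max_value=100, allow_nan=False),
        shift=st.floats(min_value=0, max_value=50, allow_nan=False),
        power=st.sampled_from([1.0, 3.0]),
    )
    def test_monotone_transform_invariance(self, seed, scale, shift, power):
        # any strictly increasing per-gene transform leaves deltas and scores
        # unchanged after transfer (medians and comparisons are rank-based)
        rng = np.random.default_rng(seed)
        genes = ["GA", "GB", "GC"]
        target = pd.DataFrame(
            rng.uniform(0.1, 10, (3, 8)), index=genes,
            columns=[f"S{i}" for i in range(8)],
        )
        transformed = (target**power) * scale + shift
        base = score_matrix(target, transfer_model(self._model(), target))
        tran = score_matrix(transformed, transfer_model(self._model(), transformed))
        pd.testing.assert_series_equal(base["score"], tran["score"])

    def test_fixed_point_on_training_cohort(self):
        # transferring onto the cohort that produced the cutoffs reproduces
        # them when cutoffs are plain medians
        rng = np.random.default_rng(4)
        genes = ["GA", "GB", "GC"]
        cohort = pd.DataFrame(
            rng.uniform(0, 100, (3, 15)), index=genes,
            columns=[f"S{i}" for i in range(15)],
        )
        entries = [
            SAHREntry(g, "oncogene_like", float(np.median(cohort.loc[g])), 2.0)
            for g in genes
        ]
        model = SAHRModel("train", entries)
        out = transfer_model(model, cohort)
        np.testing.assert_allclose(
            [e.cutoff for e in out.entries], [e.cutoff for e in entries]
        )


class TestStratify:
    def test_sign_rule(self):
        scores = pd.DataFrame(
            {"score": [-3.2, 0.5], "group": ["negative", "positive"]},
            index=["S1", "S2"],
        )
        pos, neg = stratify(scores)
        assert list(pos) == ["S2"] and list(neg) == ["S1"]

    def test_exact_zero_goes_negative(self):
        scores = pd.DataFrame({"score": [0.0, 1.0]}, index=["S1", "S2"])
        pos, neg = stratify(scores)
        assert "S1" in neg

    def test_degenerate_split_logged(self, caplog):
        scores = pd.DataFrame({"score": [1.0, 2.0]}, index=["S1", "S2"])
        with caplog.at_level(logging.WARNING, logger="sahr"):
            pos, neg = stratify(scores)
        assert len(neg) == 0
        assert any("degenerate" in r.message for r in caplog.records)


class TestSAHRScorerEstimator:
    @pytest.fixture()
    def fitted(self, small_cohort):
        expr, clinical, truth, deg = small_cohort
        tumors = clinical.tumors()
        train_ids = tumors.index[tumors["split"] == "train"]
        X = expr.normalized[train_ids].T
        y = clinical.survival_frame(train_ids)
        directions = deg.set_index("gene_id")["direction"]
        directions = directions[directions.isin(["up", "down"])]
        est = SAHRScorer().fit(X, y, directions=directions)
        return est, expr, clinical

    def test_fit_produces_catalog_and_model(self, fitted):
        est, _, _ = fitted
        assert hasattr(est, "catalog_") and hasattr(est, "model_")
        assert len(est.model_) > 0

    def test_decision_function_matches_score_matrix(self, fitted):
        est, expr, clinical = fitted
        tumors = clinical.tumors()
        test_ids = tumors.index[tumors["split"] == "test"]
        X = expr.normalized[test_ids].T
        np.testing.assert_allclose(
            est.decision_function(X),
            score_matrix(X.T, est.model_)["score"].to_numpy(),
        )
        preds = est.predict(X)
        assert set(preds) <= {-1, 1}

    def test_transfer_returns_fitted_estimator(self, fitted):
        est, expr, clinical = fitted
        tumors = clinical.tumors()
        test_ids = tumors.index[tumors["split"] == "test"]
        X = expr.normalized[test_ids].T
        moved = est.transfer(X * 100.0)
        np.testing.assert_array_equal(
            moved.predict(X * 100.0), est.transfer(X).predict(X)
        )

    def test_sklearn_param_interface(self):
        est = SAHRScorer(hr_cap=15.0)
        params = est.get_params()
        assert params["hr_cap"] == 15.0
        est.set_params(alpha=0.01)
        assert est.alpha == 0.01

    def test_unfitted_rejects_prediction(self):
        with pytest.raises(ValidationError, match="not fitted"):
            SAHRScorer().decision_function(pd.DataFrame({"G": [1.0]}))
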