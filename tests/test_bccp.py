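"""Harmonization, the compound covariate model, LOOCV and trichotomization."""

import numpy as np
import pandas as pd
import pytest

from gmsubtype import (
    BCCP,
    BCCPResults,
    DataError,
    ExpressionMatrix,
    GeneSignature,
    MouseSimConfig,
    OrthologMap,
    SampleLabels,
    harmonize,
    loocv,
    predict_cohort,
    simulate_mouse,
    trichotomize,
    zscore_genes,
)
from oracles import bayes_posterior_oracle


def _sig(genes, weights):
    return GeneSignature(pd.DataFrame({"gene_id": genes, "weight": weights}))


def _results(weights, mu_h, s_h, mu_c, s_c, priors=(0.5, 0.5)):
    return BCCPResults(None, pd.Series(weights), mu_h, s_h, mu_c, s_c, priors)


class TestZScore:
    def test_row_123_standardizes_to_unit_steps(self):
        em = ExpressionMatrix([[1.0, 2.0, 3.0]], ["g"], ["a", "b", "c"])
        z = zscore_genes(em)
        np.testing.assert_allclose(z.values[0], [-1.0, 0.0, 1.0])

    def test_affine_transform_invariance(self, rng):
        x = rng.normal(size=(20, 8))
        em = ExpressionMatrix(x, [f"g{i}" for i in range(20)], [f"s{j}" for j in range(8)])
        em2 = ExpressionMatrix(2.5 * x + 7.0, em.gene_ids, em.sample_ids)
        np.testing.assert_allclose(zscore_genes(em).values, zscore_genes(em2).values,
                                   atol=1e-10)

    def test_rows_have_mean0_sd1(self, rng):
        x = rng.normal(size=(30, 10))
        z = zscore_genes(ExpressionMatrix(x, [f"g{i}" for i in range(30)],
                                          [f"s{j}" for j in range(10)]))
        assert np.abs(z.values.mean(axis=1)).max() < 1e-8
        assert np.abs(z.values.std(axis=1, ddof=1) - 1).max() < 1e-8

    def test_zero_sd_rows_dropped(self):
        em = ExpressionMatrix([[1.0, 1.0, 1.0], [1.0, 2.0, 3.0]], ["flat", "ok"],
                              ["a", "b", "c"])
        z = zscore_genes(em)
        assert z.gene_ids == ["ok"]

    def test_fewer_than_three_samples_rejected(self):
        em = ExpressionMatrix([[1.0, 2.0]], ["g"], ["a", "b"])
        with pytest.raises(DataError, match="3 samples"):
            zscore_genes(em)


class TestHarmonize:
    def _matrices(self):
        a = ExpressionMatrix(np.arange(12.0).reshape(3, 4), ["Ma", "Mb", "Mc"],
                             [f"m{i}" for i in range(4)])
        b = ExpressionMatrix(np.arange(12.0).reshape(3, 4)[::-1] ** 2,
                             ["HA", "HB", "HD"], [f"h{i}" for i in range(4)])
        return a, b

    def test_rows_restricted_renamed_and_standardized(self):
        a, b = self._matrices()
        omap = OrthologMap(pd.DataFrame({"a": ["Ma", "Mb", "Mc"], "b": ["HA", "HB", "HC"]}))
        pair = harmonize(a, b, omap)
        assert pair.a.gene_ids == pair.b.gene_ids == ["Ma", "Mb"]
        for m in (pair.a, pair.b):
            assert np.abs(m.values.mean(axis=1)).max() < 1e-8
            assert np.abs(m.values.std(axis=1, ddof=1) - 1).max() < 1e-8

    def test_one_to_many_ortholog_excluded(self):
        a, b = self._matrices()
        omap = OrthologMap(
            pd.DataFrame({"a": ["Ma", "Ma", "Mb"], "b": ["HA", "HB", "HD"]})
        )
        pair = harmonize(a, b, omap)
        assert pair.a.gene_ids == ["Mb"]

    def test_low_signature_coverage_rejected(self):
        a, b = self._matrices()
        omap = OrthologMap(pd.DataFrame({"a": ["Ma"], "b": ["HA"]}))
        sig = _sig(["Ma", "Mb", "Mc"], [1.0, 1.0, 1.0])
        with pytest.raises(DataError, match="coverage"):
            harmonize(a, b, omap, signature=sig, min_coverage=0.7)

    def test_empty_map_rejected(self):
        a, b = self._matrices()
        with pytest.raises(DataError, match="empty"):
            harmonize(a, b, OrthologMap(pd.DataFrame({"a": [], "b": []})))


class TestCompoundCovariate:
    def test_single_gene_single_sample(self):
        res = _results({"g": 2.0}, 1, 1, -1, 1)
        z = ExpressionMatrix([[1.5, 0.0, -1.5]], ["g"], ["a", "b", "c"])
        c = res.compound_covariate(z)
        assert c["a"] == pytest.approx(3.0)

    def test_missing_genes_renormalized(self):
        res = _results({"g1": 2.0, "g2": 1.0, "g3": 1.0}, 0, 1, 0, 1)
        # only g1, g2 present: raw sum 2*1+1*1 = 3, scale = 4/3
        z = ExpressionMatrix([[1.0], [1.0]], ["g1", "g2"], ["a"])
        c = res.compound_covariate(z, min_coverage=0.5)
        assert c["a"] == pytest.approx(3.0 * 4.0 / 3.0)

    def test_all_signature_genes_missing_rejected(self):
        res = _results({"g1": 2.0}, 0, 1, 0, 1)
        z = ExpressionMatrix([[1.0]], ["other"], ["a"])
        with pytest.raises(DataError):
            res.compound_covariate(z)


class TestPosterior:
    def test_equidistant_score_with_equal_sds_gives_half(self):
        res = _results({"g": 1.0}, 2.0, 1.5, -2.0, 1.5)
        assert res.posterior_from_score(0.0)[0] == pytest.approx(0.5, abs=1e-14)

    def test_extreme_score_saturates_to_one(self):
        res = _results({"g": 1.0}, 2.0, 1.0, -2.0, 1.0)
        assert res.posterior_from_score(50.0)[0] == pytest.approx(1.0, abs=1e-12)
        assert res.posterior_from_score(-50.0)[0] == pytest.approx(0.0, abs=1e-12)

    def test_oracle_equivalence_on_random_models(self, rng):
        """100 random models x 100 scores match the direct Bayes-rule oracle to 1e-12."""
        for _ in range(100):
            mu_c = rng.normal(0, 3)
            mu_h = mu_c + rng.uniform(0.5, 5)
            s_h, s_c = rng.uniform(0.3, 3, size=2)
            pi_h = rng.uniform(0.2, 0.8)
            res = _results({"g": 1.0}, mu_h, s_h, mu_c, s_c, (pi_h, 1 - pi_h))
            cs = rng.normal((mu_h + mu_c) / 2, 3 * max(s_h, s_c), size=100)
            got = res.posterior_from_score(cs)
            for ci, gi in zip(cs, got):
                ref = bayes_posterior_oracle(ci, mu_h, s_h, mu_c, s_c, pi_h, 1 - pi_h)
                assert gi == pytest.approx(ref, abs=1e-12)

    def test_monotone_in_score_with_equal_sds(self):
        res = _results({"g": 1.0}, 1.0, 1.2, -1.0, 1.2)
        cs = np.linspace(-10, 10, 201)
        p = res.posterior_from_score(cs)
        assert (np.diff(p) >= -1e-15).all()


class TestFit:
    def test_separated_classes_recovered(self, mouse_default, fitted_model):
        expr, labels, _ = mouse_default
        res = fitted_model
        assert res.mu_high > res.mu_control
        post = pd.Series(
            res.posterior_from_score(res.train_scores.to_numpy()),
            index=res.train_scores.index,
        )
        treated = labels.labels == "treated"
        assert (post[treated] > 0.99).all()
        assert (post[~treated] < 0.01).all()

    def test_flipped_weights_invert_direction_and_warn(self, mouse_default,
                                                       mouse_signature, caplog):
        import logging

        expr, labels, _ = mouse_default
        sig, _ = mouse_signature
        flipped = GeneSignature(
            pd.DataFrame({"gene_id": sig.gene_ids, "weight": -sig.weights.values})
        )
        with caplog.at_level(logging.WARNING, logger="gmsubtype.bccp"):
            res = BCCP(zscore_genes(expr), labels, flipped, weight_mode="signature").fit()
        assert res.mu_high < res.mu_control
        assert any("direction sanity" in r.message for r in caplog.records)

    def test_scale_equivariance_of_posteriors(self, mouse_default, mouse_signature):
        expr, labels, _ = mouse_default
        sig, _ = mouse_signature
        z = zscore_genes(expr)
        res1 = BCCP(z, labels, sig, weight_mode="signature").fit()
        scaled = GeneSignature(
            pd.DataFrame({"gene_id": sig.gene_ids, "weight": 7.0 * sig.weights.values})
        )
        res2 = BCCP(z, labels, scaled, weight_mode="signature").fit()
        np.testing.assert_allclose(
            res1.posterior_from_score(res1.train_scores.to_numpy()),
            res2.posterior_from_score(res2.train_scores.to_numpy()),
            atol=1e-10,
        )

    def test_model_json_round_trip(self, fitted_model, tmp_path):
        path = tmp_path / "model.json"
        fitted_model.to_json(path)
        back = BCCPResults.from_json(path)
        pd.testing.assert_series_equal(back.weights, fitted_model.weights,
                                       check_names=False)
        assert back.mu_high == fitted_model.mu_high
        assert back.priors == fitted_model.priors
        c = np.linspace(-50, 250, 7)
        np.testing.assert_array_equal(back.posterior_from_score(c),
                                      fitted_model.posterior_from_score(c))

    def test_empty_signature_rejected(self, mouse_default):
        expr, labels, _ = mouse_default
        empty = GeneSignature(pd.DataFrame(columns=["gene_id", "weight"]))
        with pytest.raises(DataError, match="empty"):
            BCCP(zscore_genes(expr), labels, empty)

    def test_class_with_one_sample_rejected_by_default(self):
        z = ExpressionMatrix(np.random.default_rng(0).normal(size=(3, 5)),
                             ["a", "b", "c"], [f"s{i}" for i in range(5)])
        labels = SampleLabels(
            pd.Series(["treated", "control", "control", "control", "control"],
                      index=z.sample_ids),
            min_per_class=1,
        )
        with pytest.raises(DataError, match=">=2"):
            BCCP(z, labels, _sig(["a"], [1.0])).fit()


class TestTrichotomize:
    def test_printed_cutoff_rule(self):
        calls = trichotomize(pd.Series({"a": 0.9, "b": 0.5, "c": 0.1}))
        assert list(calls.table["subtype"]) == ["high", "middle", "low"]

    @pytest.mark.parametrize("p,expected", [(0.8, "middle"), (0.2, "middle"),
                                            (0.80001, "high"), (0.19999, "low")])
    def test_boundaries_fall_in_middle(self, p, expected):
        calls = trichotomize(pd.Series({"s": p}))
        assert calls.table.loc["s", "subtype"] == expected

    def test_all_half_is_all_middle(self):
        calls = trichotomize(pd.Series(0.5, index=list("abc")))
        assert (calls.table["subtype"] == "middle").all()

    def test_partition_property(self, rng):
        p = pd.Series(rng.uniform(size=500), index=[f"s{i}" for i in range(500)])
        calls = trichotomize(p)
        assert calls.counts().sum() == 500
        assert len(calls.table) == 500

    def test_invalid_probability_rejected(self):
        with pytest.raises(DataError):
            trichotomize(pd.Series({"a": 1.5}))

    def test_invalid_cutoffs_rejected(self):
        with pytest.raises(DataError):
            trichotomize(pd.Series({"a": 0.5}), lo=0.8, hi=0.2)


class TestLOOCV:
    def test_perfect_separation_gives_perfect_cv(self, mouse_default):
        expr, labels, _ = mouse_default
        cv = loocv(expr, labels)
        assert cv.sensitivity == 1.0
        assert cv.specificity == 1.0
        assert cv.misclassified == []

    def test_permuted_labels_give_chance_performance(self):
        """Label permutation destroys the signal: sens+spec averages ~1."""
        cfg = MouseSimConfig(seed=2, n_genes=800, n_fructose_up=80, n_glucose_up=80)
        expr, labels, _ = simulate_mouse(cfg)
        rng = np.random.default_rng(5)
        sums = []
        for _ in range(30):
            perm = rng.permutation(expr.sample_ids)
            plabels = type(labels)(
                labels=pd.Series(labels.labels.values, index=perm),
                groups=pd.Series(labels.groups.values, index=perm),
            )
            cv = loocv(expr, plabels)
            sums.append(cv.sensitivity + cv.specificity)
        assert abs(np.mean(sums) - 1.0) < 0.15

    def test_minimal_two_per_class_contract(self, rng):
        z = rng.normal(size=(6, 4))
        z[0, :2] += 4  # one informative gene
        expr = ExpressionMatrix(z, [f"g{i}" for i in range(6)],
                                ["t1", "t2", "c1", "c2"])
        labels = SampleLabels(pd.Series(["treated", "treated", "control", "control"],
                                        index=expr.sample_ids))
        cv = loocv(expr, labels, fixed_signature=_sig(["g0"], [3.0]))
        assert 0.0 <= cv.sensitivity <= 1.0
        assert 0.0 <= cv.specificity <= 1.0
        assert cv.posteriors.between(0, 1).all()


class TestPredictCohort:
    def test_self_prediction_recalls_training_classes(self, mouse_default, fitted_model):
        expr, labels, _ = mouse_default
        calls = predict_cohort(fitted_model, expr)
        post = calls.table["posterior_high"]
        assert (post[labels.labels == "treated"] > 0.5).all()
        assert (post[labels.labels == "control"] < 0.5).all()

    def test_two_sample_cohort_cleanly_rejected(self, mouse_default, fitted_model):
        expr, _, _ = mouse_default
        tiny = expr.subset_samples(expr.sample_ids[:2])
        with pytest.raises(DataError):
            predict_cohort(fitted_model, tiny)

    def test_cohort_calls_through_ortholog_bridge(self, mouse_default, fitted_model,
                                                  ortholog_map_default, cohort_default):
        expr, _, truth = mouse_default
        cexpr, _, ctruth = cohort_default
        calls = predict_cohort(fitted_model, cexpr, ortholog_map=ortholog_map_default,
                               train_expr=expr)
        sub = calls.table["subtype"]
        tc = ctruth.true_class.reindex(sub.index)
        assert (sub[tc == "high"].isin(["high", "middle"])).mean() >= 0.95
        assert (sub[tc == "low"].isin(["low", "middle"])).mean() >= 0.95
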