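import numpy as np
import pandas as pd
import pytest

from melanomorph import classifier as clf


def gaussian_classes(rng, n_per=60, sep=4.0):
    """Well-separated 4-class summaries fixture."""
    centers = {
        "black": (1.0, 0.28, 3.6),
        "brown": (0.7 + sep * 0.05, 0.38, 1.9),
        "grey": (0.8, 0.5 + sep * 0.04, 1.6),
        "iridescent": (1.0 + sep * 0.08, 0.3, 4.4),
    }
    rows = []
    for cat, (l, w, ar) in centers.items():
        for i in range(n_per):
            rows.append(
                dict(
                    sample_id=f"{cat}{i}",
                    color_category=cat,
                    mean_length_um=rng.normal(l, 0.04),
                    mean_width_um=rng.normal(w, 0.02),
                    aspect_ratio=rng.normal(ar, 0.15),
                    flatness=cat == "iridescent" and i % 2 == 0,
                    hollowness=cat == "iridescent" and i % 3 == 0,
                )
            )
    return pd.DataFrame(rows)


class TestFit:
    def test_qda_separable_training_accuracy(self, rng):
        df = gaussian_classes(rng)
        model = clf.fit(df, "qda")
        acc = np.mean(model.predict(df) == df["color_category"].to_numpy())
        assert acc >= 0.99

    def test_qda_priors_are_class_frequencies(self, rng):
        df = gaussian_classes(rng)
        model = clf.fit(df, "qda")
        assert model.priors.sum() == pytest.approx(1.0)
        np.testing.assert_allclose(model.priors, 0.25)

    def test_qda_rejects_qualitative_variables(self, rng):
        with pytest.raises(ValueError, match="flatness"):
            clf.fit(gaussian_classes(rng), "qda",
                    ["length", "flatness"])

    def test_qda_posteriors_match_sklearn(self, rng):
        """Cross-check our closed-form QDA against scikit-learn's."""
        from sklearn.discriminant_analysis import QuadraticDiscriminantAnalysis

        df = gaussian_classes(rng)
        model = clf.fit(df, "qda")
        X = clf.design_matrix(df, model.variables)
        sk = QuadraticDiscriminantAnalysis(store_covariance=True)
        sk.fit(X, df["color_category"])
        ours = model.predict_proba(df).to_numpy()
        theirs = sk.predict_proba(X)[:, [list(sk.classes_).index(c)
                                         for c in model.classes]]
        np.testing.assert_allclose(ours, theirs, atol=1e-6)

    def test_mlr_posterior_monotone_in_single_feature(self, rng):
        n = 100
        x = np.linspace(0.2, 2.0, n)
        df = pd.DataFrame(
            dict(
                mean_length_um=x,
                mean_width_um=0.3,
                aspect_ratio=2.0,
                flatness=False,
                hollowness=False,
                color_category=np.where(x > 1.0, "black", "brown"),
            )
        )
        model = clf.fit(df, "mlr", ["length"])
        post = model.predict_proba(df)["black"].to_numpy()
        assert (np.diff(post) >= -1e-9).all()

    def test_mlr_posteriors_sum_to_one(self, rng):
        df = gaussian_classes(rng)
        model = clf.fit(df, "mlr")
        np.testing.assert_allclose(
            model.predict_proba(df).sum(axis=1), 1.0, atol=1e-12
        )

    def test_json_round_trip(self, rng, tmp_path):
        df = gaussian_classes(rng)
        for kind in ("qda", "mlr"):
            model = clf.fit(df, kind)
            path = tmp_path / f"{kind}.json"
            model.to_json(path)
            back = clf.ColorClassifier.from_json(path)
            np.testing.assert_allclose(
                back.predict_proba(df).to_numpy(),
                model.predict_proba(df).to_numpy(),
                atol=1e-12,
            )


class TestSelectVariables:
    def test_mlr_enumerates_31_models(self, rng):
        df = gaussian_classes(rng)
        ranked = clf.select_variables(df, "mlr")
        assert len(ranked) == 31

    def test_qda_skips_qualitative_with_note(self, rng):
        df = gaussian_classes(rng)
        ranked = clf.select_variables(df, "qda")
        assert len(ranked) == 7  # 2^3 - 1 quantitative subsets
        assert ranked["note"].str.contains("skipped").all()

    def test_single_informative_feature_ranked_top(self, rng):
        n = 80
        df = pd.DataFrame(
            dict(
                mean_length_um=np.r_[rng.normal(0.6, 0.03, n),
                                     rng.normal(1.6, 0.03, n)],
                mean_width_um=rng.normal(0.4, 0.05, 2 * n),
                aspect_ratio=rng.normal(3.0, 0.3, 2 * n),
                flatness=False,
                hollowness=False,
                color_category=["brown"] * n + ["black"] * n,
            )
        )
        ranked = clf.select_variables(df, "mlr",
                                      ("length", "diameter", "aspect_ratio"))
        assert "length" in ranked.iloc[0]["variables"]


class TestCrossValidation:
    def test_kappa_matches_arithmetic_oracle(self):
        cm = np.array([[40, 10], [10, 40]])
        # direct formula: p_o = 0.8, p_e = 0.5
        assert clf.cohens_kappa(cm) == pytest.approx(0.6)

    def test_separable_data_near_perfect(self, rng):
        df = gaussian_classes(rng)
        res = clf.cross_validate(df, "qda", k=5, repeats=2, seed=0)
        assert res.accuracy >= 0.97
        assert res.kappa >= 0.95
        assert res.exact_p < 1e-10

    def test_shuffled_labels_kappa_near_zero(self, rng):
        df = gaussian_classes(rng)
        df = df.assign(
            color_category=rng.permutation(df["color_category"].to_numpy())
        )
        res = clf.cross_validate(df, "mlr", k=5, repeats=2, seed=1)
        assert abs(res.kappa) < 0.12
        assert res.exact_p > 0.01

    def test_small_class_shrinks_folds_with_warning(self, rng):
        df = gaussian_classes(rng, n_per=6)
        with pytest.warns(UserWarning, match="reducing folds"):
            res = clf.cross_validate(df, "qda", ["length"], k=10, repeats=1, seed=0)
        assert res.k == 6


class TestDecayAndFossils:
    def test_zero_fraction_zero_decay(self, rng):
        df = gaussian_classes(rng)
        model = clf.fit(df, "qda")
        decay, table = clf.model_decay(model, df, fractions=(0.0,))
        assert decay == 0.0

    def test_shape_only_model_immune_to_shrinkage(self, rng):
        df = gaussian_classes(rng)
        model = clf.fit(df, "mlr", ["aspect_ratio", "flatness", "hollowness"])
        decay, _ = clf.model_decay(model, df, fractions=(0.1, 0.3, 0.85))
        assert decay == 0.0

    def test_size_models_decay_more_than_shape_models(self, rng):
        df = gaussian_classes(rng)
        qda = clf.fit(df, "qda", ["length", "diameter"])
        mlr = clf.fit(df, "mlr", ["aspect_ratio", "flatness", "hollowness"])
        qda_decay, _ = clf.model_decay(qda, df)
        mlr_decay, _ = clf.model_decay(mlr, df)
        assert qda_decay > mlr_decay
        assert qda_decay > 0.0

    def test_fossil_at_centroid_called(self, rng):
        df = gaussian_classes(rng)
        model = clf.fit(df, "qda")
        centroid = df[df["color_category"] == "grey"].mean(numeric_only=True)
        fossil = pd.DataFrame(
            dict(sample_id=["f1"], mean_length_um=[centroid["mean_length_um"]],
                 mean_width_um=[centroid["mean_width_um"]],
                 aspect_ratio=[centroid["aspect_ratio"]])
        )
        preds = clf.predict_fossil(model, fossil)
        assert preds["call"].iloc[0] == "grey"

    def test_threshold_one_inconclusive(self, rng):
        df = gaussian_classes(rng)
        model = clf.fit(df, "mlr")
        preds = clf.predict_fossil(model, df.iloc[:5], threshold=1.0)
        assert (preds["call"] == "inconclusive").all()

    def test_flag_prefilter_forces_iridescent(self, rng):
        df = gaussian_classes(rng)
        model = clf.fit(df, "qda", flag_prefilter=True)
        fossil = df.iloc[:4].copy()
        fossil["flatness"] = True
        preds = clf.predict_fossil(model, fossil)
        assert (preds["call"] == "iridescent").all()
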