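"""Linear purity model: training, three-stage inference, special training modes."""

import numpy as np
import pandas as pd
import pytest

import bulkpurity as bp
from bulkpurity.selection import FeatureSet


def make_ranks(rng, n=60, genes=("f1", "f2", "f3")):
    idx = [f"s{i}" for i in range(n)]
    return pd.DataFrame(
        rng.uniform(0.01, 1.0, (n, len(genes))), index=idx, columns=list(genes)
    )


class TestTrain:
    def test_exact_recovery_on_noiseless_affine_labels(self, rng):
        ranks = make_ranks(rng)
        purity = (0.5 * ranks["f1"] + 0.1).rename("purity")
        model = bp.train(ranks, purity, ["f1", "f2", "f3"])
        assert model.weights[0] == pytest.approx(0.5, abs=1e-6)
        assert model.weights[1] == pytest.approx(0.0, abs=1e-6)
        assert model.weights[2] == pytest.approx(0.0, abs=1e-6)
        assert model.intercept == pytest.approx(0.1, abs=1e-6)
        assert model.feature_medians.equals(ranks.median(axis=0))

    def test_invariant_to_sample_duplication(self, rng):
        ranks = make_ranks(rng)
        purity = pd.Series(rng.uniform(0.2, 0.8, len(ranks)), index=ranks.index)
        m1 = bp.train(ranks, purity, list(ranks.columns))
        doubled = pd.concat([ranks, ranks.set_axis(ranks.index + "_dup")])
        purity2 = pd.concat([purity, purity.set_axis(purity.index + "_dup")])
        m2 = bp.train(doubled, purity2, list(ranks.columns))
        np.testing.assert_allclose(m1.weights, m2.weights, atol=1e-10)
        assert m1.intercept == pytest.approx(m2.intercept, abs=1e-10)

    def test_rank_deficient_design_warns(self, rng):
        ranks = make_ranks(rng, genes=("f1", "f2"))
        ranks["f2"] = ranks["f1"]  # collinear
        purity = pd.Series(rng.uniform(0, 1, len(ranks)), index=ranks.index)
        with pytest.warns(UserWarning, match="minimum-norm"):
            bp.train(ranks, purity, ["f1", "f2"])

    def test_underdetermined_fit_warns(self, rng):
        ranks = make_ranks(rng, n=2)
        purity = pd.Series([0.3, 0.7], index=ranks.index)
        with pytest.warns(UserWarning):
            bp.train(ranks, purity, list(ranks.columns))

    def test_labels_outside_unit_interval_rejected(self, rng):
        ranks = make_ranks(rng, n=5)
        purity = pd.Series([0.2, 0.4, 1.2, 0.5, 0.1], index=ranks.index)
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            bp.train(ranks, purity, list(ranks.columns))


class TestPredict:
    @pytest.fixture()
    def model(self):
        # hand-built model: purity = 1.2*f1 - 0.1, universe of 4 genes
        return bp.PurityModel(
            universe=["f1", "f2", "g3", "g4"],
            feature_genes=["f1", "f2"],
            weights=np.array([1.2, 0.0]),
            intercept=-0.1,
            feature_medians=pd.Series({"f1": 0.5, "f2": 0.25}),
        )

    def test_out_of_range_predictions_clip_to_bounds(self, model):
        expr = pd.DataFrame(
            [[100.0, 1.0, 2.0, 3.0], [0.001, 5.0, 6.0, 7.0]],
            index=["hi", "lo"],
            columns=["f1", "f2", "g3", "g4"],
        )
        out = bp.predict(model, expr)
        # hi: f1 ranks 4/4 -> raw 1.2*1 - 0.1 = 1.1 -> clipped to 1.0
        # lo: f1 ranks 1/4 -> raw 1.2*0.25 - 0.1 = 0.2 (in range)
        assert out.loc["hi", "purity"] == 1.0
        assert out.loc["lo", "purity"] == pytest.approx(0.2)
        neg = bp.PurityModel(
            universe=model.universe,
            feature_genes=model.feature_genes,
            weights=np.array([-1.0, 0.0]),
            intercept=0.1,
            feature_medians=model.feature_medians,
        )
        assert bp.predict(neg, expr).loc["hi", "purity"] == 0.0

    def test_missing_feature_imputed_with_training_median(self, model):
        expr = pd.DataFrame(
            [[3.0, 1.0, 2.0], [8.0, 5.0, 6.0]],
            index=["a", "b"],
            columns=["f1", "g3", "g4"],  # f2 absent
        )
        out = bp.predict(model, expr)
        assert (out["n_imputed_features"] == 1).all()
        # independent recomputation of the three-stage pipeline
        rp = bp.rank_percentile(expr, model.universe)
        x = np.column_stack(
            [rp["f1"].to_numpy(), np.full(2, model.feature_medians["f2"])]
        )
        expected = np.clip(x @ model.weights + model.intercept, 0, 1)
        np.testing.assert_allclose(out["purity"].to_numpy(), expected)

    def test_majority_imputation_warns(self, model):
        expr = pd.DataFrame(
            [[1.0, 2.0]], index=["a"], columns=["g3", "g4"]  # both features absent
        )
        with pytest.warns(UserWarning, match="half"):
            out = bp.predict(model, expr)
        assert out.loc["a", "n_imputed_features"] == 2

    def test_invariant_to_positive_rescaling(self, model, rng):
        expr = pd.DataFrame(
            rng.lognormal(1, 1, (5, 4)),
            index=[f"s{i}" for i in range(5)],
            columns=["f1", "f2", "g3", "g4"],
        )
        base = bp.predict(model, expr)
        scaled = bp.predict(model, expr * 3.7)
        pd.testing.assert_frame_equal(base, scaled)

    def test_zero_overlap_errors(self, model):
        expr = pd.DataFrame([[1.0]], index=["s"], columns=["unknown"])
        with pytest.raises(ValueError, match="no universe genes"):
            bp.predict(model, expr)

    def test_output_always_in_unit_interval(self, model, rng):
        expr = pd.DataFrame(
            rng.lognormal(2, 2, (50, 4)),
            index=[f"s{i}" for i in range(50)],
            columns=["f1", "f2", "g3", "g4"],
        )
        out = bp.predict(model, expr)
        assert out["purity"].between(0, 1).all()


class TestSerialization:
    def test_round_trip_is_bit_identical(self, tmp_path, rng):
        ranks = make_ranks(rng)
        purity = pd.Series(rng.uniform(0.1, 0.9, len(ranks)), index=ranks.index)
        model = bp.train(ranks, purity, list(ranks.columns), universe=list(ranks.columns))
        path = tmp_path / "model.json"
        model.save(path)
        loaded = bp.PurityModel.load(path)
        expr = pd.DataFrame(
            rng.lognormal(0, 1, (10, 3)),
            index=[f"q{i}" for i in range(10)],
            columns=list(ranks.columns),
        )
        before = bp.predict(model, expr)["purity"].to_numpy()
        after = bp.predict(loaded, expr)["purity"].to_numpy()
        assert np.array_equal(before, after)  # exact, not approx

    def test_rejects_foreign_json(self, tmp_path):
        path = tmp_path / "other.json"
        path.write_text('{"format": "something-else"}')
        with pytest.raises(ValueError, match="not a bulkpurity model"):
            bp.PurityModel.load(path)


@pytest.fixture(scope="module")
def fitted(small_cohort, small_ranks):
    c = small_cohort
    features = FeatureSet(
        genes=[g for g in c.informative_genes.index if g in small_ranks.columns],
        correlations=pd.Series(dtype=float),
    )
    return c, small_ranks, features


class TestTrainingModes:
    def test_per_group_models_fit_their_own_group(self, fitted):
        c, ranks, _ = fitted
        models = bp.train_per_group(ranks, c.true_purity, c.groups, seed=0)
        assert set(models) == set(c.groups.unique())
        for label, model in models.items():
            idx = c.groups.index[c.groups == label]
            pred = bp.predict(model, c.expr.loc[idx])["purity"]
            rmse = float(np.sqrt(((pred - c.true_purity.loc[idx]) ** 2).mean()))
            assert rmse <= 0.08

    def test_per_group_determinism(self, fitted):
        c, ranks, _ = fitted
        a = bp.train_per_group(ranks, c.true_purity, c.groups, seed=0)
        b = bp.train_per_group(ranks, c.true_purity, c.groups, seed=0)
        for label in a:
            np.testing.assert_array_equal(a[label].weights, b[label].weights)

    def test_pure_noise_group_predicts_its_mean_purity(self, rng):
        c = bp.make_cohort(
            n_groups=1, samples_per_group=80, n_genes=40, n_informative=0,
            group_effect_sd=0.0, seed=61,
        )
        ranks = bp.rank_percentile(c.expr, list(c.expr.columns))
        models = bp.train_per_group(ranks, c.true_purity, c.groups, seed=0)
        (model,) = models.values()
        pred = bp.predict(model, c.expr)["purity"]
        assert np.allclose(pred, c.true_purity.mean(), atol=0.05)

    def test_logo_trains_on_the_complement(self, fitted):
        c, ranks, features = fitted
        models = bp.train_leave_one_group_out(ranks, c.true_purity, c.groups, features)
        assert set(models) == set(c.groups.unique())
        # 2-group check: each model equals a direct fit on the other group
        two = c.groups[c.groups.isin(["CT1", "CT2"])]
        m2 = bp.train_leave_one_group_out(
            ranks.loc[two.index], c.true_purity.loc[two.index], two, features
        )
        direct = bp.train(
            ranks.loc[two.index[two == "CT2"]], c.true_purity, features
        )
        np.testing.assert_allclose(m2["CT1"].weights, direct.weights, atol=1e-10)

    def test_logo_generalizes_to_withheld_group(self, fitted):
        c, ranks, features = fitted
        all_model = bp.train(ranks, c.true_purity, features, universe=list(ranks.columns))
        logo = bp.train_leave_one_group_out(
            ranks, c.true_purity, c.groups, features, universe=list(ranks.columns)
        )
        rmse_all, rmse_logo = [], []
        for label, model in logo.items():
            idx = c.groups.index[c.groups == label]
            truth = c.true_purity.loc[idx]
            p_all = bp.predict(all_model, c.expr.loc[idx])["purity"]
            p_logo = bp.predict(model, c.expr.loc[idx])["purity"]
            rmse_all.append(float(np.sqrt(((p_all - truth) ** 2).mean())))
            rmse_logo.append(float(np.sqrt(((p_logo - truth) ** 2).mean())))
        # graceful degradation: withheld-type error at most twice the all-type error
        assert np.median(rmse_logo) <= 2 * max(np.median(rmse_all), 0.01)

    def test_single_group_logo_rejected(self, fitted):
        c, ranks, features = fitted
        one = pd.Series("only", index=ranks.index)
        with pytest.raises(ValueError, match=">= 2 groups"):
            bp.train_leave_one_group_out(ranks, c.true_purity, one, features)
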