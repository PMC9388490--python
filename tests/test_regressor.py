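"""Boosted-tree regressor: contract, determinism, importance."""

import numpy as np
import pandas as pd
import pytest

from protqa.featurize import feature_block
from protqa.regressor import BoostedQARegressor
from protqa.structures import LABEL_COLUMN


def make_table(rng, n_targets=4, n_models=30, n_noise=3, signal=True):
    """Synthetic feature table with one informative feature + noise columns."""
    rows, tuples = [], []
    for t in range(n_targets):
        for m in range(n_models):
            label = rng.uniform(0, 1)
            row = {"informative": label if signal else rng.uniform(0, 1)}
            for k in range(n_noise):
                row[f"noise{k}"] = rng.normal()
            row[LABEL_COLUMN] = label
            rows.append(row)
            tuples.append((f"T{t}", f"m{m:03d}"))
    idx = pd.MultiIndex.from_tuples(tuples, names=["target_id", "model_id"])
    return pd.DataFrame(rows, index=idx)


class TestFit:
    def test_single_feature_signal_is_learned(self, rng):
        table = make_table(rng, n_targets=4, n_models=60)
        model = BoostedQARegressor().fit(table)
        pred = model.predict(table)
        rmse = np.sqrt(np.mean((pred - table[LABEL_COLUMN]) ** 2))
        assert rmse < 0.02

    def test_constant_label(self, rng):
        table = make_table(rng, n_targets=3, n_models=20)
        table[LABEL_COLUMN] = 0.5
        model = BoostedQARegressor().fit(table)
        np.testing.assert_allclose(model.predict(table), 0.5, atol=1e-6)

    def test_determinism_bit_identical(self, rng):
        table = make_table(rng)
        p1 = BoostedQARegressor(random_state=3).fit(table).predict(table)
        p2 = BoostedQARegressor(random_state=3).fit(table).predict(table)
        np.testing.assert_array_equal(p1, p2)

    def test_label_out_of_range_rejected(self, rng):
        table = make_table(rng, n_targets=2, n_models=5)
        table.iloc[0, table.columns.get_loc(LABEL_COLUMN)] = 1.5
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            BoostedQARegressor().fit(table)

    def test_single_target_warns(self, rng):
        table = make_table(rng, n_targets=1, n_models=10)
        with pytest.warns(UserWarning, match="single target"):
            BoostedQARegressor().fit(table)

    def test_label_column_never_a_feature(self, rng):
        model = BoostedQARegressor().fit(make_table(rng))
        assert LABEL_COLUMN not in model.feature_names_

    def test_filtered_targets_left_out_of_schema(self, rng):
        table = make_table(rng, n_targets=4)
        model = BoostedQARegressor().fit(table, filtered_targets={"T0"})
        assert "T0" not in model.onehot_schema_.target_ids
        assert "T1" in model.onehot_schema_.target_ids


class TestPredict:
    def test_unseen_target_gets_finite_scores(self, rng):
        train = make_table(rng, n_targets=3)
        test = make_table(rng, n_targets=1).rename(index={"T0": "TX"}, level=0)
        model = BoostedQARegressor().fit(train)
        pred = model.predict(test)
        assert np.all(np.isfinite(pred))

    def test_clipping_to_unit_interval(self, rng):
        table = make_table(rng)
        model = BoostedQARegressor().fit(table)
        pred = model.predict(table)
        assert pred.min() >= 0.0 and pred.max() <= 1.0
        raw = model.learner_.predict(
            model._design(table).astype(float)
        )
        # the clip actually does something on at least the extremes
        np.testing.assert_allclose(pred, np.clip(raw, 0, 1))

    def test_missing_feature_column_named_in_error(self, rng):
        table = make_table(rng)
        model = BoostedQARegressor().fit(table)
        with pytest.raises(ValueError, match="informative"):
            model.predict(table.drop(columns=["informative"]))


class TestImportance:
    def test_informative_feature_ranks_first(self, rng):
        table = make_table(rng, n_targets=4, n_models=60)
        model = BoostedQARegressor(use_one_hot=False).fit(table)
        rep = model.feature_importance()
        top = rep.table.loc[rep.table["rank"] == 1, "feature"].iloc[0]
        assert top == "informative"

    def test_unused_feature_zero_gain(self, rng):
        table = make_table(rng, n_targets=4, n_models=60)
        table["constant"] = 1.0  # unsplittable
        model = BoostedQARegressor(use_one_hot=False).fit(table)
        rep = model.feature_importance()
        gain = rep.table.set_index("feature").loc["constant", "gain"]
        assert gain == 0.0

    def test_ranks_are_a_gain_sorted_permutation(self, rng):
        model = BoostedQARegressor().fit(make_table(rng))
        rep = model.feature_importance().table
        assert sorted(rep["rank"]) == list(range(1, len(rep) + 1))
        ordered = rep.sort_values("rank")["gain"].to_numpy()
        assert (np.diff(ordered) <= 1e-9).all()


class TestBaselinesAndPersistence:
    @pytest.mark.parametrize("backend", ["linear", "mlp"])
    def test_baselines_share_the_interface(self, rng, backend):
        table = make_table(rng, n_targets=3, n_models=20)
        model = BoostedQARegressor(backend=backend).fit(table)
        pred = model.predict(table)
        assert pred.shape == (60,)
        assert np.all((pred >= 0) & (pred <= 1))

    def test_save_load_round_trip(self, rng, tmp_path):
        table = make_table(rng)
        model = BoostedQARegressor().fit(table)
        path = tmp_path / "model.joblib"
        model.save(path)
        back = BoostedQARegressor.load(path)
        np.testing.assert_array_equal(back.predict(table), model.predict(table))
        assert (tmp_path / "model.joblib.importance.json").exists()

    def test_sklearn_clone_compatible(self):
        from sklearn.base import clone

        est = BoostedQARegressor(learning_rate=0.05, n_estimators=20)
        cloned = clone(est)
        assert cloned.get_params() == est.get_params()


def test_feature_block_classifier():
    cases = {
        "contacts8": "basic",
        "rg_z": "basic_zscore",
        "scCarbonN_median": "basic_median",
        "gdt1_consensus": "consensus",
        "rms_consensus": "consensus",
        "gdt_ts_consensus_z": "consensus_zscore",
        "gdt_ha_consensus_median": "consensus_median",
        "aa_A": "composition",
        "comp_polar": "composition",
        "OH_T0001": "one_hot",
    }
    for name, block in cases.items():
        assert feature_block(name) == block
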