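"""Consensus features: pairwise similarity matrices and pool averages."""

import numpy as np
import pandas as pd
import pytest

from protqa.consensus import (
    CONSENSUS_COLUMNS,
    RMSD_SENTINEL,
    consensus_table,
    consensus_vector,
    pairwise_similarities,
    per_target_median,
)
from protqa.structures import TargetSet
from protqa.superpose import gdt
from protqa.synthetic import DecoyConfig, make_target_set

from _util import ca_model, random_chain


def _pool(rng, n_models=5, n_res=15, sigma=1.5, target_id="T"):
    seq = "A" * n_res
    ref = random_chain(n_res, rng)
    models = [
        ca_model(ref + rng.normal(size=(n_res, 3)) * sigma, f"m{i}", target_id,
                 sequence=seq)
        for i in range(n_models)
    ]
    return TargetSet(target_id=target_id, sequence=seq, models=models)


class TestPairwiseSimilarities:
    def test_identical_models(self, rng):
        T = _pool(rng, n_models=2, sigma=0.0)
        M = pairwise_similarities(T)
        for key in ("gdt_1", "gdt_8", "gdt_ts", "gdt_ha"):
            np.testing.assert_allclose(M.array(key), 1.0)
        np.testing.assert_allclose(M.rmsd, 0.0, atol=1e-9)

    def test_single_model_pool(self, rng):
        T = _pool(rng, n_models=1)
        M = pairwise_similarities(T)
        assert M.gdt_ts.shape == (1, 1)
        assert M.gdt_ts[0, 0] == pytest.approx(1.0)
        assert M.rmsd[0, 0] == 0.0

    def test_matches_pair_by_pair_recomputation(self, rng):
        T = _pool(rng, n_models=5)
        M = pairwise_similarities(T)
        n_res = len(T.sequence)
        for i in range(5):
            for j in range(5):
                if i == j:
                    continue
                res = gdt(T.models[i], T.models[j], denominator_length=n_res)
                assert M.gdt_4[i, j] == pytest.approx(res.fractions[4.0])
                assert M.rmsd[i, j] == pytest.approx(res.rmsd_common)

    def test_symmetry(self, rng):
        T = _pool(rng, n_models=4)
        M = pairwise_similarities(T)
        for key in ("gdt_1", "gdt_2", "gdt_4", "gdt_8", "gdt_ts", "gdt_ha", "rmsd"):
            np.testing.assert_array_equal(M.array(key), M.array(key).T)

    def test_disjoint_pair_gets_worst_values(self, rng, caplog):
        seq = "A" * 20
        m1 = ca_model(random_chain(8, rng), "m1", "T", start=1, sequence=seq)
        m2 = ca_model(random_chain(8, rng), "m2", "T", start=12, sequence=seq)
        T = TargetSet(target_id="T", sequence=seq, models=[m1, m2])
        with caplog.at_level("WARNING"):
            M = pairwise_similarities(T)
        assert M.gdt_ts[0, 1] == 0.0
        assert M.rmsd[0, 1] == RMSD_SENTINEL
        assert any("unscorable" in r.message for r in caplog.records)


class TestConsensusVector:
    def test_two_model_average_includes_self(self):
        # gdt_ts(d,d)=1.0, gdt_ts(d,s)=0.5 -> consensus 0.75
        from protqa.consensus import SimilarityMatrix

        ones = np.array([[1.0, 0.5], [0.5, 1.0]])
        M = SimilarityMatrix(
            model_ids=["a", "b"],
            gdt_1=ones, gdt_2=ones, gdt_4=ones, gdt_8=ones,
            gdt_ts=ones, gdt_ha=ones,
            rmsd=np.array([[0.0, 2.0], [2.0, 0.0]]),
        )
        vec = consensus_vector(0, M)
        assert vec["gdt_ts_consensus"] == pytest.approx(0.75)
        assert vec["rms_consensus"] == pytest.approx(1.0)

    def test_emits_exactly_seven_features(self, rng):
        T = _pool(rng, n_models=3)
        table = consensus_table(pairwise_similarities(T))
        assert list(table.columns) == list(CONSENSUS_COLUMNS)
        assert len(CONSENSUS_COLUMNS) == 7

    def test_identical_pool_extremes(self, rng):
        T = _pool(rng, n_models=4, sigma=0.0)
        table = consensus_table(pairwise_similarities(T))
        for col in CONSENSUS_COLUMNS[:6]:
            np.testing.assert_allclose(table[col], 1.0)
        np.testing.assert_allclose(table["rms_consensus"], 0.0, atol=1e-9)

    def test_outlier_is_strict_consensus_minimum(self, rng):
        seq = "A" * 15
        ref = random_chain(15, rng)
        models = [
            ca_model(ref + rng.normal(size=(15, 3)) * 0.3, f"m{i}", "T", sequence=seq)
            for i in range(4)
        ]
        models.append(
            ca_model(ref + rng.normal(size=(15, 3)) * 12.0, "outlier", "T", sequence=seq)
        )
        T = TargetSet(target_id="T", sequence=seq, models=models)
        table = consensus_table(pairwise_similarities(T))
        assert table["gdt_ts_consensus"].idxmin() == "outlier"
        assert (
            table.loc["outlier", "gdt_ts_consensus"]
            < table["gdt_ts_consensus"].drop("outlier").min()
        )

    def test_permutation_invariance(self, rng):
        T = _pool(rng, n_models=5)
        table = consensus_table(pairwise_similarities(T))
        perm = TargetSet(
            target_id="T", sequence=T.sequence, models=T.models[::-1]
        )
        table_perm = consensus_table(pairwise_similarities(perm))
        pd.testing.assert_frame_equal(
            table.sort_index(), table_perm.sort_index(), atol=1e-12, rtol=0
        )


class TestPerTargetMedian:
    def _table(self, values, target="T1"):
        idx = pd.MultiIndex.from_tuples(
            [(target, f"m{i}") for i in range(len(values))],
            names=["target_id", "model_id"],
        )
        return pd.DataFrame({"f": values}, index=idx)

    def test_odd_count(self):
        out = per_target_median(self._table([0.2, 0.4, 0.9]), ["f"])
        np.testing.assert_allclose(out["f_median"], 0.4)

    def test_single_model(self):
        out = per_target_median(self._table([0.7]), ["f"])
        assert out["f_median"].iloc[0] == pytest.approx(0.7)

    def test_even_count_mean_of_middle(self):
        out = per_target_median(self._table([0.2, 0.4]), ["f"])
        np.testing.assert_allclose(out["f_median"], 0.3)

    def test_missing_values_rejected(self):
        t = self._table([0.2, np.nan])
        with pytest.raises(ValueError):
            per_target_median(t, ["f"])

    def test_per_target_independence(self):
        t = pd.concat([self._table([0.0, 1.0], "T1"), self._table([10.0], "T2")])
        out = per_target_median(t, ["f"])
        assert out.loc[("T1", "m0"), "f_median"] == pytest.approx(0.5)
        assert out.loc[("T2", "m0"), "f_median"] == pytest.approx(10.0)


def test_consensus_bounds_on_synthetic_target():
    """Each consensus gdt feature lies within [selfscore/|T|, 1]."""
    cfg = DecoyConfig(n_targets=1, models_per_target=8, sequence_length=(20, 25), seed=3)
    ts, _ = make_target_set("T0001", cfg, np.random.SeedSequence(3))
    M = pairwise_similarities(ts)
    table = consensus_table(M)
    n = ts.n_models
    for i, mid in enumerate(M.model_ids):
        self_score = M.gdt_ts[i, i]
        val = table.loc[mid, "gdt_ts_consensus"]
        assert self_score / n - 1e-12 <= val <= 1.0 + 1e-12
    assert (table["rms_consensus"] >= 0).all()
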