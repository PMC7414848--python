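"""Distance/contact evaluation: score transform, MAE, top-k precision."""

import numpy as np
import pytest

from distnet.distmap import DistanceMap
from distnet.evaluation import (count_long_range_contacts, distance_to_score,
                                evaluate_dataset, evaluate_target,
                                mae_at_threshold, separation_mask,
                                topk_precision)
from conftest import random_distance_map


class TestDistanceToScore:
    @pytest.mark.parametrize("d,expected", [
        (8.0, 0.5),   # the half-score anchor
        (3.0, 1.0),   # below 4 A saturates
        (4.0, 1.0),   # boundary: 4/4
        (16.0, 0.25),
    ])
    def test_reference_values(self, d, expected):
        assert distance_to_score(d) == pytest.approx(expected)

    def test_monotone_non_increasing(self, rng):
        d = np.sort(rng.uniform(0, 30, size=200))
        s = distance_to_score(d)
        assert np.all(np.diff(s) <= 1e-12)

    def test_preserves_distance_ordering(self, rng):
        d = rng.uniform(4.0, 30, size=100)
        s = distance_to_score(d)
        assert np.array_equal(np.argsort(-s, kind="stable"),
                              np.argsort(d, kind="stable"))

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            distance_to_score(-1.0)


class TestSeparationRanges:
    def test_classes_partition_all_separations(self):
        L = 60
        total = np.zeros((L, L), dtype=int)
        for name in ("local", "short", "medium", "long"):
            total += separation_mask(L, (name,)).astype(int)
        assert np.all(total == 1)

    def test_long_range_is_24_plus(self):
        m = separation_mask(40)
        assert not m[0, 23]
        assert m[0, 24]


class TestMAE:
    def test_perfect_prediction_zero(self, rng):
        true = random_distance_map(rng, 30)
        assert mae_at_threshold(true.values, true, 8.0) == pytest.approx(0.0)

    def test_single_pair_mean(self):
        L = 30
        values = np.full((L, L), 50.0)
        np.fill_diagonal(values, 0.0)
        values[0, 28] = values[28, 0] = 6.0  # the only sub-threshold pair
        true = DistanceMap(values=values, mask=np.ones((L, L), bool))
        pred = np.full((L, L), 10.0)
        assert mae_at_threshold(pred, true, 8.0) == pytest.approx(4.0)

    def test_no_qualifying_pair_is_nan(self):
        L = 30
        values = np.full((L, L), 50.0)
        np.fill_diagonal(values, 0.0)
        true = DistanceMap(values=values, mask=np.ones((L, L), bool))
        assert np.isnan(mae_at_threshold(values, true, 8.0))

    def test_matches_double_loop_oracle(self, rng):
        true = random_distance_map(rng, 40, observed=0.9)
        pred = np.abs(true.values + rng.normal(0, 3, size=(40, 40)))
        got = mae_at_threshold(pred, true, 8.0, ranges=("long",))
        errs = []
        for i in range(40):
            for j in range(40):
                if (true.mask[i, j] and abs(i - j) >= 24
                        and true.values[i, j] < 8.0):
                    errs.append(abs(pred[i, j] - true.values[i, j]))
        if errs:
            assert got == pytest.approx(np.mean(errs), rel=1e-10)
        else:
            assert np.isnan(got)

    def test_medium_plus_long_variant(self, rng):
        true = random_distance_map(rng, 40)
        pred = np.abs(true.values + rng.normal(0, 1, size=(40, 40)))
        both = mae_at_threshold(pred, true, 12.0, ranges=("medium", "long"))
        assert np.isfinite(both)


class TestTopKPrecision:
    def test_perfect_scores_give_100(self, rng):
        true = random_distance_map(rng, 50)
        scores = distance_to_score(np.where(true.values > 0, true.values, 50.0))
        if count_long_range_contacts(true) == 0:
            pytest.skip("fixture has no long-range contact")
        assert topk_precision(scores, true, "NC") == pytest.approx(100.0)

    def test_no_long_range_contacts_excluded(self):
        L = 40
        values = np.full((L, L), 30.0)
        np.fill_diagonal(values, 0.0)
        true = DistanceMap(values=values, mask=np.ones((L, L), bool))
        assert np.isnan(topk_precision(np.ones((L, L)), true, "L"))
        report = evaluate_target(np.ones((L, L)), true, mode="contact")
        assert report["excluded"]

    def test_matches_sort_and_count_oracle(self, rng):
        true = random_distance_map(rng, 50)
        scores = rng.random((50, 50))
        scores = (scores + scores.T) / 2
        for rule in ("L", "NC"):
            got = topk_precision(scores, true, rule)
            pairs = [(i, j) for i in range(50) for j in range(i + 1, 50)
                     if true.mask[i, j] and j - i >= 24]
            nc = sum(true.values[i, j] < 8.0 for i, j in pairs)
            if nc == 0:
                assert np.isnan(got)
                continue
            k = 50 if rule == "L" else nc
            ranked = sorted(pairs, key=lambda p: (-scores[p], p))[:k]
            expected = 100.0 * sum(true.values[i, j] < 8.0
                                   for i, j in ranked) / len(ranked)
            assert got == pytest.approx(expected, rel=1e-10)

    def test_invariant_to_monotone_score_transform(self, rng):
        true = random_distance_map(rng, 60)
        scores = rng.random((60, 60))
        a = topk_precision(scores, true, "L")
        b = topk_precision(np.exp(3 * scores) + 7, true, "L")
        assert a == pytest.approx(b)


class TestEvaluateDataset:
    def test_single_perfect_target(self, compact_dmap):
        # compact fold with NC > L, so perfect top-L precision is attainable
        true = compact_dmap
        report = evaluate_dataset({"t": true.values}, {"t": true},
                                  mode="distance")
        row = report.per_target.iloc[0]
        assert row["mae8"] == pytest.approx(0.0)
        assert row["p_l"] == pytest.approx(100.0)
        assert row["p_nc"] == pytest.approx(100.0)

    def test_excluded_target_left_out_of_aggregate(self, compact_dmap):
        good = compact_dmap
        L = 40
        faraway = np.full((L, L), 30.0)
        np.fill_diagonal(faraway, 0.0)
        lonely = DistanceMap(values=faraway, mask=np.ones((L, L), bool))
        report = evaluate_dataset(
            {"good": good.values, "lonely": lonely.values},
            {"good": good, "lonely": lonely}, mode="distance")
        assert report.per_target["excluded"].sum() == 1
        assert report.aggregate["p_l"] == pytest.approx(100.0)

    def test_batch_equals_single_target_calls(self, rng):
        truths = {f"t{k}": random_distance_map(rng, 45) for k in range(5)}
        preds = {tid: np.abs(t.values + rng.normal(0, 2, size=(45, 45)))
                 for tid, t in truths.items()}
        report = evaluate_dataset(preds, truths, mode="distance")
        for _, row in report.per_target.iterrows():
            single = evaluate_target(preds[row["id"]], truths[row["id"]],
                                     mode="distance", target_id=row["id"])
            for key in ("mae8", "mae12", "p_l", "p_nc"):
                if np.isnan(single[key]):
                    assert np.isnan(row[key])
                else:
                    assert row[key] == pytest.approx(single[key])

    def test_id_mismatch_rejected(self, rng):
        true = random_distance_map(rng, 40)
        with pytest.raises(ValueError):
            evaluate_dataset({"a": true.values}, {"b": true}, mode="distance")

    def test_mae_and_pnc_negatively_correlated(self, rng):
        # increasingly noisy predictions: MAE8 rises while P_NC falls
        truths, preds = {}, {}
        for k in range(8):
            true = random_distance_map(rng, 60)
            noise = 0.5 + 1.5 * k
            preds[f"t{k}"] = np.abs(true.values
                                    + rng.normal(0, noise, size=(60, 60)))
            truths[f"t{k}"] = true
        report = evaluate_dataset(preds, truths, mode="distance")
        kept = report.per_target[~report.per_target["excluded"]]
        r = np.corrcoef(kept["mae8"], kept["p_nc"])[0, 1]
        assert r < 0

    def test_tsv_round_trip(self, rng, tmp_path):
        import pandas as pd

        true = random_distance_map(rng, 50)
        report = evaluate_dataset({"t": true.values}, {"t": true},
                                  mode="distance")
        out = tmp_path / "report.tsv"
        report.to_tsv(out)
        frame = pd.read_csv(out, sep="\t")
        assert list(frame["id"]) == ["t", "MEAN"]
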