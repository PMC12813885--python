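"""Recall-vs-uncertainty curves, threshold selection, decision policy."""

import numpy as np
import pytest

from contourqa.calibrate import (
    AUTO,
    FLAG,
    ThresholdEntry,
    ThresholdTable,
    apply_policy,
    binned_performance,
    build_curve,
    calibrate_thresholds,
    select_threshold,
)

from oracles import (
    curve_oracle,
    make_record,
    random_instance,
    recall_below,
    threshold_oracle,
)


@pytest.fixture
def four_predictions():
    # labels [R, R, A, R]; the first two revision-required predictions are
    # correct flags, the last is missed; uncertainties ascending
    return [
        make_record(0.1, 1, 1, sample_id="s0"),
        make_record(0.2, 1, 1, sample_id="s1"),
        make_record(0.3, 0, 0, sample_id="s2"),
        make_record(0.4, 1, 0, sample_id="s3"),
    ]


class TestBuildCurve:
    def test_four_prediction_example(self, four_predictions):
        curve = build_curve(four_predictions)
        np.testing.assert_allclose(curve.cumulative_recall, [1, 1, 1, 2 / 3])
        np.testing.assert_allclose(curve.population_fraction, [0.25, 0.5, 0.75, 1.0])
        np.testing.assert_allclose(curve.uncertainties, [0.1, 0.2, 0.3, 0.4])

    def test_all_correct_gives_unit_recall(self):
        records = [make_record(0.1 * i, 1, 1, sample_id=f"s{i}") for i in range(5)]
        curve = build_curve(records)
        assert (curve.cumulative_recall == 1.0).all()

    def test_order_invariance(self, four_predictions, rng):
        curve = build_curve(four_predictions)
        shuffled = [four_predictions[i] for i in rng.permutation(4)]
        curve2 = build_curve(shuffled)
        np.testing.assert_array_equal(curve.cumulative_recall, curve2.cumulative_recall)
        np.testing.assert_array_equal(curve.uncertainties, curve2.uncertainties)

    def test_full_prefix_recall_equals_overall_recall(self, rng):
        records = random_instance(rng, 40)
        curve = build_curve(records)
        pos = [r for r in records if r.true_label == 1]
        overall = sum(r.prediction.predicted_label == 1 for r in pos) / len(pos)
        assert curve.cumulative_recall[-1] == pytest.approx(overall)

    def test_no_revision_required_raises(self):
        records = [make_record(0.1, 0, 0), make_record(0.2, 0, 1)]
        with pytest.raises(ValueError, match="revision-required"):
            build_curve(records)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            build_curve([])


class TestSelectThreshold:
    def test_first_drop_below_target(self, four_predictions):
        curve = build_curve(four_predictions)
        tau = select_threshold(curve, 0.98)
        assert tau == 0.4
        assert recall_below(four_predictions, tau) >= 0.98

    def test_never_drops_gives_one(self):
        records = [make_record(0.1 * i, 1, 1, sample_id=f"s{i}") for i in range(5)]
        assert select_threshold(build_curve(records), 0.98) == 1.0

    def test_target_one_stops_at_first_miss(self):
        records = [
            make_record(0.05, 1, 1, sample_id="s0"),
            make_record(0.15, 1, 0, sample_id="s1"),  # first missed revision
            make_record(0.25, 1, 1, sample_id="s2"),
        ]
        assert select_threshold(build_curve(records), 1.0) == 0.15

    def test_invalid_target_rejected(self, four_predictions):
        curve = build_curve(four_predictions)
        with pytest.raises(ValueError):
            select_threshold(curve, 0.0)

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(2024)
        for i in range(50):
            records = random_instance(rng, int(rng.integers(2, 51)))
            target = float(rng.uniform(0.5, 1.0))
            curve = build_curve(records)
            tau = select_threshold(curve, target)
            assert tau == pytest.approx(threshold_oracle(records, target), abs=0)
            assert recall_below(records, tau) >= target

    def test_curve_matches_oracle(self, rng):
        records = random_instance(rng, 30)
        u, recalls, fractions = curve_oracle(records)
        curve = build_curve(records)
        np.testing.assert_allclose(curve.uncertainties, u)
        np.testing.assert_allclose(curve.cumulative_recall, recalls)
        np.testing.assert_allclose(curve.population_fraction, fractions)


class TestCalibrateThresholds:
    def test_per_structure_and_overrides(self, rng):
        records = (random_instance(rng, 40, structure="a")
                   + random_instance(rng, 40, structure="b"))
        table = calibrate_thresholds(records, target_recall=0.9,
                                     overrides={"b": 1.0})
        assert table.entries["a"].target_recall == 0.9
        assert table.entries["b"].target_recall == 1.0
        for name, entry in table.entries.items():
            group = [r for r in records if r.structure == name]
            assert entry.val_recall_below_tau >= entry.target_recall
            u = np.array([r.prediction.entropy for r in group])
            assert entry.population_below_tau == pytest.approx((u < entry.tau).mean())

    def test_idempotence(self, rng):
        records = random_instance(rng, 60)
        t1 = calibrate_thresholds(records)
        t2 = calibrate_thresholds(records)
        assert t1 == t2

    def test_json_round_trip(self, tmp_path, rng):
        table = calibrate_thresholds(random_instance(rng, 40))
        path = tmp_path / "thresholds.json"
        table.to_json(path)
        assert ThresholdTable.from_json(path) == table


class TestApplyPolicy:
    def make_table(self, tau):
        return ThresholdTable(entries={"a": ThresholdEntry(tau, 0.98, 1.0, 1.0)})

    def test_zero_entropy_is_auto(self):
        decisions = apply_policy([make_record(0.0, 0, 0)], self.make_table(0.5))
        assert decisions[0].decision == AUTO

    def test_entropy_equal_to_tau_is_flagged(self):
        decisions = apply_policy([make_record(0.5, 0, 0)], self.make_table(0.5))
        assert decisions[0].decision == FLAG

    def test_population_bookkeeping(self, rng):
        records = [make_record(u, 0, 0, sample_id=f"s{i}")
                   for i, u in enumerate([0.1] * 7 + [0.9] * 3)]
        decisions = apply_policy(records, self.make_table(0.5))
        n_auto = sum(d.decision == AUTO for d in decisions)
        assert n_auto == 7 and len(decisions) == 10

    def test_missing_structure_raises(self):
        with pytest.raises(KeyError):
            apply_policy([make_record(0.1, 0, 0, structure="zzz")], self.make_table(0.5))


class TestBinnedPerformance:
    def test_default_is_80_bins(self):
        import inspect

        from contourqa.calibrate import binned_performance as fn

        assert inspect.signature(fn).parameters["n_bins"].default == 80

    def test_single_bin_recovers_overall_accuracy(self, rng):
        records = random_instance(rng, 50)
        df = binned_performance(records, n_bins=1)
        overall = np.mean([r.prediction.predicted_label == r.true_label for r in records])
        assert len(df) == 1
        assert df.iloc[0]["accuracy"] == pytest.approx(overall)

    def test_matches_binning_oracle(self, rng):
        from oracles import binning_oracle

        records = random_instance(rng, 200)
        df = binned_performance(records, n_bins=17).set_index("bin")
        oracle = binning_oracle(records, 17)
        assert set(df.index) == set(oracle)
        for b, row in oracle.items():
            assert df.loc[b, "n"] == row["n"]
            assert df.loc[b, "accuracy"] == pytest.approx(row["accuracy"])
            assert df.loc[b, "mean_uncertainty"] == pytest.approx(row["mean_uncertainty"])
            if row["recall"] is None:
                assert np.isnan(df.loc[b, "recall"])
            else:
                assert df.loc[b, "recall"] == pytest.approx(row["recall"])

    def test_invalid_bin_count_rejected(self, rng):
        with pytest.raises(ValueError):
            binned_performance(random_instance(rng, 10), n_bins=0)
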