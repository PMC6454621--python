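import numpy as np
import pytest

from mngpipe import decode as dec
from mngpipe.decode import (DecodingTrial, activity_gate, balanced_accuracy,
                            chance_level, compute_afr, feat1_force,
                            feat1_velocity, leave_one_out, predict_custom,
                            train_custom, true_series)


def _trial(feat_rates, label, rest_rate=0.0, rest_s=2.0, move_s=4.0):
    """Trial whose single-unit rate is constant during the movement."""
    t = np.arange(0.0, rest_s + move_s, dec.DT)
    fr = np.full_like(t, rest_rate)
    fr[t >= rest_s] = feat_rates
    return DecodingTrial(t=t, fr_matrix=fr[None, :], label=float(label),
                         onset=rest_s, rest_mask=t < rest_s)


class TestAfr:
    def test_single_unit_is_normalized_rate(self):
        fr = np.array([[0.0, 5.0, 10.0]])
        afr, ok = compute_afr(fr)
        assert ok
        np.testing.assert_allclose(afr, [0.0, 0.5, 1.0])

    def test_pointwise_mean_against_hand_computation(self):
        fr = np.array([[2.0, 4.0], [6.0, 0.0]])
        afr, ok = compute_afr(fr)
        np.testing.assert_allclose(afr, [1.0, 0.5])   # mean / max(mean)

    def test_all_zero_rates_flagged(self):
        afr, ok = compute_afr(np.zeros((2, 5)))
        assert not ok and not afr.any()

    def test_frozen_norm_respected(self):
        afr, _ = compute_afr(np.array([[1.0, 2.0]]), norm=4.0)
        np.testing.assert_allclose(afr, [0.25, 0.5])


class TestFeat1Force:
    @pytest.mark.parametrize("afr,expected", [
        (0.0, -1 + 1 / 2.25), (0.5, 0.0), (1.0, 3.0)])
    def test_closed_form_values(self, afr, expected):
        assert feat1_force(afr) == pytest.approx(expected)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            feat1_force(np.array([1.2]))
        with pytest.raises(ValueError):
            feat1_force(np.array([-0.1]))

    def test_monotone_on_unit_interval(self):
        a = np.linspace(0, 1, 100)
        assert (np.diff(feat1_force(a)) > 0).all()


class TestFeat1Velocity:
    def test_flat_series_is_zero(self):
        t = np.linspace(0, 2, 201)
        assert not feat1_velocity(np.ones_like(t) * 0.3, t, 0.5).any()

    def test_unit_ramp_has_unit_slope_magnitude(self):
        t = np.linspace(0, 1, 1001)
        f = feat1_velocity(t.copy(), t, t_min=0.0)
        assert f[-1] == pytest.approx(1.0)
        assert (f[1:] >= 0).all()

    def test_noisy_ramp_slope_within_ci(self, rng):
        t = np.linspace(0, 4, 2001)
        a = 0.2 * t + rng.normal(0, 0.02, t.size)
        f = feat1_velocity(a, t, t_min=0.0, guard_s=1.0)
        tail = f[t > 3.0]
        assert tail.mean() == pytest.approx(0.2, rel=0.15)


class TestActivityGate:
    def test_all_below_lower_threshold_rests(self):
        assert not activity_gate(np.full(100, -1.0), 1.0, 0.0).any()

    def test_hand_traced_hysteresis(self):
        f = np.array([0.0, 0.5, 1.2, 0.6, 0.6, -0.1, 0.5, 1.5, 0.2, -1.0])
        got = activity_gate(f, T_u1=1.0, T_l1=0.0)
        # manual trace: rest until 1.2 crosses up, held through 0.6s,
        # closed by -0.1, reopened by 1.5, held at 0.2, closed by -1.0
        expected = [False, False, True, True, True, False, False, True,
                    True, False]
        np.testing.assert_array_equal(got, expected)

    def test_between_thresholds_from_start_stays_rest(self):
        assert not activity_gate(np.full(50, 0.5), 1.0, 0.0).any()

    def test_inverted_thresholds_rejected(self):
        with pytest.raises(ValueError):
            activity_gate(np.zeros(5), 0.0, 1.0)


class TestCustomDecoder:
    def test_constant_feature_trials_recover_centroids(self):
        # force task: constant normalized AFR per class maps through the
        # closed-form feature to an exactly computable centroid
        trials = [_trial(r, lv) for r, lv in
                  [(10.0, 1.0), (10.0, 1.0), (40.0, 2.0), (40.0, 2.0)]]
        model = train_custom(trials, "force")
        f_low = feat1_force(10.0 / 40.0)
        f_high = feat1_force(1.0)
        assert model.centroids[1.0] == pytest.approx(f_low, abs=1e-6)
        assert model.centroids[2.0] == pytest.approx(f_high, abs=1e-6)

    def test_well_separated_classes_decode_perfectly(self):
        trials = [_trial(r, lv) for r, lv in
                  [(10.0, 1.0), (10.0, 1.0), (40.0, 2.0), (40.0, 2.0)]]
        cm, models = leave_one_out(trials, "force")
        assert len(models) == len(trials)
        active_counts = cm.counts[1:, 1:]
        assert balanced_accuracy(cm.counts) > 0.9
        # no active sample of one class lands on the other
        assert active_counts[0, 1] == 0 and active_counts[1, 0] == 0

    def test_leave_one_out_fold_structure(self):
        trials = [_trial(10.0 * (i + 1), float(i % 2)) for i in range(6)]
        for tr in trials:
            tr.label += 1.0
        _, models = leave_one_out(trials, "force")
        assert len(models) == 6

    def test_equidistant_feature_breaks_tie_to_lowest_level(self):
        model = dec.DecoderModel(task="force",
                                 centroids={1.0: 0.0, 2.0: 1.0},
                                 T_u1=-10.0, T_l1=-20.0, afr_norm=1.0)
        trial = _trial(0.0, 1.0)
        trial.fr_matrix = np.full_like(trial.fr_matrix, 1.0)
        f = dec._trial_feat1(trial, "force", model.afr_norm)
        # force all features to the midpoint 0.5 via a crafted model
        model.centroids = {1.0: f[0] - 0.3, 2.0: f[0] + 0.3}
        pred = predict_custom(model, trial)
        assert set(pred) == {1.0}

    def test_gating_soundness_no_prediction_while_resting(self):
        trials = [_trial(r, lv, rest_rate=0.5) for r, lv in
                  [(20.0, 1.0), (22.0, 1.0), (40.0, 2.0), (44.0, 2.0)]]
        model = train_custom(trials, "force")
        for tr in trials:
            pred = predict_custom(model, tr)
            f = dec._trial_feat1(tr, model.task, model.afr_norm)
            active = activity_gate(f, model.T_u1, model.T_l1)
            assert not pred[~active].any()


class TestBalancedAccuracy:
    def test_identity_matrix_is_perfect(self):
        assert balanced_accuracy(np.eye(4) * 7) == 1.0

    def test_uniform_confusion_is_chance(self):
        assert balanced_accuracy(np.full((4, 4), 5.0)) == pytest.approx(0.25)

    def test_hand_computed_two_class_case(self):
        assert balanced_accuracy([[8, 2], [3, 7]]) == pytest.approx(0.75)

    def test_zero_event_class_rejected(self):
        with pytest.raises(ValueError):
            balanced_accuracy([[1, 0], [0, 0]])

    def test_equals_macro_recall_oracle_on_random_matrices(self, rng):
        # counting oracle: recall computed per class from raw event lists
        for _ in range(1000):
            k = rng.integers(2, 6)
            counts = rng.integers(1, 30, size=(k, k)).astype(float)
            oracle = np.mean([counts[i, i] / counts[i].sum()
                              for i in range(k)])
            assert balanced_accuracy(counts) == pytest.approx(oracle)

    def test_chance_level_conventions(self):
        assert chance_level(4, include_rest=True) == 0.2
        assert chance_level(4, include_rest=False) == 0.25
        assert chance_level(3, include_rest=True) == 0.25


class TestConfusionMatrix:
    def test_rows_sum_to_event_counts_and_aggregate(self):
        cm1 = dec.ConfusionMatrix.empty([1.0, 2.0])
        cm1.add_events([0.0, 1.0, 1.0, 2.0], [0.0, 1.0, 2.0, 2.0])
        assert cm1.counts.sum() == 4
        np.testing.assert_allclose(cm1.counts.sum(axis=1), [1, 2, 1])
        cm2 = dec.ConfusionMatrix.empty([1.0, 2.0])
        cm2.add_events([1.0], [1.0])
        agg = dec.ConfusionMatrix.aggregate([cm1, cm2])
        # sum of row-normalized matrices; unseen rows normalize to zero
        assert agg[1, 1] == pytest.approx(0.5 + 1.0)


class TestLdaVariants:
    def test_two_separated_gaussian_classes_reach_zero_error(self, rng):
        trials = []
        for lv, mean in [(1.0, 15.0), (2.0, 45.0)]:
            for _ in range(3):
                rate = mean + rng.normal(0, 1.0)
                trials.append(_trial(rate, lv))
        cm, _ = leave_one_out(trials, "force", variant="lda_custom")
        active = cm.counts[1:, 1:]
        err = (active.sum() - np.trace(active)) / max(active.sum(), 1)
        assert err < 0.05

    def test_uninformative_feature_gives_chance_accuracy(self, rng):
        # identical rates across classes: held-out assignment cannot beat
        # chance systematically
        trials = [_trial(30.0 + rng.normal(0, 0.1), lv)
                  for lv in [1.0, 1.0, 1.0, 2.0, 2.0, 2.0]]
        cm, models = leave_one_out(trials, "force", variant="lda_custom")
        active = cm.counts[1:, 1:]
        acc = np.trace(active) / active.sum()
        assert 0.2 <= acc <= 0.8

    def test_multi_unit_beats_single_unit_on_shared_sessions(
            self, force_scenario):
        _sess, _trains, _units, _filtered, trials = force_scenario
        cm_mu, _ = leave_one_out(trials, "force", variant="lda_multi_unit")
        cm_su, _ = leave_one_out(trials, "force", variant="lda_single_unit")
        acc_mu = balanced_accuracy(cm_mu.counts)
        acc_su = balanced_accuracy(cm_su.counts)
        # multi-unit features carry the envelope on top of the rates
        assert acc_mu >= acc_su - 0.05

    def test_shrinkage_reported_for_singular_scatter(self):
        trials = [_trial(10.0, 1.0), _trial(10.0, 1.0),
                  _trial(40.0, 2.0), _trial(40.0, 2.0)]
        from mngpipe.decode import lda_variants

        lda, model = lda_variants(trials, "force", "custom")
        assert model.shrinkage_applied
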