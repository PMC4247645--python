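"""Event-based metrics, ROC machinery, and the leave-one-out driver."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from premove.evaluation import (DetectionTrace, correct_trials_and_anticipation,
                                event_outcomes, roc)
from premove.features import test_window_times as window_grid

GRID = window_grid()


def _trace(det_times, trial=0):
    scores = np.where(np.isin(GRID, det_times), 1.0, -1.0)
    return DetectionTrace(trial=trial, times=GRID, scores=scores, threshold=0.0)


def test_event_outcomes_hand_count():
    """A detects only at -0.5 (TPE+TNE); B only at -1.5 (FPE+FNE); C never."""
    out = event_outcomes([_trace([-0.5]), _trace([-1.5]), _trace([])])
    assert (out.tpe, out.fpe, out.tne, out.fne) == (1, 1, 2, 2)
    assert out.sensitivity == pytest.approx(1 / 3)
    assert out.specificity == pytest.approx(2 / 3)


def test_window_ending_at_minus_one_counts_as_rest():
    out = event_outcomes([_trace([-1.0])])
    assert (out.tpe, out.fpe, out.tne, out.fne) == (0, 1, 0, 1)


def test_all_detections_and_no_detections():
    every = event_outcomes([_trace(list(GRID))] * 4)
    assert every.sensitivity == 1.0 and every.specificity == 0.0
    none = event_outcomes([_trace([])] * 4)
    assert none.sensitivity == 0.0 and none.specificity == 1.0


def test_event_outcomes_match_brute_force_on_random_traces():
    rng = np.random.default_rng(0)
    for _ in range(20):
        n = rng.integers(3, 30)
        scores = rng.normal(size=(n, GRID.size))
        thr = rng.normal()
        traces = [DetectionTrace(trial=i, times=GRID, scores=scores[i],
                                 threshold=thr) for i in range(n)]
        out = event_outcomes(traces)
        # independent re-derivation from raw detection sets
        tpe = fpe = tne = fne = 0
        for i in range(n):
            det = set(GRID[scores[i] >= thr])
            if any(t <= -1.0 for t in det):
                fpe += 1
            else:
                tne += 1
            if any(t > -1.0 for t in det):
                tpe += 1
            else:
                fne += 1
        assert (out.tpe, out.fpe, out.tne, out.fne) == (tpe, fpe, tne, fne)
        assert out.tpe + out.fne == n and out.fpe + out.tne == n


def test_decode_trial_threshold_extremes():
    tr = DetectionTrace(trial=0, times=GRID,
                        scores=np.linspace(-1, 1, GRID.size),
                        threshold=np.inf)
    assert tr.detections.size == 0
    tr.threshold = -np.inf
    assert tr.detections.size == 17


def test_monotone_scores_detect_a_suffix():
    tr = DetectionTrace(trial=0, times=GRID,
                        scores=np.linspace(-1, 1, GRID.size), threshold=0.3)
    det = tr.detections
    np.testing.assert_array_equal(det, GRID[GRID >= det[0]])


# ------------------------------------------------------------- ROC

def test_roc_perfect_separation_has_auc_one():
    n = 10
    scores = np.full((n, GRID.size), -1.0)
    scores[:, GRID > -1.0] = 1.0
    summary = roc(scores, GRID)
    assert summary.auc == pytest.approx(1.0)


def test_roc_endpoints_and_monotonicity():
    rng = np.random.default_rng(1)
    scores = rng.normal(size=(25, GRID.size))
    s = roc(scores, GRID)
    assert s.roc_fpr[0] == 0.0 and s.roc_tpr[0] == 0.0
    assert s.roc_fpr[-1] == 1.0 and s.roc_tpr[-1] == 1.0
    assert np.all(np.diff(s.roc_fpr) >= 0)
    assert np.all(np.diff(s.roc_tpr) >= 0)
    # event-count conservation at every threshold
    for th in s.thresholds[::50]:
        out = event_outcomes([DetectionTrace(i, GRID, scores[i], th)
                              for i in range(25)])
        assert out.tpe + out.fne == 25 and out.fpe + out.tne == 25
    assert 0.0 <= s.auc <= 1.0


@settings(max_examples=30, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000), n=st.integers(2, 40))
def test_event_counts_conserved_and_monotone_for_any_scores(seed, n):
    """For arbitrary score matrices: TPE+FNE = FPE+TNE = N at every
    threshold, and sensitivity (specificity) is monotone in the threshold."""
    rng = np.random.default_rng(seed)
    scores = rng.normal(size=(n, GRID.size))
    prev_sens, prev_spec = -1.0, 2.0
    for thr in np.sort(np.unique(scores))[::-7]:
        out = event_outcomes([DetectionTrace(i, GRID, scores[i], thr)
                              for i in range(n)])
        assert out.tpe + out.fne == n
        assert out.fpe + out.tne == n
        assert out.sensitivity >= prev_sens - 1e-12
        assert out.specificity <= prev_spec + 1e-12
        prev_sens, prev_spec = out.sensitivity, out.specificity


def test_constant_scores_flag_degenerate_roc():
    with pytest.warns(UserWarning, match="degenerate"):
        s = roc(np.zeros((5, GRID.size)), GRID)
    assert s.auc == 0.5 and s.degenerate


def test_working_point_balances_sensitivity_specificity():
    rng = np.random.default_rng(2)
    scores = rng.normal(size=(40, GRID.size))
    scores[:, GRID > -1.0] += 1.0
    s = roc(scores, GRID)
    assert abs(s.sensitivity - s.specificity) <= 0.1


def test_correct_trials_and_anticipation_definitions():
    clean_hit = np.full(GRID.size, -1.0)
    clean_hit[np.isclose(GRID, -0.375)] = 1.0
    clean_hit[np.isclose(GRID, -0.125)] = 1.0
    rest_violation = clean_hit.copy()
    rest_violation[np.isclose(GRID, -1.5)] = 1.0
    never = np.full(GRID.size, -1.0)
    pct, antic = correct_trials_and_anticipation(
        np.vstack([clean_hit, rest_violation, never]), GRID, threshold=0.0)
    assert pct == pytest.approx(100 / 3)
    assert antic == [pytest.approx(-0.375)]    # first detection, not the later one
    pct_none, antic_none = correct_trials_and_anticipation(
        never[None, :], GRID, threshold=0.0)
    assert pct_none == 0.0 and antic_none == []


# ------------------------------------------------------------- LOO driver

def test_loo_scores_every_trial_once(loo_small, strong_trials_small):
    n = strong_trials_small.n_trials
    assert loo_small.fold_scores.shape == (n, 17)
    assert len(loo_small.fold_models) == n
    assert np.isfinite(loo_small.fold_scores).all()


def test_loo_detects_strong_effect(loo_small):
    assert loo_small.auc >= 0.7
    assert loo_small.percent_correct > 20.0
    for a in loo_small.anticipations_s:
        assert -1.0 < a <= 0.0


def test_fold_models_are_deterministic(strong_trials_small, config, loo_small):
    """Refitting a fold reproduces the identical model (no hidden state)."""
    from premove.evaluation import _subset_trialset
    from premove.features import NormalizationStats, TrialFeaturePipeline
    from premove.sda import fit_sda
    from premove.spatial import fit_osf

    pipeline = TrialFeaturePipeline(strong_trials_small, config)
    train_idx = np.arange(1, pipeline.n_trials)
    betas = []
    for _ in range(2):
        train_set = _subset_trialset(pipeline, train_idx)
        osf_e = fit_osf(train_set, "ERD")
        osf_m = fit_osf(train_set, "MRCP")
        X, y = pipeline.training_matrix(pipeline.vectors(train_idx, osf_e, osf_m))
        stats = NormalizationStats.fit(X)
        betas.append(fit_sda(stats.apply(X), y, budget=len(train_idx) - 1,
                             ridge=config.sda_ridge).beta)
    np.testing.assert_array_equal(betas[0], betas[1])
    ref = loo_small.fold_models[0][0].beta
    np.testing.assert_allclose(betas[0], ref)


def test_held_out_trial_never_shapes_the_fold_model(strong_trials_small, config):
    """Scrambling the held-out trial's samples leaves the fold model fixed."""
    from premove.evaluation import _subset_trialset
    from premove.features import NormalizationStats, TrialFeaturePipeline
    from premove.sda import fit_sda
    from premove.spatial import fit_osf

    rng = np.random.default_rng(3)
    tampered = strong_trials_small.data.copy()
    tampered[0] = rng.permutation(tampered[0].ravel()).reshape(tampered[0].shape)
    betas = []
    for data in (strong_trials_small.data, tampered):
        ts = type(strong_trials_small)(
            data=data, fs=strong_trials_small.fs,
            channel_labels=list(strong_trials_small.channel_labels))
        pipeline = TrialFeaturePipeline(ts, config)
        train_idx = np.arange(1, pipeline.n_trials)
        train_set = _subset_trialset(pipeline, train_idx)
        osf_e = fit_osf(train_set, "ERD")
        osf_m = fit_osf(train_set, "MRCP")
        X, y = pipeline.training_matrix(pipeline.vectors(train_idx, osf_e, osf_m))
        stats = NormalizationStats.fit(X)
        betas.append(fit_sda(stats.apply(X), y, budget=len(train_idx) - 1,
                             ridge=config.sda_ridge).beta)
    np.testing.assert_array_equal(betas[0], betas[1])


def test_loo_requires_ten_trials(strong_trials_small, config):
    from premove.containers import TrialSet
    from premove.evaluation import loo_evaluate

    small = TrialSet(data=strong_trials_small.data[:6], fs=512.0,
                     channel_labels=list(strong_trials_small.channel_labels))
    with pytest.raises(ValueError, match="10 kept trials"):
        loo_evaluate(small, config)


def test_single_permutation_warns_and_reports_nan_sd(strong_trials_small, config):
    from premove.evaluation import loo_evaluate

    with pytest.warns(UserWarning, match="single permutation"):
        s = loo_evaluate(strong_trials_small, config, n_permutations=1, seed=9)
    assert np.isnan(s.chance_sd)
    assert np.isfinite(s.chance_mean)
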