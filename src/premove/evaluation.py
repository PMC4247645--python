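"""Trial-based leave-one-out evaluation with event-level metrics.

Each held-out trial is scored on the 17 sliding test windows over [-3, 0] s
(right edges t = -2 .. 0, step 0.125 s).  A trial contributes two events:

* rest event — the span judged on windows with t in [-2, -1] (the window
  ending exactly at -1 lies wholly in the rest phase and is a rest exemplar
  in training, so it is assigned to rest); TNE if no detection there, FPE
  otherwise.
* intention event — windows with t in (-1, 0]; TPE if any detection, FNE
  otherwise.

ROC curves sweep the detection threshold over the pooled scores of all folds;
the working point is the threshold with the smallest |sensitivity -
specificity|.  A correct trial has a clean rest event and a detected
intention event at that threshold; its anticipation is the first detection
time in (-1, 0].  The empirical chance level repeats the whole procedure
with training-window labels shuffled per fold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .containers import TrialSet
from .features import NormalizationStats, TrialFeaturePipeline, test_window_times
from .sda import SdaModel, fit_sda, score
from .spatial import fit_osf

REST_EDGE = -1.0      # window right edges <= -1 belong to the rest event


@dataclass
class DetectionTrace:
    """Per-window decision values of one trial plus a detection threshold."""

    trial: int
    times: np.ndarray
    scores: np.ndarray
    threshold: float = np.inf

    @property
    def detections(self) -> np.ndarray:
        return self.times[self.scores >= self.threshold]


@dataclass
class EventOutcome:
    tpe: int
    fpe: int
    tne: int
    fne: int

    @property
    def sensitivity(self) -> float:
        return self.tpe / max(self.tpe + self.fne, 1)

    @property
    def specificity(self) -> float:
        return self.tne / max(self.tne + self.fpe, 1)


@dataclass
class EvalSummary:
    auc: float
    roc_fpr: np.ndarray
    roc_tpr: np.ndarray
    thresholds: np.ndarray
    working_threshold: float
    sensitivity: float
    specificity: float
    percent_correct: float
    anticipations_s: list[float]
    n_trials: int
    chance_mean: float = np.nan
    chance_sd: float = np.nan
    chance_percents: list[float] = field(default_factory=list)
    fold_scores: np.ndarray | None = None
    window_times: np.ndarray | None = None
    fold_models: list = field(default_factory=list)
    degenerate: bool = False

    def to_dict(self) -> dict:
        return {
            "auc": self.auc,
            "working_threshold": self.working_threshold,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "percent_correct": self.percent_correct,
            "anticipation_mean_s": float(np.mean(self.anticipations_s))
            if self.anticipations_s else None,
            "anticipation_sd_s": float(np.std(self.anticipations_s, ddof=1))
            if len(self.anticipations_s) > 1 else None,
            "anticipations_s": list(map(float, self.anticipations_s)),
            "n_trials": self.n_trials,
            "chance_mean": None if np.isnan(self.chance_mean) else self.chance_mean,
            "chance_sd": None if np.isnan(self.chance_sd) else self.chance_sd,
            "chance_percents": list(map(float, self.chance_percents)),
            "roc": {"fpr": self.roc_fpr.tolist(), "tpr": self.roc_tpr.tolist()},
        }


def decode_trial(model: SdaModel, stats: NormalizationStats,
                 vectors: np.ndarray, times: np.ndarray | None = None,
                 threshold: float = np.inf, trial: int = -1) -> DetectionTrace:
    """Score all test windows of one trial (vectors: n_windows x features)."""
    if times is None:
        times = test_window_times()
    s = score(model, stats.apply(vectors))
    return DetectionTrace(trial=trial, times=np.asarray(times),
                          scores=np.asarray(s), threshold=threshold)


def event_outcomes(traces) -> EventOutcome:
    """Aggregate event-level confusion counts over detection traces."""
    traces = list(traces)
    if not traces:
        raise ValueError("no traces")
    tpe = fpe = tne = fne = 0
    for tr in traces:
        det = tr.detections
        rest_hit = np.any(det <= REST_EDGE)
        int_hit = np.any(det > REST_EDGE)
        fpe += rest_hit
        tne += not rest_hit
        tpe += int_hit
        fne += not int_hit
    return EventOutcome(tpe=int(tpe), fpe=int(fpe), tne=int(tne), fne=int(fne))


def _interval_maxima(scores: np.ndarray, times: np.ndarray
                     ) -> tuple[np.ndarray, np.ndarray]:
    rest = times <= REST_EDGE
    return scores[:, rest].max(axis=1), scores[:, ~rest].max(axis=1)


def roc(scores: np.ndarray, times: np.ndarray) -> EvalSummary:
    """Event-based ROC over a sweep of the pooled score range.

    scores is trials x windows.  Sensitivity/specificity per threshold follow
    from the per-trial interval maxima; AUC by the trapezoid rule; the
    working point minimizes |sensitivity - specificity| (ties: highest
    threshold).  Constant scores yield a flagged degenerate ROC with
    AUC = 0.5.
    """
    scores = np.asarray(scores, dtype=float)
    n = scores.shape[0]
    rest_max, int_max = _interval_maxima(scores, np.asarray(times))
    uniq = np.unique(scores)
    thresholds = np.concatenate([[np.inf], uniq[::-1]])
    sens = np.array([(int_max >= th).mean() for th in thresholds])
    spec = np.array([(rest_max < th).mean() for th in thresholds])
    fpr, tpr = 1 - spec, sens
    auc = float(np.trapezoid(tpr, fpr))
    degenerate = uniq.size == 1
    if degenerate:
        warnings.warn("constant scores: degenerate ROC, AUC = 0.5")
        auc = 0.5
    gap = np.abs(sens - spec)
    best = int(np.flatnonzero(gap == gap.min())[0])   # thresholds are descending
    return EvalSummary(
        auc=auc, roc_fpr=fpr, roc_tpr=tpr, thresholds=thresholds,
        working_threshold=float(thresholds[best]),
        sensitivity=float(sens[best]), specificity=float(spec[best]),
        percent_correct=np.nan, anticipations_s=[], n_trials=n,
        degenerate=degenerate)


def correct_trials_and_anticipation(scores: np.ndarray, times: np.ndarray,
                                    threshold: float
                                    ) -> tuple[float, list[float]]:
    """% of trials with a clean rest event and a detected intention event,
    plus the anticipation (first detection time in (-1, 0]) of each."""
    scores = np.asarray(scores, dtype=float)
    times = np.asarray(times)
    rest_max, int_max = _interval_maxima(scores, times)
    correct = (rest_max < threshold) & (int_max >= threshold)
    anticipations = []
    int_times = times[times > REST_EDGE]
    int_scores = scores[:, times > REST_EDGE]
    for i in np.flatnonzero(correct):
        first = int_times[np.flatnonzero(int_scores[i] >= threshold)[0]]
        anticipations.append(float(first))
    return 100.0 * correct.mean(), anticipations


def _summarize(scores: np.ndarray, times: np.ndarray) -> EvalSummary:
    summary = roc(scores, times)
    pct, antic = correct_trials_and_anticipation(scores, times,
                                                 summary.working_threshold)
    summary.percent_correct = pct
    summary.anticipations_s = antic
    summary.fold_scores = scores
    summary.window_times = np.asarray(times)
    return summary


def loo_evaluate(trials: TrialSet, config, n_permutations: int = 0,
                 seed: int | None = None, keep_models: bool = False
                 ) -> EvalSummary:
    """Trial-based leave-one-out decoding with pooled event-based metrics.

    Per fold: the two optimal spatial filters, the normalization statistics
    and the sparse discriminant are fit on the N-1 training trials only, and
    the held-out trial is scored on the 17 sliding windows.  All folds' scores
    pool into one ROC.  With ``n_permutations`` > 0 the whole procedure is
    repeated with training-window labels shuffled per fold (spatial filters
    and normalization are label-free and reused), giving the empirical chance
    level of the percent-correct metric.
    """
    pipeline = TrialFeaturePipeline(trials, config)
    n = pipeline.n_trials
    if n < 10:
        raise ValueError(f"need at least 10 kept trials, have {n}")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    times = pipeline.times
    fold_scores = np.empty((n, times.size))
    perm_scores = np.empty((n_permutations, n, times.size))
    models = []

    budget_cfg = config.sda_budget
    for i in range(n):
        train_idx = np.array([j for j in range(n) if j != i])
        train_set = _subset_trialset(pipeline, train_idx)
        osf_erd = fit_osf(train_set, "ERD", band=config.osf_erd_band,
                          init_channel=config.osf_erd_init,
                          max_iter=config.osf_max_iter, tol=config.osf_tol)
        osf_mrcp = fit_osf(train_set, "MRCP", band=config.mrcp_band,
                           init_channel=config.osf_mrcp_init,
                           max_iter=config.osf_max_iter, tol=config.osf_tol)
        vec_train = pipeline.vectors(train_idx, osf_erd, osf_mrcp)
        X, y = pipeline.training_matrix(vec_train)
        stats = NormalizationStats.fit(X)
        Xn = stats.apply(X)
        budget = budget_cfg if budget_cfg is not None else len(train_idx) - 1
        model = fit_sda(Xn, y, budget, config.sda_ridge,
                        max_iter=config.sda_max_iter, tol=config.sda_tol)
        vec_test = pipeline.vectors(np.array([i]), osf_erd, osf_mrcp)[0]
        fold_scores[i] = score(model, stats.apply(vec_test))
        if keep_models:
            models.append((model, stats, osf_erd, osf_mrcp))
        for j in range(n_permutations):
            y_perm = rng.permutation(y)
            pm = fit_sda(Xn, y_perm, budget, config.sda_ridge,
                         max_iter=config.sda_max_iter, tol=config.sda_tol)
            perm_scores[j, i] = score(pm, stats.apply(vec_test))

    summary = _summarize(fold_scores, times)
    summary.fold_models = models
    if n_permutations > 0:
        percents = [
            _summarize(perm_scores[j], times).percent_correct
            for j in range(n_permutations)
        ]
        summary.chance_percents = percents
        summary.chance_mean = float(np.mean(percents))
        if n_permutations > 1:
            summary.chance_sd = float(np.std(percents, ddof=1))
        else:
            warnings.warn("a single permutation gives no chance dispersion")
    return summary


def chance_level(trials: TrialSet, config, n_permutations: int = 10,
                 seed: int | None = None) -> tuple[float, float]:
    """Empirical chance of percent-correct by per-fold label shuffling."""
    if n_permutations < 3:
        warnings.warn("fewer than 3 permutations: chance estimate is unstable")
    summary = loo_evaluate(trials, config, n_permutations=n_permutations,
                           seed=seed)
    return summary.chance_mean, summary.chance_sd


def _subset_trialset(pipeline: TrialFeaturePipeline, idx: np.ndarray) -> TrialSet:
    return TrialSet(data=pipeline.raw[idx], fs=pipeline.fs,
                    channel_labels=list(pipeline.labels),
                    window=pipeline.trials.window,
                    movement=pipeline.trials.movement)
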