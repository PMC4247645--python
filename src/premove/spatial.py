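"""Reference-free spatial filtering: CAR, small Laplacian, and SNR-optimal filters.

The optimal spatial filter (OSF) is a per-channel weight vector w, constrained
to sum to zero (making the projection invariant to any common reference), that
extremizes the decibel signal-to-noise ratio between peri-movement epochs
([-1, 1] s) and rest epochs ([-3, -1] s) of band-filtered trials:

    SNR(w) = (1/L) sum_i 10 log10( P_Si / P_Ni ),

with P the mean squared amplitude of the projected epoch.  The SNR is
maximized for the slow MRCP band (the potential grows toward the onset) and
minimized for the 7-30 Hz ERD band (power drops before movement).  The search
starts from a CAR-for-anchor-channel vector (Cz for MRCP, C3 for ERD).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from . import montage
from .containers import TrialSet
from .signals import bandpass

_LOG10 = np.log(10.0)


def car(trials: TrialSet) -> TrialSet:
    """Common average reference: subtract the instantaneous mean over channels."""
    if trials.data.shape[1] < 2:
        raise ValueError("CAR needs at least 2 channels")
    data = trials.data - trials.data.mean(axis=1, keepdims=True)
    return _with_data(trials, data)


def laplacian(trials: TrialSet, neighbors: dict[str, list[str]] | None = None,
              ) -> TrialSet:
    """Small Laplacian: each channel minus the mean of its available neighbors.

    Channels with no neighbors are passed through unchanged (flagged by the
    returned set on attribute ``passthrough``).
    """
    labels = trials.channel_labels
    if neighbors is None:
        neighbors = montage.laplacian_neighbors(labels)
    unknown = [lb for lb in labels if lb not in neighbors]
    if unknown:
        raise KeyError(f"channels missing from montage neighbor table: {unknown}")
    idx = {lb: i for i, lb in enumerate(labels)}
    data = trials.data.copy()
    passthrough = []
    for lb in labels:
        nbrs = [idx[n] for n in neighbors[lb] if n in idx]
        if not nbrs:
            passthrough.append(lb)
            continue
        data[:, idx[lb], :] = trials.data[:, idx[lb], :] \
            - trials.data[:, nbrs, :].mean(axis=1)
    out = _with_data(trials, data)
    out.passthrough = passthrough  # type: ignore[attr-defined]
    return out


def _with_data(trials: TrialSet, data: np.ndarray) -> TrialSet:
    return TrialSet(data=data, fs=trials.fs,
                    channel_labels=list(trials.channel_labels),
                    window=trials.window, movement=trials.movement,
                    kept=trials.kept.copy(),
                    rejection_reasons=dict(trials.rejection_reasons))


# ---------------------------------------------------------------------------
# optimal spatial filter

@dataclass
class SpatialFilterProblem:
    """Signal/noise epoch pair sets for the OSF objective.

    ``signal`` and ``noise`` are L x channels x samples arrays cut from the
    same band-filtered trials: [-1, 1] s around the onset for the signal of
    interest, [-3, -1] s for the noise/rest reference.
    """

    signal: np.ndarray
    noise: np.ndarray
    mode: str                       # "maximize" (MRCP) | "minimize" (ERD)
    band: tuple[float, float]
    channel_labels: list[str]
    init_channel: str

    def __post_init__(self):
        self.signal = np.asarray(self.signal, dtype=float)
        self.noise = np.asarray(self.noise, dtype=float)
        if self.signal.shape[0] != self.noise.shape[0]:
            raise ValueError("signal and noise must have equal epoch counts")
        if self.signal.shape[1] != self.noise.shape[1]:
            raise ValueError("signal and noise must share the channel order")
        if self.mode not in ("maximize", "minimize"):
            raise ValueError("mode must be 'maximize' or 'minimize'")
        # per-epoch channel covariance (scaled): power of w.x is w' C w / n
        self._cov_s = np.einsum("lct,ldt->lcd", self.signal, self.signal) \
            / self.signal.shape[2]
        self._cov_n = np.einsum("lct,ldt->lcd", self.noise, self.noise) \
            / self.noise.shape[2]

    @property
    def n_channels(self) -> int:
        return self.signal.shape[1]


@dataclass
class SpatialFilter:
    """Sum-zero channel weights targeting one correlate (ERD or MRCP)."""

    w: np.ndarray
    target: str
    channel_labels: list[str]
    achieved_snr_db: float = np.nan
    init_snr_db: float = np.nan
    converged: bool = True

    def __post_init__(self):
        self.w = np.asarray(self.w, dtype=float)
        if abs(self.w.sum()) > 1e-8:
            raise ValueError("filter weights must sum to zero")
        if not np.any(self.w):
            raise ValueError("filter weights must not be all zero")

    def to_json(self) -> str:
        return json.dumps({
            "target": self.target, "channel_labels": self.channel_labels,
            "w": self.w.tolist(),
            "achieved_snr_db": float(self.achieved_snr_db),
            "init_snr_db": float(self.init_snr_db),
            "converged": bool(self.converged),
        })

    @classmethod
    def from_json(cls, payload: str) -> "SpatialFilter":
        d = json.loads(payload)
        return cls(w=np.array(d["w"]), target=d["target"],
                   channel_labels=d["channel_labels"],
                   achieved_snr_db=d["achieved_snr_db"],
                   init_snr_db=d["init_snr_db"], converged=d["converged"])


def car_vector(labels, anchor: str) -> np.ndarray:
    """CAR-for-channel weight vector: 1 - 1/c at the anchor, -1/c elsewhere."""
    labels = list(labels)
    c = len(labels)
    w = np.full(c, -1.0 / c)
    w[labels.index(anchor)] += 1.0
    return w


def snr_db(w: np.ndarray, problem: SpatialFilterProblem) -> float:
    """Mean over epochs of 10 log10(P_signal / P_noise) for the projection w.x."""
    w = np.asarray(w, dtype=float)
    if w.shape[0] != problem.n_channels:
        raise ValueError("weight length must equal the channel count")
    p_s = np.einsum("c,lcd,d->l", w, problem._cov_s, w)
    p_n = np.einsum("c,lcd,d->l", w, problem._cov_n, w)
    if np.any(p_n <= 0):
        raise ValueError("degenerate noise epoch: zero projected power")
    return float(np.mean(10.0 * np.log10(p_s / p_n)))


def _snr_and_grad(w: np.ndarray, problem: SpatialFilterProblem
                  ) -> tuple[float, np.ndarray]:
    sw = problem._cov_s @ w          # L x c
    nw = problem._cov_n @ w
    p_s = sw @ w
    p_n = nw @ w
    val = np.mean(10.0 * np.log10(p_s / p_n))
    grad = (20.0 / _LOG10) * np.mean(sw / p_s[:, None] - nw / p_n[:, None], axis=0)
    return float(val), grad


def build_problem(trials: TrialSet, target: str, band: tuple[float, float],
                  init_channel: str,
                  signal_window: tuple[float, float] = (-1.0, 1.0),
                  noise_window: tuple[float, float] = (-3.0, -1.0),
                  ) -> SpatialFilterProblem:
    """Band-filter kept trials and cut the signal/noise epoch pairs."""
    mode = "maximize" if target == "MRCP" else "minimize"
    data = bandpass(trials.kept_data(), band, trials.fs, axis=2)
    t = trials.times

    def cut(win):
        sel = (t >= win[0]) & (t < win[1])
        return data[:, :, sel]

    return SpatialFilterProblem(signal=cut(signal_window), noise=cut(noise_window),
                                mode=mode, band=band,
                                channel_labels=list(trials.channel_labels),
                                init_channel=init_channel)


def optimize_filter(problem: SpatialFilterProblem, target: str,
                    max_iter: int = 500, tol: float = 1e-6) -> SpatialFilter:
    """Constrained local optimization of the SNR from the CAR-anchor start."""
    w0 = car_vector(problem.channel_labels, problem.init_channel)
    init_snr = snr_db(w0, problem)
    sign = -1.0 if problem.mode == "maximize" else 1.0

    def objective(w):
        val, grad = _snr_and_grad(w, problem)
        return sign * val, sign * grad

    c = problem.n_channels
    res = minimize(objective, w0, jac=True, method="SLSQP",
                   constraints=[{"type": "eq", "fun": lambda w: w.sum(),
                                 "jac": lambda w: np.ones(c)}],
                   options={"maxiter": max_iter, "ftol": tol})
    # accept any constraint-satisfying improvement: SLSQP may stop with a
    # line-search status near a flat optimum while the iterate is fine
    w = res.x
    converged = bool(np.any(w)) and abs(w.sum()) < 1e-8
    if converged:
        achieved = snr_db(w, problem)
        improved = achieved >= init_snr if problem.mode == "maximize" \
            else achieved <= init_snr
        if not improved:
            converged = False
    if not converged:
        warnings.warn(f"OSF optimization for {target} failed; keeping the "
                      "CAR-anchor initialization")
        w, achieved = w0, init_snr
    w = w / np.linalg.norm(w)        # presentation only: SNR is scale-invariant
    w = w - w.sum() / c              # re-impose sum-zero against roundoff
    return SpatialFilter(w=w, target=target,
                         channel_labels=list(problem.channel_labels),
                         achieved_snr_db=snr_db(w, problem),
                         init_snr_db=init_snr, converged=converged)


def fit_osf(trials: TrialSet, target: str,
            band: tuple[float, float] | None = None,
            init_channel: str | None = None,
            max_iter: int = 500, tol: float = 1e-6) -> SpatialFilter:
    """Fit the optimal spatial filter for one correlate on (training) trials."""
    if target not in ("ERD", "MRCP"):
        raise ValueError("target must be 'ERD' or 'MRCP'")
    if int(trials.kept.sum()) < 5:
        raise ValueError("OSF fitting needs at least 5 kept trials")
    if band is None:
        band = (0.1, 1.0) if target == "MRCP" else (7.0, 30.0)
    if init_channel is None:
        init_channel = "Cz" if target == "MRCP" else "C3"
    problem = build_problem(trials, target, band, init_channel)
    return optimize_filter(problem, target, max_iter=max_iter, tol=tol)


def apply_filter(trials: TrialSet, filt: SpatialFilter) -> np.ndarray:
    """Project every trial onto the filter: returns trials x samples."""
    if list(trials.channel_labels) != list(filt.channel_labels):
        raise ValueError("channel order mismatch between trials and filter")
    return np.einsum("c,tcs->ts", filt.w, trials.data)
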