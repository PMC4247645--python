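"""Sparse discriminant analysis: joint feature selection and linear classification.

Two-class SDA via sparse optimal scoring (elastic-net penalized): iterate
(a) an elastic-net regression of the current class scores on the features,
with the LARS path stopped at a feature budget K, and (b) a score update from
the class-indicator structure.  For two classes the problem has a single
discriminant direction, so the iteration converges in a few passes; the
budget K must stay below the number of training trials so the within-class
covariance remains estimable.

The decision value is beta . x + intercept with higher = intention; the
intercept centers the two class score means symmetrically around 0.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from sklearn.linear_model import lars_path


@dataclass
class SdaModel:
    beta: np.ndarray                # sparse coefficient vector
    intercept: float
    budget: int
    ridge: float
    n_iter: int = 0
    converged: bool = True

    @property
    def selected(self) -> np.ndarray:
        return np.flatnonzero(self.beta)

    def to_json(self) -> str:
        nz = self.selected
        return json.dumps({
            "n_features": int(self.beta.size),
            "indices": nz.tolist(),
            "weights": self.beta[nz].tolist(),
            "intercept": self.intercept,
            "budget": self.budget, "ridge": self.ridge,
        })

    @classmethod
    def from_json(cls, payload: str) -> "SdaModel":
        d = json.loads(payload)
        beta = np.zeros(d["n_features"])
        beta[np.array(d["indices"], dtype=int)] = d["weights"]
        return cls(beta=beta, intercept=d["intercept"], budget=d["budget"],
                   ridge=d["ridge"])


def _elastic_net_budget(X: np.ndarray, y: np.ndarray, budget: int,
                        ridge: float) -> np.ndarray:
    """Elastic-net coefficients with at most `budget` nonzeros.

    Solved as a lasso on the ridge-augmented design (X stacked over
    sqrt(ridge) I); the LARS path is walked and the last point whose active
    set is within budget is kept.  Ties at the K-th entering feature resolve
    by path order (earlier-entering feature kept), which is deterministic.
    """
    n, p = X.shape
    X_aug = np.vstack([X, np.sqrt(ridge) * np.eye(p)])
    y_aug = np.concatenate([y, np.zeros(p)])
    _, _, coefs = lars_path(X_aug, y_aug, method="lasso",
                            max_iter=max(3 * budget, budget + 25))
    best = np.zeros(p)
    for j in range(coefs.shape[1]):
        if np.count_nonzero(coefs[:, j]) <= budget:
            best = coefs[:, j]
        else:
            break
    return best


def fit_sda(X: np.ndarray, y: np.ndarray, budget: int, ridge: float = 1e-2,
            max_iter: int = 30, tol: float = 1e-6) -> SdaModel:
    """Fit the sparse discriminant on normalized features.

    X is windows x features, y in {0 (rest), 1 (intention)}; `budget` is the
    maximum number of selected features (must be >= 1 and < n windows).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    n, p = X.shape
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError("both classes must be present")
    if budget < 1:
        raise ValueError("budget must be >= 1")
    if budget >= n:
        raise ValueError("budget must be smaller than the number of windows")

    is_int = y == 1
    pi_rest = float(np.mean(~is_int))
    pi_int = float(np.mean(is_int))
    # optimal scores orthogonal to the trivial constant, unit D-norm
    theta = np.array([-np.sqrt(pi_int / pi_rest), np.sqrt(pi_rest / pi_int)])

    beta = np.zeros(p)
    n_iter = 0
    converged = False
    for n_iter in range(1, max_iter + 1):
        target = np.where(is_int, theta[1], theta[0])
        beta_new = _elastic_net_budget(X, target, budget, ridge)
        if not np.any(beta_new):
            beta = beta_new
            break
        scores = X @ beta_new
        raw = np.array([scores[~is_int].mean(), scores[is_int].mean()])
        raw = raw - (pi_rest * raw[0] + pi_int * raw[1])
        norm = np.sqrt(pi_rest * raw[0] ** 2 + pi_int * raw[1] ** 2)
        if norm > 0:
            theta_new = raw / norm
            if theta_new[1] < 0:
                theta_new = -theta_new
        else:
            theta_new = theta
        delta = np.linalg.norm(beta_new - beta) / max(np.linalg.norm(beta_new), 1e-12)
        beta, theta = beta_new, theta_new
        if delta < tol:
            converged = True
            break

    scores = X @ beta
    if np.any(beta):
        m_rest = scores[~is_int].mean()
        m_int = scores[is_int].mean()
        if m_int < m_rest:              # enforce higher-score = intention
            beta = -beta
            m_rest, m_int = -m_rest, -m_int
        intercept = -(m_rest + m_int) / 2.0
    else:
        intercept = 0.0
    return SdaModel(beta=beta, intercept=float(intercept), budget=budget,
                    ridge=ridge, n_iter=n_iter, converged=converged)


def score(model: SdaModel, x: np.ndarray) -> np.ndarray | float:
    """Decision value(s) beta . x + intercept; accepts a vector or a batch."""
    x = np.asarray(x, dtype=float)
    if x.shape[-1] != model.beta.size:
        raise ValueError("feature length mismatch")
    return x @ model.beta + model.intercept


def selection_map(models, index_map) -> dict:
    """Fraction of models selecting each feature, projected onto the
    channel x frequency (ERD) and channel x time (MRCP) grids."""
    models = list(models)
    if not models:
        raise ValueError("no models")
    p = models[0].beta.size
    if len(index_map) != p or any(m.beta.size != p for m in models):
        raise ValueError("models and index map are inconsistent")
    freq = np.zeros(p)
    for m in models:
        freq += m.beta != 0
    freq /= len(models)
    erd: dict[str, dict[float, float]] = {}
    mrcp: dict[str, dict[float, float]] = {}
    for f, (kind, ch, coord) in zip(freq, index_map):
        target = erd if kind == "erd" else mrcp
        target.setdefault(ch, {})[coord] = float(f)
    return {"per_feature": freq, "erd": erd, "mrcp": mrcp}
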