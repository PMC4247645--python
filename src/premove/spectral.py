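"""Batched Burg autoregressive spectral estimation.

Burg's method fits an AR(p) model by minimizing forward+backward prediction
error through a Levinson-style reflection-coefficient recursion; its power
spectrum P(f) = e / |1 + sum_k a_k exp(-2 pi i f k / fs)|^2 gives the sharp,
short-window band-power estimates used for the ERD features (1 s windows,
order 16, evaluated at integer frequencies).

Implemented in-house and vectorized over a leading batch axis so thousands of
sliding windows are fit in one pass; a zero-variance window yields an
all-zero spectrum instead of failing.
"""

from __future__ import annotations

import numpy as np

_EPS = 1e-12


def burg(x: np.ndarray, order: int) -> tuple[np.ndarray, np.ndarray]:
    """AR coefficients and residual variance by Burg's method.

    x is (..., n); returns (a, e) with a of shape (..., order) such that the
    model is A(z) = 1 + a_1 z^-1 + ... + a_p z^-p, and e the driving-noise
    variance.  Batches with (numerically) zero variance get a = 0, e = 0.
    """
    x = np.asarray(x, dtype=float)
    batch_shape = x.shape[:-1]
    n = x.shape[-1]
    if order >= n:
        raise ValueError("order must be smaller than the window length")
    x = x.reshape(-1, n)
    B = x.shape[0]

    a = np.zeros((B, order))
    e = np.mean(x ** 2, axis=1)
    dead = e < _EPS                      # constant windows: defined zero spectrum
    f = x.copy()
    b = x.copy()
    for m in range(order):
        fm = f[:, m + 1:]
        bm = b[:, :n - m - 1]
        den = np.sum(fm ** 2 + bm ** 2, axis=1)
        num = -2.0 * np.sum(fm * bm, axis=1)
        k = np.where(den > _EPS, num / np.maximum(den, _EPS), 0.0)
        if m > 0:
            a[:, :m] = a[:, :m] + k[:, None] * a[:, m - 1::-1]
        a[:, m] = k
        fm_new = fm + k[:, None] * bm
        bm_new = bm + k[:, None] * fm
        f[:, m + 1:] = fm_new
        b[:, :n - m - 1] = bm_new
        e = e * (1.0 - k ** 2)
    a[dead] = 0.0
    e[dead] = 0.0
    return a.reshape(*batch_shape, order), e.reshape(batch_shape)


def ar_psd(a: np.ndarray, e: np.ndarray, freqs, fs: float) -> np.ndarray:
    """Evaluate the AR power spectrum at `freqs` (Hz); shape (..., len(freqs)).

    Scaled as a two-sided density e / (fs |A|^2); the absolute scale cancels in
    normalized features but is consistent across windows.
    """
    a = np.asarray(a, dtype=float)
    e = np.asarray(e, dtype=float)
    freqs = np.asarray(freqs, dtype=float)
    order = a.shape[-1]
    k = np.arange(1, order + 1)
    basis = np.exp(-2j * np.pi * np.outer(freqs, k) / fs)   # F x p
    denom = np.abs(1.0 + a @ basis.T) ** 2                   # ... x F
    zero = e[..., None] <= 0
    out = np.where(zero, 0.0, e[..., None] / (fs * np.maximum(denom, _EPS)))
    return out
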