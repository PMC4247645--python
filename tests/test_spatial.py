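"""CAR, small Laplacian, and the SNR-optimal spatial filter."""

import numpy as np
import pytest

from premove import montage
from premove.containers import TrialSet
from premove.spatial import (SpatialFilter, SpatialFilterProblem, apply_filter,
                             car, car_vector, fit_osf, laplacian,
                             optimize_filter, snr_db)


def _trialset(data, labels=None):
    n_ch = data.shape[1]
    labels = labels or list(montage.CHANNELS_32[:n_ch])
    n = data.shape[2]
    return TrialSet(data=data, fs=512.0, channel_labels=labels,
                    window=(-3.0, n / 512.0 - 3.0))


# ---------------------------------------------------------------- CAR

def test_car_zeroes_identical_channels():
    data = np.ones((2, 4, 512))
    out = car(_trialset(data))
    np.testing.assert_allclose(out.data, 0.0)


def test_car_two_channels_closed_form():
    rng = np.random.default_rng(0)
    a, b = rng.normal(size=(2, 512))
    out = car(_trialset(np.stack([a, b])[None, :, :], labels=["C3", "C4"]))
    np.testing.assert_allclose(out.data[0, 0], (a - b) / 2)
    np.testing.assert_allclose(out.data[0, 1], (b - a) / 2)


def test_car_channel_sum_is_zero():
    rng = np.random.default_rng(1)
    out = car(_trialset(rng.normal(size=(3, 32, 512))))
    np.testing.assert_allclose(out.data.sum(axis=1), 0.0, atol=1e-9)


def test_car_requires_two_channels():
    with pytest.raises(ValueError):
        car(_trialset(np.zeros((1, 1, 512)), labels=["Cz"]))


# ---------------------------------------------------------------- Laplacian

def test_laplacian_uniform_field_zero_at_fully_neighbored_channels():
    ts = _trialset(np.ones((1, 32, 512)), labels=list(montage.CHANNELS_32))
    out = laplacian(ts)
    nbrs = montage.laplacian_neighbors(montage.CHANNELS_32)
    for ch, ns in nbrs.items():
        if len(ns) == 4:
            np.testing.assert_allclose(out.data[0, ts.channel_index(ch)], 0.0)


def test_laplacian_isolated_source_passes_through():
    ts = _trialset(np.zeros((1, 32, 512)), labels=list(montage.CHANNELS_32))
    s = np.sin(np.arange(512) / 20.0)
    ts.data[0, ts.channel_index("C3")] = s
    out = laplacian(ts)
    np.testing.assert_allclose(out.data[0, ts.channel_index("C3")], s)


def test_laplacian_matches_table_lookup_oracle():
    rng = np.random.default_rng(2)
    ts = _trialset(rng.normal(size=(2, 32, 256)),
                   labels=list(montage.CHANNELS_32))
    out = laplacian(ts)
    nbrs = montage.laplacian_neighbors(montage.CHANNELS_32)
    idx = {lb: i for i, lb in enumerate(ts.channel_labels)}
    for ch in ("C3", "Cz", "AFz", "P4", "FC5"):
        expected = ts.data[:, idx[ch], :].copy()
        if nbrs[ch]:
            expected -= np.mean([ts.data[:, idx[n], :] for n in nbrs[ch]],
                                axis=0)
        np.testing.assert_allclose(out.data[:, idx[ch], :], expected)


def test_laplacian_unknown_channel_errors():
    ts = _trialset(np.zeros((1, 2, 512)), labels=["C3", "NOPE"])
    with pytest.raises(KeyError, match="NOPE"):
        laplacian(ts)


# ---------------------------------------------------------------- SNR

def _problem(signal, noise, mode="maximize"):
    labels = [f"ch{i}" for i in range(signal.shape[1])]
    return SpatialFilterProblem(signal=signal, noise=noise, mode=mode,
                                band=(7.0, 30.0), channel_labels=labels,
                                init_channel="ch0")


def test_snr_identical_epochs_is_zero_db():
    rng = np.random.default_rng(3)
    x = rng.normal(size=(4, 3, 128))
    prob = _problem(x, x.copy())
    assert snr_db(np.array([1.0, 0.5, -0.2]), prob) == pytest.approx(0.0)


def test_snr_hand_example_six_db():
    signal = np.array([[[2.0, 2.0], [0.0, 0.0]]])
    noise = np.array([[[1.0, 1.0], [0.0, 0.0]]])
    prob = _problem(signal, noise)
    assert snr_db(np.array([1.0, -1.0]), prob) == pytest.approx(
        10 * np.log10(4.0), abs=1e-9)


def test_snr_scale_invariance():
    rng = np.random.default_rng(4)
    prob = _problem(rng.normal(size=(5, 4, 64)), rng.normal(size=(5, 4, 64)))
    w = rng.normal(size=4)
    assert snr_db(2 * w, prob) == pytest.approx(snr_db(w, prob))
    assert snr_db(-w, prob) == pytest.approx(snr_db(w, prob))


def test_snr_degenerate_noise_errors():
    prob_ok = _problem(np.ones((1, 2, 8)), np.ones((1, 2, 8)))
    with pytest.raises(ValueError):
        snr_db(np.array([1.0, -1.0]), prob_ok)  # projected noise power 0


# ---------------------------------------------------------------- OSF

def test_car_anchor_vector_sums_to_zero():
    w = car_vector(list(montage.CHANNELS_32), "Cz")
    assert w.sum() == pytest.approx(0.0, abs=1e-12)
    assert w[list(montage.CHANNELS_32).index("Cz")] == pytest.approx(1 - 1 / 32)


def test_filter_invariants_enforced():
    with pytest.raises(ValueError, match="sum to zero"):
        SpatialFilter(w=np.array([1.0, 0.0]), target="ERD",
                      channel_labels=["a", "b"])
    with pytest.raises(ValueError, match="zero"):
        SpatialFilter(w=np.zeros(2), target="ERD", channel_labels=["a", "b"])


def _planted_problem(mode, n_ch=8, L=12, seed=0, planted=None):
    """Epoch pairs with a burst planted in a single channel's signal window."""
    rng = np.random.default_rng(seed)
    planted = n_ch // 2 if planted is None else planted
    signal = rng.normal(size=(L, n_ch, 256))
    noise = rng.normal(size=(L, n_ch, 256))
    if mode == "maximize":
        signal[:, planted, :] += 4 * np.sin(np.arange(256) / 5.0)
    else:
        signal[:, planted, :] *= 0.2
    labels = [f"ch{i}" for i in range(n_ch)]
    return SpatialFilterProblem(signal=signal, noise=noise, mode=mode,
                                band=(7.0, 30.0), channel_labels=labels,
                                init_channel=f"ch{planted}")


@pytest.mark.parametrize("mode,target", [("maximize", "MRCP"),
                                         ("minimize", "ERD")])
def test_osf_improves_monotonically_from_init(mode, target):
    prob = _planted_problem(mode)
    filt = optimize_filter(prob, target)
    assert filt.w.sum() == pytest.approx(0.0, abs=1e-8)
    if mode == "maximize":
        assert filt.achieved_snr_db >= filt.init_snr_db
    else:
        assert filt.achieved_snr_db <= filt.init_snr_db


def test_osf_finds_planted_channel():
    prob = _planted_problem("maximize", planted=3)
    filt = optimize_filter(prob, "MRCP")
    assert int(np.argmax(np.abs(filt.w))) == 3


def test_osf_matches_grid_search_oracle_on_three_channels():
    """On a 3-channel problem the sum-zero constraint leaves 2 free weights;
    a coarse grid over directions bounds the optimum independently."""
    prob = _planted_problem("maximize", n_ch=3)
    filt = optimize_filter(prob, "MRCP")
    best = -np.inf
    for theta in np.linspace(0, np.pi, 721, endpoint=False):
        a, b = np.cos(theta), np.sin(theta)
        w = np.array([a, b, -a - b])
        if np.abs(w).max() < 1e-9:
            continue
        best = max(best, snr_db(w, prob))
    assert filt.achieved_snr_db == pytest.approx(best, abs=0.5)
    assert filt.achieved_snr_db >= best - 0.5


def test_fit_osf_validates_inputs(strong_trials_small):
    with pytest.raises(ValueError, match="target"):
        fit_osf(strong_trials_small, "XXX")
    few = TrialSet(data=strong_trials_small.data[:3], fs=512.0,
                   channel_labels=list(strong_trials_small.channel_labels))
    with pytest.raises(ValueError, match="5 kept trials"):
        fit_osf(few, "ERD")


# ---------------------------------------------------------------- apply

def test_apply_one_hot_copies_channel():
    rng = np.random.default_rng(5)
    ts = _trialset(rng.normal(size=(3, 4, 128)), labels=["a", "b", "c", "d"])
    w = np.array([0.0, 1.0, 0.0, 0.0])
    w -= w.mean()
    filt = SpatialFilter(w=w, target="ERD", channel_labels=["a", "b", "c", "d"])
    manual = np.einsum("c,tcs->ts", w, ts.data)
    np.testing.assert_allclose(apply_filter(ts, filt), manual)


def test_apply_car_anchor_equals_channel_after_car():
    rng = np.random.default_rng(6)
    ts = _trialset(rng.normal(size=(2, 32, 128)),
                   labels=list(montage.CHANNELS_32))
    w = car_vector(ts.channel_labels, "Cz")
    filt = SpatialFilter(w=w, target="MRCP",
                         channel_labels=list(ts.channel_labels))
    carred = car(ts)
    np.testing.assert_allclose(apply_filter(ts, filt),
                               carred.data[:, ts.channel_index("Cz"), :],
                               atol=1e-12)


def test_sum_zero_filters_ignore_common_offset():
    rng = np.random.default_rng(7)
    ts = _trialset(rng.normal(size=(2, 8, 128)),
                   labels=[f"ch{i}" for i in range(8)])
    w = rng.normal(size=8)
    w -= w.mean()
    filt = SpatialFilter(w=w, target="ERD",
                         channel_labels=list(ts.channel_labels))
    shifted = _trialset(ts.data + 42.0, labels=list(ts.channel_labels))
    np.testing.assert_allclose(apply_filter(ts, filt),
                               apply_filter(shifted, filt), atol=1e-9)


def test_apply_channel_mismatch_errors():
    ts = _trialset(np.zeros((1, 3, 64)), labels=["a", "b", "c"])
    filt = SpatialFilter(w=np.array([0.5, -0.5]), target="ERD",
                         channel_labels=["a", "b"])
    with pytest.raises(ValueError):
        apply_filter(ts, filt)
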