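"""Electrode montage: 10/10 grid coordinates, Gaussian scalp maps, Laplacian neighbors.

The montage is the 32-electrode subset of the international 10/10 system used
for upper-limb movement studies: a fronto-parietal grid centred on the motor
cortex (rows AF/F/FC/C/CP/P, columns 5/3/1/z/2/4/6), referenced at acquisition
time to the left earlobe.  Channels are laid out on an integer grid so that
"nearest neighbor" (small Laplacian) and scalp-map distances are well defined
without a spherical head model.
"""

from __future__ import annotations

import numpy as np

#: Ordered 32-channel montage (row-major, left to right).
CHANNELS_32: tuple[str, ...] = (
    "AFz",
    "F3", "F1", "Fz", "F2", "F4",
    "FC5", "FC3", "FC1", "FCz", "FC2", "FC4", "FC6",
    "C5", "C3", "C1", "Cz", "C2", "C4", "C6",
    "CP5", "CP3", "CP1", "CPz", "CP2", "CP4", "CP6",
    "P3", "P1", "Pz", "P2", "P4",
)

#: The 8 central-midline channels whose slow time courses feed the MRCP features.
MRCP_CHANNELS: tuple[str, ...] = ("FCz", "FC2", "C1", "Cz", "C2", "CP1", "CPz", "CP2")

_ROW_Y = {"AF": 3.0, "F": 2.0, "FC": 1.0, "C": 0.0, "CP": -1.0, "P": -2.0}
_COL_X = {"5": -3.0, "3": -2.0, "1": -1.0, "z": 0.0, "2": 1.0, "4": 2.0, "6": 3.0}


def channel_position(label: str) -> tuple[float, float]:
    """2-D grid coordinate (x: left negative, y: frontal positive) of a label."""
    for row in sorted(_ROW_Y, key=len, reverse=True):
        if label.startswith(row):
            col = label[len(row):]
            if col in _COL_X:
                return _COL_X[col], _ROW_Y[row]
    raise KeyError(f"channel {label!r} not on the 10/10 grid")


def positions(labels) -> np.ndarray:
    return np.array([channel_position(lb) for lb in labels], dtype=float)


def scalp_map(labels, peak: str, sigma: float = 1.3) -> np.ndarray:
    """Gaussian spatial mixing map peaked at `peak`, evaluated at `labels`.

    Used by the synthetic generator to project a cortical source to channels;
    sigma is in inter-electrode grid units.
    """
    pos = positions(labels)
    px, py = channel_position(peak)
    d2 = (pos[:, 0] - px) ** 2 + (pos[:, 1] - py) ** 2
    return np.exp(-d2 / (2.0 * sigma ** 2))


def laplacian_neighbors(labels) -> dict[str, list[str]]:
    """Small-Laplacian neighbor sets: the orthogonally adjacent grid channels.

    Each channel's neighbors are the (up to 4) channels one grid step away
    along x or y that are present in `labels`; edge channels keep whatever
    subset exists.
    """
    labels = list(labels)
    pos = {lb: channel_position(lb) for lb in labels}
    by_pos = {v: k for k, v in pos.items()}
    out: dict[str, list[str]] = {}
    for lb, (x, y) in pos.items():
        nbrs = []
        for dx, dy in ((-1.0, 0.0), (1.0, 0.0), (0.0, -1.0), (0.0, 1.0)):
            cand = by_pos.get((x + dx, y + dy))
            if cand is not None:
                nbrs.append(cand)
        out[lb] = nbrs
    return out


def erd_feature_channels(labels, drop=()) -> list[str]:
    """Channels feeding the band-power (ERD) features: the fronto-central (FCx),
    central (Cx) and centro-parietal (CPx) rows, minus any dropped channels."""
    dropset = set(drop)
    out = []
    for lb in labels:
        if lb in dropset:
            continue
        # parse the row prefix longest-first ("CP" before "C")
        row = next(
            (r for r in sorted(_ROW_Y, key=len, reverse=True)
             if lb.startswith(r) and lb[len(r):] in _COL_X),
            None,
        )
        if row in ("FC", "C", "CP"):
            out.append(lb)
    return out
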