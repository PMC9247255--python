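"""Electrode montage utilities for the standard 10-20/10-10 system.

Positions come from MNE's idealized 10-05 montage; only channel labels and
relative Euclidean distances are used (nearest-neighbour Laplacian, distance-
based source mixing), so the exact head model is irrelevant.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

#: The 30 fronto-parietal channels used for connectivity analysis:
#: frontal (F1-F6), fronto-central (FC1-FC6), central (C1-C6),
#: centro-parietal (CP1-CP6) and parietal (P1-P6) lines.
CONNECTIVITY_CHANNELS: tuple[str, ...] = tuple(
    f"{line}{i}" for line in ("F", "FC", "C", "CP", "P") for i in range(1, 7)
)

#: Default simulation montage: the connectivity subset plus the midline,
#: 35 channels in total.  C3/C4/Cz are included (C3 = "C3" in the C line).
DEFAULT_MONTAGE: tuple[str, ...] = CONNECTIVITY_CHANNELS + (
    "Fz",
    "FCz",
    "Cz",
    "CPz",
    "Pz",
)


@lru_cache(maxsize=1)
def _standard_positions() -> dict[str, np.ndarray]:
    """3-D electrode positions (meters) from MNE's 10-05 template."""
    import warnings

    import mne

    for name in ("standard_1005", "colin27_1005"):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", FutureWarning)
                montage = mne.channels.make_standard_montage(name)
            break
        except ValueError:
            continue
    else:  # pragma: no cover - template always present in supported MNE
        raise RuntimeError("no standard 10-05 montage template available")
    return {ch: pos.copy() for ch, pos in montage.get_positions()["ch_pos"].items()}


def channel_positions(channels: list[str] | tuple[str, ...]) -> np.ndarray:
    """Return an (n_channels, 3) array of electrode positions in meters.

    Raises
    ------
    KeyError
        If a label is not a standard 10-05 channel name.
    """
    table = _standard_positions()
    missing = [ch for ch in channels if ch not in table]
    if missing:
        raise KeyError(f"unknown channel label(s): {missing}")
    return np.array([table[ch] for ch in channels])


def neighbor_indices(
    channels: list[str] | tuple[str, ...], k: int = 4
) -> dict[str, list[int]]:
    """Indices of each channel's ``k`` nearest montage neighbours.

    Used by the Hjorth surface Laplacian.  Raises ``ValueError`` when a
    channel has fewer than two neighbours available.
    """
    pos = channel_positions(channels)
    n = len(channels)
    if n - 1 < 2:
        raise ValueError("montage too small: every channel needs >= 2 neighbors")
    dist = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=-1)
    np.fill_diagonal(dist, np.inf)
    k_eff = min(k, n - 1)
    out: dict[str, list[int]] = {}
    for i, ch in enumerate(channels):
        order = np.argsort(dist[i])[:k_eff]
        out[ch] = [int(j) for j in order]
    return out


def mixing_matrix(
    channels: list[str] | tuple[str, ...], sigma: float = 0.04
) -> np.ndarray:
    """Row-normalized nonnegative channel x source mixing weights.

    Gaussian kernel of inter-electrode Euclidean distance with length scale
    ``sigma`` (meters); one background source under each electrode.
    """
    pos = channel_positions(channels)
    dist = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=-1)
    w = np.exp(-(dist**2) / (2.0 * sigma**2))
    return w / w.sum(axis=1, keepdims=True)


def source_projection(
    channels: list[str] | tuple[str, ...], source_channel: str, sigma: float = 0.03
) -> np.ndarray:
    """Weights projecting a focal cortical source under ``source_channel``
    onto every montage channel (Gaussian falloff, peak weight 1)."""
    pos = channel_positions(channels)
    src = channel_positions([source_channel])[0]
    dist = np.linalg.norm(pos - src[None, :], axis=-1)
    return np.exp(-(dist**2) / (2.0 * sigma**2))
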