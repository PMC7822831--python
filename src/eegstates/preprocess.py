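"""Filtering, average reference, 2-s epoching and bad-epoch rejection.

This is a deliberately minimal, fully specified preprocessing chain:
zero-phase Butterworth band-pass, average reference, fixed-length epochs,
and an epoch-level bad-channel-ratio rule (< 0.25 keeps the epoch) with a
distance-weighted nearest-neighbour interpolation of bad channels in kept
epochs. Artifact *detection* is not performed here — bad-channel masks are
an input.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .montage import Montage, Recording

__all__ = ["EpochedRecording", "bandpass_filter", "rereference_average", "epoch_and_reject"]

REJECT_RATIO = 0.25
EPOCH_SECONDS = 2.0


@dataclass
class EpochedRecording:
    """Consecutive equal-length epochs of one recording."""

    epochs: np.ndarray  # (n_epochs, n_channels, n_samples_per_epoch)
    kept: np.ndarray  # (n_epochs,) bool
    srate: float
    band: tuple[float, float] | None = None
    condition: str = "rest"
    run: int = 0

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]

    def kept_epochs(self) -> np.ndarray:
        return self.epochs[self.kept]


def bandpass_filter(rec: Recording, band) -> Recording:
    """Zero-phase 4th-order Butterworth band-pass (forward–backward)."""
    lo, hi = float(band[0]), float(band[1])
    nyq = rec.srate / 2.0
    if not 0 < lo < hi < nyq:
        raise ValueError(f"band {band} outside (0, {nyq}) Hz")
    sos = signal.butter(4, [lo, hi], btype="bandpass", fs=rec.srate, output="sos")
    return rec.copy_with(signal.sosfiltfilt(sos, rec.data, axis=1))


def rereference_average(rec: Recording) -> Recording:
    """Subtract the instantaneous mean across channels (idempotent)."""
    if rec.n_channels < 2:
        raise ValueError("average reference needs at least 2 channels")
    return rec.copy_with(rec.data - rec.data.mean(axis=0, keepdims=True))


def _interpolate_bad(
    epoch: np.ndarray, bad: np.ndarray, montage: Montage, n_neighbors: int = 4
) -> np.ndarray:
    """Replace bad channels by the inverse-distance mean of nearest good ones."""
    good = np.flatnonzero(~bad)
    if good.size == 0:
        return epoch
    out = epoch.copy()
    pos = montage.positions
    for ch in np.flatnonzero(bad):
        d = np.linalg.norm(pos[good] - pos[ch], axis=1)
        order = np.argsort(d)[:n_neighbors]
        w = 1.0 / np.maximum(d[order], 1e-6)
        out[ch] = (w[:, None] * epoch[good[order]]).sum(axis=0) / w.sum()
    return out


def epoch_and_reject(
    rec: Recording,
    bad_channel_mask: np.ndarray | None = None,
    epoch_seconds: float = EPOCH_SECONDS,
    reject_ratio: float = REJECT_RATIO,
    montage: Montage | None = None,
    band: tuple[float, float] | None = None,
) -> EpochedRecording:
    """Cut consecutive non-overlapping epochs and apply the bad-channel rule.

    ``bad_channel_mask`` is (n_epochs, n_channels) boolean (or None for no
    bad channels). An epoch is kept iff #bad/#channels < ``reject_ratio``;
    bad channels in kept epochs are interpolated (requires ``montage``).
    Trailing partial epochs are dropped.
    """
    n_len = int(round(epoch_seconds * rec.srate))
    if abs(epoch_seconds * rec.srate - n_len) > 1e-9:
        raise ValueError("epoch length must be an integer number of samples")
    n_epochs = rec.n_samples // n_len
    if n_epochs < 1:
        raise ValueError(f"recording shorter than one {epoch_seconds}-s epoch")
    epochs = rec.data[:, : n_epochs * n_len].reshape(rec.n_channels, n_epochs, n_len)
    epochs = np.ascontiguousarray(epochs.transpose(1, 0, 2))

    if bad_channel_mask is None:
        kept = np.ones(n_epochs, dtype=bool)
    else:
        bad = np.asarray(bad_channel_mask, dtype=bool)
        if bad.shape != (n_epochs, rec.n_channels):
            raise ValueError("bad_channel_mask must be (n_epochs, n_channels)")
        ratio = bad.mean(axis=1)
        kept = ratio < reject_ratio
        for e in np.flatnonzero(kept):
            if bad[e].any():
                if montage is None:
                    raise ValueError("montage required to interpolate bad channels")
                epochs[e] = _interpolate_bad(epochs[e], bad[e], montage)

    return EpochedRecording(
        epochs=epochs,
        kept=kept,
        srate=rec.srate,
        band=band,
        condition=rec.condition,
        run=rec.run,
    )
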