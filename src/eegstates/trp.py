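"""Task-related power (TRP) in alpha sub-bands.

Per channel i, condition k and run j the log band power during the task is
referenced against the rest block recorded at the start of the experiment:

    TRP_ki = mean_j [ log(Pow_i, activation)_kj - log(Pow_i, reference)_kj ]

Band power is the composite-Simpson integral of the Welch PSD (Hann taper,
1000-sample windows, 500-sample overlap at 500 Hz) between the band edges.
Channel TRP is aggregated into the five cortical areas per hemisphere;
midline channels never contribute.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal
from scipy.integrate import simpson

from .montage import AREAS, Montage
from .preprocess import EpochedRecording

__all__ = ["BandPower", "TRPTable", "welch_psd", "band_power", "compute_trp", "aggregate_regions"]

LOWER_ALPHA = (8.0, 10.0)
UPPER_ALPHA = (10.0, 12.0)


@dataclass
class BandPower:
    power: np.ndarray  # (n_channels,), µV²
    band: tuple[float, float]
    condition: str = "rest"
    run: int = 0

    def __post_init__(self) -> None:
        self.power = np.asarray(self.power, dtype=float)
        if np.any(self.power < 0):
            raise ValueError("band power must be non-negative")


@dataclass
class TRPTable:
    """Log power change per channel (rows) and task condition (columns)."""

    values: pd.DataFrame
    band: tuple[float, float]


def welch_psd(
    epoched: EpochedRecording, win: int = 1000, overlap: int = 500, nfft: int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """One-sided Welch PSD (density scaling, Hann) over kept epochs.

    Kept epochs are concatenated in time before segmenting. The spectrum is
    evaluated on a 4× zero-padded grid by default: the spectral resolution
    stays srate/win, but the finer grid lets composite-Simpson band
    integrals capture narrow spectral lines accurately. Returns
    ``(freqs, psd)`` with ``psd`` of shape (n_channels, n_freqs).
    """
    kept = epoched.kept_epochs()
    if kept.shape[0] == 0:
        raise ValueError("no kept epochs")
    data = np.concatenate(list(kept), axis=1)
    if win > data.shape[1]:
        raise ValueError(f"window of {win} samples exceeds available {data.shape[1]} samples")
    if overlap >= win:
        raise ValueError("overlap must be smaller than the window")
    freqs, psd = signal.welch(
        data,
        fs=epoched.srate,
        window="hann",
        nperseg=win,
        noverlap=overlap,
        nfft=nfft if nfft is not None else 4 * win,
        scaling="density",
        detrend="constant",
        axis=1,
    )
    return freqs, psd


def band_power(
    freqs: np.ndarray, psd: np.ndarray, band, condition: str = "rest", run: int = 0
) -> BandPower:
    """Composite-Simpson integral of the PSD between the band edges (inclusive)."""
    lo, hi = float(band[0]), float(band[1])
    if lo < freqs[0] or hi > freqs[-1]:
        raise ValueError(f"band {band} outside PSD range [{freqs[0]}, {freqs[-1]}] Hz")
    sel = (freqs >= lo - 1e-12) & (freqs <= hi + 1e-12)
    if sel.sum() < 3:
        raise ValueError("Simpson integration needs at least 3 frequency bins in band")
    power = simpson(np.atleast_2d(psd)[:, sel], x=freqs[sel], axis=1)
    return BandPower(power=power, band=(lo, hi), condition=condition, run=run)


def compute_trp(
    activation: dict[str, list[BandPower]],
    reference: BandPower,
    channels: tuple[str, ...],
    log_base: str = "e",
) -> TRPTable:
    """Mean over runs of log(activation) − log(reference), per channel/condition."""
    log = np.log if log_base == "e" else np.log10
    ref = reference.power
    _check_positive(ref, channels, "reference")
    cols = {}
    for cond, runs in activation.items():
        if len(runs) < 1:
            raise ValueError(f"no runs for condition {cond!r}")
        vals = []
        for bp in runs:
            _check_positive(bp.power, channels, f"{cond} run {bp.run}")
            vals.append(log(bp.power) - log(ref))
        cols[cond] = np.mean(vals, axis=0)
    values = pd.DataFrame(cols, index=list(channels))
    values.index.name = "channel"
    return TRPTable(values=values, band=reference.band)


def _check_positive(power: np.ndarray, channels, what: str) -> None:
    bad = np.flatnonzero(power <= 0)
    if bad.size:
        names = [channels[i] for i in bad[:5]]
        raise ValueError(f"non-positive band power in {what} at channels {names}")


def aggregate_regions(trp: TRPTable, montage: Montage) -> pd.DataFrame:
    """Mean TRP per (area, hemisphere, condition); midline excluded by design."""
    rows = []
    for (area, hemi), chans in sorted(montage.groups().items()):
        if len(chans) == 0:
            raise ValueError(f"empty electrode group {(area, hemi)}")
        sub = trp.values.loc[list(chans)]
        for cond in trp.values.columns:
            rows.append(
                {
                    "area": area,
                    "hemisphere": hemi,
                    "condition": cond,
                    "band_lo": trp.band[0],
                    "band_hi": trp.band[1],
                    "value": float(sub[cond].mean()),
                }
            )
    df = pd.DataFrame(rows)
    df["area"] = pd.Categorical(df["area"], categories=list(AREAS), ordered=True)
    df = df.sort_values(["condition", "hemisphere", "area"]).reset_index(drop=True)
    df["area"] = df["area"].astype(str)
    return df
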