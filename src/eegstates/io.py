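"""Readers and writers for the interchange recording format.

The native interchange format is a channels×samples ``.npy`` matrix next to
a JSON sidecar carrying channel names, sampling rate, condition and run.
BrainVision (``.vhdr``) and EDF files are read through mne. On reading,
channels are always reordered into canonical montage order so topography
vectors are comparable across every stage.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .montage import Montage, Recording, make_montage

__all__ = ["write_recording", "read_recording"]

SIDECAR_SUFFIX = ".json"
DATA_SUFFIX = ".npy"


def write_recording(rec: Recording, prefix) -> Path:
    """Write `rec` as ``<prefix>.npy`` + ``<prefix>.json``; returns the sidecar path."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    np.save(prefix.with_suffix(DATA_SUFFIX), rec.data)
    sidecar = {
        "channels": list(rec.channel_names),
        "srate": rec.srate,
        "condition": rec.condition,
        "run": rec.run,
        "units": "uV",
        "data_file": prefix.with_suffix(DATA_SUFFIX).name,
    }
    path = prefix.with_suffix(SIDECAR_SUFFIX)
    path.write_text(json.dumps(sidecar, indent=1, sort_keys=True))
    return path


def _reorder(data: np.ndarray, names: list[str], montage: Montage) -> np.ndarray:
    have = set(names)
    want = set(montage.channels)
    missing = sorted(want - have)
    if missing:
        raise ValueError(f"recording is missing {len(missing)} montage channels: {missing}")
    unknown = sorted(have - want)
    if unknown:
        raise ValueError(f"recording contains unknown channels: {unknown}")
    lut = {n: i for i, n in enumerate(names)}
    return data[[lut[ch] for ch in montage.channels]]


def read_recording(
    path,
    format: str = "matrix",
    montage: Montage | None = None,
    condition: str | None = None,
    run: int | None = None,
    expected_srate: float | None = None,
) -> Recording:
    """Read a recording and reorder its channels to montage order.

    ``format`` is one of ``matrix`` (npy + JSON sidecar), ``brainvision``
    (``.vhdr``) or ``edf``. ``condition``/``run`` override whatever the file
    carries. A mismatch between ``expected_srate`` and the file is a hard
    error.
    """
    montage = montage or make_montage()
    path = Path(path)
    if format == "matrix":
        sidecar = json.loads(path.with_suffix(SIDECAR_SUFFIX).read_text())
        data = np.load(path.parent / sidecar["data_file"])
        names = list(sidecar["channels"])
        srate = float(sidecar["srate"])
        condition = condition if condition is not None else sidecar.get("condition", "rest")
        run = run if run is not None else int(sidecar.get("run", 0))
    elif format in ("brainvision", "edf"):
        import mne

        reader = mne.io.read_raw_brainvision if format == "brainvision" else mne.io.read_raw_edf
        raw = reader(path, preload=True, verbose="error")
        raw.pick("eeg")
        data = raw.get_data() * 1e6  # volts -> µV
        names = list(raw.ch_names)
        srate = float(raw.info["sfreq"])
        condition = condition or "rest"
        run = run if run is not None else 0
    else:
        raise ValueError(f"unknown format {format!r}")

    if expected_srate is not None and abs(srate - expected_srate) > 1e-9:
        raise ValueError(f"sampling rate {srate} Hz does not match expected {expected_srate} Hz")
    data = _reorder(np.asarray(data, dtype=float), names, montage)
    return Recording(
        data=data,
        srate=srate,
        channel_names=montage.channels,
        condition=condition,
        run=run,
    )
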