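"""63-channel 10-10 montage with cortical-area / hemisphere groups.

The analysis cap is a 64-channel actiCHamp layout referenced to Cz, leaving
63 analysis channels. 52 of them are assigned to five cortical areas
(frontal, central, temporal, parietal, occipital) per hemisphere — 9/4/5/4/4
electrodes each; the remaining 11 (five midline, six inferior lateral) carry
no area and are excluded from region-aggregated statistics.

The printed right-hemisphere area lists of the source protocol contain FC4
twice (frontal and central) and never mention FC6; the groups here resolve
the duplicate by left/right symmetry (FC1,FC3 frontal / FC5 central on the
left mirrors to FC2,FC4 frontal / FC6 central on the right). Pass a custom
``groups`` mapping to :func:`make_montage` to override.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AREAS",
    "CONDITIONS",
    "TASK_CONDITIONS",
    "DEFAULT_GROUPS",
    "Montage",
    "Recording",
    "make_montage",
]

AREAS = ("frontal", "central", "temporal", "parietal", "occipital")

#: experiment conditions; "rest" is the reference block.
CONDITIONS = ("rest", "generation", "evolution", "evaluation")
TASK_CONDITIONS = ("generation", "evolution", "evaluation")

DEFAULT_GROUPS: dict[tuple[str, str], tuple[str, ...]] = {
    ("frontal", "left"): ("Fp1", "AF3", "AF7", "F1", "F3", "F5", "F7", "FC1", "FC3"),
    ("central", "left"): ("FC5", "C1", "C3", "C5"),
    ("temporal", "left"): ("FT7", "T7", "TP7", "CP5", "P5"),
    ("parietal", "left"): ("CP1", "CP3", "P1", "P3"),
    ("occipital", "left"): ("PO3", "PO7", "P7", "O1"),
    ("frontal", "right"): ("Fp2", "AF4", "AF8", "F2", "F4", "F6", "F8", "FC2", "FC4"),
    ("central", "right"): ("FC6", "C2", "C4", "C6"),
    ("temporal", "right"): ("FT8", "T8", "TP8", "CP6", "P6"),
    ("parietal", "right"): ("CP2", "CP4", "P2", "P4"),
    ("occipital", "right"): ("PO4", "PO8", "P8", "O2"),
}

#: channels recorded but assigned to no cortical area.
MIDLINE_CHANNELS = ("Fz", "CPz", "Pz", "POz", "Oz")
EXTRA_LATERAL_CHANNELS = ("FT9", "FT10", "TP9", "TP10", "PO9", "PO10")


def _hemisphere_of(name: str) -> str:
    if name.endswith("z"):
        return "midline"
    digits = "".join(c for c in name if c.isdigit())
    return "left" if int(digits) % 2 == 1 else "right"


@dataclass(frozen=True)
class Montage:
    """Ordered channel set with unit-sphere positions and group labels."""

    channels: tuple[str, ...]
    positions: np.ndarray  # (n_channels, 3), unit sphere
    area: dict[str, str] = field(repr=False)  # channel -> area or "none"
    hemisphere: dict[str, str] = field(repr=False)  # channel -> left/right/midline

    def __post_init__(self) -> None:
        if len(self.channels) != self.positions.shape[0]:
            raise ValueError("positions/channels length mismatch")
        seen: set[str] = set()
        for (_, _), chans in self.groups().items():
            dup = seen.intersection(chans)
            if dup:
                raise ValueError(f"channels in two groups: {sorted(dup)}")
            seen.update(chans)

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    def index(self, names) -> np.ndarray:
        """Row indices of `names` in montage order."""
        lut = {c: i for i, c in enumerate(self.channels)}
        try:
            return np.array([lut[n] for n in names], dtype=int)
        except KeyError as exc:
            raise KeyError(f"unknown channel {exc.args[0]!r}") from None

    def groups(self) -> dict[tuple[str, str], tuple[str, ...]]:
        """(area, hemisphere) -> electrode names, midline never included."""
        out: dict[tuple[str, str], list[str]] = {}
        for ch in self.channels:
            a, h = self.area[ch], self.hemisphere[ch]
            if a == "none" or h == "midline":
                continue
            out.setdefault((a, h), []).append(ch)
        return {k: tuple(v) for k, v in out.items()}

    def group(self, area: str, hemisphere: str) -> tuple[str, ...]:
        return self.groups()[(area, hemisphere)]

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(
            {
                "name": self.channels,
                "x": self.positions[:, 0],
                "y": self.positions[:, 1],
                "z": self.positions[:, 2],
                "area": [self.area[c] for c in self.channels],
                "hemisphere": [self.hemisphere[c] for c in self.channels],
            }
        ).to_csv(path, index=False)


@functools.lru_cache(maxsize=4)
def _standard_positions() -> dict[str, np.ndarray]:
    """Unit-sphere electrode positions from the 10-05 standard layout."""
    import warnings

    import mne

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        std = mne.channels.make_standard_montage("standard_1005")
    pos = std.get_positions()["ch_pos"]
    out = {}
    for name, xyz in pos.items():
        v = np.asarray(xyz, dtype=float)
        n = np.linalg.norm(v)
        out[name] = v / n if n > 0 else v
    return out


@functools.lru_cache(maxsize=4)
def make_montage(groups: tuple | None = None) -> Montage:
    """The fixed 63-channel analysis montage.

    Parameters
    ----------
    groups
        Optional override of the area×hemisphere electrode mapping, given as
        a tuple of ((area, hemisphere), (channels...)) pairs. Defaults to
        :data:`DEFAULT_GROUPS`.
    """
    gmap = dict(groups) if groups is not None else DEFAULT_GROUPS
    grouped: list[str] = [ch for chans in gmap.values() for ch in chans]
    channels = tuple(grouped) + MIDLINE_CHANNELS + EXTRA_LATERAL_CHANNELS
    if len(set(channels)) != 63:
        raise ValueError(f"montage must contain 63 unique channels, got {len(set(channels))}")

    area = {ch: "none" for ch in channels}
    for (a, _), chans in gmap.items():
        for ch in chans:
            area[ch] = a
    hemisphere = {ch: _hemisphere_of(ch) for ch in channels}

    std = _standard_positions()
    positions = np.stack([std[ch] for ch in channels])
    return Montage(channels=channels, positions=positions, area=area, hemisphere=hemisphere)


@dataclass
class Recording:
    """Continuous multichannel EEG in µV, channels in montage order."""

    data: np.ndarray  # (n_channels, n_samples), µV
    srate: float
    channel_names: tuple[str, ...]
    condition: str = "rest"
    run: int = 0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be channels × samples")
        if self.data.shape[0] != len(self.channel_names):
            raise ValueError("data row count must equal channel count")
        if self.srate <= 0:
            raise ValueError("srate must be positive")
        if self.data.shape[1] < 1:
            raise ValueError("recording must contain at least one sample")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.srate

    def copy_with(self, data: np.ndarray) -> "Recording":
        return Recording(
            data=data,
            srate=self.srate,
            channel_names=self.channel_names,
            condition=self.condition,
            run=self.run,
        )
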