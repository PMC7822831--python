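"""Synthetic study generator.

Emulates the structure of a loosely controlled 4-condition creativity
experiment: per participant one 3-min rest block plus 3 runs × 3 task
conditions (idea generation, idea evolution, evaluation) recorded at 500 Hz
on the 63-channel montage. The EEG model is a sequence of semi-stable
microstate templates driven by an alpha-band (8–12 Hz) amplitude envelope,
plus 1/f-shaped and white noise:

    X[:, t] = a(t) * template[label(t)] + pink(t) + white(t),  avg-referenced

The state intensity a(t) = gain * (A sin(2π f t + φ) + B b(t)) combines an
alpha oscillation (amplitude A) with a broadband 1–30 Hz component b(t)
(amplitude B); the polarity-inverting sinusoid gives the scalp field two
GFP peaks per alpha cycle and the broadband part densifies them, as in real
EEG. Because the whole intensity scales with the condition gain, in-band
power scales with gain² and region TRP against rest equals ln(gain²) up to
noise. Condition effects enter through that gain, through per-condition
class coverage weights, and through truncated-normal task completion times
whose defaults are the behavioural means of the emulated study (generation
54.047 s, evolution 92.785 s, evaluation 16.476 s).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats as sps

from ._rng import seed_stream
from .montage import CONDITIONS, TASK_CONDITIONS, Montage, Recording, make_montage
from .topographies import average_reference_maps, orthogonal_topographies, unit_norm_maps

__all__ = [
    "StudyConfig",
    "GroundTruth",
    "StudyDataset",
    "sample_label_sequence",
    "render_recording",
    "generate_study",
]


def _default_coverage_bias() -> dict[str, np.ndarray]:
    # mild condition-dependent class preferences: C/D favoured at rest,
    # A/E favoured during the tasks, F suppressed during idea evolution.
    return {
        "rest": np.array([0.140, 0.167, 0.210, 0.190, 0.130, 0.163]),
        "generation": np.array([0.190, 0.167, 0.170, 0.160, 0.180, 0.133]),
        "evolution": np.array([0.190, 0.167, 0.190, 0.160, 0.180, 0.113]),
        "evaluation": np.array([0.180, 0.167, 0.150, 0.160, 0.170, 0.173]),
    }


def _default_alpha_gain() -> dict[str, float]:
    # alpha power decreases from rest to every task (gain < 1), least so
    # during idea evolution, most during evaluation.
    return {"rest": 1.0, "generation": 0.70, "evolution": 0.85, "evaluation": 0.65}


@dataclass
class StudyConfig:
    """Study conditions of the synthetic experiment."""

    n_participants: int = 28
    n_runs: int = 3
    srate: float = 500.0
    n_classes: int = 6
    rest_seconds: float = 180.0
    mean_run_duration_ms: float = 120.0
    alpha_freq_hz: float = 10.0
    alpha_freq_jitter_hz: float = 1.0  # participant alpha drawn uniformly ± this
    alpha_amp: float = 50.0  # µV intensity of a unit-norm template
    broadband_amp: float = 18.0  # µV broadband (1-30 Hz) intensity component
    noise_sd: float = 2.0  # µV per channel (pink), white adds 0.5× this
    template_jitter_corr: float = 0.95  # participant vs group template
    condition_alpha_gain: dict[str, float] = field(default_factory=_default_alpha_gain)
    condition_coverage_bias: dict[str, np.ndarray] = field(default_factory=_default_coverage_bias)
    time_means: dict[str, float] = field(
        default_factory=lambda: {"generation": 54.047, "evolution": 92.785, "evaluation": 16.476}
    )
    time_sds: dict[str, float] = field(
        default_factory=lambda: {"generation": 23.5, "evolution": 27.5, "evaluation": 5.8}
    )
    max_task_seconds: float = 180.0
    min_task_seconds: float = 6.0
    #: cap on rendered EEG length per task block (None = the completion time);
    #: behavioural completion times are unaffected.
    max_render_seconds: float | None = None

    def null_effects(self) -> "StudyConfig":
        """Copy with all condition effects switched off (null study)."""
        k = self.n_classes
        return replace(
            self,
            condition_alpha_gain={c: 1.0 for c in CONDITIONS},
            condition_coverage_bias={c: np.full(k, 1.0 / k) for c in CONDITIONS},
        )


@dataclass
class GroundTruth:
    """Planted quantities every downstream stage should recover."""

    templates: np.ndarray  # (K, n_channels) group-level, unit norm, avg ref
    participant_templates: dict[int, np.ndarray]
    label_sequences: dict[tuple[int, str, int], np.ndarray]
    mean_run_duration_ms: float
    condition_alpha_gain: dict[str, float]
    condition_coverage_bias: dict[str, np.ndarray]
    time_means: dict[str, float]
    time_sds: dict[str, float]


@dataclass
class StudyDataset:
    montage: Montage
    recordings: dict[tuple[int, str, int], Recording]  # (participant, condition, run)
    completion_times: pd.DataFrame  # participant, condition, run, seconds
    ground_truth: GroundTruth
    config: StudyConfig


def _stationary_run_freq(draw: np.ndarray) -> np.ndarray:
    """Stationary run-class frequencies of the no-self-repeat chain."""
    K = draw.shape[0]
    P = np.tile(draw, (K, 1))
    np.fill_diagonal(P, 0.0)
    P /= P.sum(axis=1, keepdims=True)
    pi = np.full(K, 1.0 / K)
    for _ in range(500):
        nxt = pi @ P
        nxt /= nxt.sum()
        if np.max(np.abs(nxt - pi)) < 1e-14:
            break
        pi = nxt
    return pi


def _compensated_weights(target: np.ndarray) -> np.ndarray:
    """Draw weights whose no-self-repeat stationary coverage equals `target`."""
    draw = target.copy()
    for _ in range(100):
        pi = _stationary_run_freq(draw)
        draw = draw * target / np.maximum(pi, 1e-12)
        draw /= draw.sum()
        if np.max(np.abs(pi - target)) < 1e-12:
            break
    return draw


def sample_label_sequence(
    K: int,
    weights,
    mean_dur_ms: float,
    n_samples: int,
    srate: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Piecewise-constant class labels with gamma(shape=2) run lengths.

    Run classes are drawn with no immediate self-transition (for K > 1);
    the drawing distribution is adjusted so the long-run class coverage of
    the chain equals `weights`. The sequence is truncated to exactly
    `n_samples`.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if mean_dur_ms <= 0:
        raise ValueError("mean duration must be positive")
    weights = np.asarray(weights, dtype=float)
    if weights.shape != (K,) or not np.isclose(weights.sum(), 1.0):
        raise ValueError("weights must be a length-K probability vector")
    if K == 1:
        return np.zeros(n_samples, dtype=int)

    draw = _compensated_weights(weights)
    labels = np.empty(n_samples, dtype=int)
    pos = 0
    prev = -1
    mean_samples = mean_dur_ms / 1000.0 * srate
    while pos < n_samples:
        w = draw.copy()
        if prev >= 0:
            w[prev] = 0.0
            w = w / w.sum()
        cls = int(rng.choice(K, p=w))
        length = max(1, int(round(rng.gamma(shape=2.0, scale=mean_samples / 2.0))))
        labels[pos : pos + length] = cls
        pos += length
        prev = cls
    return labels


def _pink_noise(n_channels: int, n_samples: int, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance 1/f-power-shaped noise, independent per channel."""
    white = rng.standard_normal((n_channels, n_samples))
    spec = np.fft.rfft(white, axis=1)
    freqs = np.fft.rfftfreq(n_samples, d=1.0)
    scale = np.zeros_like(freqs)
    scale[1:] = 1.0 / np.sqrt(freqs[1:])
    pink = np.fft.irfft(spec * scale, n=n_samples, axis=1)
    sd = pink.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return pink / sd


def render_recording(
    labels: np.ndarray,
    templates: np.ndarray,
    alpha_gain: float,
    noise_sd: float,
    srate: float,
    rng: np.random.Generator,
    alpha_freq_hz: float = 10.0,
    alpha_amp: float = 50.0,
    broadband_amp: float = 18.0,
    condition: str = "rest",
    run: int = 0,
    channel_names: tuple[str, ...] | None = None,
) -> Recording:
    """Render a label sequence into a noisy average-referenced recording."""
    from scipy import signal as sg

    templates = np.asarray(templates, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if labels.min() < 0 or labels.max() >= templates.shape[0]:
        raise ValueError("labels index outside template set")
    n_ch = templates.shape[1]
    if channel_names is not None and len(channel_names) != n_ch:
        raise ValueError("template/montage size mismatch")
    n = labels.shape[0]
    t = np.arange(n) / srate
    phase = rng.uniform(0, 2 * np.pi)
    intensity = alpha_amp * np.sin(2 * np.pi * alpha_freq_hz * t + phase)
    if broadband_amp > 0 and n > 50:
        sos = sg.butter(4, [1.0, min(30.0, 0.45 * srate)], btype="bandpass", fs=srate, output="sos")
        b = sg.sosfiltfilt(sos, rng.standard_normal(n))
        sd = b.std()
        if sd > 0:
            intensity = intensity + broadband_amp * b / sd
    envelope = alpha_gain * intensity
    signal = templates[labels].T * envelope  # (n_ch, n)
    if noise_sd > 0:
        signal = signal + noise_sd * _pink_noise(n_ch, n, rng)
        signal = signal + 0.5 * noise_sd * rng.standard_normal((n_ch, n))
    signal = signal - signal.mean(axis=0, keepdims=True)
    names = channel_names if channel_names is not None else tuple(f"ch{i}" for i in range(n_ch))
    return Recording(data=signal, srate=srate, channel_names=names, condition=condition, run=run)


def _jitter_templates(templates: np.ndarray, corr: float, rng: np.random.Generator) -> np.ndarray:
    """Rotate each template toward a random direction so corr(new, old) ≈ `corr`."""
    out = np.empty_like(templates)
    sin = np.sqrt(max(0.0, 1.0 - corr**2))
    for k, g in enumerate(templates):
        u = rng.standard_normal(g.shape[0])
        u -= u.mean()
        u -= (u @ g) * g
        u /= np.linalg.norm(u)
        out[k] = corr * g + sin * u
    return unit_norm_maps(average_reference_maps(out))


def _draw_time(cond: str, cfg: StudyConfig, rng: np.random.Generator) -> float:
    mu, sd = cfg.time_means[cond], cfg.time_sds[cond]
    lo, hi = cfg.min_task_seconds, cfg.max_task_seconds
    a, b = (lo - mu) / sd, (hi - mu) / sd
    return float(sps.truncnorm.rvs(a, b, loc=mu, scale=sd, random_state=rng))


def generate_study(config: StudyConfig | None = None, seed: int = 0) -> StudyDataset:
    """Generate the full synthetic study with stored ground truth."""
    cfg = config or StudyConfig()
    if cfg.n_participants < 2:
        raise ValueError("need at least 2 participants for paired statistics")
    montage = make_montage()
    group_templates = orthogonal_topographies(montage, cfg.n_classes)

    participant_templates: dict[int, np.ndarray] = {}
    label_sequences: dict[tuple[int, str, int], np.ndarray] = {}
    recordings: dict[tuple[int, str, int], Recording] = {}
    times_rows = []

    for pid in range(1, cfg.n_participants + 1):
        rng_p = seed_stream(seed, f"participant/{pid}")
        ptempl = _jitter_templates(group_templates, cfg.template_jitter_corr, rng_p)
        participant_templates[pid] = ptempl
        alpha_freq = cfg.alpha_freq_hz + cfg.alpha_freq_jitter_hz * rng_p.uniform(-1, 1)

        blocks: list[tuple[str, int, float]] = [("rest", 0, cfg.rest_seconds)]
        for run in range(1, cfg.n_runs + 1):
            for cond in TASK_CONDITIONS:
                rng_t = seed_stream(seed, f"time/{pid}/{cond}/{run}")
                seconds = _draw_time(cond, cfg, rng_t)
                times_rows.append(
                    {"participant": pid, "condition": cond, "run": run, "seconds": seconds}
                )
                blocks.append((cond, run, seconds))

        for cond, run, seconds in blocks:
            render_seconds = seconds
            # the cap shortens rendered task EEG only; rest is the reference
            # block and keeps its configured length
            if cfg.max_render_seconds is not None and cond != "rest":
                render_seconds = min(render_seconds, cfg.max_render_seconds)
            n_samples = int(round(render_seconds * cfg.srate))
            rng_r = seed_stream(seed, f"eeg/{pid}/{cond}/{run}")
            labels = sample_label_sequence(
                cfg.n_classes,
                cfg.condition_coverage_bias[cond],
                cfg.mean_run_duration_ms,
                n_samples,
                cfg.srate,
                rng_r,
            )
            rec = render_recording(
                labels,
                ptempl,
                alpha_gain=cfg.condition_alpha_gain[cond],
                noise_sd=cfg.noise_sd,
                srate=cfg.srate,
                rng=rng_r,
                alpha_freq_hz=alpha_freq,
                alpha_amp=cfg.alpha_amp,
                broadband_amp=cfg.broadband_amp,
                condition=cond,
                run=run,
                channel_names=montage.channels,
            )
            label_sequences[(pid, cond, run)] = labels
            recordings[(pid, cond, run)] = rec

    truth = GroundTruth(
        templates=group_templates,
        participant_templates=participant_templates,
        label_sequences=label_sequences,
        mean_run_duration_ms=cfg.mean_run_duration_ms,
        condition_alpha_gain=dict(cfg.condition_alpha_gain),
        condition_coverage_bias={k: np.asarray(v) for k, v in cfg.condition_coverage_bias.items()},
        time_means=dict(cfg.time_means),
        time_sds=dict(cfg.time_sds),
    )
    return StudyDataset(
        montage=montage,
        recordings=recordings,
        completion_times=pd.DataFrame(times_rows),
        ground_truth=truth,
        config=cfg,
    )
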