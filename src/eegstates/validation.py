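"""Recovery and calibration diagnostics for the synthetic-study pipeline.

These functions measure how well the analysis chain recovers the planted
ground truth of a synthetic study (templates, class coverages, durations,
alpha gains) and calibrate the randomization statistics on known null and
planted-effect designs. They are used by the test suite and by the
reproduction script.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.optimize import linear_sum_assignment

from . import microstates as ms
from .montage import CONDITIONS, TASK_CONDITIONS
from .stats import tanova

__all__ = [
    "match_templates",
    "template_recovery",
    "parameter_recovery",
    "trp_recovery",
    "tanova_null_rejection_rate",
    "tanova_power",
    "kmeans_brute_force_gap",
]


def match_templates(estimated: np.ndarray, truth: np.ndarray):
    """One-to-one |corr|-maximal matching; returns (mapping est->true, corrs)."""
    C = np.abs(ms._correlation_matrix(estimated, truth))
    rows, cols = linear_sum_assignment(-C)
    return {int(r): int(c) for r, c in zip(rows, cols)}, C[rows, cols]


def template_recovery(model: ms.MicrostateModel, truth_templates: np.ndarray) -> float:
    """Smallest |spatial correlation| of the matched template pairs."""
    _, corrs = match_templates(model.templates, truth_templates)
    return float(np.min(corrs))


def parameter_recovery(study, micro) -> dict:
    """Worst relative errors of per-condition coverage and duration recovery."""
    truth = study.ground_truth
    mapping, _ = match_templates(micro["global_model"].templates, truth.templates)
    K = truth.templates.shape[0]
    per_cond_cov: dict[str, list] = {c: [] for c in CONDITIONS}
    per_cond_dur: dict[str, list] = {c: [] for c in CONDITIONS}
    for (pid, cond, run), par in micro["parameters"].items():
        cov = np.zeros(K)
        dur = np.full(K, np.nan)
        for est_k, true_k in mapping.items():
            cov[true_k] = par.coverage[est_k]
            dur[true_k] = par.duration_ms[est_k]
        per_cond_cov[cond].append(cov)
        per_cond_dur[cond].append(dur)

    cov_err = dur_err = 0.0
    details = {}
    for cond in CONDITIONS:
        if not per_cond_cov[cond]:
            continue
        est_cov = np.mean(per_cond_cov[cond], axis=0)
        est_dur = np.nanmean(np.stack(per_cond_dur[cond]), axis=0)
        w = truth.condition_coverage_bias[cond]
        ce = np.abs(est_cov - w) / w
        de = np.abs(est_dur - truth.mean_run_duration_ms) / truth.mean_run_duration_ms
        cov_err = max(cov_err, float(np.max(ce)))
        dur_err = max(dur_err, float(np.nanmax(de)))
        details[cond] = {"coverage": est_cov, "duration_ms": est_dur}
    return {
        "coverage_max_rel_err": cov_err,
        "duration_max_rel_err": dur_err,
        "per_condition": details,
    }


def trp_recovery(study, broadband_epochs, band=(8.0, 12.0)) -> dict:
    """Region TRP vs ln(gain²) for each task condition, pooled over regions.

    Computed from Welch spectra of the 1–30 Hz epochs integrated over the
    alpha band, so the estimate is independent of each participant's exact
    alpha frequency.
    """
    from .trp import aggregate_regions, band_power, compute_trp, welch_psd

    montage = study.montage
    worst = 0.0
    per_condition = {}
    pids = sorted({k[0] for k in broadband_epochs})
    region_vals = {c: [] for c in TASK_CONDITIONS}
    for pid in pids:
        f, psd = welch_psd(broadband_epochs[(pid, "rest", 0)])
        ref = band_power(f, psd, band, condition="rest")
        activation = {}
        for cond in TASK_CONDITIONS:
            runs = []
            for key, ep in sorted(broadband_epochs.items()):
                if key[0] == pid and key[1] == cond:
                    ff, pp = welch_psd(ep)
                    runs.append(band_power(ff, pp, band, condition=cond, run=key[2]))
            activation[cond] = runs
        table = compute_trp(activation, ref, montage.channels)
        regions = aggregate_regions(table, montage)
        for cond in TASK_CONDITIONS:
            region_vals[cond].append(regions.query("condition == @cond")["value"].mean())
    for cond in TASK_CONDITIONS:
        est = float(np.mean(region_vals[cond]))
        target = float(np.log(study.ground_truth.condition_alpha_gain[cond] ** 2))
        rel = abs(est - target) / abs(target)
        worst = max(worst, rel)
        per_condition[cond] = {"estimate": est, "target": target, "rel_err": rel}
    return {"max_rel_err": worst, "per_condition": per_condition}


def tanova_null_rejection_rate(
    n_replicates: int = 500,
    n_subjects: int = 28,
    n_levels: int = 3,
    n_channels: int = 63,
    n_perm: int = 200,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Type-I error of the one-factor TANOVA on independent Gaussian maps."""
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_replicates):
        maps = rng.standard_normal((n_subjects, n_levels, n_channels))
        p = tanova(maps, n_perm=n_perm, seed=int(rng.integers(2**31)))["condition"].p
        hits += p < alpha
    return hits / n_replicates


def tanova_power(
    n_replicates: int = 50,
    n_subjects: int = 28,
    n_channels: int = 63,
    shift_corr: float = 0.8,
    noise_sd: float = 1.0,
    n_perm: int = 200,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Rejection rate with one condition's mean map rotated to corr ≈ 0.8.

    Three conditions share a common mean topography except the last, whose
    mean is rotated to the requested spatial correlation; participant maps
    add unit-variance Gaussian noise per channel.
    """
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_replicates):
        base = rng.standard_normal(n_channels)
        base = (base - base.mean()) / base.std()
        ortho = rng.standard_normal(n_channels)
        ortho -= ortho.mean()
        ortho -= (ortho @ base) / (base @ base) * base
        ortho = ortho / ortho.std()
        shifted = shift_corr * base + np.sqrt(1 - shift_corr**2) * ortho
        means = np.stack([base, base, shifted])
        maps = means[None] + noise_sd * rng.standard_normal((n_subjects, 3, n_channels))
        p = tanova(maps, n_perm=n_perm, seed=int(rng.integers(2**31)))["condition"].p
        hits += p < alpha
    return hits / n_replicates


def kmeans_brute_force_gap(
    templates: np.ndarray, n_instances: int = 5, n_maps: int = 8, seed: int = 0
) -> float:
    """Worst gap between best-of-restarts F and the enumerated K=2 optimum."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for i in range(n_instances):
        maps = []
        for _ in range(n_maps):
            g = templates[rng.integers(0, 2)]
            maps.append(
                rng.choice([-1.0, 1.0]) * g * rng.uniform(5, 15)
                + 3.0 * rng.standard_normal(g.size)
            )
        maps = np.stack(maps)
        maps -= maps.mean(axis=1, keepdims=True)
        model = ms.fit_modified_kmeans(maps, 2, restarts=50, seed=int(rng.integers(2**31)))
        oracle = _brute_force_two_class(maps)
        worst = max(worst, abs(model.F - oracle) / max(oracle, 1e-12))
    return worst


def _brute_force_two_class(maps: np.ndarray) -> float:
    n, n_s = maps.shape
    best = np.inf
    for bits in itertools.product([0, 1], repeat=n - 1):
        assign = np.array((0,) + bits)
        if len(set(assign)) < 2:
            continue
        total = 0.0
        for k in (0, 1):
            sub = maps[assign == k]
            scatter = sub.T @ sub
            total += float(np.einsum("ij,ij->", sub, sub)) - float(
                np.linalg.eigvalsh(scatter)[-1]
            )
        best = min(best, total / (n * (n_s - 1)))
    return best
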