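"""EEG microstate segmentation: GFP peaks, polarity-invariant modified
k-means, cross-validation model selection, hierarchical permutation
alignment, backfitting, and coverage/duration parameters.

Notation (N_S channels, N_T peak maps, N_K classes): the modified k-means
minimizes

    F = 1/(N_T (N_S - 1)) Σ_t || V_t - Σ_k a_kt Γ_k ||²

with unit-norm templates Γ_k, assignment by argmax_k (V_t·Γ_k)² (polarity
ignored) and intensity a_kt = V_t·Γ_k for the assigned class only. The
number of classes is chosen by the cross-validation criterion

    CV = [ Σ_t (V_t·V_t − (V_t·Γ_{label(t)})²) / (N_T (N_S−1)) ]
         · ((N_S−1)/(N_S−1−N_K))²

Spatial correlation between maps is the Pearson correlation across
channels of average-referenced maps; its absolute value is used wherever
polarity is ignored.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np

from .preprocess import EpochedRecording
from .topographies import average_reference_maps, unit_norm_maps

__all__ = [
    "TopographySet",
    "MicrostateModel",
    "Segmentation",
    "MicrostateParameters",
    "gfp_curve",
    "detect_gfp_peaks",
    "extract_peak_maps",
    "spatial_correlation",
    "fit_modified_kmeans",
    "cv_criterion",
    "gev",
    "select_k",
    "align_and_average",
    "aggregate_hierarchy",
    "backfit_labels",
    "compute_parameters",
    "sort_classes",
    "load_reference_maps",
]


# ---------------------------------------------------------------------------
# GFP and peak maps


def gfp_curve(data: np.ndarray) -> np.ndarray:
    """Global field power: spatial (population) SD per sample.

    `data` is channels × samples; returns one value per sample.
    """
    data = np.asarray(data, dtype=float)
    if data.shape[0] < 2:
        raise ValueError("GFP needs at least 2 channels")
    return data.std(axis=0, ddof=0)


def detect_gfp_peaks(gfp: np.ndarray) -> np.ndarray:
    """Strict local maxima of a GFP curve; plateaus count once, at their
    first sample; the first and last samples are never peaks."""
    gfp = np.asarray(gfp, dtype=float)
    n = gfp.shape[0]
    if n < 3:
        return np.array([], dtype=int)
    peaks = []
    t = 1
    while t < n - 1:
        if gfp[t] > gfp[t - 1]:
            # walk over a possible plateau
            u = t
            while u + 1 < n and gfp[u + 1] == gfp[t]:
                u += 1
            if u < n - 1 and gfp[u + 1] < gfp[t]:
                peaks.append(t)
            t = u + 1
        else:
            t += 1
    return np.array(peaks, dtype=int)


@dataclass
class TopographySet:
    """Average-referenced maps at GFP peaks, with their epoch provenance."""

    maps: np.ndarray  # (n_maps, n_channels)
    epoch_index: np.ndarray  # (n_maps,)
    sample_index: np.ndarray  # (n_maps,) within-epoch sample
    source: tuple = ()  # e.g. (participant, condition, run)

    @property
    def n_maps(self) -> int:
        return self.maps.shape[0]

    @property
    def n_channels(self) -> int:
        return self.maps.shape[1]


def extract_peak_maps(epoched: EpochedRecording, source: tuple = ()) -> TopographySet:
    """GFP-peak maps of every kept epoch (epochs are assumed 1–30 Hz data)."""
    maps, eidx, sidx = [], [], []
    for e in np.flatnonzero(epoched.kept):
        epoch = epoched.epochs[e]
        peaks = detect_gfp_peaks(gfp_curve(epoch))
        for p in peaks:
            maps.append(epoch[:, p])
            eidx.append(e)
            sidx.append(p)
    if not maps:
        return TopographySet(
            maps=np.empty((0, epoched.epochs.shape[1])),
            epoch_index=np.array([], dtype=int),
            sample_index=np.array([], dtype=int),
            source=source,
        )
    return TopographySet(
        maps=average_reference_maps(np.stack(maps)),
        epoch_index=np.array(eidx),
        sample_index=np.array(sidx),
        source=source,
    )


# ---------------------------------------------------------------------------
# Modified k-means and model selection


@dataclass
class MicrostateModel:
    templates: np.ndarray  # (N_K, N_S) unit-norm, average-referenced
    F: float  # converged cost of the best restart
    cv: float | None = None
    level: str = "run"
    source: tuple = ()
    labels: tuple[str, ...] = field(default_factory=tuple)  # class letters after sorting

    @property
    def n_classes(self) -> int:
        return self.templates.shape[0]


def spatial_correlation(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson correlation across channels of two maps."""
    a = np.asarray(a, dtype=float) - np.mean(a)
    b = np.asarray(b, dtype=float) - np.mean(b)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    return float(a @ b / (na * nb))


def _correlation_matrix(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """(n_a, n_b) Pearson correlations between two stacks of maps."""
    A = average_reference_maps(A)
    B = average_reference_maps(B)
    A = A / np.maximum(np.linalg.norm(A, axis=1, keepdims=True), 1e-300)
    B = B / np.maximum(np.linalg.norm(B, axis=1, keepdims=True), 1e-300)
    return A @ B.T


def _assign(maps: np.ndarray, templates: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Polarity-invariant assignment; returns (labels, projections a_t)."""
    proj = maps @ templates.T  # (n_maps, K)
    labels = np.argmax(proj**2, axis=1)
    a = proj[np.arange(maps.shape[0]), labels]
    return labels, a


def _cost(maps: np.ndarray, a: np.ndarray) -> float:
    """Eq.-style cost: mean residual norm² over N_T(N_S−1)."""
    n_t, n_s = maps.shape
    total = float(np.einsum("ij,ij->", maps, maps))
    return (total - float(a @ a)) / (n_t * (n_s - 1))


def _principal_template(maps: np.ndarray) -> np.ndarray:
    """Unit-norm principal eigenvector of the scatter of `maps`."""
    scatter = maps.T @ maps
    # power iteration with eigh fallback for robustness at tiny sizes
    vals, vecs = np.linalg.eigh(scatter)
    v = vecs[:, -1]
    return v / np.linalg.norm(v)


def fit_modified_kmeans(
    maps: TopographySet | np.ndarray,
    K: int,
    restarts: int = 100,
    seed: int | np.random.Generator = 0,
    max_iter: int = 1000,
    tol: float = 1e-6,
    source: tuple = (),
    level: str = "run",
    trace: list | None = None,
) -> MicrostateModel:
    """Polarity-invariant modified k-means, best of `restarts` random starts.

    Each restart initializes the templates from K distinct observed maps,
    alternates assignment/eigenvector updates until the relative change of
    the cost F drops below `tol` (or `max_iter`), and the restart with the
    smallest converged F wins. An emptied class is re-seeded from the map
    with the worst fit.
    """
    X = maps.maps if isinstance(maps, TopographySet) else np.asarray(maps, dtype=float)
    n_t, n_s = X.shape
    if K < 1:
        raise ValueError("K must be >= 1")
    if K > n_t:
        raise ValueError(f"K={K} exceeds the {n_t} available maps")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    best_F = np.inf
    best_templates: np.ndarray | None = None
    for restart in range(restarts):
        idx = rng.choice(n_t, size=K, replace=False)
        templates = unit_norm_maps(X[idx].copy())
        prev_F = np.inf
        f_history: list[float] = []
        for _ in range(max_iter):
            labels, a = _assign(X, templates)
            # re-seed empty classes from the worst-fit map
            for k in range(K):
                if not np.any(labels == k):
                    resid = np.einsum("ij,ij->i", X, X) - a**2
                    templates[k] = X[np.argmax(resid)] / np.linalg.norm(X[np.argmax(resid)])
                    labels, a = _assign(X, templates)
            F = _cost(X, a)
            f_history.append(F)
            if prev_F - F <= tol * max(prev_F, 1e-300) and np.isfinite(prev_F):
                break
            prev_F = F
            for k in range(K):
                members = X[labels == k]
                if members.shape[0]:
                    templates[k] = _principal_template(members)
        labels, a = _assign(X, templates)
        F = _cost(X, a)
        if trace is not None:
            trace.append((restart, f_history + [F]))
        if F < best_F:
            best_F = F
            best_templates = templates.copy()

    assert best_templates is not None
    return MicrostateModel(
        templates=average_reference_maps(unit_norm_maps(best_templates)),
        F=best_F,
        source=source,
        level=level,
    )


def cv_criterion(maps: TopographySet | np.ndarray, model: MicrostateModel) -> float:
    """Cross-validation criterion of a fitted model on peak maps."""
    X = maps.maps if isinstance(maps, TopographySet) else np.asarray(maps, dtype=float)
    n_t, n_s = X.shape
    n_k = model.n_classes
    if n_k >= n_s - 1:
        raise ValueError(f"CV undefined for N_K={n_k} with N_S={n_s}")
    _, a = _assign(X, model.templates)
    resid = float(np.einsum("ij,ij->", X, X)) - float(a @ a)
    sigma2 = resid / (n_t * (n_s - 1))
    return sigma2 * ((n_s - 1) / (n_s - 1 - n_k)) ** 2


def gev(maps: TopographySet | np.ndarray, model: MicrostateModel) -> float:
    """Global explained variance of the model on the peak maps."""
    X = maps.maps if isinstance(maps, TopographySet) else np.asarray(maps, dtype=float)
    _, a = _assign(X, model.templates)
    total = float(np.einsum("ij,ij->", X, X))
    if total == 0:
        return 0.0
    return 1.0 - (total - float(a @ a)) / total


def select_k(
    maps: TopographySet | np.ndarray,
    k_range=range(1, 11),
    restarts: int = 100,
    seed: int = 0,
    source: tuple = (),
) -> tuple[int, dict[int, float], dict[int, MicrostateModel]]:
    """Fit every K in `k_range`; the K minimizing CV wins.

    Returns (best_k, cv_curve, fitted models per K).
    """
    rng = np.random.default_rng(seed)
    curve: dict[int, float] = {}
    models: dict[int, MicrostateModel] = {}
    for k in k_range:
        model = fit_modified_kmeans(maps, k, restarts=restarts, seed=rng, source=source)
        model.cv = cv_criterion(maps, model)
        curve[k] = model.cv
        models[k] = model
    best = min(curve, key=curve.get)
    return best, curve, models


# ---------------------------------------------------------------------------
# Hierarchical alignment


def _best_permutation(mean_t: np.ndarray, templates: np.ndarray) -> tuple[tuple[int, ...], float]:
    """Class permutation maximizing Σ |corr| against the running mean."""
    C = np.abs(_correlation_matrix(mean_t, templates))  # (K, K)
    K = C.shape[0]
    best_perm, best_score = None, -np.inf
    for perm in itertools.permutations(range(K)):
        score = C[np.arange(K), perm].sum()
        if score > best_score:
            best_score, best_perm = score, perm
    return best_perm, best_score


def align_and_average(
    models: list[MicrostateModel],
    max_permutation_k: int = 10,
    max_passes: int = 50,
    level: str = "mean",
    source: tuple = (),
) -> MicrostateModel:
    """Mean model over equally sized models via full-permutation alignment.

    For each input model all N_K! class permutations are scored by the sum
    of absolute spatial correlations against the current mean; the best
    permutation is applied, each aligned template is sign-flipped to
    correlate positively with its mean class, and the mean templates are
    re-averaged and renormalized. Passes repeat until assignments are
    stable.
    """
    if not models:
        raise ValueError("no models to align")
    K = models[0].n_classes
    n_s = models[0].templates.shape[1]
    for m in models:
        if m.n_classes != K or m.templates.shape[1] != n_s:
            raise ValueError("all models must share N_K and N_S")
    if math.factorial(K) > math.factorial(max_permutation_k):
        raise ValueError(
            f"{K}! permutations exceed the configured cap ({max_permutation_k}!); lower K"
        )

    mean_t = models[0].templates.copy()
    prev_perms: list[tuple[int, ...]] | None = None
    for _ in range(max_passes):
        aligned = np.zeros((len(models), K, n_s))
        perms: list[tuple[int, ...]] = []
        for i, m in enumerate(models):
            perm, _ = _best_permutation(mean_t, m.templates)
            perms.append(perm)
            t = m.templates[list(perm)]
            for k in range(K):
                if spatial_correlation(mean_t[k], t[k]) < 0:
                    t[k] = -t[k]
            aligned[i] = t
        mean_t = unit_norm_maps(average_reference_maps(aligned.mean(axis=0)))
        if perms == prev_perms:
            break
        prev_perms = perms
    return MicrostateModel(
        templates=mean_t, F=float(np.mean([m.F for m in models])), level=level, source=source
    )


def aggregate_hierarchy(
    run_models: dict[tuple[int, str, int], MicrostateModel],
) -> dict[str, object]:
    """runs → participant-condition → condition → global mean models.

    `run_models` maps (participant, condition, run) to a fitted model. A
    missing cell is skipped. Returns dicts of models at each level plus the
    single global model.
    """
    import warnings

    by_pc: dict[tuple[int, str], list[MicrostateModel]] = {}
    for (pid, cond, run), m in sorted(run_models.items()):
        by_pc.setdefault((pid, cond), []).append(m)
    pc_models = {
        key: align_and_average(ms, level="participant-condition", source=key)
        for key, ms in by_pc.items()
    }

    by_cond: dict[str, list[MicrostateModel]] = {}
    for (pid, cond), m in sorted(pc_models.items()):
        by_cond.setdefault(cond, []).append(m)
    cond_models = {
        cond: align_and_average(ms, level="condition", source=(cond,))
        for cond, ms in by_cond.items()
    }
    if not cond_models:
        warnings.warn("no models to aggregate")
        return {"participant_condition": {}, "condition": {}, "global": None}

    global_model = align_and_average(
        [cond_models[c] for c in sorted(cond_models)], level="global", source=("global",)
    )
    return {
        "participant_condition": pc_models,
        "condition": cond_models,
        "global": global_model,
    }


# ---------------------------------------------------------------------------
# Backfitting and parameters


@dataclass
class Segmentation:
    """Per-epoch sample labels with edge runs masked out."""

    labels: np.ndarray  # (n_epochs, n_len) int, -1 for excluded epochs
    retained: np.ndarray  # (n_epochs, n_len) bool
    intensities: np.ndarray  # (n_epochs, n_len) a_kt of the assigned class
    n_classes: int
    srate: float
    source: tuple = ()


def _runs_of(labels: np.ndarray) -> list[tuple[int, int, int]]:
    """Maximal runs of equal labels: (class, start, length)."""
    runs = []
    start = 0
    for t in range(1, len(labels) + 1):
        if t == len(labels) or labels[t] != labels[start]:
            runs.append((int(labels[start]), start, t - start))
            start = t
    return runs


def backfit_labels(
    epoched: EpochedRecording, model: MicrostateModel, source: tuple = ()
) -> Segmentation:
    """Label every sample of the kept epochs with the best-matching class.

    GFP-peak maps are labelled by maximal absolute spatial correlation with
    the templates; every other sample inherits the label of its temporally
    nearest peak (boundary at the midpoint, ties to the earlier peak). The
    first and last run of every epoch are dropped from the retained mask.
    Epochs with fewer than 2 peaks are excluded entirely.
    """
    import warnings

    n_epochs, n_ch, n_len = epoched.epochs.shape
    labels = np.full((n_epochs, n_len), -1, dtype=int)
    retained = np.zeros((n_epochs, n_len), dtype=bool)
    intensities = np.zeros((n_epochs, n_len))

    for e in np.flatnonzero(epoched.kept):
        epoch = epoched.epochs[e]
        peaks = detect_gfp_peaks(gfp_curve(epoch))
        if peaks.size < 2:
            warnings.warn(f"epoch {e} has fewer than 2 GFP peaks; excluded")
            continue
        peak_maps = average_reference_maps(epoch[:, peaks].T)
        corr = _correlation_matrix(peak_maps, model.templates)
        peak_labels = np.argmax(np.abs(corr), axis=1)
        # nearest-peak fill: boundaries at midpoints, ties to the earlier peak
        t = np.arange(n_len)
        nearest = np.searchsorted(peaks, t)  # first peak >= t
        nearest = np.clip(nearest, 0, peaks.size - 1)
        prev = np.clip(nearest - 1, 0, peaks.size - 1)
        d_next = np.abs(peaks[nearest] - t)
        d_prev = np.abs(t - peaks[prev])
        choose_prev = d_prev <= d_next
        pick = np.where(choose_prev, prev, nearest)
        labels[e] = peak_labels[pick]
        proj = average_reference_maps(epoch.T) @ model.templates.T
        intensities[e] = proj[t, labels[e]]
        runs = _runs_of(labels[e])
        retained[e] = True
        _, s0, l0 = runs[0]
        retained[e, s0 : s0 + l0] = False
        _, s1, l1 = runs[-1]
        retained[e, s1 : s1 + l1] = False

    return Segmentation(
        labels=labels,
        retained=retained,
        intensities=intensities,
        n_classes=model.n_classes,
        srate=epoched.srate,
        source=source,
    )


@dataclass
class MicrostateParameters:
    coverage: np.ndarray  # (K,) fractions, mean over epochs
    duration_ms: np.ndarray  # (K,) mean run length, NaN where class absent
    n_epochs: int
    source: tuple = ()


def compute_parameters(seg: Segmentation, srate: float | None = None) -> MicrostateParameters:
    """Coverage and mean duration per class, averaged over 2-s epochs.

    Per epoch, coverage_k is the fraction of retained samples labelled k and
    duration_k the mean length (ms) of retained class-k runs; the per-run
    value averages over the epochs where the class occurs.
    """
    srate = srate or seg.srate
    K = seg.n_classes
    cov_rows, dur_rows = [], []
    for e in range(seg.labels.shape[0]):
        mask = seg.retained[e]
        if not mask.any():
            continue
        runs = [r for r in _runs_of(seg.labels[e]) if mask[r[1]]]
        n_ret = int(mask.sum())
        cov = np.zeros(K)
        dur = np.full(K, np.nan)
        for k in range(K):
            kruns = [r for r in runs if r[0] == k]
            if kruns:
                samples = sum(r[2] for r in kruns)
                cov[k] = samples / n_ret
                dur[k] = np.mean([r[2] for r in kruns]) / srate * 1000.0
        cov_rows.append(cov)
        dur_rows.append(dur)
    if not cov_rows:
        raise ValueError("no retained samples in any epoch")
    import warnings

    coverage = np.mean(cov_rows, axis=0)
    with warnings.catch_warnings():
        # a class absent from every epoch legitimately yields NaN duration
        warnings.filterwarnings("ignore", message="Mean of empty slice")
        duration = np.nanmean(np.stack(dur_rows), axis=0)
    return MicrostateParameters(
        coverage=coverage, duration_ms=duration, n_epochs=len(cov_rows), source=seg.source
    )


# ---------------------------------------------------------------------------
# Class letters


def load_reference_maps(path=None) -> tuple[np.ndarray, tuple[str, ...]]:
    """Reference topographies for letter sorting (synthetic stand-in set).

    Returns (maps (K, N_S), letters). A CSV with a `class` column and one
    column per channel can be supplied to override the packaged set.
    """
    import importlib.resources

    import pandas as pd

    if path is None:
        ref = importlib.resources.files("eegstates.data") / "canonical_maps_synthetic.csv"
        with importlib.resources.as_file(ref) as p:
            df = pd.read_csv(p)
    else:
        df = pd.read_csv(path)
    letters = tuple(df["class"])
    maps = df.drop(columns=["class"]).to_numpy(dtype=float)
    return unit_norm_maps(average_reference_maps(maps)), letters


def sort_classes(
    model: MicrostateModel, reference: tuple[np.ndarray, tuple[str, ...]] | None = None
) -> MicrostateModel:
    """Order and letter the model's classes by maximal |corr| with the
    reference set (one-to-one assignment)."""
    from scipy.optimize import linear_sum_assignment

    ref_maps, letters = reference if reference is not None else load_reference_maps()
    if model.n_classes > ref_maps.shape[0]:
        raise ValueError("more classes than reference maps; supply a larger reference set")
    C = np.abs(_correlation_matrix(model.templates, ref_maps))
    rows, cols = linear_sum_assignment(-C)
    order = rows[np.argsort(cols)] if len(rows) == len(cols) else rows
    new_letters = tuple(letters[c] for c in np.sort(cols))
    templates = model.templates[order]
    return MicrostateModel(
        templates=templates,
        F=model.F,
        cv=model.cv,
        level=model.level,
        source=model.source,
        labels=new_letters,
    )
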