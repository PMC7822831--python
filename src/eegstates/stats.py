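"""Topographic randomization tests (TANOVA) and parametric statistics.

TANOVA compares scalp-field topographies between conditions without
channel-wise testing: maps are GFP-normalized per participant, the effect
statistic is the summed GFP of the deviations of level-mean maps from the
grand-mean map, and the null distribution is built by relabelling within
participants. P-values use the add-one permutation estimator

    p = (1 + #{perm >= observed}) / (1 + n_perm)

The parametric side provides an m-way within-subject (repeated measures)
ANOVA with Greenhouse–Geisser correction and partial eta squared, paired
t-tests with Bonferroni correction, and the within-participant
normalization of task completion times.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "TestResult",
    "gfp_of_map",
    "tanova",
    "paired_tanova",
    "rm_anova_gg",
    "paired_tests_bonferroni",
    "normalize_times",
]


@dataclass
class TestResult:
    name: str
    statistic: float
    p: float
    df: tuple[float, ...] = ()
    p_adj: float | None = None
    eta_p2: float | None = None
    ci: tuple[float, float] | None = None
    correction: str | None = None
    note: str | None = None


def gfp_of_map(m: np.ndarray) -> float:
    m = np.asarray(m, dtype=float)
    return float(np.sqrt(np.mean((m - m.mean()) ** 2)))


def _gfp_normalize(maps: np.ndarray) -> np.ndarray:
    """Divide each map (last axis = channels) by its GFP."""
    maps = np.asarray(maps, dtype=float)
    centered = maps - maps.mean(axis=-1, keepdims=True)
    g = np.sqrt(np.mean(centered**2, axis=-1, keepdims=True))
    if np.any(g == 0):
        raise ValueError("constant map has zero GFP")
    return centered / g


def _effect_statistic(maps: np.ndarray) -> np.ndarray:
    """Σ_levels GFP(level mean − grand mean).

    `maps` has shape (..., n_subj, L, C); subject axis is -3. Returns the
    statistic over leading axes (vectorized over permutations).
    """
    level_means = maps.mean(axis=-3)  # (..., L, C)
    grand = level_means.mean(axis=-2, keepdims=True)
    dev = level_means - grand
    g = np.sqrt(np.mean((dev - dev.mean(axis=-1, keepdims=True)) ** 2, axis=-1))
    return g.sum(axis=-1)


def _perm_indices(rng, n_perm: int, n_subj: int, L: int) -> np.ndarray:
    """(n_perm, n_subj, L) independent within-subject level permutations."""
    r = rng.random((n_perm, n_subj, L))
    return np.argsort(r, axis=-1)


def tanova(
    maps: np.ndarray,
    factors: tuple[str, ...] = ("condition",),
    n_perm: int = 5000,
    seed: int = 0,
    normalize: bool = True,
) -> dict[str, TestResult]:
    """One- or two-factor TANOVA on per-participant mean maps.

    ``maps`` is (n_subj, L1, C) for one factor or (n_subj, L1, L2, C) for
    two; the design must be complete (no NaNs). For two factors the null
    for each main effect permutes that factor's labels within participant
    (within the other factor's levels); the interaction permutes all cells
    jointly within participant and tests the double-centered residual.
    """
    maps = np.asarray(maps, dtype=float)
    if np.any(~np.isfinite(maps)):
        raise ValueError("incomplete design: NaNs in the topography cells")
    if maps.ndim - 2 != len(factors):
        raise ValueError("maps shape does not match the number of factors")
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    if normalize:
        spread = np.ptp(maps, axis=-1)
        if np.any(spread == 0):
            return {
                f: TestResult(name=f, statistic=0.0, p=1.0, note="constant map; p forced to 1")
                for f in _effect_names(factors)
            }
        maps = _gfp_normalize(maps)
    rng = np.random.default_rng(seed)

    results: dict[str, TestResult] = {}
    if len(factors) == 1:
        results[factors[0]] = _tanova_one_factor(maps, factors[0], n_perm, rng)
        return results

    n_subj, L1, L2, C = maps.shape
    # main effect of factor 1: collapse factor 2, permute factor-1 labels
    results[factors[0]] = _tanova_one_factor(maps.mean(axis=2), factors[0], n_perm, rng)
    results[factors[1]] = _tanova_one_factor(maps.mean(axis=1), factors[1], n_perm, rng)

    # interaction: double-centered cell maps, joint within-subject cell shuffle
    flat = maps.reshape(n_subj, L1 * L2, C)
    obs = _interaction_statistic(maps)
    perms = _perm_indices(rng, n_perm, n_subj, L1 * L2)
    subj = np.arange(n_subj)[None, :, None]
    shuffled = flat[subj, perms]  # (n_perm, n_subj, L1*L2, C)
    null = _interaction_statistic(shuffled.reshape(n_perm, n_subj, L1, L2, C))
    p = (1.0 + np.sum(null >= obs)) / (1.0 + n_perm)
    results[f"{factors[0]}*{factors[1]}"] = TestResult(
        name=f"{factors[0]}*{factors[1]}", statistic=float(obs), p=float(p)
    )
    return results


def _effect_names(factors: tuple[str, ...]) -> list[str]:
    names = list(factors)
    if len(factors) == 2:
        names.append(f"{factors[0]}*{factors[1]}")
    return names


def _tanova_one_factor(maps: np.ndarray, name: str, n_perm: int, rng) -> TestResult:
    n_subj, L, C = maps.shape
    obs = float(_effect_statistic(maps))
    perms = _perm_indices(rng, n_perm, n_subj, L)
    subj = np.arange(n_subj)[None, :, None]
    null = _effect_statistic(maps[subj, perms])
    p = (1.0 + np.sum(null >= obs)) / (1.0 + n_perm)
    return TestResult(name=name, statistic=obs, p=float(p))


def _interaction_statistic(maps: np.ndarray) -> np.ndarray:
    """Summed GFP of double-centered cell means; maps (..., n, L1, L2, C)."""
    cell = maps.mean(axis=-4)  # (..., L1, L2, C)
    m1 = cell.mean(axis=-2, keepdims=True)
    m2 = cell.mean(axis=-3, keepdims=True)
    grand = cell.mean(axis=(-3, -2), keepdims=True)
    resid = cell - m1 - m2 + grand
    g = np.sqrt(np.mean((resid - resid.mean(axis=-1, keepdims=True)) ** 2, axis=-1))
    return g.sum(axis=(-2, -1))


def paired_tanova(
    maps_a: np.ndarray, maps_b: np.ndarray, n_perm: int = 5000, seed: int = 0
) -> TestResult:
    """Paired topography comparison: GFP of the difference of grand means,
    null by swapping A/B within participant."""
    A = _gfp_normalize(np.asarray(maps_a, dtype=float))
    B = _gfp_normalize(np.asarray(maps_b, dtype=float))
    if A.shape != B.shape:
        raise ValueError("A and B must contain the same participants")
    n_subj = A.shape[0]
    rng = np.random.default_rng(seed)
    obs = gfp_of_map((A - B).mean(axis=0))
    diff = A - B  # (n_subj, C)
    signs = np.where(rng.random((n_perm, n_subj)) < 0.5, 1.0, -1.0)
    null_mean = (signs[:, :, None] * diff[None]).mean(axis=1)
    centered = null_mean - null_mean.mean(axis=-1, keepdims=True)
    null = np.sqrt(np.mean(centered**2, axis=-1))
    p = (1.0 + np.sum(null >= obs)) / (1.0 + n_perm)
    return TestResult(name="paired_tanova", statistic=float(obs), p=float(p))


# ---------------------------------------------------------------------------
# Repeated-measures ANOVA with Greenhouse–Geisser correction


def _orth_contrasts(levels: int) -> np.ndarray:
    """(levels-1, levels) orthonormal contrasts (Helmert)."""
    C = np.zeros((levels - 1, levels))
    for i in range(levels - 1):
        C[i, : i + 1] = 1.0
        C[i, i + 1] = -(i + 1)
        C[i] /= np.linalg.norm(C[i])
    return C


def _subject_cell_means(df, dv, within, subject):
    """(n_subj, l1, ..., lm) array of subject×cell means plus level labels."""
    levels = [list(pd.unique(df[f])) for f in within]
    subjects = list(pd.unique(df[subject]))
    means = df.groupby([subject, *within], sort=False)[dv].mean()
    grid = pd.MultiIndex.from_product([subjects, *levels], names=[subject, *within])
    filled = means.reindex(grid)
    if filled.isna().any():
        raise ValueError("missing cells in the within-subject design")
    Y = filled.to_numpy().reshape(len(subjects), *[len(lv) for lv in levels])
    return Y, levels, subjects


def rm_anova_gg(
    df: pd.DataFrame,
    dv: str,
    within: list[str],
    subject: str = "participant",
    sphericity_alpha: float = 0.05,
) -> pd.DataFrame:
    """Fully within-subject ANOVA for any number of within factors.

    Returns one row per effect with the uncorrected F, partial eta squared,
    Greenhouse–Geisser epsilon, Mauchly sphericity p, and the GG-corrected
    degrees of freedom and p-value (applied when Mauchly p < alpha and the
    effect has more than one numerator df).
    """
    Y, levels, subjects = _subject_cell_means(df, dv, within, subject)
    n = len(subjects)
    if n < 2:
        raise ValueError("need at least 2 participants")
    m = len(within)
    rows = []
    for r in range(1, m + 1):
        for combo in itertools.combinations(range(m), r):
            rows.append(_rm_effect(Y, within, combo, n, sphericity_alpha))
    return pd.DataFrame(rows)


def _collapse(Y: np.ndarray, keep: tuple[int, ...]) -> np.ndarray:
    """Average Y (subj, f1..fm) over within-factors not in `keep`."""
    m = Y.ndim - 1
    drop = tuple(1 + j for j in range(m) if j not in keep)
    Z = Y.mean(axis=drop) if drop else Y
    return Z


def _ie_effect(cellmeans: np.ndarray) -> np.ndarray:
    """Inclusion–exclusion effect estimate over all factor axes of
    `cellmeans` (no subject axis)."""
    m = cellmeans.ndim
    est = np.zeros_like(cellmeans)
    for r in range(m + 1):
        for combo in itertools.combinations(range(m), r):
            marg = cellmeans.mean(axis=tuple(a for a in range(m) if a not in combo), keepdims=True)
            sign = (-1) ** (m - r)
            est = est + sign * marg
    return est


def _rm_effect(Y, within, combo, n, sphericity_alpha) -> dict:
    m = Y.ndim - 1
    Z = _collapse(Y, combo)  # (n, levels of effect factors)
    p_levels = Z.shape[1:]
    q = int(np.prod([Y.shape[1 + j] for j in range(m) if j not in combo]))
    cell = Z.mean(axis=0)
    e = _ie_effect(cell)
    ss_effect = n * q * float(np.sum(e**2))
    # subject-wise effect estimates
    d = np.stack([_ie_effect(Z[s]) for s in range(n)])
    ss_err = q * float(np.sum((d - e[None]) ** 2))
    df1 = int(np.prod([p - 1 for p in p_levels]))
    df2 = df1 * (n - 1)
    ms_e = ss_effect / df1
    ms_r = ss_err / df2 if df2 > 0 else np.nan
    F = ms_e / ms_r if ms_r > 0 else 0.0
    eta = ss_effect / (ss_effect + ss_err) if (ss_effect + ss_err) > 0 else 0.0

    # Greenhouse–Geisser epsilon and Mauchly test on the contrast scores
    C = _orth_contrasts(p_levels[0])
    for p in p_levels[1:]:
        C = np.kron(C, _orth_contrasts(p))
    Zc = Z.reshape(n, -1) @ C.T  # (n, df1)
    if df1 == 1:
        eps, mauchly_p = 1.0, 1.0
    else:
        S = np.cov(Zc, rowvar=False, ddof=1)
        tr = np.trace(S)
        tr2 = float(np.sum(S * S.T))
        eps = tr**2 / (df1 * tr2) if tr2 > 0 else 1.0
        eps = float(np.clip(eps, 1.0 / df1, 1.0))
        mauchly_p = _mauchly_p(S, n, df1)

    apply_gg = df1 > 1 and mauchly_p < sphericity_alpha
    df1_c = eps * df1 if apply_gg else float(df1)
    df2_c = eps * df2 if apply_gg else float(df2)
    p_val = float(sps.f.sf(F, df1_c, df2_c)) if np.isfinite(F) and df2 > 0 else np.nan

    return {
        "effect": "*".join(within[j] for j in combo),
        "F": float(F),
        "df1": df1_c,
        "df2": df2_c,
        "p": p_val,
        "eta_p2": float(eta),
        "epsilon": float(eps),
        "mauchly_p": float(mauchly_p),
        "gg_applied": bool(apply_gg),
        "ss_effect": ss_effect,
        "ss_error": ss_err,
    }


def _mauchly_p(S: np.ndarray, n: int, d: int) -> float:
    sign, logdet = np.linalg.slogdet(S)
    if sign <= 0:
        return 0.0
    log_w = logdet - d * np.log(np.trace(S) / d)
    chi2 = -(n - 1 - (2 * d**2 + d + 2) / (6.0 * d)) * log_w
    dof = d * (d + 1) // 2 - 1
    if dof <= 0:
        return 1.0
    return float(sps.chi2.sf(max(chi2, 0.0), dof))


# ---------------------------------------------------------------------------
# Paired t-tests and behavioural normalization


def paired_tests_bonferroni(
    contrasts: list[tuple[str, np.ndarray, np.ndarray]], conf: float = 0.95
) -> list[TestResult]:
    """Two-sided paired t-tests with CI of the mean difference; Bonferroni
    over the whole requested family (p_adj = min(1, m·p))."""
    m = len(contrasts)
    out = []
    for name, x, y in contrasts:
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if x.shape != y.shape or x.ndim != 1 or x.size < 2:
            raise ValueError(f"contrast {name!r}: need paired 1-d samples of equal length >= 2")
        d = x - y
        sd = d.std(ddof=1)
        n = d.size
        if sd == 0:
            out.append(
                TestResult(
                    name=name,
                    statistic=np.nan,
                    p=1.0 if np.allclose(d, 0) else 0.0,
                    df=(n - 1,),
                    p_adj=None,
                    ci=(float(d.mean()), float(d.mean())),
                    correction="bonferroni",
                    note="zero variance of differences; t undefined",
                )
            )
            continue
        t = d.mean() / (sd / np.sqrt(n))
        p = 2 * sps.t.sf(abs(t), n - 1)
        half = sps.t.ppf(0.5 + conf / 2, n - 1) * sd / np.sqrt(n)
        out.append(
            TestResult(
                name=name,
                statistic=float(t),
                p=float(p),
                df=(n - 1,),
                p_adj=float(min(1.0, m * p)),
                ci=(float(d.mean() - half), float(d.mean() + half)),
                correction="bonferroni",
            )
        )
    return out


def normalize_times(
    times: pd.DataFrame, family: str = "condition", average: bool = False
) -> pd.DataFrame:
    """Z-score completion times within participant.

    ``family='condition'`` normalizes each participant's runs within each
    condition (for the within-condition RUN analysis); ``family='all'``
    normalizes across all of a participant's tasks (for the between-condition
    analysis). With ``average=True`` the normalized values are averaged per
    participant×condition.
    """
    df = times.copy()
    group_cols = ["participant", "condition"] if family == "condition" else ["participant"]

    def _z(g):
        if g.shape[0] < 2:
            raise ValueError(f"normalization group too small for participant {g.name}")
        sd = g["seconds"].std(ddof=1)
        if sd == 0:
            raise ValueError(f"zero-variance completion times for participant {g.name}")
        g = g.copy()
        g["normalized"] = (g["seconds"] - g["seconds"].mean()) / sd
        return g

    df = df.groupby(group_cols, group_keys=False)[df.columns].apply(_z)
    if average:
        df = (
            df.groupby(["participant", "condition"], as_index=False)["normalized"]
            .mean()
            .sort_values(["participant", "condition"])
            .reset_index(drop=True)
        )
    return df
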