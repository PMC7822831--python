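import itertools

import numpy as np
import pytest

from eegstates import microstates as ms
from eegstates.topographies import average_reference_maps, unit_norm_maps

# ---------------------------------------------------------------------------
# GFP and peaks


def test_gfp_hand_values():
    assert ms.gfp_curve(np.array([[3.0], [3.0]]))[0] == 0.0
    assert ms.gfp_curve(np.array([[1.0], [-1.0]]))[0] == pytest.approx(1.0, abs=1e-15)
    # population form: sqrt(mean of squared deviations)
    m = np.array([[1.0], [2.0], [3.0], [6.0]])
    assert ms.gfp_curve(m)[0] == pytest.approx(np.std([1, 2, 3, 6]), abs=1e-15)


def test_gfp_is_offset_invariant():
    rng = np.random.default_rng(0)
    x = rng.standard_normal((63, 200))
    np.testing.assert_allclose(ms.gfp_curve(x), ms.gfp_curve(x + 11.3), atol=1e-10)


def test_no_peaks_on_monotone_curve():
    assert ms.detect_gfp_peaks(np.arange(50.0)).size == 0


def test_plateau_peak_at_first_sample():
    gfp = np.array([0.0, 1.0, 2.0, 2.0, 1.0, 0.0])
    np.testing.assert_array_equal(ms.detect_gfp_peaks(gfp), [2])


def test_boundaries_are_never_peaks():
    assert ms.detect_gfp_peaks(np.array([5.0, 1.0, 4.0])).size == 0


def test_peaks_match_brute_force_scan():
    rng = np.random.default_rng(1)
    gfp = np.abs(rng.standard_normal(500)).cumsum() % 3.7  # wiggly positive curve
    got = set(ms.detect_gfp_peaks(gfp).tolist())
    expected = {
        t for t in range(1, len(gfp) - 1) if gfp[t] > gfp[t - 1] and gfp[t] > gfp[t + 1]
    }
    # brute force finds strict maxima; plateau starts are the only extras
    assert expected <= got
    for t in got - expected:
        assert gfp[t] > gfp[t - 1]


# ---------------------------------------------------------------------------
# Modified k-means


def _noisy_maps(templates, n_per, noise, rng):
    maps = []
    for k, g in enumerate(templates):
        for _ in range(n_per):
            sign = rng.choice([-1.0, 1.0])
            maps.append(sign * g * rng.uniform(5, 15) + noise * rng.standard_normal(g.size))
    return average_reference_maps(np.stack(maps))


def test_single_cluster_of_identical_maps(templates6):
    maps = np.tile(templates6[0] * 7.0, (10, 1))
    model = ms.fit_modified_kmeans(maps, 1, restarts=3, seed=0)
    assert model.F == pytest.approx(0.0, abs=1e-12)
    assert abs(ms.spatial_correlation(model.templates[0], templates6[0])) == pytest.approx(1.0)


def test_two_orthogonal_templates_with_random_polarity(templates6):
    rng = np.random.default_rng(2)
    truth = templates6[:2]
    maps = _noisy_maps(truth, 20, 0.0, rng)
    model = ms.fit_modified_kmeans(maps, 2, restarts=10, seed=3)
    corr = np.abs(ms._correlation_matrix(model.templates, truth))
    assert model.F <= 1e-12
    row, col = np.unravel_index(np.argmax(corr), corr.shape)
    assert sorted(np.max(corr, axis=1)) == pytest.approx([1.0, 1.0], abs=1e-9)


def test_cost_descends_every_iteration(templates6):
    rng = np.random.default_rng(3)
    maps = _noisy_maps(templates6[:4], 15, 2.0, rng)
    trace: list = []
    ms.fit_modified_kmeans(maps, 4, restarts=5, seed=4, trace=trace)
    assert len(trace) == 5
    for _, fs in trace:
        diffs = np.diff(fs)
        assert np.all(diffs <= 1e-10 * max(fs))


def test_k_larger_than_map_count_is_an_error():
    with pytest.raises(ValueError):
        ms.fit_modified_kmeans(np.ones((3, 63)), 4, restarts=1, seed=0)


def brute_force_two_class_cost(maps):
    """Global optimum of the K=2 modified k-means by enumerating all
    2-colorings (polarity handled by the eigenvector update)."""
    n = maps.shape[0]
    best = np.inf
    for bits in itertools.product([0, 1], repeat=n - 1):
        assign = np.array((0,) + bits)
        if len(set(assign)) < 2:
            continue
        total = 0.0
        for k in (0, 1):
            sub = maps[assign == k]
            scatter = sub.T @ sub
            w = np.linalg.eigvalsh(scatter)[-1]
            total += float(np.einsum("ij,ij->", sub, sub)) - w
        best = min(best, total / (n * (maps.shape[1] - 1)))
    return best


def test_restarts_reach_global_optimum_on_small_instances(templates6):
    rng = np.random.default_rng(5)
    for trial in range(5):
        maps = _noisy_maps(templates6[:2], 4, 3.0, rng)  # 8 maps
        model = ms.fit_modified_kmeans(maps, 2, restarts=50, seed=trial)
        oracle = brute_force_two_class_cost(maps)
        assert model.F == pytest.approx(oracle, rel=1e-9)


# ---------------------------------------------------------------------------
# CV criterion and model selection


def test_cv_zero_for_perfect_fit(templates6):
    maps = np.stack([3.0 * templates6[0], -2.0 * templates6[1]])
    model = ms.MicrostateModel(templates=templates6[:2], F=0.0)
    assert ms.cv_criterion(maps, model) == pytest.approx(0.0, abs=1e-12)


def test_cv_matches_hand_arithmetic_on_toy_instance():
    # N_S = 4 channels, 2 maps, K = 1
    v1 = np.array([1.0, -1.0, 1.0, -1.0])
    v2 = np.array([1.0, 1.0, -1.0, -1.0])
    maps = np.stack([v1, v2])
    gamma = unit_norm_maps(v1[None])  # assigned template for both maps
    model = ms.MicrostateModel(templates=gamma, F=0.0)
    # residual: v1 fits exactly (4 - 4 = 0); v2 is orthogonal (4 - 0 = 4)
    sigma2 = (0.0 + 4.0) / (2 * (4 - 1))
    expected = sigma2 * ((4 - 1) / (4 - 1 - 1)) ** 2
    assert ms.cv_criterion(maps, model) == pytest.approx(expected, abs=1e-12)


def test_cv_penalty_grows_with_k():
    rng = np.random.default_rng(6)
    maps = rng.standard_normal((30, 10))
    m1 = ms.fit_modified_kmeans(maps, 1, restarts=5, seed=0)
    # same residuals, larger K penalty: compare the penalty factors directly
    n_s = 10
    pen = lambda k: ((n_s - 1) / (n_s - 1 - k)) ** 2
    assert pen(2) > pen(1)
    with pytest.raises(ValueError):
        ms.cv_criterion(maps, ms.MicrostateModel(templates=np.ones((9, 10)), F=0.0))


def test_select_k_prefers_one_class_for_single_template(templates6):
    rng = np.random.default_rng(7)
    maps = np.stack([templates6[0] * rng.uniform(5, 10) * rng.choice([-1, 1]) for _ in range(40)])
    best, curve, _ = ms.select_k(maps, k_range=range(1, 5), restarts=5, seed=0)
    assert best == 1
    assert set(curve) == {1, 2, 3, 4}


def test_gev_bounded_and_monotone_in_k(templates6):
    rng = np.random.default_rng(8)
    maps = _noisy_maps(templates6, 15, 3.0, rng)
    prev = -1.0
    for k in range(1, 7):
        model = ms.fit_modified_kmeans(maps, k, restarts=10, seed=9)
        g = ms.gev(maps, model)
        assert 0.0 <= g <= 1.0
        assert g >= prev - 1e-9
        prev = g


# ---------------------------------------------------------------------------
# Alignment


def test_alignment_recovers_shuffled_classes(templates6):
    a = ms.MicrostateModel(templates=templates6, F=0.0)
    perm = [2, 0, 5, 1, 3, 4]
    b = ms.MicrostateModel(templates=templates6[perm], F=0.0)
    mean = ms.align_and_average([a, b])
    corr = np.abs(ms._correlation_matrix(mean.templates, a.templates))
    np.testing.assert_allclose(np.diag(corr), 1.0, atol=1e-9)


def test_alignment_ignores_polarity(templates6):
    a = ms.MicrostateModel(templates=templates6, F=0.0)
    b = ms.MicrostateModel(templates=-templates6, F=0.0)
    mean = ms.align_and_average([a, b])
    corr = np.abs(np.diag(ms._correlation_matrix(mean.templates, templates6)))
    np.testing.assert_allclose(corr, 1.0, atol=1e-12)


def test_alignment_cap_on_permutation_count(templates6):
    models = [ms.MicrostateModel(templates=templates6[:4], F=0.0)] * 2
    with pytest.raises(ValueError, match="cap"):
        ms.align_and_average(models, max_permutation_k=3)


def test_hierarchy_of_identical_models_is_a_fixed_point(templates6):
    run_models = {
        (pid, cond, run): ms.MicrostateModel(templates=templates6, F=0.0)
        for pid in (1, 2)
        for cond in ("rest", "generation")
        for run in (0, 1)
    }
    agg = ms.aggregate_hierarchy(run_models)
    assert set(agg["condition"]) == {"rest", "generation"}
    corr = np.abs(np.diag(ms._correlation_matrix(agg["global"].templates, templates6)))
    np.testing.assert_allclose(corr, 1.0, atol=1e-9)


# ---------------------------------------------------------------------------
# Backfitting and parameters


def _epoched_from(data, srate=500.0):
    from eegstates.preprocess import EpochedRecording

    data = np.asarray(data, dtype=float)
    return EpochedRecording(
        epochs=data[None], kept=np.array([True]), srate=srate, band=(1.0, 30.0)
    )


def test_backfit_exact_and_sign_flipped_template(templates6):
    t = np.arange(1000) / 500.0
    wave = np.sin(2 * np.pi * 10 * t)
    for sign in (1.0, -1.0):
        data = sign * np.outer(templates6[2], wave) * 30.0
        seg = ms.backfit_labels(_epoched_from(data), ms.MicrostateModel(templates=templates6, F=0.0))
        # every sample is labelled 3rd class whatever the polarity; with a
        # single uniform run the edge-removal rule then retains nothing
        assert np.all(seg.labels[0] == 2)
        assert not seg.retained[0].any()


def test_worked_example_edge_removal_rule():
    """Runs A(2), B(3), A(1) in one epoch: only the B run is retained, so
    coverage(B) = 1 and duration(B) = 3 samples = 6 ms at 500 Hz."""
    labels = np.array([[0, 0, 1, 1, 1, 0]])
    retained = np.array([[False, False, True, True, True, False]])
    seg = ms.Segmentation(
        labels=labels,
        retained=retained,
        intensities=np.zeros_like(labels, dtype=float),
        n_classes=2,
        srate=500.0,
    )
    par = ms.compute_parameters(seg)
    np.testing.assert_allclose(par.coverage, [0.0, 1.0])
    assert par.duration_ms[1] == pytest.approx(6.0)
    assert np.isnan(par.duration_ms[0])


def test_backfit_applies_edge_removal(templates6):
    # alternating template blocks; first and last runs must be masked out
    t = np.arange(1000) / 500.0
    wave = 30.0 * np.sin(2 * np.pi * 10 * t)
    labels = np.repeat(np.arange(5) % 2, 200)
    data = templates6[labels].T * wave
    seg = ms.backfit_labels(_epoched_from(data), ms.MicrostateModel(templates=templates6[:2], F=0.0))
    assert not seg.retained[0, 0]
    assert not seg.retained[0, -1]
    assert seg.retained[0].any()


def test_epoch_with_too_few_peaks_is_excluded(templates6):
    data = np.outer(templates6[0], np.linspace(0, 1, 1000))  # monotone GFP
    with pytest.warns(UserWarning, match="fewer than 2"):
        seg = ms.backfit_labels(
            _epoched_from(data), ms.MicrostateModel(templates=templates6, F=0.0)
        )
    assert not seg.retained.any()
    with pytest.raises(ValueError, match="retained"):
        ms.compute_parameters(seg)


def test_coverages_sum_to_one_per_epoch(recovery_micro):
    for seg in list(recovery_micro["segmentations"].values())[:5]:
        for e in range(seg.labels.shape[0]):
            mask = seg.retained[e]
            if not mask.any():
                continue
            runs = [r for r in ms._runs_of(seg.labels[e]) if mask[r[1]]]
            total = sum(r[2] for r in runs)
            assert total == mask.sum()


def test_parameters_invariant_under_class_relabelling(templates6):
    rng = np.random.default_rng(10)
    labels = rng.integers(0, 3, size=(1, 60))
    retained = np.ones((1, 60), dtype=bool)
    retained[0, :5] = retained[0, -5:] = False
    seg = ms.Segmentation(
        labels=labels, retained=retained, intensities=np.zeros((1, 60)), n_classes=3, srate=500.0
    )
    par = ms.compute_parameters(seg)
    perm = np.array([2, 0, 1])  # new label of old class k is perm[k]
    seg2 = ms.Segmentation(
        labels=perm[labels],
        retained=retained,
        intensities=np.zeros((1, 60)),
        n_classes=3,
        srate=500.0,
    )
    par2 = ms.compute_parameters(seg2)
    np.testing.assert_allclose(par2.coverage[perm], par.coverage, atol=1e-12)
    np.testing.assert_allclose(par2.duration_ms[perm], par.duration_ms, atol=1e-12)


def test_class_sorting_assigns_letters(templates6):
    from eegstates.microstates import load_reference_maps, sort_classes

    ref_maps, letters = load_reference_maps()
    assert letters == ("A", "B", "C", "D", "E", "F")
    shuffled = ms.MicrostateModel(templates=ref_maps[[3, 1, 5, 0, 2, 4]], F=0.0)
    sorted_model = sort_classes(shuffled)
    assert sorted_model.labels == ("A", "B", "C", "D", "E", "F")
    corr = np.abs(np.diag(ms._correlation_matrix(sorted_model.templates, ref_maps)))
    np.testing.assert_allclose(corr, 1.0, atol=1e-9)
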