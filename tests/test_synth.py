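import numpy as np
import pytest

from eegstates.microstates import _correlation_matrix, detect_gfp_peaks, gfp_curve
from eegstates.synth import (
    StudyConfig,
    generate_study,
    render_recording,
    sample_label_sequence,
)


def _run_lengths(labels):
    change = np.flatnonzero(np.diff(labels) != 0)
    return np.diff(np.concatenate([[0], change + 1, [len(labels)]]))


def test_single_class_sequence_is_constant():
    labels = sample_label_sequence(1, [1.0], 80.0, 500, 500.0, np.random.default_rng(0))
    assert np.all(labels == 0)


def test_mean_run_length_matches_request():
    rng = np.random.default_rng(1)
    labels = sample_label_sequence(6, np.full(6, 1 / 6), 80.0, 30000, 500.0, rng)
    mean_ms = _run_lengths(labels).mean() / 500.0 * 1000.0
    assert abs(mean_ms - 80.0) / 80.0 < 0.10


def test_runs_partition_the_sequence_and_never_self_repeat():
    rng = np.random.default_rng(2)
    labels = sample_label_sequence(4, np.full(4, 0.25), 60.0, 7000, 500.0, rng)
    lengths = _run_lengths(labels)
    assert lengths.sum() == 7000
    change = np.flatnonzero(np.diff(labels) != 0)
    assert np.all(labels[change] != labels[change + 1])


def test_long_run_coverage_matches_weights():
    rng = np.random.default_rng(3)
    w = np.array([0.14, 0.167, 0.21, 0.19, 0.13, 0.163])
    labels = sample_label_sequence(6, w, 120.0, 1_000_000, 500.0, rng)
    cov = np.bincount(labels, minlength=6) / len(labels)
    assert np.max(np.abs(cov - w) / w) < 0.05


def test_invalid_sequence_arguments():
    rng = np.random.default_rng(0)
    with pytest.raises(ValueError):
        sample_label_sequence(0, [], 80.0, 100, 500.0, rng)
    with pytest.raises(ValueError):
        sample_label_sequence(2, [0.5, 0.5], -5.0, 100, 500.0, rng)


def test_noiseless_rendering_matches_active_template(templates6, montage):
    rng = np.random.default_rng(4)
    labels = sample_label_sequence(6, np.full(6, 1 / 6), 100.0, 2000, 500.0, rng)
    rec = render_recording(
        labels, templates6, 1.0, 0.0, 500.0, rng, channel_names=montage.channels
    )
    # every sample is proportional to its active template
    corr = np.abs(
        np.einsum("ij,ij->i", rec.data.T, templates6[labels])
        / np.linalg.norm(rec.data.T, axis=1)
    )
    np.testing.assert_allclose(corr, 1.0, atol=1e-9)
    # average-referenced by construction
    np.testing.assert_allclose(rec.data.mean(axis=0), 0.0, atol=1e-9)


def test_rendering_is_deterministic_per_seed(templates6, montage):
    labels = np.zeros(1000, dtype=int)
    a = render_recording(
        labels, templates6, 1.0, 2.0, 500.0, np.random.default_rng(9), channel_names=montage.channels
    )
    b = render_recording(
        labels, templates6, 1.0, 2.0, 500.0, np.random.default_rng(9), channel_names=montage.channels
    )
    assert np.array_equal(a.data, b.data)


def test_template_size_mismatch_is_an_error(templates6):
    with pytest.raises(ValueError, match="mismatch"):
        render_recording(
            np.zeros(100, dtype=int),
            templates6,
            1.0,
            0.0,
            500.0,
            np.random.default_rng(0),
            channel_names=("a", "b"),
        )


def test_alpha_band_power_scales_with_gain(templates6, montage):
    from eegstates.preprocess import epoch_and_reject
    from eegstates.trp import band_power, welch_psd

    labels = np.zeros(10000, dtype=int)
    powers = []
    for gain in (0.6, 0.8, 1.0, 1.3):
        rec = render_recording(
            labels,
            templates6,
            gain,
            1.0,
            500.0,
            np.random.default_rng(11),
            channel_names=montage.channels,
        )
        ep = epoch_and_reject(rec)
        f, psd = welch_psd(ep)
        powers.append(band_power(f, psd, (8, 12)).power.mean())
    assert np.all(np.diff(powers) > 0)


def test_noiseless_backfit_recovers_planted_labels_at_peaks(templates6, montage):
    """Labelling GFP-peak maps with the true templates recovers the planted
    sequence almost perfectly on a noiseless rendering."""
    rng = np.random.default_rng(5)
    labels = sample_label_sequence(6, np.full(6, 1 / 6), 120.0, 15000, 500.0, rng)
    rec = render_recording(
        labels, templates6, 1.0, 0.0, 500.0, rng, channel_names=montage.channels
    )
    peaks = detect_gfp_peaks(gfp_curve(rec.data))
    peak_maps = rec.data[:, peaks].T
    corr = _correlation_matrix(peak_maps, templates6)
    recovered = np.argmax(np.abs(corr), axis=1)
    assert (recovered == labels[peaks]).mean() >= 0.99


def test_generate_study_structure_and_time_ordering():
    cfg = StudyConfig(n_participants=4, rest_seconds=10.0, max_render_seconds=6.0)
    study = generate_study(cfg, seed=1)
    # 1 rest + 3 runs x 3 task conditions per participant
    assert len(study.recordings) == 4 * 10
    means = study.completion_times.groupby("condition")["seconds"].mean()
    assert means["evolution"] > means["generation"] > means["evaluation"]
    for key, rec in study.recordings.items():
        assert rec.duration <= 180.0 + 1e-9


def test_null_configuration_has_unit_gains():
    cfg = StudyConfig(n_participants=2, rest_seconds=8.0, max_render_seconds=6.0).null_effects()
    study = generate_study(cfg, seed=2)
    assert all(g == 1.0 for g in study.ground_truth.condition_alpha_gain.values())
    for w in study.ground_truth.condition_coverage_bias.values():
        np.testing.assert_allclose(w, 1.0 / 6.0)


def test_fewer_than_two_participants_is_an_error():
    with pytest.raises(ValueError, match="participants"):
        generate_study(StudyConfig(n_participants=1), seed=0)


def test_participant_templates_stay_close_to_group(templates6):
    cfg = StudyConfig(n_participants=3, rest_seconds=8.0, max_render_seconds=6.0)
    study = generate_study(cfg, seed=3)
    for ptempl in study.ground_truth.participant_templates.values():
        corr = np.abs(np.diag(_correlation_matrix(ptempl, study.ground_truth.templates)))
        assert np.all(corr >= 0.90)
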