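"""End-to-end orchestration: simulate → preprocess → TRP → microstates →
statistics, with one master seed and a deterministic JSON report."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import microstates as ms
from . import stats as st
from . import synth, trp
from ._rng import child_seed
from .montage import CONDITIONS, TASK_CONDITIONS, make_montage
from .preprocess import bandpass_filter, epoch_and_reject, rereference_average

__all__ = ["RunConfig", "run_pipeline", "preprocess_study", "microstate_stage", "trp_stage"]

BANDS = {"lower_alpha": (8.0, 10.0), "upper_alpha": (10.0, 12.0), "broadband": (1.0, 30.0)}


@dataclass
class RunConfig:
    """One config drives every stage; every random stage draws a named seed."""

    seed: int = 0
    out_dir: str = "pipeline_out"
    simulate: bool = True
    n_participants: int = 4
    n_runs: int = 3
    rest_seconds: float = 30.0
    max_render_seconds: float | None = 20.0
    epoch_seconds: float = 2.0
    k_group: int = 6
    k_range: tuple[int, int] = (1, 10)
    restarts: int = 20
    run_select_k: bool = True
    n_perm: int = 1000
    run_stats: bool = True

    def study_config(self) -> synth.StudyConfig:
        return synth.StudyConfig(
            n_participants=self.n_participants,
            n_runs=self.n_runs,
            rest_seconds=self.rest_seconds,
            max_render_seconds=self.max_render_seconds,
        )

    def config_hash(self) -> str:
        """Hash of the analysis parameters (paths excluded)."""
        payload = dataclasses.asdict(self)
        payload.pop("out_dir", None)
        blob = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    @classmethod
    def from_toml(cls, path) -> "RunConfig":
        import tomllib

        data = tomllib.loads(Path(path).read_text())
        kwargs = {k: v for k, v in data.items() if k in {f.name for f in dataclasses.fields(cls)}}
        if "k_range" in kwargs:
            kwargs["k_range"] = tuple(kwargs["k_range"])
        return cls(**kwargs)


def preprocess_study(study: synth.StudyDataset, epoch_seconds: float = 2.0):
    """Band-pass + average reference + epoching for every recording.

    Returns {band_name: {(pid, cond, run): EpochedRecording}}.
    """
    out = {name: {} for name in BANDS}
    for key, rec in study.recordings.items():
        for name, band in BANDS.items():
            filt = rereference_average(bandpass_filter(rec, band))
            out[name][key] = epoch_and_reject(
                filt, epoch_seconds=epoch_seconds, montage=study.montage, band=band
            )
    return out


def trp_stage(epoched_by_band, montage, channels) -> dict[str, dict]:
    """TRP tables and region aggregates for both alpha sub-bands."""
    results = {}
    for band_name in ("lower_alpha", "upper_alpha"):
        band = BANDS[band_name]
        per_participant = {}
        pids = sorted({k[0] for k in epoched_by_band[band_name]})
        for pid in pids:
            freqs, psd = trp.welch_psd(epoched_by_band[band_name][(pid, "rest", 0)])
            ref = trp.band_power(freqs, psd, band, condition="rest")
            activation = {}
            for cond in TASK_CONDITIONS:
                runs = []
                for key, ep in sorted(epoched_by_band[band_name].items()):
                    if key[0] == pid and key[1] == cond:
                        f, p = trp.welch_psd(ep)
                        runs.append(trp.band_power(f, p, band, condition=cond, run=key[2]))
                activation[cond] = runs
            table = trp.compute_trp(activation, ref, channels)
            per_participant[pid] = {
                "table": table,
                "regions": trp.aggregate_regions(table, montage),
            }
        results[band_name] = per_participant
    return results


def microstate_stage(broadband_epochs, config: RunConfig):
    """Per-run fits, optional CV model selection, hierarchy, backfit, parameters."""
    peak_sets = {
        key: ms.extract_peak_maps(ep, source=key) for key, ep in sorted(broadband_epochs.items())
    }

    selected_k = {}
    if config.run_select_k:
        lo, hi = config.k_range
        for key, ts in peak_sets.items():
            best, curve, _ = ms.select_k(
                ts,
                k_range=range(lo, hi + 1),
                restarts=config.restarts,
                seed=child_seed(config.seed, f"select_k/{key}"),
            )
            selected_k[key] = {"best_k": best, "cv_curve": curve}

    run_models = {
        key: ms.fit_modified_kmeans(
            ts,
            config.k_group,
            restarts=config.restarts,
            seed=np.random.default_rng(child_seed(config.seed, f"kmeans/{key}")),
            source=key,
        )
        for key, ts in peak_sets.items()
    }
    for key, model in run_models.items():
        model.cv = ms.cv_criterion(peak_sets[key], model)

    hierarchy = ms.aggregate_hierarchy(run_models)
    global_model = ms.sort_classes(hierarchy["global"])

    segmentations = {
        key: ms.backfit_labels(ep, global_model, source=key)
        for key, ep in sorted(broadband_epochs.items())
    }
    parameters = {key: ms.compute_parameters(seg) for key, seg in segmentations.items()}
    gevs = {key: ms.gev(ts, global_model) for key, ts in peak_sets.items() if ts.n_maps}

    # per-(participant, condition, class) sign-aligned mean peak maps for TANOVA
    cell_maps = {}
    for key, ts in peak_sets.items():
        if ts.n_maps == 0:
            continue
        pid, cond, _ = key
        corr = ms._correlation_matrix(ts.maps, global_model.templates)
        labels = np.argmax(np.abs(corr), axis=1)
        signs = np.sign(corr[np.arange(ts.n_maps), labels])
        for k in range(global_model.n_classes):
            sel = labels == k
            if not sel.any():
                continue
            mean_map = (ts.maps[sel] * signs[sel, None]).mean(axis=0)
            cell_maps.setdefault((pid, cond, k), []).append(mean_map)
    cell_maps = {k: np.mean(v, axis=0) for k, v in cell_maps.items()}

    return {
        "selected_k": selected_k,
        "run_models": run_models,
        "hierarchy": hierarchy,
        "global_model": global_model,
        "segmentations": segmentations,
        "parameters": parameters,
        "gev": gevs,
        "cell_maps": cell_maps,
    }


def _stats_stage(study, trp_results, micro, config: RunConfig):
    out = {}
    seed = config.seed

    # behavioural times: between-condition RM-ANOVA on normalized+averaged times
    times = st.normalize_times(study.completion_times, family="all", average=True)
    aov = st.rm_anova_gg(times, dv="normalized", within=["condition"], subject="participant")
    out["times_condition_anova"] = aov.to_dict("records")

    # TRP 3x5x2 RM-ANOVA per band
    for band_name, per_pid in trp_results.items():
        rows = []
        for pid, res in per_pid.items():
            for r in res["regions"].itertuples(index=False):
                rows.append(
                    {
                        "participant": pid,
                        "condition": r.condition,
                        "area": r.area,
                        "hemisphere": r.hemisphere,
                        "value": r.value,
                    }
                )
        df = pd.DataFrame(rows)
        aov = st.rm_anova_gg(
            df, dv="value", within=["condition", "area", "hemisphere"], subject="participant"
        )
        out[f"trp_anova_{band_name}"] = aov.to_dict("records")

    # microstate parameters: 4 x K RM-ANOVAs on coverage and duration
    K = config.k_group
    rows = []
    for (pid, cond, run), par in micro["parameters"].items():
        for k in range(K):
            rows.append(
                {
                    "participant": pid,
                    "condition": cond,
                    "run": run,
                    "class": k,
                    "coverage": par.coverage[k],
                    "duration_ms": par.duration_ms[k],
                }
            )
    pdf = pd.DataFrame(rows)
    for dv in ("coverage", "duration_ms"):
        sub = pdf.dropna(subset=[dv])
        aov = st.rm_anova_gg(sub, dv=dv, within=["condition", "class"], subject="participant")
        out[f"parameters_anova_{dv}"] = aov.to_dict("records")

    # two-factor TANOVA on per-(participant, condition, class) mean maps
    pids = sorted({k[0] for k in micro["cell_maps"]})
    conds = [c for c in CONDITIONS if any(k[1] == c for k in micro["cell_maps"])]
    n_ch = next(iter(micro["cell_maps"].values())).shape[0]
    maps = np.full((len(pids), len(conds), K, n_ch), np.nan)
    for (pid, cond, k), m in micro["cell_maps"].items():
        maps[pids.index(pid), conds.index(cond), k] = m
    if np.all(np.isfinite(maps)):
        res = st.tanova(
            maps,
            factors=("condition", "class"),
            n_perm=config.n_perm,
            seed=child_seed(seed, "tanova"),
        )
        out["tanova"] = {k: dataclasses.asdict(v) for k, v in res.items()}
    else:
        out["tanova"] = {"note": "incomplete topography crossing; TANOVA skipped"}
    return out


def _report(study, trp_results, micro, stats_out, config: RunConfig) -> dict:
    truth = study.ground_truth
    gm = micro["global_model"]
    corr = np.abs(ms._correlation_matrix(gm.templates, truth.templates))
    from scipy.optimize import linear_sum_assignment

    rows, cols = linear_sum_assignment(-corr)
    recovery = {int(r): float(corr[r, c]) for r, c in zip(rows, cols)}

    report = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "selected_k": {
            "/".join(map(str, k)): v["best_k"] for k, v in micro["selected_k"].items()
        },
        "global_template_letters": list(gm.labels),
        "global_template_truth_correlation": recovery,
        "gev_mean": float(np.mean(list(micro["gev"].values()))),
        "trp_regions": {
            band: {
                str(pid): res["regions"]["value"].round(6).tolist()
                for pid, res in per_pid.items()
            }
            for band, per_pid in trp_results.items()
        },
        "parameters": {
            "/".join(map(str, key)): {
                "coverage": [round(float(c), 6) for c in par.coverage],
                "duration_ms": [
                    None if not np.isfinite(d) else round(float(d), 4) for d in par.duration_ms
                ],
            }
            for key, par in micro["parameters"].items()
        },
        "stats": stats_out,
        "completion_time_means": study.completion_times.groupby("condition")["seconds"]
        .mean()
        .round(6)
        .to_dict(),
    }
    return report


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and write ``report.json`` under ``config.out_dir``.

    The same config and seed always produce a byte-identical report.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    study = synth.generate_study(config.study_config(), seed=child_seed(config.seed, "simulate"))
    epoched = preprocess_study(study, epoch_seconds=config.epoch_seconds)
    montage = study.montage
    trp_results = trp_stage(epoched, montage, montage.channels)
    micro = microstate_stage(epoched["broadband"], config)
    stats_out = _stats_stage(study, trp_results, micro, config) if config.run_stats else {}

    report = _report(study, trp_results, micro, stats_out, config)
    (out_dir / "report.json").write_text(
        json.dumps(_sanitize(report), indent=1, sort_keys=True, allow_nan=False)
    )

    # tidy CSV side outputs
    study.completion_times.to_csv(out_dir / "times.csv", index=False)
    rows = []
    for band, per_pid in trp_results.items():
        for pid, res in per_pid.items():
            r = res["regions"].copy()
            r.insert(0, "participant", pid)
            r.insert(0, "band", band)
            rows.append(r)
    pd.concat(rows).to_csv(out_dir / "trp_regions.csv", index=False)
    return report


def _sanitize(obj):
    """Make a report JSON-safe: numpy scalars to python, non-finite to None."""
    if isinstance(obj, dict):
        return {str(k): _sanitize(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_sanitize(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_sanitize(v) for v in obj.tolist()]
    if isinstance(obj, (np.integer, int)) and not isinstance(obj, bool):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        f = float(obj)
        return f if np.isfinite(f) else None
    return obj
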