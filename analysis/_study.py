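"""Shared study construction for the numbered analysis drivers.

Every driver rebuilds the same seeded synthetic study (4 participants,
3 runs, 6 planted microstate classes, 90-s rest, task blocks rendered up to
30 s) so each script is independently re-runnable; heavy intermediates are
kept in memory, narrative tables go to results/.
"""

from pathlib import Path

SEED = 0
RESULTS = Path(__file__).resolve().parent.parent / "results"


def build_study():
    from eegstates.synth import StudyConfig, generate_study

    cfg = StudyConfig(n_participants=4, rest_seconds=90.0, max_render_seconds=30.0)
    return generate_study(cfg, seed=SEED)


def build_epochs(study):
    from eegstates.pipeline import preprocess_study

    return preprocess_study(study)


def build_micro(epochs):
    from eegstates.pipeline import RunConfig, microstate_stage

    cfg = RunConfig(seed=SEED, n_participants=4, restarts=10, run_select_k=False)
    return microstate_stage(epochs["broadband"], cfg)
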