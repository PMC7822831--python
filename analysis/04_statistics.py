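"""Statistics: behavioural times, TANOVA on topographies, parameter ANOVAs.

Normalizes task completion times within participant and tests the
between-condition effect; runs the two-factor CONDITION × CLASS TANOVA on
per-participant mean class topographies with class-wise and paired
follow-ups; and analyses microstate coverage/duration with 4 × 6
within-subject ANOVAs plus Bonferroni-corrected paired t-tests.
"""

import dataclasses
import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _study import RESULTS, SEED, build_epochs, build_micro, build_study

from eegstates.montage import CONDITIONS
from eegstates.stats import normalize_times, paired_tests_bonferroni, rm_anova_gg, tanova


def main() -> None:
    study = build_study()
    epochs = build_epochs(study)
    micro = build_micro(epochs)
    RESULTS.mkdir(exist_ok=True)
    out_rows = []

    # behavioural completion times
    norm = normalize_times(study.completion_times, family="all", average=True)
    aov = rm_anova_gg(norm, dv="normalized", within=["condition"], subject="participant")
    print("completion times, between-condition within-subject ANOVA (normalized):")
    print(aov[["effect", "F", "df1", "df2", "p", "eta_p2"]].round(4).to_string(index=False))
    wide = norm.pivot(index="participant", columns="condition", values="normalized")
    contrasts = [
        ("evolution-generation", wide["evolution"], wide["generation"]),
        ("evolution-evaluation", wide["evolution"], wide["evaluation"]),
        ("generation-evaluation", wide["generation"], wide["evaluation"]),
    ]
    for r in paired_tests_bonferroni(contrasts):
        out_rows.append({"family": "times", **dataclasses.asdict(r)})
        print(f"  {r.name}: t={r.statistic:.3f}, p={r.p:.4f}, p_adj={r.p_adj:.4f}")

    # topographies: two-factor TANOVA on sign-aligned class mean maps
    K = micro["global_model"].n_classes
    pids = sorted({k[0] for k in micro["cell_maps"]})
    conds = [c for c in CONDITIONS if any(k[1] == c for k in micro["cell_maps"])]
    n_ch = next(iter(micro["cell_maps"].values())).shape[0]
    maps = np.full((len(pids), len(conds), K, n_ch), np.nan)
    for (pid, cond, k), m in micro["cell_maps"].items():
        maps[pids.index(pid), conds.index(cond), k] = m
    if np.all(np.isfinite(maps)):
        res = tanova(maps, factors=("condition", "class"), n_perm=1000, seed=SEED)
        print("\nCONDITION x CLASS TANOVA (1000 permutations):")
        for name, r in res.items():
            print(f"  {name}: statistic={r.statistic:.4f}, p={r.p:.4f}")
            out_rows.append({"family": "tanova", **dataclasses.asdict(r)})
    else:
        print("\nTANOVA skipped: incomplete participant x condition x class crossing")

    # microstate parameters: 4 x K ANOVAs and paired follow-ups on coverage
    rows = []
    letters = micro["global_model"].labels
    for (pid, cond, run), par in micro["parameters"].items():
        for k, letter in enumerate(letters):
            rows.append(
                {
                    "participant": pid,
                    "condition": cond,
                    "class": letter,
                    "coverage": par.coverage[k],
                    "duration_ms": par.duration_ms[k],
                }
            )
    pdf = pd.DataFrame(rows)
    for dv in ("coverage", "duration_ms"):
        aov = rm_anova_gg(
            pdf.dropna(subset=[dv]), dv=dv, within=["condition", "class"], subject="participant"
        )
        print(f"\n{dv}: CONDITION x CLASS within-subject ANOVA")
        print(aov[["effect", "F", "df1", "df2", "p", "eta_p2", "gg_applied"]].round(4).to_string(index=False))
        for rec in aov.to_dict("records"):
            out_rows.append({"family": f"anova_{dv}", **rec})

    cellmeans = pdf.groupby(["participant", "condition", "class"])["coverage"].mean().unstack("condition")
    contrasts = []
    for letter in letters:
        sub = cellmeans.xs(letter, level="class")
        contrasts.append((f"coverage_{letter}_rest_vs_evolution", sub["rest"], sub["evolution"]))
    print("\npaired t-tests, class coverage rest vs idea evolution (Bonferroni):")
    for r in paired_tests_bonferroni(contrasts):
        print(f"  {r.name}: t={r.statistic:.3f}, p={r.p:.4f}, p_adj={r.p_adj:.4f}")
        out_rows.append({"family": "paired_coverage", **dataclasses.asdict(r)})

    pd.DataFrame(out_rows).to_csv(RESULTS / "statistics.csv", index=False)
    print(f"\nwrote {RESULTS/'statistics.csv'}")


if __name__ == "__main__":
    main()
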