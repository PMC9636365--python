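import numpy as np
import pandas as pd
import pytest

import overreach as ov


@pytest.fixture(scope="session")
def reference_matrix() -> ov.ScoreMatrix:
    return ov.build_reference_score_matrix()


@pytest.fixture(scope="session")
def reference_cutoffs() -> ov.CutoffSet:
    return ov.reference_cutoffs()


@pytest.fixture()
def tiny_cohort() -> pd.DataFrame:
    """Two subjects, hand-sized values on all six phases."""
    rows = []
    base = {
        "A": dict(poms_fatigue=40.0, hr_max=185.0, glucose_end=6.0, lactate_end=13.0, rpe_mean=17.0),
        "B": dict(poms_fatigue=45.0, hr_max=180.0, glucose_end=6.5, lactate_end=14.0, rpe_mean=18.0),
    }
    for subj, vals in base.items():
        for phase in ("BL", "LT", "MT1", "MT2", "MAL", "RE"):
            row = {"subject_id": subj, "phase_id": phase, **vals}
            if phase == "MAL":
                row["poms_fatigue"] += 10.0
                row["hr_max"] -= 6.0
                row["glucose_end"] -= 1.5
                row["lactate_end"] -= 1.4
                row["rpe_mean"] += 1.2
            rows.append(row)
    return pd.DataFrame(rows)


def brute_force_scores(panels, baselines, cutoffs, specs=ov.DEFAULT_PARAMETERS):
    """Independent per-cell evaluation of the scoring inequality (plain loops)."""
    out = []
    for _, row in panels.iterrows():
        rec = {"subject_id": row["subject_id"], "phase_id": row["phase_id"]}
        for s in specs:
            obs = row[s.name]
            if pd.isna(obs):
                rec[s.name] = 0
                continue
            b = baselines.values.loc[row["subject_id"], s.name]
            c = (
                cutoffs.values.loc[row["subject_id"], s.name]
                if cutoffs.per_subject
                else cutoffs.values[s.name]
            )
            dev = obs - b
            rec[s.name] = int(s.direction * dev > s.direction * c)
        out.append(rec)
    return (
        pd.DataFrame(out)
        .set_index(["subject_id", "phase_id"])
        .sort_index()
    )
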