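"""Synthetic cohorts: a constrained reference score matrix and generators for
measurement panels, respiration records and exercise sessions.

The published study deposited no raw data; what it prints are marginals — how
many of the 11 subjects scored positive on each parameter in each phase, and
how many accumulated >= k of 5 scores per phase. This module (a) rebuilds a
deterministic binary score matrix consistent with those marginals, and (b)
realises any feasible score matrix as continuous measurement panels whose
re-derived scores round-trip exactly, so every diagnostic operation can be
exercised end to end.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .model import Baselines, CutoffSet, ScoreMatrix, compute_baselines, score
from .params import (
    BIOPSY_PHASES,
    DEFAULT_PARAMETER_NAMES,
    DEFAULT_PARAMETERS,
    DEFAULT_SCHEDULE,
    PUBLISHED_GROUP_MEANS,
    ParameterSpec,
    PhaseSchedule,
)

__all__ = [
    "MarginalConstraints",
    "load_reference_constraints",
    "build_reference_score_matrix",
    "GeneratorConfig",
    "reference_cutoffs",
    "generate_measurements",
    "generate_respiration",
    "generate_effect_cohort",
    "generate_session",
    "simulate_cohort",
]


@dataclass(frozen=True)
class MarginalConstraints:
    """Published per-phase scoring marginals.

    ``param_counts``: parameters x phases, subjects scoring positive on each
    parameter. ``cumulative``: k x phases, subjects with >= k of 5 scores.
    """

    param_counts: pd.DataFrame
    cumulative: pd.DataFrame
    cohort_size: int = 11

    def validate(self) -> None:
        for phase in self.param_counts.columns:
            cum = self.cumulative[phase].to_numpy()
            if (np.diff(cum) > 0).any():
                raise ValueError(f"phase {phase!r}: cumulative counts increase in k")
            if (cum > self.cohort_size).any() or (cum < 0).any():
                raise ValueError(f"phase {phase!r}: cumulative counts outside 0..n")
            col_total = int(self.param_counts[phase].sum())
            exact = self.exact_counts()[phase]
            joint_total = int(sum(k * c for k, c in exact.items()))
            if col_total != joint_total:
                raise ValueError(
                    f"phase {phase!r}: parameter counts total {col_total} but the "
                    f"joint distribution implies {joint_total} positive scores"
                )

    def exact_counts(self) -> pd.DataFrame:
        """Subjects with exactly k scores per phase (difference of cumulatives)."""
        cum = self.cumulative.sort_index()
        exact = cum - cum.shift(-1).fillna(0)
        return exact.astype(int)

    def row_sums(self, phase: str) -> list[int]:
        """Per-subject score totals for one phase, descending."""
        exact = self.exact_counts()[phase]
        sums = [k for k in sorted(exact.index, reverse=True) for _ in range(exact[k])]
        sums += [0] * (self.cohort_size - len(sums))
        return sums


def load_reference_constraints() -> MarginalConstraints:
    """The packaged 11-subject, 6-phase study marginals."""
    with importlib.resources.files("overreach.data").joinpath(
        "score_marginals.csv"
    ).open() as fh:
        raw = pd.read_csv(fh)
    phases = [c for c in raw.columns if c not in ("kind", "name")]
    params = raw[raw["kind"] == "parameter"].set_index("name")[phases]
    cum = raw[raw["kind"] == "cumulative"].copy()
    cum["name"] = cum["name"].astype(int)
    cum = cum.set_index("name")[phases].rename_axis(index="k")
    mc = MarginalConstraints(param_counts=params.astype(int), cumulative=cum.astype(int))
    mc.validate()
    return mc


def _gale_ryser_feasible(row_sums: Sequence[int], col_sums: Sequence[int]) -> tuple[bool, str]:
    """Gale-Ryser feasibility of a 0/1 matrix with the given margins."""
    r = sorted(row_sums, reverse=True)
    c = list(col_sums)
    if sum(r) != sum(c):
        return False, f"row total {sum(r)} != column total {sum(c)}"
    if r and r[0] > len(c):
        return False, f"row sum {r[0]} exceeds {len(c)} columns"
    for k in range(1, len(r) + 1):
        lhs = sum(r[:k])
        rhs = sum(min(cj, k) for cj in c)
        if lhs > rhs:
            return False, f"Gale-Ryser bound violated at k={k}: {lhs} > {rhs}"
    return True, ""


def _fill_phase(
    row_sums: Sequence[int],
    col_sums: Sequence[int],
    n_params: int,
    rng: np.random.Generator | None,
) -> np.ndarray:
    """Greedy bipartite construction: highest row sums first, columns by
    descending remaining capacity, index-order tie-breaking (or seeded
    tie-breaking when ``rng`` is given)."""
    n = len(row_sums)
    remaining = np.array(col_sums, dtype=int)
    out = np.zeros((n, n_params), dtype=int)
    order = np.argsort(-np.array(row_sums), kind="stable")
    if rng is not None:
        perm = rng.permutation(n)
        order = perm[np.argsort(-np.array(row_sums)[perm], kind="stable")]
    for i in order:
        r = row_sums[i]
        if r == 0:
            continue
        if rng is None:
            cols = np.argsort(-remaining, kind="stable")[:r]
        else:
            jitter = rng.random(n_params)
            cols = np.lexsort((jitter, -remaining))[:r]
        out[i, cols] = 1
        remaining[cols] -= 1
    if (remaining != 0).any():
        raise ValueError("greedy fill failed to satisfy column sums")
    return out


def build_reference_score_matrix(
    constraints: MarginalConstraints | None = None,
    subject_ids: Sequence[str] | None = None,
    rng: np.random.Generator | None = None,
) -> ScoreMatrix:
    """Deterministic binary score matrix matching the published marginals.

    Per phase the column sums equal the per-parameter positive counts and the
    row-sum distribution equals the published joint (>= k of 5) distribution.
    Which subject received which parameter's score is not identified by the
    marginals; the default assignment is a canonical deterministic greedy
    (subject 1 gets the most scores). Pass a seeded ``rng`` for a randomized
    alternative consistent with the same marginals.
    """
    mc = constraints or load_reference_constraints()
    mc.validate()
    params = list(mc.param_counts.index)
    phases = list(mc.param_counts.columns)
    n = mc.cohort_size
    subjects = list(subject_ids or [f"S{i:02d}" for i in range(1, n + 1)])
    if len(subjects) != n:
        raise ValueError(f"need {n} subject ids, got {len(subjects)}")

    blocks = []
    for phase in phases:
        row_sums = mc.row_sums(phase)
        col_sums = mc.param_counts[phase].tolist()
        ok, why = _gale_ryser_feasible(row_sums, col_sums)
        if not ok:
            raise ValueError(f"phase {phase!r}: infeasible marginals ({why})")
        block = _fill_phase(row_sums, col_sums, len(params), rng)
        frame = pd.DataFrame(block, columns=params)
        frame.insert(0, "subject_id", subjects)
        frame.insert(1, "phase_id", phase)
        blocks.append(frame)
    tall = pd.concat(blocks, ignore_index=True)
    scores = tall.set_index(["subject_id", "phase_id"])[params]
    return ScoreMatrix(scores=scores.sort_index())


def reference_cutoffs(
    group_means: Mapping[str, tuple[float, float]] = PUBLISHED_GROUP_MEANS,
) -> CutoffSet:
    """Full-precision cut-offs from the published group means.

    (MAL mean - normal mean) / 2 without display rounding, e.g. the POMS
    fatigue cut-off is 4.65 although the published table prints 4.7.
    """
    normal = pd.Series({k: v[0] for k, v in group_means.items()})
    mal = pd.Series({k: v[1] for k, v in group_means.items()})
    return CutoffSet(
        values=((mal - normal) / 2.0).rename("cutoff"),
        provenance="derived",
        normal_means=normal,
        mal_means=mal,
    )


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-conditions configuration for the synthetic generators.

    Parameter means are the published normal-phase group means; MAL shifts are
    the published MAL-vs-normal mean differences. Between-subject SDs are
    plausible values (the study prints only figure error bars) and are meant
    to be overridden when better estimates exist. Respiration is in arbitrary
    but consistent units; only the relative MAL effect (default -40%) is
    anchored to the study.
    """

    n_subjects: int = 11
    parameter_means: Mapping[str, float] = field(
        default_factory=lambda: {
            "poms_fatigue": 42.6,
            "hr_max": 183.6,
            "glucose_end": 6.11,
            "lactate_end": 13.28,
            "rpe_mean": 17.5,
        }
    )
    parameter_between_sd: Mapping[str, float] = field(
        default_factory=lambda: {
            "poms_fatigue": 8.0,
            "hr_max": 8.0,
            "glucose_end": 0.6,
            "lactate_end": 1.8,
            "rpe_mean": 1.0,
        }
    )
    mal_mean_shifts: Mapping[str, float] = field(
        default_factory=lambda: {
            "poms_fatigue": +9.3,
            "hr_max": -5.1,
            "glucose_end": -1.43,
            "lactate_end": -1.25,
            "rpe_mean": +1.0,
        }
    )
    beyond_range: tuple[float, float] = (1.2, 2.0)
    within_range: tuple[float, float] = (0.0, 0.8)
    max_redraws: int = 10
    respiration_mean: float = 100.0
    respiration_between_sd: float = 15.0
    respiration_within_sd: float = 8.0
    mal_respiration_effect: float = -0.40
    warmup_power_w: float = 100.0
    interval_power_w: float = 250.0
    session_rer: float = 0.95
    hr_rest_bpm: float = 70.0
    hr_warmup_bpm: float = 140.0
    hr_interval_bpm: float = 185.0
    hr_tau_work_s: float = 45.0
    hr_tau_rest_s: float = 60.0


DEFAULT_GENERATOR_CONFIG = GeneratorConfig()


def _target_deviations(
    cells: np.ndarray,
    normal_idx: np.ndarray,
    rng: np.random.Generator,
    config: GeneratorConfig,
) -> np.ndarray:
    """Normalized target deviations (units of |cutoff|, adverse direction
    positive) for one subject-parameter across phases, arranged so that the
    normal-phase targets average exactly zero — the individual baseline then
    lands on the subject anchor and every realised deviation equals its
    target."""
    lo_b, hi_b = config.beyond_range
    lo_w, hi_w = config.within_range
    y = np.empty(len(cells), dtype=float)
    normal_mask = np.zeros(len(cells), dtype=bool)
    normal_mask[normal_idx] = True
    pos_normal = normal_mask & (cells == 1)
    zero_normal = normal_mask & (cells == 0)
    m = int(zero_normal.sum())
    if pos_normal.any() and m == 0:
        raise ValueError(
            "matrix requires a positive score in every normal-reference phase; "
            "no measurement set can deviate above its own baseline everywhere"
        )
    y[pos_normal] = rng.uniform(lo_b, hi_b, pos_normal.sum())
    if m:
        balance = -float(y[pos_normal].sum()) / m
        wiggle = rng.uniform(-0.2, 0.2, m)
        y[zero_normal] = balance + (wiggle - wiggle.mean())
    test = ~normal_mask
    pos_test = test & (cells == 1)
    zero_test = test & (cells == 0)
    y[pos_test] = rng.uniform(lo_b, hi_b, pos_test.sum())
    y[zero_test] = rng.uniform(lo_w, hi_w, zero_test.sum())
    return y


def generate_measurements(
    matrix: ScoreMatrix,
    config: GeneratorConfig = DEFAULT_GENERATOR_CONFIG,
    cutoffs: CutoffSet | None = None,
    seed: int | np.random.Generator = 0,
    schedule: PhaseSchedule = DEFAULT_SCHEDULE,
    specs: Sequence[ParameterSpec] = DEFAULT_PARAMETERS,
) -> pd.DataFrame:
    """Continuous measurement panels whose re-derived scores equal ``matrix``.

    Each subject-parameter gets an anchor value from the phase-mean +/- SD
    model; deviations are placed beyond the cut-off (positive cells, margin
    1.2-2.0x) or within it (zero cells, 0-0.8x), with the normal-phase
    deviations balanced to sum to zero so the recomputed individual baseline
    equals the anchor and the round trip is exact. The result is re-scored as
    a verification; mismatching subjects are redrawn up to ``max_redraws``
    times before an incompatible-configuration error.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    cutoffs = cutoffs or reference_cutoffs()
    if cutoffs.per_subject:
        raise ValueError("generation needs group cut-offs, not per-subject ones")
    params = list(matrix.scores.columns)
    phases = [p for p in schedule.phases if p in matrix.scores.index.get_level_values("phase_id")]
    normal_idx = np.array([phases.index(p) for p in schedule.normal_phases if p in phases])
    subjects = matrix.scores.index.get_level_values("subject_id").unique()

    rows = []
    for subj in subjects:
        sub_scores = matrix.scores.xs(subj, level="subject_id").reindex(phases)
        for attempt in range(config.max_redraws + 1):
            values = np.empty((len(phases), len(params)))
            for j, p in enumerate(params):
                cut = float(cutoffs.values[p])
                if cut == 0 and sub_scores[p].to_numpy().any():
                    raise ValueError(f"parameter {p!r} has zero cut-off but positive cells")
                anchor = rng.normal(config.parameter_means[p], config.parameter_between_sd[p])
                y = _target_deviations(sub_scores[p].to_numpy(), normal_idx, rng, config)
                # cut carries the adverse sign, y is in adverse-direction units
                values[:, j] = anchor + cut * y
            frame = pd.DataFrame(values, columns=params)
            frame.insert(0, "subject_id", subj)
            frame.insert(1, "phase_id", phases)
            _clip_physiologic(frame)
            # verify after clipping: a clipped extreme could otherwise flip a cell
            check = _rescore(frame, cutoffs, schedule, specs)
            if check.equals(sub_scores.astype(int)):
                rows.append(frame)
                break
        else:
            raise RuntimeError(
                f"could not realise the score pattern for subject {subj!r} in "
                f"{config.max_redraws} redraws; configuration incompatible"
            )
    return pd.concat(rows, ignore_index=True)


def _clip_physiologic(frame: pd.DataFrame) -> None:
    if "hr_max" in frame:
        frame["hr_max"] = frame["hr_max"].clip(lower=1.0)
    if "rpe_mean" in frame:
        frame["rpe_mean"] = frame["rpe_mean"].clip(6.0, 20.0)
    for col in ("glucose_end", "lactate_end"):
        if col in frame:
            frame[col] = frame[col].clip(lower=0.0)


def _rescore(
    frame: pd.DataFrame,
    cutoffs: CutoffSet,
    schedule: PhaseSchedule,
    specs: Sequence[ParameterSpec],
) -> pd.DataFrame:
    baselines = compute_baselines(frame, schedule, specs)
    sm = score(frame, baselines, cutoffs, specs)
    return (
        sm.scores.xs(frame["subject_id"].iloc[0], level="subject_id")
        .reindex(frame["phase_id"])
        .astype(int)
    )


def generate_respiration(
    config: GeneratorConfig = DEFAULT_GENERATOR_CONFIG,
    seed: int | np.random.Generator = 0,
    n_subjects: int | None = None,
    phases: Sequence[str] = BIOPSY_PHASES,
    schedule: PhaseSchedule = DEFAULT_SCHEDULE,
) -> pd.DataFrame:
    """Intrinsic mitochondrial respiration records per subject and phase.

    Normal-load phases scatter around a subject-level mean; the maladaptive
    phase is shifted by ``mal_respiration_effect`` (default -40% of the
    subject mean). MT2 is omitted: no biopsy was taken there.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    n = n_subjects or config.n_subjects
    rows = []
    for i in range(1, n + 1):
        subj = f"S{i:02d}"
        level = rng.normal(config.respiration_mean, config.respiration_between_sd)
        for phase in phases:
            mean = level * (1.0 + config.mal_respiration_effect) if phase == schedule.mal_phase else level
            rows.append(
                {
                    "subject_id": subj,
                    "phase_id": phase,
                    "respiration": mean + rng.normal(0.0, config.respiration_within_sd),
                }
            )
    return pd.DataFrame(rows)


def generate_effect_cohort(
    config: GeneratorConfig = DEFAULT_GENERATOR_CONFIG,
    seed: int | np.random.Generator = 0,
    noise_sd: Mapping[str, float] | None = None,
    schedule: PhaseSchedule = DEFAULT_SCHEDULE,
    specs: Sequence[ParameterSpec] = DEFAULT_PARAMETERS,
) -> pd.DataFrame:
    """Mean-shift cohort for classifier-recovery simulations.

    Unlike :func:`generate_measurements` (which realises a prescribed score
    pattern), this draws every phase around the subject's own level with
    measurement noise and shifts only the maladaptive phase by the published
    effect sizes. Default noise SD is half the cut-off magnitude, i.e. a
    quarter of the MAL effect.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    names = [s.name for s in specs]
    if noise_sd is None:
        noise_sd = {p: abs(config.mal_mean_shifts[p]) / 4.0 for p in names}
    rows = []
    for i in range(1, config.n_subjects + 1):
        subj = f"S{i:02d}"
        level = {
            p: rng.normal(config.parameter_means[p], config.parameter_between_sd[p])
            for p in names
        }
        for phase in schedule.phases:
            row = {"subject_id": subj, "phase_id": phase}
            for p in names:
                shift = config.mal_mean_shifts[p] if phase == schedule.mal_phase else 0.0
                row[p] = level[p] + shift + rng.normal(0.0, noise_sd[p])
            rows.append(row)
    return pd.DataFrame(rows)


def generate_session(
    config: GeneratorConfig = DEFAULT_GENERATOR_CONFIG,
    seed: int | np.random.Generator = 0,
    noise_sd_hr: float = 1.5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """A synthetic interval-training session at 1 Hz with segment markers.

    Layout: 10 min warm-up at 100 W, 2 min rest, then five 4-min work
    intervals separated by 3 min of passive rest. Heart rate relaxes
    exponentially toward a segment target (rising in work, decaying in rest);
    VO2 tracks power through the same first-order response and VCO2 is
    RER x VO2.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    segments: list[tuple[str, float, float, float]] = [("warmup", 600, config.warmup_power_w, config.hr_warmup_bpm)]
    segments.append(("rest 0", 120, 0.0, config.hr_rest_bpm + 30))
    for k in range(1, 6):
        power = config.interval_power_w * rng.uniform(0.97, 1.03)
        segments.append((f"interval {k}", 240, power, config.hr_interval_bpm))
        segments.append((f"rest {k}", 180, 0.0, config.hr_rest_bpm + 30))

    times, hrs, powers, vo2s, labels = [], [], [], [], []
    marker_rows = []
    t = 0
    hr = config.hr_rest_bpm
    vo2 = 0.3
    for label, dur, power, hr_target in segments:
        tau = config.hr_tau_work_s if power > 0 else config.hr_tau_rest_s
        vo2_target = 0.3 + 0.0115 * power  # ~10 mL/min/W + rest metabolism
        marker_rows.append({"label": label, "start_s": t, "end_s": t + dur - 1})
        for _ in range(int(dur)):
            hr += (hr_target - hr) / tau
            vo2 += (vo2_target - vo2) / 25.0
            times.append(t)
            hrs.append(hr + rng.normal(0.0, noise_sd_hr))
            powers.append(power)
            vo2s.append(max(vo2 + rng.normal(0.0, 0.03), 0.05))
            labels.append(label)
            t += 1
    session = pd.DataFrame(
        {
            "time_s": np.array(times, dtype=float),
            "hr_bpm": np.clip(hrs, 40.0, None),
            "vo2_lmin": vo2s,
            "power_w": np.array(powers, dtype=float),
            "label": labels,
        }
    )
    session["vco2_lmin"] = session["vo2_lmin"] * config.session_rer
    session = session[["time_s", "hr_bpm", "vo2_lmin", "vco2_lmin", "power_w", "label"]]
    return session, pd.DataFrame(marker_rows)


def simulate_cohort(
    seed: int = 0,
    config: GeneratorConfig = DEFAULT_GENERATOR_CONFIG,
    randomized_matrix: bool = False,
) -> dict:
    """One full synthetic cohort: score matrix, panels, respiration records.

    Returns a dict with keys ``matrix`` (ScoreMatrix), ``panels``,
    ``respiration`` (DataFrames) and ``cutoffs`` (the full-precision reference
    CutoffSet used to place the measurements).
    """
    rng = np.random.default_rng(seed)
    matrix = build_reference_score_matrix(rng=rng if randomized_matrix else None)
    cutoffs = reference_cutoffs()
    panels = generate_measurements(matrix, config, cutoffs, seed=rng)
    respiration = generate_respiration(config, seed=rng)
    return {"matrix": matrix, "panels": panels, "respiration": respiration, "cutoffs": cutoffs}
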