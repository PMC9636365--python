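"""Individual baselines, group cut-offs, directional scoring and classification.

The model works on a tidy *panel* table: one row per (subject, phase), one
column per diagnostic parameter. For each subject and parameter an individual
baseline is the mean over the normal-reference phases. A group cut-off is half
the difference between the cohort mean during the maladaptive phase and the
cohort mean during normal training load, carrying the sign of the adverse
direction. A subject-phase observation scores 1 on a parameter when its
deviation from the individual baseline exceeds the cut-off strictly in the
adverse direction; a subject is flagged as maladapted in a phase when at least
``threshold`` (default 3) of the 5 parameters score 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .params import (
    BIOPSY_PHASES,
    DEFAULT_PARAMETERS,
    DEFAULT_SCHEDULE,
    ParameterSpec,
    PhaseSchedule,
)

__all__ = [
    "Baselines",
    "CutoffSet",
    "ScoreMatrix",
    "CorrelationReport",
    "compute_baselines",
    "derive_cutoffs",
    "fixed_cutoffs",
    "individual_cutoffs",
    "score",
    "classify",
    "respiration_deltas",
    "correlate_scores_respiration",
    "pooled_mean",
]


def _check_panels(panels: pd.DataFrame, parameters: Sequence[str]) -> None:
    for col in ("subject_id", "phase_id"):
        if col not in panels.columns:
            raise ValueError(f"panel table is missing required column {col!r}")
    missing = [p for p in parameters if p not in panels.columns]
    if missing:
        raise ValueError(f"panel table is missing parameter columns {missing}")
    dup = panels.duplicated(["subject_id", "phase_id"])
    if dup.any():
        pairs = panels.loc[dup, ["subject_id", "phase_id"]].to_records(index=False)
        raise ValueError(f"duplicate (subject, phase) rows: {list(pairs)[:5]}")


@dataclass
class Baselines:
    """Per-subject baselines: parameter means over the normal-reference phases.

    ``values`` is subjects x parameters; ``counts`` holds the number of
    non-missing normal-phase observations behind each mean.
    """

    values: pd.DataFrame
    counts: pd.DataFrame

    @property
    def subjects(self) -> pd.Index:
        return self.values.index

    @property
    def parameters(self) -> pd.Index:
        return self.values.columns


@dataclass
class CutoffSet:
    """Signed per-parameter deviation thresholds.

    ``values`` is a Series (group mode) or a subjects x parameters DataFrame
    (individual mode). ``provenance`` records how they were obtained; for
    derived cut-offs the group means used are kept for reporting.
    """

    values: pd.Series | pd.DataFrame
    provenance: Literal["derived", "fixed", "individual"]
    normal_means: pd.Series | None = None
    mal_means: pd.Series | None = None

    @property
    def per_subject(self) -> bool:
        return isinstance(self.values, pd.DataFrame)

    def for_subject(self, subject_id) -> pd.Series:
        return self.values.loc[subject_id] if self.per_subject else self.values


@dataclass
class ScoreMatrix:
    """Binary positive-score indicators, (subject, phase) x parameter.

    ``scores`` has a (subject_id, phase_id) MultiIndex; cells are 0/1.
    ``missing`` marks cells scored 0 because the observation was absent.
    """

    scores: pd.DataFrame
    missing: pd.DataFrame | None = None

    @property
    def n_scores(self) -> pd.Series:
        return self.scores.sum(axis=1).rename("n_scores")

    def phase_parameter_counts(self) -> pd.DataFrame:
        """Subjects scoring positive per (parameter, phase) — the published
        table's per-parameter count layout."""
        counts = self.scores.groupby(level="phase_id", sort=False).sum()
        return counts.T

    def cumulative_counts(self, max_k: int | None = None) -> pd.DataFrame:
        """Number of subjects with >= k positive scores per phase, k = 1..K."""
        k_max = max_k or self.scores.shape[1]
        n = self.n_scores
        rows = {}
        for k in range(1, k_max + 1):
            rows[k] = (n >= k).groupby(level="phase_id", sort=False).sum()
        return pd.DataFrame(rows).T.rename_axis(index="k")


def compute_baselines(
    panels: pd.DataFrame,
    schedule: PhaseSchedule = DEFAULT_SCHEDULE,
    specs: Sequence[ParameterSpec] = DEFAULT_PARAMETERS,
) -> Baselines:
    """Individual baseline = mean over the subject's normal-reference phases.

    Missing phase values are skipped (the contributing count drops, with a
    warning). A subject with no usable normal-phase value for a parameter is a
    hard error: without a baseline that subject cannot be scored at all.
    """
    names = [s.name for s in specs]
    _check_panels(panels, names)
    normal = panels[panels["phase_id"].isin(schedule.normal_phases)]
    if normal.empty:
        raise ValueError("no rows in any normal-reference phase")
    grouped = normal.groupby("subject_id", sort=True)[names]
    values = grouped.mean()
    counts = grouped.count()

    n_phases = len(schedule.normal_phases)
    incomplete = counts < n_phases
    if incomplete.to_numpy().any():
        for subj, row in counts[incomplete.any(axis=1)].iterrows():
            for p in names:
                if row[p] < n_phases:
                    if row[p] == 0:
                        raise ValueError(
                            f"subject {subj!r} has no normal-phase value for "
                            f"parameter {p!r}; baseline undefined"
                        )
                    warnings.warn(
                        f"subject {subj!r}: baseline for {p!r} uses "
                        f"{int(row[p])}/{n_phases} normal phases",
                        stacklevel=2,
                    )
    return Baselines(values=values, counts=counts.astype(int))


def _group_means(
    panels: pd.DataFrame,
    phases: Iterable[str],
    names: Sequence[str],
    pooling: str,
) -> pd.Series:
    sub = panels[panels["phase_id"].isin(list(phases))]
    if sub[names].count().eq(0).any() or sub.empty:
        empty = [p for p in names if sub.empty or sub[p].count() == 0]
        raise ValueError(f"no observations in phases {list(phases)} for {empty or names}")
    if pooling == "observations":
        return sub[names].mean()
    if pooling == "subjects":
        return sub.groupby("subject_id")[names].mean().mean()
    raise ValueError(f"unknown pooling mode {pooling!r}")


def derive_cutoffs(
    panels: pd.DataFrame,
    schedule: PhaseSchedule = DEFAULT_SCHEDULE,
    specs: Sequence[ParameterSpec] = DEFAULT_PARAMETERS,
    pooling: Literal["observations", "subjects"] = "observations",
) -> CutoffSet:
    """Group cut-off per parameter: (MAL mean - normal mean) / 2, full precision.

    Group means pool all subject x normal-phase observations with equal weight
    by default; ``pooling="subjects"`` averages within subject first. A derived
    cut-off whose sign contradicts the parameter's adverse direction triggers a
    direction-mismatch warning (it usually means the cohort shows no adverse
    shift for that parameter).
    """
    names = [s.name for s in specs]
    _check_panels(panels, names)
    mal = panels[panels["phase_id"] == schedule.mal_phase]
    if mal["subject_id"].nunique() < 2:
        raise ValueError(
            f"need the maladaptive phase {schedule.mal_phase!r} for >=2 subjects"
        )
    normal_means = _group_means(panels, schedule.normal_phases, names, pooling)
    mal_means = _group_means(panels, [schedule.mal_phase], names, pooling)
    cutoffs = (mal_means - normal_means) / 2.0
    for s in specs:
        if np.sign(cutoffs[s.name]) != s.direction:
            warnings.warn(
                f"cut-off for {s.name!r} ({cutoffs[s.name]:+.4g}) does not match "
                f"the adverse direction ({s.direction:+d})",
                stacklevel=2,
            )
    return CutoffSet(
        values=cutoffs.rename("cutoff"),
        provenance="derived",
        normal_means=normal_means,
        mal_means=mal_means,
    )


def fixed_cutoffs(values: Mapping[str, float]) -> CutoffSet:
    """Wrap externally supplied cut-offs (e.g. the published table's values)."""
    return CutoffSet(values=pd.Series(dict(values), name="cutoff"), provenance="fixed")


def individual_cutoffs(
    panels: pd.DataFrame,
    schedule: PhaseSchedule = DEFAULT_SCHEDULE,
    specs: Sequence[ParameterSpec] = DEFAULT_PARAMETERS,
) -> CutoffSet:
    """Per-subject cut-offs: half the subject's own MAL-vs-baseline shift.

    A non-default experimentation mode. Individual cut-offs are less stable
    than group-derived ones (a single aberrant measurement moves them), which
    is why the group mode is the default.
    """
    names = [s.name for s in specs]
    _check_panels(panels, names)
    baselines = compute_baselines(panels, schedule, specs)
    mal = (
        panels[panels["phase_id"] == schedule.mal_phase]
        .set_index("subject_id")[names]
        .reindex(baselines.subjects)
    )
    if mal.isna().all(axis=1).any():
        missing = mal.index[mal.isna().all(axis=1)].tolist()
        raise ValueError(f"subjects {missing} have no {schedule.mal_phase!r} observations")
    return CutoffSet(values=(mal - baselines.values) / 2.0, provenance="individual")


def score(
    panels: pd.DataFrame,
    baselines: Baselines,
    cutoffs: CutoffSet,
    specs: Sequence[ParameterSpec] = DEFAULT_PARAMETERS,
) -> ScoreMatrix:
    """Score each (subject, phase, parameter) cell.

    A cell is 1 iff ``direction * (observed - baseline) > direction * cutoff``
    — i.e. the deviation from the individual baseline exceeds the cut-off
    strictly in the adverse direction. A deviation exactly equal to the
    cut-off scores 0. Missing observations score 0 and are flagged in
    ``missing`` (conservative: absence of evidence is not evidence of
    maladaptation).
    """
    names = [s.name for s in specs]
    _check_panels(panels, names)
    not_covered = set(panels["subject_id"]) - set(baselines.subjects)
    if not_covered:
        raise ValueError(f"no baselines for subjects {sorted(not_covered)}")
    if cutoffs.per_subject:
        missing_cut = set(panels["subject_id"]) - set(cutoffs.values.index)
        if missing_cut:
            raise ValueError(f"no individual cut-offs for subjects {sorted(missing_cut)}")
    missing_params = set(names) - set(
        cutoffs.values.columns if cutoffs.per_subject else cutoffs.values.index
    )
    if missing_params:
        raise ValueError(f"cut-offs missing parameters {sorted(missing_params)}")

    idx = pd.MultiIndex.from_frame(
        panels[["subject_id", "phase_id"]], names=["subject_id", "phase_id"]
    )
    obs = panels[names].set_axis(idx)
    base = baselines.values.reindex(idx.get_level_values("subject_id")).set_axis(idx)
    deviation = obs - base

    dirs = pd.Series({s.name: s.direction for s in specs})[names]
    if cutoffs.per_subject:
        cut = (
            cutoffs.values[names]
            .reindex(idx.get_level_values("subject_id"))
            .set_axis(idx)
        )
    else:
        cut = cutoffs.values[names]
    # adverse-direction comparison; strict inequality so ties score 0
    exceeded = deviation.mul(dirs, axis=1) > (cut * dirs if not cutoffs.per_subject else cut.mul(dirs, axis=1))
    missing = obs.isna()
    scores = exceeded.astype(int).where(~missing, 0).astype(int)
    return ScoreMatrix(scores=scores.sort_index(), missing=missing.sort_index())


def classify(scores: ScoreMatrix, threshold: int = 3) -> pd.DataFrame:
    """Flag subject-phases with ``n_scores >= threshold`` (default 3 of 5).

    Returns a frame ordered by (subject, phase) with columns n_scores,
    flagged, threshold.
    """
    n_params = scores.scores.shape[1]
    if not 1 <= threshold <= n_params:
        raise ValueError(f"threshold must be in 1..{n_params}, got {threshold}")
    out = scores.n_scores.reset_index()
    out["flagged"] = out["n_scores"] >= threshold
    out["threshold"] = threshold
    return out.sort_values(["subject_id", "phase_id"], ignore_index=True)


def respiration_deltas(
    records: pd.DataFrame,
    schedule: PhaseSchedule = DEFAULT_SCHEDULE,
) -> pd.DataFrame:
    """Reference each respiration value to the subject's normal respiration.

    Normal respiration is the mean over the subject's normal-reference phases
    (mean over whichever are present, with a warning when some are missing).
    Adds ``normal_respiration`` and ``delta = respiration - normal_respiration``
    columns. Deltas over a subject's complete set of normal phases sum to 0 by
    construction.
    """
    for col in ("subject_id", "phase_id", "respiration"):
        if col not in records.columns:
            raise ValueError(f"respiration table is missing column {col!r}")
    normal = records[records["phase_id"].isin(schedule.normal_phases)]
    stats_ = normal.groupby("subject_id")["respiration"].agg(["mean", "count"])
    missing_subjects = set(records["subject_id"]) - set(
        stats_.index[stats_["count"] > 0]
    )
    if missing_subjects:
        raise ValueError(
            f"subjects {sorted(missing_subjects)} have no normal-phase respiration"
        )
    short = stats_.index[stats_["count"] < len(schedule.normal_phases)]
    for subj in short:
        warnings.warn(
            f"subject {subj!r}: normal respiration from "
            f"{int(stats_.loc[subj, 'count'])}/{len(schedule.normal_phases)} phases",
            stacklevel=2,
        )
    out = records.copy()
    out["normal_respiration"] = out["subject_id"].map(stats_["mean"])
    out["delta"] = out["respiration"] - out["normal_respiration"]
    return out


@dataclass(frozen=True)
class CorrelationReport:
    r: float
    p: float
    n: int
    n_dropped: int = 0


def correlate_scores_respiration(
    n_scores: pd.Series | pd.DataFrame,
    deltas: pd.DataFrame,
    biopsy_phases: Sequence[str] = BIOPSY_PHASES,
) -> CorrelationReport:
    """Pearson correlation between accumulated scores and respiration change.

    Pairs (n_scores, delta) are matched on (subject, phase), restricted to
    phases with biopsies. The p-value is the standard two-sided t-transform
    with n-2 degrees of freedom. Zero variance in either vector is an error
    (r is undefined there, not 0).
    """
    if isinstance(n_scores, pd.DataFrame):
        n_scores = n_scores.set_index(["subject_id", "phase_id"])["n_scores"]
    d = deltas.set_index(["subject_id", "phase_id"])["delta"]
    d = d[d.index.get_level_values("phase_id").isin(list(biopsy_phases))]
    s = n_scores[n_scores.index.get_level_values("phase_id").isin(list(biopsy_phases))]
    joined = pd.concat([s.rename("n_scores"), d.rename("delta")], axis=1, join="inner")
    n_dropped = int(joined["delta"].isna().sum() + joined["n_scores"].isna().sum())
    joined = joined.dropna()
    if len(joined) < 3:
        raise ValueError(f"need >=3 matched pairs, got {len(joined)}")
    x = joined["n_scores"].to_numpy(float)
    y = joined["delta"].to_numpy(float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in scores or deltas; correlation undefined")
    res = stats.pearsonr(x, y)
    return CorrelationReport(
        r=float(res.statistic), p=float(res.pvalue), n=len(joined), n_dropped=n_dropped
    )


def pooled_mean(
    strata: Sequence[tuple[int, float]],
    decimals: int | None = None,
) -> float:
    """Sample-size-weighted pooled mean of stratum means.

    ``strata`` is a sequence of (n, mean). The result is rounded
    half-away-from-zero to ``decimals``; when ``decimals`` is None the largest
    number of decimals printed in the inputs is used, matching how pooled rows
    are printed in subject-characteristics tables.
    """
    if not strata:
        raise ValueError("no strata")
    ns = np.array([n for n, _ in strata], dtype=float)
    means = np.array([m for _, m in strata], dtype=float)
    if (ns < 1).any():
        raise ValueError("every stratum needs n >= 1")
    total = ns.sum()
    if total <= 0:
        raise ValueError("zero total n")
    pooled = float((ns * means).sum() / total)
    if decimals is None:
        decimals = max(_printed_decimals(m) for _, m in strata)
    shifted = pooled * 10**decimals
    rounded = np.sign(shifted) * np.floor(np.abs(shifted) + 0.5)
    return float(rounded / 10**decimals)


def _printed_decimals(x: float) -> int:
    text = f"{x!r}"
    if "." in text:
        return len(text.split(".")[1])
    return 0
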