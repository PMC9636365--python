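"""End-to-end diagnostic pipeline: panels in, auditable report out."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import model
from .io import RunConfig, read_panels, read_respiration, write_table
from .params import DEFAULT_PARAMETERS

logger = logging.getLogger("overreach")

__all__ = ["DiagnosticReport", "run_pipeline"]


@dataclass
class DiagnosticReport:
    """Everything one diagnostic run produced.

    ``detail`` has one row per subject-phase-parameter (observed value,
    baseline, deviation, cut-off applied, score); ``classification`` one row
    per subject-phase; ``parameter_summary`` mirrors the published cut-off
    table (group means, cut-off, positive counts per phase);
    ``joint_summary`` the >= k of 5 counts per phase. ``correlation`` is
    filled when respiration records were supplied.
    """

    detail: pd.DataFrame
    classification: pd.DataFrame
    parameter_summary: pd.DataFrame
    joint_summary: pd.DataFrame
    cutoffs: model.CutoffSet
    correlation: model.CorrelationReport | None = None

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        scores_wide = (
            self.detail.pivot_table(
                index=["subject_id", "phase_id"], columns="parameter", values="score"
            )
            .astype(int)
            .reset_index()
        )
        scores_wide = scores_wide.merge(
            self.classification, on=["subject_id", "phase_id"]
        )
        paths = {
            "detail": write_table(self.detail, out / "report_detail.csv"),
            "scores": write_table(scores_wide, out / "scores.csv"),
            "parameter_summary": write_table(
                self.parameter_summary.reset_index(), out / "summary_parameters.csv"
            ),
            "joint_summary": write_table(
                self.joint_summary.reset_index(), out / "summary_joint.csv"
            ),
        }
        lines = [self.summary_text()]
        (out / "summary.txt").write_text("\n".join(lines) + "\n")
        paths["summary"] = out / "summary.txt"
        return paths

    def summary_text(self) -> str:
        flagged = self.classification[self.classification["flagged"]]
        per_phase = flagged.groupby("phase_id", sort=False)["subject_id"].count()
        lines = [
            f"cut-off mode: {self.cutoffs.provenance}",
            "flagged subjects per phase: "
            + (
                ", ".join(f"{ph}={n}" for ph, n in per_phase.items())
                if len(per_phase)
                else "none"
            ),
        ]
        if self.correlation is not None:
            c = self.correlation
            lines.append(
                f"scores vs respiration change: r={c.r:.3f}, p={c.p:.3g}, n={c.n}"
            )
        return "\n".join(lines)


def run_pipeline(config: RunConfig) -> DiagnosticReport:
    """Baselines -> cut-offs -> scores -> classification (-> correlation).

    Reads the configured panel (and optional respiration) CSVs, applies the
    configured cut-off mode and threshold, and assembles the report. The exact
    cut-offs and mode used are recorded so fixed-published and derived runs
    stay auditable.
    """
    specs = DEFAULT_PARAMETERS
    names = [s.name for s in specs]
    panels = read_panels(config.panels)
    schedule = config.schedule
    baselines = model.compute_baselines(panels, schedule, specs)
    if config.cutoff_mode == "derived":
        cutoffs = model.derive_cutoffs(panels, schedule, specs, pooling=config.pooling)
    elif config.cutoff_mode == "fixed":
        cutoffs = model.fixed_cutoffs(config.fixed_cutoffs)
    else:
        cutoffs = model.individual_cutoffs(panels, schedule, specs)
    logger.info("cut-offs (%s): %s", cutoffs.provenance, cutoffs.values.to_dict()
                if not cutoffs.per_subject else "per-subject")

    scores = model.score(panels, baselines, cutoffs, specs)
    classification = model.classify(scores, threshold=config.threshold)

    detail_rows = []
    idx = pd.MultiIndex.from_frame(panels[["subject_id", "phase_id"]])
    for p in names:
        obs = panels[p].set_axis(idx)
        base = baselines.values[p].reindex(idx.get_level_values("subject_id")).set_axis(idx)
        cut = (
            cutoffs.values[p].reindex(idx.get_level_values("subject_id")).set_axis(idx)
            if cutoffs.per_subject
            else pd.Series(cutoffs.values[p], index=idx)
        )
        detail_rows.append(
            pd.DataFrame(
                {
                    "subject_id": idx.get_level_values("subject_id"),
                    "phase_id": idx.get_level_values("phase_id"),
                    "parameter": p,
                    "observed": obs.to_numpy(),
                    "baseline": base.to_numpy(),
                    "deviation": (obs - base).to_numpy(),
                    "cutoff": cut.to_numpy(),
                    "score": scores.scores[p].reindex(idx).to_numpy(),
                }
            )
        )
    detail = pd.concat(detail_rows, ignore_index=True).sort_values(
        ["subject_id", "phase_id", "parameter"], ignore_index=True
    )

    param_summary = scores.phase_parameter_counts()
    if not cutoffs.per_subject:
        param_summary.insert(0, "cutoff", cutoffs.values[param_summary.index])
        if cutoffs.normal_means is not None:
            param_summary.insert(0, "mean_mal", cutoffs.mal_means[param_summary.index])
            param_summary.insert(0, "mean_normal", cutoffs.normal_means[param_summary.index])
    joint = scores.cumulative_counts()

    correlation = None
    if config.respiration is not None:
        records = read_respiration(config.respiration)
        deltas = model.respiration_deltas(records, schedule)
        correlation = model.correlate_scores_respiration(scores.n_scores, deltas)

    return DiagnosticReport(
        detail=detail,
        classification=classification,
        parameter_summary=param_summary,
        joint_summary=joint,
        cutoffs=cutoffs,
        correlation=correlation,
    )
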