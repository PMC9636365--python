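"""CSV interchange and run configuration.

All tables travel as UTF-8 CSV with a header row and dot decimal separators,
one row per subject-phase (panels, respiration, scores) or per sample
(sessions). Unknown columns are preserved and ignored; a malformed numeric
cell is reported with its file, row and column.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from .params import DEFAULT_PARAMETER_NAMES, DEFAULT_SCHEDULE, PhaseSchedule

__all__ = [
    "read_panels",
    "read_respiration",
    "read_session",
    "read_markers",
    "write_table",
    "RunConfig",
    "load_config",
]

PANEL_REQUIRED = ("subject_id", "phase_id") + tuple(DEFAULT_PARAMETER_NAMES)
RESPIRATION_REQUIRED = ("subject_id", "phase_id", "respiration")
SESSION_REQUIRED = ("time_s", "hr_bpm", "vo2_lmin", "vco2_lmin", "power_w")
MARKER_REQUIRED = ("label", "start_s", "end_s")


def _read_csv(path: str | Path, required: Sequence[str], numeric: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype=str, skipinitialspace=True)
    if df.empty:
        raise ValueError(f"{path}: no data rows")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    for col in numeric:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna() & (df[col].str.strip() != "")
        if bad.any():
            row = int(bad.idxmax()) + 2  # header + 1-based
            raise ValueError(
                f"{path}: cannot parse {df[col][bad.idxmax()]!r} as a number "
                f"(row {row}, column {col!r}); use dot decimal separators"
            )
        df[col] = converted
    return df


def read_panels(path: str | Path) -> pd.DataFrame:
    """Read a subject-phase panel table (empty cell = missing measurement)."""
    return _read_csv(path, PANEL_REQUIRED, DEFAULT_PARAMETER_NAMES)


def read_respiration(path: str | Path) -> pd.DataFrame:
    return _read_csv(path, RESPIRATION_REQUIRED, ("respiration",))


def read_session(path: str | Path) -> pd.DataFrame:
    return _read_csv(path, SESSION_REQUIRED, SESSION_REQUIRED)


def read_markers(path: str | Path) -> pd.DataFrame:
    return _read_csv(path, MARKER_REQUIRED, ("start_s", "end_s"))


def write_table(df: pd.DataFrame, path: str | Path) -> Path:
    """Write a table as CSV, numerics at 6 significant digits (lossless for
    the measurement scales used here)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    out = df.copy()
    for col in out.columns:
        if pd.api.types.is_float_dtype(out[col]):
            out[col] = out[col].map(lambda v: "" if pd.isna(v) else f"{v:.6g}")
    out.to_csv(path, index=False)
    return path


@dataclass
class RunConfig:
    """Configuration for the end-to-end diagnostic pipeline."""

    panels: str | Path
    respiration: str | Path | None = None
    out_dir: str | Path = "overreach_out"
    schedule: PhaseSchedule = field(default_factory=lambda: DEFAULT_SCHEDULE)
    threshold: int = 3
    cutoff_mode: str = "derived"  # derived | fixed | individual
    fixed_cutoffs: Mapping[str, float] | None = None
    pooling: str = "observations"  # observations | subjects
    seed: int = 0
    verbose: bool = False

    def __post_init__(self) -> None:
        if self.cutoff_mode not in ("derived", "fixed", "individual"):
            raise ValueError(f"unknown cutoff_mode {self.cutoff_mode!r}")
        if self.cutoff_mode == "fixed" and not self.fixed_cutoffs:
            raise ValueError("cutoff_mode 'fixed' needs fixed_cutoffs values")


def load_config(path: str | Path) -> RunConfig:
    """Load a RunConfig from a YAML key-value file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    schedule_kwargs = {}
    if "phases" in raw:
        schedule_kwargs["phases"] = tuple(raw.pop("phases"))
    if "normal_phases" in raw:
        schedule_kwargs["normal_phases"] = tuple(raw.pop("normal_phases"))
    if "mal_phase" in raw:
        schedule_kwargs["mal_phase"] = raw.pop("mal_phase")
    schedule = PhaseSchedule(**schedule_kwargs) if schedule_kwargs else DEFAULT_SCHEDULE
    return RunConfig(schedule=schedule, **raw)
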