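"""Session-level physiology: windowed peaks, heart-rate recovery, substrate
oxidation, mood-state composites and derived ratios.

These are the quantities the diagnostic parameters are computed from: the
session HR_max is the highest 30-s rolling mean of heart rate anywhere in the
session, interval VO2 is the highest consecutive 120-s mean during the
interval plateau, heart-rate recovery (HRR) is the drop from a work bout's
peak 30-s heart rate to the heart rate at fixed time points after the bout,
and substrate oxidation comes from indirect calorimetry via stoichiometric
(Brouwer-type) equations on VO2 and VCO2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "resample_to_1hz",
    "rolling_window_peak",
    "heart_rate_recovery",
    "session_mean_hrr",
    "BROUWER_COEFFICIENTS",
    "CALORIC_COEFFICIENTS",
    "SubstrateReport",
    "brouwer_substrates",
    "guarded_ratio",
    "gross_efficiency",
    "PomsProfile",
    "poms_derived",
    "initial_pacing_target",
    "summarize_session",
]

SESSION_COLUMNS = ("time_s", "hr_bpm", "vo2_lmin", "vco2_lmin", "power_w")


def resample_to_1hz(session: pd.DataFrame) -> pd.DataFrame:
    """Linearly interpolate session signals onto a 1 s grid.

    Device exports differ (breath-by-breath, 5 s bins); all windowing here
    assumes a uniform 1 Hz grid, so resample first. Input needs a strictly
    increasing ``time_s`` column; other numeric columns are interpolated.
    """
    if "time_s" not in session.columns:
        raise ValueError("session table is missing column 'time_s'")
    t = session["time_s"].to_numpy(float)
    if len(t) < 2:
        raise ValueError("need at least two samples to resample")
    if not np.all(np.diff(t) > 0):
        raise ValueError("time_s must be strictly increasing")
    grid = np.arange(math.ceil(t[0]), math.floor(t[-1]) + 1, dtype=float)
    out = {"time_s": grid}
    for col in session.columns:
        if col == "time_s":
            continue
        if pd.api.types.is_numeric_dtype(session[col]):
            out[col] = np.interp(grid, t, session[col].to_numpy(float))
    return pd.DataFrame(out)


def rolling_window_peak(
    values: Sequence[float] | np.ndarray,
    window_s: float,
    fs: float = 1.0,
) -> tuple[float, float]:
    """Peak mean over every contiguous window of ``window_s`` seconds.

    Returns ``(peak_mean, start_time_s)``; the earliest window wins ties.
    Windows slide one sample at a time with an inclusive start. A series
    shorter than the window is an error.
    """
    x = np.asarray(values, dtype=float)
    w = int(round(window_s * fs))
    if w < 1:
        raise ValueError(f"window must span at least one sample, got {window_s} s")
    if len(x) < w:
        raise ValueError(
            f"series of {len(x)} samples is shorter than the {w}-sample window"
        )
    csum = np.concatenate([[0.0], np.cumsum(x)])
    means = (csum[w:] - csum[:-w]) / w
    i = int(np.argmax(means))  # argmax returns the first maximum: earliest window
    return float(means[i]), float(i / fs)


def heart_rate_recovery(
    time_s: Sequence[float] | np.ndarray,
    hr_bpm: Sequence[float] | np.ndarray,
    bout_start_s: float,
    bout_end_s: float,
    timepoints_s: Sequence[float] = (30.0, 60.0),
    peak_window_s: float = 30.0,
) -> dict[float, float | None]:
    """HRR per time point for one work bout.

    ``HRR_t`` = (peak 30-s windowed HR mean within the bout) minus the HR at
    ``t`` seconds after the bout ends. The trace must be on a 1 Hz grid
    (see :func:`resample_to_1hz`). A time point beyond the recorded recovery
    is reported as ``None`` rather than extrapolated.
    """
    t = np.asarray(time_s, dtype=float)
    hr = np.asarray(hr_bpm, dtype=float)
    mask = (t >= bout_start_s) & (t <= bout_end_s)
    if mask.sum() < int(peak_window_s):
        raise ValueError("work bout shorter than the peak reference window")
    peak, _ = rolling_window_peak(hr[mask], peak_window_s)
    out: dict[float, float | None] = {}
    for tp in timepoints_s:
        target = bout_end_s + tp
        idx = np.flatnonzero(t == target)
        out[float(tp)] = float(peak - hr[idx[0]]) if idx.size else None
    return out


def session_mean_hrr(
    per_interval: Sequence[Mapping[float, float | None]],
) -> dict[float, float | None]:
    """Average per-interval HRR values into a session mean per time point.

    Missing (truncated) values are skipped; a time point missing from every
    interval stays ``None``.
    """
    if not per_interval:
        raise ValueError("no intervals")
    keys = sorted({k for d in per_interval for k in d})
    out: dict[float, float | None] = {}
    for k in keys:
        vals = [d[k] for d in per_interval if d.get(k) is not None]
        out[k] = float(np.mean(vals)) if vals else None
    return out


#: Stoichiometric oxidation coefficients (g/min per L/min of gas):
#: fat = a_fat*VO2 + b_fat*VCO2, carbohydrate = a_cho*VO2 + b_cho*VCO2.
BROUWER_COEFFICIENTS: Mapping[str, float] = {
    "fat_vo2": 1.695,
    "fat_vco2": -1.701,
    "cho_vo2": -2.965,
    "cho_vco2": 4.170,
}

#: Caloric equivalents (kcal per litre of gas) for energy expenditure.
CALORIC_COEFFICIENTS: Mapping[str, float] = {"kcal_per_l_o2": 3.820, "kcal_per_l_co2": 1.150}

_KCAL_MIN_TO_W = 4184.0 / 60.0


@dataclass(frozen=True)
class SubstrateReport:
    """Substrate oxidation from one (VO2, VCO2) pair.

    Oxidation rates are clipped at 0 (the stoichiometric equations go negative
    outside RER 0.7-1.0, which is physiologically meaningless); the unclipped
    values are retained in ``raw_cho_g_min`` / ``raw_fat_g_min``. RER is
    reported unclipped, with a note when it falls outside [0.7, 1.0].
    """

    cho_g_min: float
    fat_g_min: float
    energy_kcal_min: float
    energy_w: float
    rer: float
    raw_cho_g_min: float
    raw_fat_g_min: float
    notes: tuple[str, ...] = ()
    coefficients: Mapping[str, float] = field(default_factory=lambda: dict(BROUWER_COEFFICIENTS))


def brouwer_substrates(
    vo2_lmin: float,
    vco2_lmin: float,
    coefficients: Mapping[str, float] = BROUWER_COEFFICIENTS,
    caloric: Mapping[str, float] = CALORIC_COEFFICIENTS,
) -> SubstrateReport:
    """Carbohydrate and fat oxidation (g/min) and energy expenditure.

    Defaults: fat = 1.695*VO2 - 1.701*VCO2 and CHO = 4.170*VCO2 - 2.965*VO2,
    with energy expenditure from per-litre caloric equivalents of O2 and CO2
    (both coefficient sets are configurable and recorded in the report).
    """
    if vo2_lmin <= 0:
        raise ValueError(f"VO2 must be positive, got {vo2_lmin}")
    if vco2_lmin < 0:
        raise ValueError(f"VCO2 must be non-negative, got {vco2_lmin}")
    rer = vco2_lmin / vo2_lmin
    raw_fat = coefficients["fat_vo2"] * vo2_lmin + coefficients["fat_vco2"] * vco2_lmin
    raw_cho = coefficients["cho_vo2"] * vo2_lmin + coefficients["cho_vco2"] * vco2_lmin
    notes: list[str] = []
    if not 0.7 <= rer <= 1.0:
        notes.append(f"RER {rer:.3f} outside [0.7, 1.0]; oxidation rates extrapolated")
    if raw_fat < 0 or raw_cho < 0:
        notes.append("negative oxidation rate clipped to 0")
    kcal = caloric["kcal_per_l_o2"] * vo2_lmin + caloric["kcal_per_l_co2"] * vco2_lmin
    return SubstrateReport(
        cho_g_min=max(raw_cho, 0.0),
        fat_g_min=max(raw_fat, 0.0),
        energy_kcal_min=kcal,
        energy_w=kcal * _KCAL_MIN_TO_W,
        rer=rer,
        raw_cho_g_min=raw_cho,
        raw_fat_g_min=raw_fat,
        notes=tuple(notes),
        coefficients=dict(coefficients),
    )


def guarded_ratio(numerator: float, denominator: float) -> tuple[float, bool]:
    """``numerator / denominator`` with a missing-value guard.

    Returns ``(value, ok)``; a zero, negative-where-invalid or NaN denominator
    yields ``(nan, False)`` instead of a silent infinity.
    """
    if denominator is None or not np.isfinite(denominator) or denominator <= 0:
        return float("nan"), False
    if numerator is None or not np.isfinite(numerator):
        return float("nan"), False
    return float(numerator / denominator), True


def gross_efficiency(power_w: float, vo2_lmin: float, vco2_lmin: float) -> float:
    """Mechanical power as a percentage of metabolic power.

    Metabolic power comes from the caloric energy-expenditure estimate of
    :func:`brouwer_substrates` converted to watts.
    """
    metabolic_w = brouwer_substrates(vo2_lmin, vco2_lmin).energy_w
    value, ok = guarded_ratio(power_w, metabolic_w)
    return value * 100.0 if ok else float("nan")


@dataclass(frozen=True)
class PomsProfile:
    """Profile of Mood States subscale scores."""

    tension: float
    depression: float
    anger: float
    fatigue: float
    confusion: float
    vigor: float


def poms_derived(profile: PomsProfile) -> tuple[float, float]:
    """Total mood disturbance and energy index from the six POMS subscales.

    TMD = tension + depression + anger + fatigue + confusion - vigor;
    EI = vigor - fatigue. A missing (None/NaN) subscale is an error naming it.
    """
    for name in ("tension", "depression", "anger", "fatigue", "confusion", "vigor"):
        v = getattr(profile, name)
        if v is None or (isinstance(v, float) and math.isnan(v)):
            raise ValueError(f"POMS subscale {name!r} is missing")
    tmd = (
        profile.tension
        + profile.depression
        + profile.anger
        + profile.fatigue
        + profile.confusion
        - profile.vigor
    )
    ei = profile.vigor - profile.fatigue
    return float(tmd), float(ei)


def initial_pacing_target(lactate_threshold_power_w: float) -> float:
    """First-interval pacing target: 117% of lactate-threshold power."""
    if lactate_threshold_power_w <= 0:
        raise ValueError("lactate-threshold power must be positive")
    return 1.17 * lactate_threshold_power_w


def summarize_session(
    session: pd.DataFrame,
    markers: pd.DataFrame,
    hrr_timepoints_s: Sequence[float] = (30.0, 60.0),
    hr_window_s: float = 30.0,
    vo2_window_s: float = 120.0,
) -> tuple[pd.DataFrame, dict]:
    """Per-interval summaries plus session-level aggregates.

    ``session`` must have the canonical columns (time_s, hr_bpm, vo2_lmin,
    vco2_lmin, power_w), on or resampled to a 1 Hz grid; ``markers`` labels
    segments with columns (label, start_s, end_s), interval segments labelled
    ``interval <k>``. Session HR_max is the peak 30-s mean anywhere in the
    session; interval VO2 is the peak 120-s mean within the interval; power
    and HR means use the full interval length; HRR is averaged over intervals
    into a session mean.
    """
    for col in SESSION_COLUMNS:
        if col not in session.columns:
            raise ValueError(f"session table is missing column {col!r}")
    session = resample_to_1hz(session)
    t = session["time_s"].to_numpy()
    hr = session["hr_bpm"].to_numpy()

    intervals = markers[markers["label"].str.startswith("interval")].sort_values("start_s")
    rows = []
    hrr_per_interval = []
    for _, m in intervals.iterrows():
        seg = session[(session["time_s"] >= m["start_s"]) & (session["time_s"] <= m["end_s"])]
        vo2_plateau, _ = rolling_window_peak(seg["vo2_lmin"], min(vo2_window_s, len(seg)))
        hr_peak, _ = rolling_window_peak(seg["hr_bpm"], min(hr_window_s, len(seg)))
        hrr = heart_rate_recovery(
            t, hr, m["start_s"], m["end_s"], hrr_timepoints_s, hr_window_s
        )
        hrr_per_interval.append(hrr)
        row = {
            "interval": m["label"],
            "power_mean_w": float(seg["power_w"].mean()),
            "hr_mean_bpm": float(seg["hr_bpm"].mean()),
            "hr_peak_bpm": float(hr_peak),
            "vo2_plateau_lmin": float(vo2_plateau),
        }
        row.update({f"hrr_{int(tp)}s": hrr[tp] for tp in hrr})
        rows.append(row)
    if not rows:
        raise ValueError("no interval segments in markers")
    interval_table = pd.DataFrame(rows)

    session_hr_max, _ = rolling_window_peak(hr, hr_window_s)
    mean_hrr = session_mean_hrr(hrr_per_interval)
    summary = {
        "hr_max_bpm": float(session_hr_max),
        "power_mean_w": float(interval_table["power_mean_w"].mean()),
        "vo2_plateau_mean_lmin": float(interval_table["vo2_plateau_lmin"].mean()),
        **{f"hrr_{int(tp)}s_mean": mean_hrr[tp] for tp in mean_hrr},
    }
    return interval_table, summary
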