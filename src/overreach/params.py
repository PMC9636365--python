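"""Parameter definitions and the training-phase schedule.

The diagnostic model watches five session-level parameters. Maladaptation
manifests as an *increase* in perceived fatigue (POMS fatigue subscale) and
perceived exertion (Borg RPE), and as a *decrease* in maximal session heart
rate and in end-of-session blood glucose and lactate. Each parameter therefore
carries a direction: +1 when higher-than-baseline values are adverse, -1 when
lower-than-baseline values are.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence


@dataclass(frozen=True)
class ParameterSpec:
    """One diagnostic parameter.

    Attributes
    ----------
    name : str
        Canonical identifier, used as the column name in panel tables.
    direction : int
        +1 if maladaptation manifests as an increase, -1 as a decrease.
    units : str
        Measurement units, for reports only.
    """

    name: str
    direction: int
    units: str = ""

    def __post_init__(self) -> None:
        if self.direction not in (+1, -1):
            raise ValueError(f"direction must be +1 or -1, got {self.direction}")


#: The five default diagnostic parameters.
DEFAULT_PARAMETERS: tuple[ParameterSpec, ...] = (
    ParameterSpec("poms_fatigue", +1, "score"),
    ParameterSpec("hr_max", -1, "bpm"),
    ParameterSpec("glucose_end", -1, "mmol/L"),
    ParameterSpec("lactate_end", -1, "mmol/L"),
    ParameterSpec("rpe_mean", +1, "Borg 6-20"),
)

DEFAULT_PARAMETER_NAMES: tuple[str, ...] = tuple(p.name for p in DEFAULT_PARAMETERS)


def specs_by_name(specs: Sequence[ParameterSpec] = DEFAULT_PARAMETERS) -> dict[str, ParameterSpec]:
    return {s.name: s for s in specs}


def directions(specs: Sequence[ParameterSpec] = DEFAULT_PARAMETERS) -> dict[str, int]:
    return {s.name: s.direction for s in specs}


@dataclass(frozen=True)
class PhaseSchedule:
    """Ordered training phases and their roles.

    ``normal_phases`` are the phases whose measurements define each subject's
    individual baseline (training load low enough that measurements are
    unaffected by maladaptation). ``mal_phase`` is the phase used to derive
    group cut-offs. Any phase may be scored; phases outside ``normal_phases``
    and ``mal_phase`` (the default MT2) are test-only.
    """

    phases: tuple[str, ...] = ("BL", "LT", "MT1", "MT2", "MAL", "RE")
    normal_phases: tuple[str, ...] = ("BL", "LT", "MT1", "RE")
    mal_phase: str = "MAL"

    def __post_init__(self) -> None:
        if len(self.normal_phases) < 2:
            raise ValueError("need at least two normal-reference phases")
        if self.mal_phase in self.normal_phases:
            raise ValueError("the maladaptive phase cannot be a normal-reference phase")
        missing = set(self.normal_phases) - set(self.phases) | {self.mal_phase} - set(self.phases)
        if missing:
            raise ValueError(f"phases {sorted(missing)} not in the schedule order")


DEFAULT_SCHEDULE = PhaseSchedule()

#: Phases with muscle biopsies (no biopsy at MT2).
BIOPSY_PHASES: tuple[str, ...] = ("BL", "LT", "MT1", "MAL", "RE")

#: Cut-off values as printed in the published diagnostic table (display-rounded).
PUBLISHED_CUTOFFS: Mapping[str, float] = {
    "poms_fatigue": +4.7,
    "hr_max": -2.5,
    "glucose_end": -0.71,
    "lactate_end": -0.62,
    "rpe_mean": +0.5,
}

#: Published group means over normal-load phases and over the maladaptive phase.
PUBLISHED_GROUP_MEANS: Mapping[str, tuple[float, float]] = {
    "poms_fatigue": (42.6, 51.9),
    "hr_max": (183.6, 178.5),
    "glucose_end": (6.11, 4.68),
    "lactate_end": (13.28, 12.03),
    "rpe_mean": (17.5, 18.5),
}
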