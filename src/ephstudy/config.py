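"""Threshold configuration for echo derivation and case definitions.

All clinically meaningful cutoffs live here so that the derivation and
classification code contains no magic numbers.  Defaults follow the
guideline values used throughout the package; every field can be
overridden from a YAML file (see :func:`load_thresholds`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml


@dataclass(frozen=True)
class DiastolicThresholds:
    """Decision-table cutoffs for grading LV diastolic function.

    The staging algorithm uses the mitral E/A ratio, the E/E' ratio and
    the septal annular velocity E'; in atrial fibrillation the E/A ratio
    is replaced by the E-wave deceleration time.  The shipped defaults
    follow the staging literature commonly used in elderly cohort
    studies:

    * ``ea_lower`` / ``ea_upper``: E/A bounds separating impaired
      relaxation (E/A <= lower), the pseudonormal window
      (lower < E/A < upper) and restrictive filling (E/A >= upper).
    * ``e_over_eprime``: E/E' at or above which filling pressure is
      considered raised.
    * ``e_prime_low`` (cm/s): annular velocity below which relaxation is
      considered impaired enough to support a pseudonormal grade.
    * ``dec_time_restrictive`` (ms): deceleration time below which an
      AF participant is graded restrictive.
    """

    ea_lower: float = 0.75
    ea_upper: float = 1.5
    e_over_eprime: float = 10.0
    e_prime_low: float = 8.0
    dec_time_restrictive: float = 140.0


@dataclass(frozen=True)
class CaseThresholds:
    """Cutoffs for the three echocardiographic PH case definitions.

    The fallback criteria are expressed as TRV cutoffs (m/s); the
    equivalent tricuspid-gradient cutoff is ``4 * trv**2`` and is derived,
    never stored, so the two can not drift apart.
    """

    epasp_primary: float = 40.0       # mmHg
    trv_primary: float = 3.0          # m/s -> gradient > 36 mmHg
    epasp_stringent: float = 50.0     # mmHg
    trv_stringent: float = 3.4        # m/s -> gradient > 46.24 mmHg
    rvedd_dilated: float = 42.0       # mm
    fs_dysfunction: float = 29.0      # %

    @property
    def gradient_primary(self) -> float:
        return 4.0 * self.trv_primary ** 2

    @property
    def gradient_stringent(self) -> float:
        return 4.0 * self.trv_stringent ** 2


@dataclass(frozen=True)
class RapThresholds:
    """IVC criteria for the categorical right-atrial-pressure estimate."""

    ivc_diameter: float = 21.0        # mm
    ivc_collapse: float = 0.5         # fraction on sniff test
    rap_low: float = 3.0              # mmHg
    rap_mid: float = 8.0
    rap_high: float = 15.0


@dataclass(frozen=True)
class Thresholds:
    diastolic: DiastolicThresholds = field(default_factory=DiastolicThresholds)
    case: CaseThresholds = field(default_factory=CaseThresholds)
    rap: RapThresholds = field(default_factory=RapThresholds)

    def to_dict(self) -> dict:
        return asdict(self)


def load_thresholds(path: str | Path | None = None) -> Thresholds:
    """Load thresholds from a YAML file; missing keys keep their defaults."""
    if path is None:
        return Thresholds()
    raw = yaml.safe_load(Path(path).read_text()) or {}
    return Thresholds(
        diastolic=DiastolicThresholds(**raw.get("diastolic", {})),
        case=CaseThresholds(**raw.get("case", {})),
        rap=RapThresholds(**raw.get("rap", {})),
    )
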