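"""Severity-score computations.

Three ingredients used throughout the pipeline:

* the logistic conversion of a SAPS II score (0-163) into an in-hospital
  death probability, as published by Le Gall and colleagues for the
  original SAPS II validation cohort;
* a linear rescaling of SAPS II onto the SOFA scale (0-24), obtained by
  matching the maxima of the two scores (163 -> 24);
* an adjusted DIVI prioritization score that sums tier points for the
  SOFA-equivalent severity, the number of secondary diagnoses (standing
  in for the "limiting prognosis" criterion) and, optionally, age.
  Lower DIVI totals indicate a better prognosis.

The tier tables are configuration objects so that a hospital-specific
point table can be dropped in without code changes.
"""

from __future__ import annotations

import bisect
import math
from dataclasses import dataclass, field, fields as dc_fields
from typing import Sequence

import numpy as np
import yaml

from .data_prep import PreparedPatient
from .errors import ConfigurationError, DomainError

SAPS_MAX = 163.0
SOFA_MAX = 24.0
TISS_MAX = 78.0

# Le Gall logistic coefficients: logit = b0 + b1*S + b2*ln(S+1)
_LEGALL_B0 = -7.7631
_LEGALL_B1 = 0.0737
_LEGALL_B2 = 0.9971


def _check_saps(saps) -> None:
    arr = np.asarray(saps, dtype=float)
    if np.any(arr < 0.0) or np.any(arr > SAPS_MAX):
        raise DomainError(f"SAPS II score outside [0, {SAPS_MAX:g}]: {saps!r}")


def legall_logit(saps):
    """Logit of the SAPS II-predicted in-hospital mortality.

    Accepts a scalar or array-like SAPS II score in [0, 163]; strictly
    increasing in the score.
    """
    _check_saps(saps)
    s = np.asarray(saps, dtype=float)
    out = _LEGALL_B0 + _LEGALL_B1 * s + _LEGALL_B2 * np.log(s + 1.0)
    return float(out) if np.isscalar(saps) or out.ndim == 0 else out


def saps_predicted_mortality(saps):
    """SAPS II-predicted in-hospital death probability (inverse-logit)."""
    logit = legall_logit(saps)
    out = 1.0 / (1.0 + np.exp(-np.asarray(logit, dtype=float)))
    return float(out) if np.isscalar(saps) or out.ndim == 0 else out


def saps_to_sofa_equivalent(saps):
    """Map SAPS II linearly onto the SOFA scale via the maxima (163 -> 24).

    Returned values are real-valued; no rounding before tier lookup.
    """
    _check_saps(saps)
    s = np.asarray(saps, dtype=float)
    out = s * (SOFA_MAX / SAPS_MAX)
    return float(out) if np.isscalar(saps) or out.ndim == 0 else out


@dataclass(frozen=True)
class TierScale:
    """Piecewise-constant point lookup: value v earns points[i] where i is
    the number of breaks <= v (breaks strictly increasing)."""

    breaks: tuple
    points: tuple

    def __post_init__(self):
        if len(self.points) != len(self.breaks) + 1:
            raise ConfigurationError("need exactly len(breaks)+1 point values")
        if any(b >= c for b, c in zip(self.breaks, self.breaks[1:])):
            raise ConfigurationError("tier breaks must be strictly increasing")
        if any((int(p) != p or p < 0) for p in self.points):
            raise ConfigurationError("tier points must be nonnegative integers")

    def lookup(self, value: float) -> int:
        return int(self.points[bisect.bisect_right(self.breaks, value)])


@dataclass(frozen=True)
class DiviPointTable:
    """Tier tables of the adjusted DIVI prioritization score.

    Defaults follow the four-tier structure of the DIVI triage guideline
    mapped onto the SOFA-equivalent scale, secondary-diagnosis tiers for
    the limiting-prognosis criterion, and age tiers for the secondary age
    criterion.  Lower totals = better prognosis.
    """

    sofa: TierScale = field(
        default_factory=lambda: TierScale(breaks=(6.0, 9.0, 12.0), points=(1, 2, 3, 4))
    )
    secondary_diagnoses: TierScale = field(
        default_factory=lambda: TierScale(breaks=(7, 13, 19), points=(0, 1, 2, 3))
    )
    age: TierScale = field(
        default_factory=lambda: TierScale(breaks=(50, 65, 80), points=(0, 1, 2, 3))
    )

    def max_total(self, include_age: bool) -> int:
        total = max(self.sofa.points) + max(self.secondary_diagnoses.points)
        if include_age:
            total += max(self.age.points)
        return total

    def to_yaml(self) -> str:
        payload = {
            f.name: {
                "breaks": list(getattr(self, f.name).breaks),
                "points": list(getattr(self, f.name).points),
            }
            for f in dc_fields(self)
        }
        return yaml.safe_dump(payload, sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "DiviPointTable":
        payload = yaml.safe_load(text)
        if not isinstance(payload, dict):
            raise ConfigurationError("DIVI table YAML must be a mapping")
        kwargs = {}
        for name, block in payload.items():
            try:
                kwargs[name] = TierScale(
                    breaks=tuple(block["breaks"]), points=tuple(block["points"])
                )
            except (KeyError, TypeError) as exc:
                raise ConfigurationError(f"malformed tier block {name!r}") from exc
        return cls(**kwargs)


DEFAULT_DIVI_TABLE = DiviPointTable()


@dataclass(frozen=True)
class ScoredPatient(PreparedPatient):
    """Analysis-ready patient augmented with severity-score derivatives."""

    saps_pred_mort: float = 0.0
    sofa_equiv: float = 0.0
    divi_noage: int = 0
    divi_age: int = 0


def divi_points(
    patient: PreparedPatient, include_age: bool, table: DiviPointTable = DEFAULT_DIVI_TABLE
) -> int:
    """Adjusted DIVI total for one patient (sum of tier points)."""
    sofa_eq = saps_to_sofa_equivalent(patient.saps)
    total = table.sofa.lookup(sofa_eq) + table.secondary_diagnoses.lookup(
        patient.n_secondary
    )
    if include_age:
        total += table.age.lookup(patient.age)
    return total


def score_patient(
    patient: PreparedPatient, table: DiviPointTable = DEFAULT_DIVI_TABLE
) -> ScoredPatient:
    return ScoredPatient(
        patient_id=patient.patient_id,
        age=patient.age,
        saps=patient.saps,
        tiss=patient.tiss,
        n_secondary=patient.n_secondary,
        covid=patient.covid,
        icu_los=patient.icu_los,
        hosp_los=patient.hosp_los,
        died=patient.died,
        saps_pred_mort=saps_predicted_mortality(patient.saps),
        sofa_equiv=saps_to_sofa_equivalent(patient.saps),
        divi_noage=divi_points(patient, include_age=False, table=table),
        divi_age=divi_points(patient, include_age=True, table=table),
    )


def score_patients(
    patients: Sequence[PreparedPatient], table: DiviPointTable = DEFAULT_DIVI_TABLE
) -> list:
    """Score a prepared cohort; order preserved."""
    return [score_patient(p, table) for p in patients]
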