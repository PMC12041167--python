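"""The ten tertiary-triage policies and single-timepoint swap mechanics.

A fully occupied ICU (60 beds by default) faces a queue of critical-care
patients.  A policy decides which occupants may be displaced (the
*eligible set*, limited by the triage cap m) and which queue patients are
admitted in their place:

====  ==========================  ==================
 id    policy                      class
====  ==========================  ==================
 0     no tertiary triage          baseline
 1     random                      non-criterion
 2     FCFS (reverse for ICU)      non-criterion
 3     age                         criterion
 4     SAPS II                     criterion + score
 5     TISS                        criterion + score
 6     secondary-diagnosis count   criterion
 7     ICU length of stay          criterion
 8     adjusted DIVI without age   criterion + score
 9     adjusted DIVI with age      criterion + score
====  ==========================  ==================

For ranked (criterion/score) policies a lower key means a better claim to
a bed; the eligible set holds the m occupants with the *worst* keys, the
queue is sorted best first, pairs are compared positionally, and a swap
happens only on strict improvement.  Ties always keep the incumbent.
Random and FCFS policies swap unconditionally (a prognosis-blind rule has
no notion of improvement).  Every swap keeps the census constant.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .errors import ConfigurationError, PolicyUsageError, StateError
from .scoring import ScoredPatient

DEFAULT_CAPACITY = 60


class Policy(enum.IntEnum):
    NO_TRIAGE = 0
    RANDOM = 1
    FCFS = 2
    AGE = 3
    SAPS = 4
    TISS = 5
    SECONDARY_DIAGNOSES = 6
    ICU_LOS = 7
    DIVI_NO_AGE = 8
    DIVI_AGE = 9


POLICY_LABELS = {
    Policy.NO_TRIAGE: "no tertiary triage",
    Policy.RANDOM: "random",
    Policy.FCFS: "first come, first served",
    Policy.AGE: "age-based",
    Policy.SAPS: "SAPS II-based",
    Policy.TISS: "TISS-based",
    Policy.SECONDARY_DIAGNOSES: "secondary-diagnoses-based",
    Policy.ICU_LOS: "ICU-LOS-based",
    Policy.DIVI_NO_AGE: "adjusted DIVI without age",
    Policy.DIVI_AGE: "adjusted DIVI with age",
}

BASELINE_POLICIES = frozenset({Policy.NO_TRIAGE})
NON_CRITERION_POLICIES = frozenset({Policy.RANDOM, Policy.FCFS})
CRITERION_POLICIES = frozenset({Policy.AGE, Policy.SECONDARY_DIAGNOSES, Policy.ICU_LOS})
SCORE_POLICIES = frozenset({Policy.SAPS, Policy.TISS, Policy.DIVI_NO_AGE, Policy.DIVI_AGE})
RANKED_POLICIES = CRITERION_POLICIES | SCORE_POLICIES

_KEY_ATTR = {
    Policy.AGE: "age",
    Policy.SAPS: "saps",
    Policy.TISS: "tiss",
    Policy.SECONDARY_DIAGNOSES: "n_secondary",
    Policy.ICU_LOS: "icu_los",
    Policy.DIVI_NO_AGE: "divi_noage",
    Policy.DIVI_AGE: "divi_age",
}


def policy_key(patient: ScoredPatient, policy: Policy, elapsed_days: int = 0) -> float:
    """Ranking key of one patient under a ranked policy (lower = better
    claim to a bed).  Policy 7 uses the patient's total ICU-LOS attribute,
    not the elapsed time."""
    policy = Policy(policy)
    if policy not in RANKED_POLICIES:
        raise PolicyUsageError(f"policy {int(policy)} has no ranking key")
    return float(getattr(patient, _KEY_ATTR[policy]))


@dataclass
class IcuState:
    """Fully occupied ICU: aligned lists of occupants and elapsed days."""

    patients: List[ScoredPatient]
    elapsed: List[int]
    capacity: int = DEFAULT_CAPACITY

    def __post_init__(self):
        if len(self.patients) != len(self.elapsed):
            raise StateError("patients and elapsed must be aligned")
        if any(e < 0 for e in self.elapsed):
            raise StateError("elapsed days must be nonnegative")

    @property
    def full(self) -> bool:
        return len(self.patients) == self.capacity


@dataclass
class TriageEvent:
    """Outcome of one triage application."""

    admitted: list = field(default_factory=list)  # queue patient ids
    discharged: list = field(default_factory=list)  # occupant patient ids
    rejected: list = field(default_factory=list)  # queue ids not admitted


# ---------------------------------------------------------------------------
# Array core (shared by the object API and the Monte-Carlo engine)
# ---------------------------------------------------------------------------

def eligible_order(
    keys: Optional[np.ndarray],
    elapsed: np.ndarray,
    policy: Policy,
    cap: int,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Occupant positions exposed to triage, in displacement order.

    Ranked policies expose the cap worst keys (worst first; ties resolved
    by smaller elapsed days, then stable input order); FCFS exposes the
    most recently admitted; random draws uniformly; baseline exposes none.
    """
    n = len(elapsed)
    if cap < 0 or cap > n:
        raise ConfigurationError(f"triage cap {cap} outside [0, {n}]")
    policy = Policy(policy)
    if policy == Policy.NO_TRIAGE or cap == 0:
        return np.empty(0, dtype=np.intp)
    if policy == Policy.RANDOM:
        if rng is None:
            raise ConfigurationError("random policy needs an rng")
        return rng.choice(n, size=cap, replace=False)
    idx = np.arange(n)
    if policy == Policy.FCFS:
        return np.lexsort((idx, elapsed))[:cap]
    return np.lexsort((idx, elapsed, -keys))[:cap]


def plan_swaps(
    keys_occ: Optional[np.ndarray],
    elapsed: np.ndarray,
    keys_queue: Optional[np.ndarray],
    n_queue: int,
    policy: Policy,
    cap: int,
    rng: Optional[np.random.Generator] = None,
) -> Tuple[np.ndarray, np.ndarray]:
    """Return (discharge positions, admitted queue positions), aligned."""
    policy = Policy(policy)
    elig = eligible_order(keys_occ, elapsed, policy, cap, rng)
    k = min(n_queue, len(elig))
    empty = np.empty(0, dtype=np.intp)
    if policy == Policy.NO_TRIAGE or k == 0:
        return empty, empty
    if policy == Policy.RANDOM:
        return elig[:k], rng.choice(n_queue, size=k, replace=False)
    if policy == Policy.FCFS:
        return elig[:k], np.arange(k, dtype=np.intp)
    qorder = np.lexsort((np.arange(n_queue), keys_queue))
    n_swap = 0
    for i in range(k):  # queue best-first vs incumbent worst-first
        if keys_queue[qorder[i]] < keys_occ[elig[i]]:
            n_swap += 1
        else:
            break  # later pairs cannot improve either
    return elig[:n_swap], qorder[:n_swap]


# ---------------------------------------------------------------------------
# Object API
# ---------------------------------------------------------------------------

def _keys_or_none(patients, policy):
    if Policy(policy) in RANKED_POLICIES:
        return np.array([policy_key(p, policy) for p in patients], dtype=float)
    return None


def eligible_set(
    state: IcuState, policy: Policy, cap: int,
    rng: Optional[np.random.Generator] = None,
) -> list:
    """The occupants exposed to triage, as (patient, elapsed_days) pairs."""
    keys = _keys_or_none(state.patients, policy)
    order = eligible_order(keys, np.asarray(state.elapsed), policy, cap, rng)
    return [(state.patients[i], state.elapsed[i]) for i in order]


def apply_triage(
    state: IcuState,
    queue: Sequence[ScoredPatient],
    policy: Policy,
    cap: int,
    rng: Optional[np.random.Generator] = None,
) -> Tuple[IcuState, TriageEvent]:
    """One triage application; returns the new (full) state and the event.

    Admitted patients enter with 0 elapsed days; the census is unchanged.
    """
    if not state.full:
        raise StateError(
            f"triage requires a full ICU ({len(state.patients)}/{state.capacity})"
        )
    keys_occ = _keys_or_none(state.patients, policy)
    keys_queue = _keys_or_none(queue, policy)
    disc, adm = plan_swaps(
        keys_occ, np.asarray(state.elapsed), keys_queue, len(queue), policy, cap, rng
    )
    patients = list(state.patients)
    elapsed = list(state.elapsed)
    for occ_pos, q_pos in zip(disc, adm):
        patients[occ_pos] = queue[q_pos]
        elapsed[occ_pos] = 0
    admitted_pos = set(int(i) for i in adm)
    event = TriageEvent(
        admitted=[queue[i].patient_id for i in adm],
        discharged=[state.patients[i].patient_id for i in disc],
        rejected=[q.patient_id for i, q in enumerate(queue) if i not in admitted_pos],
    )
    return IcuState(patients, elapsed, capacity=state.capacity), event


def realized_mortality(state: IcuState) -> float:
    """Fraction of current occupants who die in hospital."""
    if not state.full:
        raise StateError("mortality metrics require a full ICU")
    return float(np.mean([p.died for p in state.patients]))


def predicted_mortality(state: IcuState) -> float:
    """Mean SAPS II-predicted death probability of current occupants."""
    if not state.full:
        raise StateError("mortality metrics require a full ICU")
    return float(np.mean([p.saps_pred_mort for p in state.patients]))
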