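"""Monte-Carlo study: scenarios x policies x timepoints x runs.

Each run draws a full ICU occupancy (60 patients sampled with replacement
from the scored cohort, elapsed days discrete-uniform on {1..7}) and, at
each of T=3 consecutive timepoints, a fresh queue; triage is applied,
both mortality metrics are recorded post-triage, and every occupant's
elapsed time advances one day.  No other arrivals or departures occur
inside the horizon.

Occupancy and queue draws use a substream keyed by (seed, scenario, run)
only, so all policies see identical patient draws (common random
numbers); policy-internal randomness (the random policy's pairing) uses a
separate substream that also carries the policy id.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .scoring import ScoredPatient
from .triage_engine import (
    DEFAULT_CAPACITY,
    Policy,
    RANKED_POLICIES,
    IcuState,
    _KEY_ATTR,
    plan_swaps,
)


@dataclass(frozen=True)
class Scenario:
    """Queue length q and triage cap m of one stress scenario."""

    scenario_id: int
    queue_size: int
    triage_cap: int


#: The six studied (q, m) combinations with m <= q/2, in study order.
SCENARIOS = (
    Scenario(1, 12, 6),
    Scenario(2, 30, 6),
    Scenario(3, 30, 12),
    Scenario(4, 60, 6),
    Scenario(5, 60, 12),
    Scenario(6, 60, 30),
)

ALL_POLICIES = tuple(Policy)


@dataclass(frozen=True)
class SimConfig:
    icu_capacity: int = DEFAULT_CAPACITY
    n_timepoints: int = 3
    n_runs: int = 1000
    elapsed_max: int = 7  # discrete uniform {1..elapsed_max} at t=1
    seed: int = 0

    def validate(self) -> None:
        if min(self.icu_capacity, self.n_timepoints, self.n_runs, self.elapsed_max) < 1:
            raise ConfigurationError("all SimConfig sizes must be positive")


@dataclass(frozen=True)
class RunResult:
    """Row schema of the long-format result table."""

    scenario: int
    policy: int
    run: int
    t: int
    realized_mortality: float
    predicted_mortality: float
    n_admitted: int
    n_discharged: int
    n_rejected: int


RESULT_COLUMNS = (
    "scenario",
    "policy",
    "run",
    "t",
    "realized_mortality",
    "predicted_mortality",
    "n_admitted",
    "n_discharged",
    "n_rejected",
)


class CohortMatrix:
    """Column store of a scored cohort for the vectorized engine."""

    def __init__(self, patients: Sequence[ScoredPatient]):
        if len(patients) == 0:
            raise ConfigurationError("cohort must be nonempty")
        self.patients = list(patients)
        self.died = np.array([p.died for p in patients], dtype=float)
        self.pred = np.array([p.saps_pred_mort for p in patients], dtype=float)
        self._keys = {
            pol: np.array([getattr(p, attr) for p in patients], dtype=float)
            for pol, attr in _KEY_ATTR.items()
        }

    def __len__(self) -> int:
        return len(self.patients)

    def keys(self, policy: Policy) -> Optional[np.ndarray]:
        return self._keys.get(Policy(policy))


def _as_matrix(cohort) -> CohortMatrix:
    return cohort if isinstance(cohort, CohortMatrix) else CohortMatrix(cohort)


def _draw_rng(seed: int, scenario_id: int, run: int) -> np.random.Generator:
    return np.random.default_rng([seed, scenario_id, run])


def _policy_rng(seed: int, scenario_id: int, policy: int, run: int) -> np.random.Generator:
    return np.random.default_rng([seed, scenario_id, int(policy), 1 + run, 0x5EED])


def sample_occupancy(
    cohort: Sequence[ScoredPatient], config: SimConfig, rng: np.random.Generator
) -> IcuState:
    """Full ICU drawn with replacement; elapsed ~ U{1..elapsed_max}."""
    idx, elapsed = _sample_occupancy_idx(len(cohort), config, rng)
    patients = [cohort[i] for i in idx]
    return IcuState(patients, list(elapsed), capacity=config.icu_capacity)


def _sample_occupancy_idx(n_cohort: int, config: SimConfig, rng):
    idx = rng.integers(0, n_cohort, size=config.icu_capacity)
    elapsed = rng.integers(1, config.elapsed_max + 1, size=config.icu_capacity)
    return idx, elapsed


def sample_queue(
    cohort: Sequence[ScoredPatient], q: int, rng: np.random.Generator
) -> list:
    """q i.i.d. draws with replacement; draw order = arrival order."""
    return [cohort[i] for i in rng.integers(0, len(cohort), size=q)]


def run_scenario(
    cohort,
    scenario: Scenario,
    policy: Policy,
    config: SimConfig = SimConfig(),
) -> pd.DataFrame:
    """All Monte-Carlo runs of one (scenario, policy) cell.

    Returns the long-format table with one row per (run, t).
    """
    config.validate()
    policy = Policy(policy)
    if scenario.triage_cap > config.icu_capacity:
        raise ConfigurationError("triage cap exceeds ICU capacity")
    mat = _as_matrix(cohort)
    keys = mat.keys(policy)
    ranked = policy in RANKED_POLICIES
    rows = np.empty((config.n_runs * config.n_timepoints, len(RESULT_COLUMNS)))
    r = 0
    for run in range(config.n_runs):
        draw = _draw_rng(config.seed, scenario.scenario_id, run)
        pol_rng = _policy_rng(config.seed, scenario.scenario_id, policy, run)
        occ, elapsed = _sample_occupancy_idx(len(mat), config, draw)
        occ = occ.copy()
        for t in range(1, config.n_timepoints + 1):
            queue = draw.integers(0, len(mat), size=scenario.queue_size)
            disc, adm = plan_swaps(
                keys[occ] if ranked else None,
                elapsed,
                keys[queue] if ranked else None,
                scenario.queue_size,
                policy,
                scenario.triage_cap,
                pol_rng,
            )
            occ[disc] = queue[adm]
            elapsed[disc] = 0
            rows[r] = (
                scenario.scenario_id,
                int(policy),
                run,
                t,
                mat.died[occ].mean(),
                mat.pred[occ].mean(),
                len(adm),
                len(disc),
                scenario.queue_size - len(adm),
            )
            r += 1
            elapsed = elapsed + 1
    frame = pd.DataFrame(rows, columns=list(RESULT_COLUMNS))
    for col in ("scenario", "policy", "run", "t", "n_admitted", "n_discharged", "n_rejected"):
        frame[col] = frame[col].astype(int)
    return frame


def run_study(
    cohort,
    config: SimConfig = SimConfig(),
    scenarios: Iterable[Scenario] = SCENARIOS,
    policies: Iterable[Policy] = ALL_POLICIES,
    progress=None,
) -> pd.DataFrame:
    """Full factorial study; long table keyed by (scenario, policy, run, t)."""
    mat = _as_matrix(cohort)
    parts = []
    for scenario in scenarios:
        for policy in policies:
            if progress is not None:
                progress(scenario, Policy(policy))
            parts.append(run_scenario(mat, scenario, policy, config))
    return pd.concat(parts, ignore_index=True)
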