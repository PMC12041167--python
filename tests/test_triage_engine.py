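"""Triage mechanics: keys, eligible sets, swaps, and the enumeration oracle."""

import itertools

import numpy as np
import pytest

import triage_sim as ts
from triage_sim.errors import ConfigurationError, PolicyUsageError, StateError
from triage_sim.triage_engine import (
    CRITERION_POLICIES,
    NON_CRITERION_POLICIES,
    RANKED_POLICIES,
    SCORE_POLICIES,
    IcuState,
    Policy,
)

from conftest import make_scored


def make_state(patients, elapsed=None, capacity=None):
    elapsed = list(elapsed) if elapsed is not None else [1] * len(patients)
    return IcuState(list(patients), elapsed, capacity=capacity or len(patients))


def random_patient(rng, i):
    return make_scored(
        pid=f"r{i}",
        age=float(rng.integers(18, 100)),
        saps=float(rng.integers(0, 164)),
        tiss=float(rng.integers(0, 79)),
        n_secondary=int(rng.integers(0, 30)),
        icu_los=int(rng.integers(0, 20)),
        died=bool(rng.random() < 0.3),
    )


class TestPolicyClasses:
    def test_table_partition(self):
        assert NON_CRITERION_POLICIES == {Policy.RANDOM, Policy.FCFS}
        assert CRITERION_POLICIES == {Policy.AGE, Policy.SECONDARY_DIAGNOSES, Policy.ICU_LOS}
        assert SCORE_POLICIES == {Policy.SAPS, Policy.TISS, Policy.DIVI_NO_AGE, Policy.DIVI_AGE}
        assert len(Policy) == 10


class TestPolicyKey:
    def test_lower_age_is_better_claim(self):
        young, old = make_scored(age=40.0), make_scored(age=70.0)
        assert ts.policy_key(young, Policy.AGE) < ts.policy_key(old, Policy.AGE)

    def test_saps_key_is_score_value(self):
        assert ts.policy_key(make_scored(saps=20.0), Policy.SAPS) == 20.0

    def test_divi_age_tier_separates_patients(self):
        a = make_scored(saps=70.0, n_secondary=10, age=45.0)
        b = make_scored(saps=70.0, n_secondary=10, age=82.0)
        assert ts.policy_key(a, Policy.DIVI_AGE) < ts.policy_key(b, Policy.DIVI_AGE)
        assert ts.policy_key(a, Policy.DIVI_NO_AGE) == ts.policy_key(b, Policy.DIVI_NO_AGE)

    def test_unranked_policies_have_no_key(self):
        for policy in (Policy.NO_TRIAGE, Policy.RANDOM, Policy.FCFS):
            with pytest.raises(PolicyUsageError):
                ts.policy_key(make_scored(), policy)


class TestEligibleSet:
    def test_baseline_exposes_nobody(self):
        state = make_state([make_scored(pid=str(i)) for i in range(4)])
        assert ts.eligible_set(state, Policy.NO_TRIAGE, cap=2) == []

    def test_age_policy_exposes_the_oldest(self):
        ages = [30.0, 80.0, 50.0, 90.0, 40.0, 60.0, 70.0, 20.0]
        state = make_state([make_scored(pid=str(i), age=a) for i, a in enumerate(ages)])
        chosen = {p.patient_id for p, _ in ts.eligible_set(state, Policy.AGE, cap=3)}
        assert chosen == {"1", "3", "6"}  # ages 80, 90, 70

    def test_reverse_fcfs_exposes_most_recent(self):
        state = make_state(
            [make_scored(pid=str(i)) for i in range(3)], elapsed=[5, 1, 3]
        )
        chosen = [p.patient_id for p, _ in ts.eligible_set(state, Policy.FCFS, cap=2)]
        assert chosen == ["1", "2"]  # elapsed 1 then 3

    def test_key_ties_prefer_smaller_elapsed(self):
        state = make_state(
            [make_scored(pid=str(i), age=70.0) for i in range(3)], elapsed=[4, 2, 3]
        )
        chosen = [p.patient_id for p, _ in ts.eligible_set(state, Policy.AGE, cap=2)]
        assert chosen == ["1", "2"]

    def test_cap_above_census_rejected(self):
        state = make_state([make_scored()])
        with pytest.raises(ConfigurationError):
            ts.eligible_set(state, Policy.AGE, cap=2)


class TestApplyTriage:
    def test_dominant_queue_fills_the_cap(self):
        """Queue-of-12 instance where six queue members beat every eligible
        incumbent: six swaps, six rejections (the illustrative example)."""
        state = make_state(
            [make_scored(pid=f"icu{i}", age=60.0 + i) for i in range(60)],
            capacity=60,
        )
        queue = [make_scored(pid=f"q{i}", age=20.0 + i) for i in range(12)]
        new, event = ts.apply_triage(state, queue, Policy.AGE, cap=6)
        assert len(event.admitted) == len(event.discharged) == 6
        assert len(event.rejected) == 6
        assert len(new.patients) == 60
        assert set(event.admitted) == {f"q{i}" for i in range(6)}
        assert set(event.discharged) == {f"icu{i}" for i in range(54, 60)}

    def test_empty_queue_or_zero_cap_change_nothing(self):
        state = make_state([make_scored(pid=str(i)) for i in range(5)])
        for queue, cap in ([], 3), ([make_scored(pid="q")], 0):
            new, event = ts.apply_triage(state, queue, Policy.AGE, cap=cap)
            assert new.patients == state.patients
            assert event.admitted == [] and event.discharged == []

    def test_strictly_worse_queue_never_swapped(self):
        state = make_state([make_scored(pid=str(i), saps=20.0) for i in range(4)])
        queue = [make_scored(pid="q", saps=90.0)]
        _, event = ts.apply_triage(state, queue, Policy.SAPS, cap=4)
        assert event.admitted == [] and event.rejected == ["q"]

    def test_ties_keep_the_incumbent(self):
        state = make_state([make_scored(pid="i", saps=30.0)])
        _, event = ts.apply_triage(state, [make_scored(pid="q", saps=30.0)], Policy.SAPS, cap=1)
        assert event.admitted == []

    def test_admitted_enter_with_zero_elapsed(self):
        state = make_state([make_scored(pid="i", saps=90.0)], elapsed=[5])
        new, _ = ts.apply_triage(state, [make_scored(pid="q", saps=10.0)], Policy.SAPS, cap=1)
        assert new.elapsed == [0]

    def test_non_full_state_rejected(self):
        state = IcuState([make_scored()], [1], capacity=60)
        with pytest.raises(StateError):
            ts.apply_triage(state, [], Policy.AGE, cap=1)

    def test_unconditional_policies_swap_min_queue_cap(self, rng):
        state = make_state([random_patient(rng, i) for i in range(6)])
        queue = [random_patient(rng, 100 + i) for i in range(4)]
        for policy in (Policy.RANDOM, Policy.FCFS):
            _, event = ts.apply_triage(state, queue, policy, cap=3, rng=rng)
            assert len(event.admitted) == len(event.discharged) == 3

    def test_fcfs_admits_in_arrival_order(self):
        state = make_state([make_scored(pid=str(i)) for i in range(4)], elapsed=[4, 1, 3, 2])
        queue = [make_scored(pid=f"q{i}") for i in range(3)]
        _, event = ts.apply_triage(state, queue, Policy.FCFS, cap=2)
        assert event.admitted == ["q0", "q1"]
        assert event.discharged == ["1", "3"]  # most recently admitted first

    def test_random_policy_reproducible(self, rng):
        state = make_state([random_patient(rng, i) for i in range(8)])
        queue = [random_patient(rng, 50 + i) for i in range(5)]
        events = []
        for _ in range(2):
            _, ev = ts.apply_triage(
                state, queue, Policy.RANDOM, cap=4, rng=np.random.default_rng(3)
            )
            events.append((ev.admitted, ev.discharged))
        assert events[0] == events[1]


def brute_force_minimum(state, queue, policy, cap):
    """Minimum total policy key over occupancies reachable by swapping
    at most `cap` eligible occupants for queue members (exhaustive)."""
    keys_occ = [ts.policy_key(p, policy) for p in state.patients]
    keys_q = [ts.policy_key(p, policy) for p in queue]
    eligible = [
        state.patients.index(p) for p, _ in ts.eligible_set(state, policy, cap)
    ]
    best = sum(keys_occ)
    for k in range(1, min(cap, len(queue)) + 1):
        for out in itertools.combinations(eligible, k):
            removed = sum(keys_occ[i] for i in out)
            for inn in itertools.combinations(range(len(queue)), k):
                total = sum(keys_occ) - removed + sum(keys_q[i] for i in inn)
                best = min(best, total)
    return best


class TestEnumerationOracle:
    @pytest.mark.parametrize("policy", sorted(RANKED_POLICIES))
    @pytest.mark.parametrize("trial", range(8))
    def test_ranked_policies_reach_the_enumeration_optimum(self, policy, trial):
        rng = np.random.default_rng(1000 * int(policy) + trial)
        n_beds = int(rng.integers(2, 7))
        n_queue = int(rng.integers(0, 5))
        cap = int(rng.integers(0, n_beds + 1))
        state = make_state(
            [random_patient(rng, i) for i in range(n_beds)],
            elapsed=list(rng.integers(0, 8, size=n_beds)),
        )
        queue = [random_patient(rng, 100 + i) for i in range(n_queue)]
        new, event = ts.apply_triage(state, queue, policy, cap=cap)
        achieved = sum(ts.policy_key(p, policy) for p in new.patients)
        assert achieved == pytest.approx(brute_force_minimum(state, queue, policy, cap))
        assert len(event.admitted) == len(event.discharged) <= min(len(queue), cap)
        assert len(new.patients) == n_beds

    @pytest.mark.parametrize("policy", sorted(Policy))
    def test_census_and_swap_bound_all_policies(self, policy):
        rng = np.random.default_rng(77 + int(policy))
        state = make_state(
            [random_patient(rng, i) for i in range(6)],
            elapsed=list(rng.integers(0, 8, size=6)),
        )
        queue = [random_patient(rng, 100 + i) for i in range(4)]
        new, event = ts.apply_triage(state, queue, policy, cap=3, rng=rng)
        assert len(new.patients) == 6
        assert len(event.admitted) == len(event.discharged) <= 3
        assert set(event.admitted).isdisjoint(event.rejected)

    @pytest.mark.parametrize("policy", sorted(RANKED_POLICIES))
    def test_exchange_optimality(self, policy):
        """No rejected queue member strictly beats a retained eligible
        incumbent unless the swap bound was hit."""
        rng = np.random.default_rng(7 + int(policy))
        state = make_state(
            [random_patient(rng, i) for i in range(6)],
            elapsed=list(rng.integers(0, 8, size=6)),
        )
        queue = [random_patient(rng, 100 + i) for i in range(4)]
        cap = 3
        eligible_ids = {p.patient_id for p, _ in ts.eligible_set(state, policy, cap)}
        new, event = ts.apply_triage(state, queue, policy, cap=cap)
        if len(event.admitted) == min(len(queue), cap):
            return
        retained = [
            p for p in new.patients
            if p.patient_id in eligible_ids and p.patient_id not in event.discharged
        ]
        rejected = [q for q in queue if q.patient_id in event.rejected]
        for q in rejected:
            for inc in retained:
                assert ts.policy_key(q, policy) >= ts.policy_key(inc, policy)


class TestMortalityMetrics:
    def test_extremes_and_arithmetic(self):
        dead = make_state([make_scored(pid=str(i), died=True) for i in range(4)])
        alive = make_state([make_scored(pid=str(i), died=False) for i in range(4)])
        assert ts.realized_mortality(dead) == 1.0
        assert ts.realized_mortality(alive) == 0.0
        mixed = make_state(
            [make_scored(pid=str(i), died=(i % 4 == 0)) for i in range(60)], capacity=60
        )
        assert ts.realized_mortality(mixed) == pytest.approx(15 / 60)

    def test_predicted_is_mean_of_le_gall(self):
        state = make_state([make_scored(pid="a", saps=20.0), make_scored(pid="b", saps=60.0)])
        expected = np.mean([ts.saps_predicted_mortality(20), ts.saps_predicted_mortality(60)])
        assert ts.predicted_mortality(state) == pytest.approx(expected)
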