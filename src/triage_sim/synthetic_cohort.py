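"""Synthetic raw-export generator calibrated to the published cohort table.

The real fourth-wave ICU cohort (n=1083) is not public; this module
produces raw exports whose marginal moments reproduce the printed cohort
statistics: age 64.6±15.7 y, first SAPS II 35.0±12.7, first TISS 9.4±5.4,
12.2±6.4 secondary diagnoses, 22.8% SARS-CoV-2, ICU LOS 4.0±5.4 d,
hospital LOS 17.8±13.6 d, and 23.8% in-hospital mortality.

Continuous attributes are truncated normals whose *parent location* is
solved so the truncated mean hits the printed mean (plain parameterization
would bias means upward, badly so for the zero-truncated LOS).  A Gaussian
copula ties age, TISS, secondary diagnoses and ICU-LOS to the SAPS II
latent (see ``_SAPS_RHO``) so that, as in real ICU cohorts, every triage
criterion is mildly prognostic; the TISS and secondary-diagnosis links are
calibrated against the printed non-survivor subgroup means.  Death, given
SAPS II, is Bernoulli with the Le Gall logit shifted by a constant offset
calibrated so the cohort mean equals the target mortality.  The shift
makes score-based triage effective and reproduces, by construction, the
systematic underestimation of realized mortality by the unshifted Le Gall
prediction.

A configurable number of implausible records (default 4, mirroring the
published exclusion count) is appended, cycling deterministically through
the three plausibility rules so each is exercised.
"""

from __future__ import annotations

import csv
import datetime as dt
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import optimize
from scipy import stats as sps

from .errors import CalibrationError, DomainError, ParameterError
from .records import EXPORT_COLUMNS, Diagnosis, RawPatientRecord, record_to_row
from .scoring import SAPS_MAX, TISS_MAX, legall_logit

#: First admission date of the emulated study window (fourth pandemic wave).
STUDY_START = dt.date(2021, 9, 1)
STUDY_DAYS = 121  # through 31 December

_MAIN_DIAGNOSES = (
    Diagnosis("J96.00", "Acute respiratory failure"),
    Diagnosis("A41.9", "Sepsis, unspecified organism"),
    Diagnosis("I21.9", "Acute myocardial infarction"),
    Diagnosis("J18.9", "Pneumonia, unspecified organism"),
    Diagnosis("S06.5", "Traumatic subdural haemorrhage"),
    Diagnosis("K65.9", "Peritonitis, unspecified"),
)
_COVID_MAIN = Diagnosis("U07.1", "COVID-19, virus identified")

#: Pool of secondary-diagnosis ICD-10 codes, large enough that a sampled
#: count is realized exactly (sampling without replacement).
_SECONDARY_POOL = tuple(
    f"{letter}{num:02d}.{sub}"
    for letter, nums in (("I", range(10, 26)), ("E", range(10, 26)), ("N", range(17, 33)))
    for num in nums
    for sub in ("0", "9")
)[:64]


@dataclass(frozen=True)
class GeneratorParams:
    """Generator configuration; defaults are the published cohort margins."""

    n_patients: int = 1083
    age_mean: float = 64.6
    age_sd: float = 15.7
    saps_mean: float = 35.0
    saps_sd: float = 12.7
    tiss_mean: float = 9.4
    tiss_sd: float = 5.4
    secdiag_mean: float = 12.2
    secdiag_sd: float = 6.4
    covid_fraction: float = 0.228
    icu_los_mean: float = 4.0
    icu_los_sd: float = 5.4
    hosp_los_mean: float = 17.8
    hosp_los_sd: float = 13.6
    target_mortality: float = 0.238
    n_implausible: int = 4
    los_distribution: str = "truncnorm"  # or "lognormal"
    seed: int = 0

    def validate(self) -> None:
        sds = (
            self.age_sd,
            self.saps_sd,
            self.tiss_sd,
            self.secdiag_sd,
            self.icu_los_sd,
            self.hosp_los_sd,
        )
        if any(sd <= 0 for sd in sds):
            raise ParameterError("all standard deviations must be > 0")
        if not (0.0 <= self.covid_fraction <= 1.0):
            raise ParameterError("covid_fraction must be in [0, 1]")
        if not (0.0 < self.target_mortality < 1.0):
            raise ParameterError("target_mortality must be in (0, 1)")
        if self.n_patients < 0 or self.n_implausible < 0:
            raise ParameterError("counts must be nonnegative")
        if self.los_distribution not in ("truncnorm", "lognormal"):
            raise ParameterError(f"unknown LOS family {self.los_distribution!r}")


def _truncnorm_mean(mu: float, sigma: float, lo: float, hi: float) -> float:
    a, b = (lo - mu) / sigma, (hi - mu) / sigma
    return float(sps.truncnorm.mean(a, b, loc=mu, scale=sigma))


def _matched_truncnorm(mean: float, sd: float, lo: float, hi: float):
    """Frozen truncnorm whose *truncated* mean equals ``mean``.

    Parent scale stays at ``sd``; the parent location is solved by
    monotone root finding (the truncated mean is increasing in it).
    """
    lo_mu, hi_mu = mean - 30.0 * sd, mean + 30.0 * sd
    mu = optimize.brentq(
        lambda m: _truncnorm_mean(m, sd, lo, hi) - mean, lo_mu, hi_mu, xtol=1e-10
    )
    a, b = (lo - mu) / sd, (hi - mu) / sd
    return sps.truncnorm(a, b, loc=mu, scale=sd)


def _lognormal_dist(mean: float, sd: float):
    """Frozen log-normal with the given mean and SD (both matched)."""
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    return sps.lognorm(s=np.sqrt(sigma2), scale=np.exp(mu))


#: Gaussian-copula correlations of each attribute with the SAPS II latent.
#: TISS and secondary-diagnosis values reproduce the printed non-survivor
#: subgroup means (TISS 11.9, 14.5 secondary diagnoses, given non-survivor
#: SAPS ~44); age reflects the age component of SAPS II itself; the mild
#: ICU-LOS link encodes longer stays for sicker patients.
_SAPS_RHO = {"age": 0.40, "tiss": 0.65, "secdiag": 0.50, "icu_los": 0.25}


def death_probability(saps, offset: float):
    """Death probability of the offset-shifted Le Gall model.

    ``offset == 0`` reduces to the published SAPS II-predicted mortality;
    strictly increasing in both arguments.
    """
    logit = np.asarray(legall_logit(saps), dtype=float) + offset
    out = 1.0 / (1.0 + np.exp(-logit))
    return float(out) if out.ndim == 0 else out


def calibrate_offset(saps_sample: Sequence[float], target_mortality: float) -> float:
    """Offset c with mean_i death_probability(s_i, c) == target (to 1e-6).

    The mean is strictly increasing in c, so the root is unique; an
    unattainable target raises ``CalibrationError``.
    """
    saps = np.asarray(list(saps_sample), dtype=float)
    if saps.size == 0:
        raise CalibrationError("empty SAPS sample")
    if not (0.0 < target_mortality < 1.0):
        raise CalibrationError("target mortality must be in (0, 1)")
    lo, hi = -20.0, 20.0  # +-20 logit units span all plausibly calibratable targets

    def gap(c):
        return float(np.mean(death_probability(saps, c))) - target_mortality

    if gap(lo) > 0.0 or gap(hi) < 0.0:
        raise CalibrationError(
            f"target {target_mortality} unattainable for this SAPS sample"
        )
    return float(optimize.brentq(gap, lo, hi, xtol=1e-9))


def _systematic_bernoulli(p: np.ndarray, rng) -> np.ndarray:
    """Bernoulli(p_i) flags via systematic sampling on the cumulative scale.

    A unit-spaced random grid over the cumulated probabilities gives each
    patient exactly probability p_i of holding a grid point, while the
    count in any contiguous block is pinned to the block's summed
    probability (+-1).  Cumulating in risk order therefore makes the
    empirical death rate track the conditional risk curve within every
    severity stratum - the generated cohort behaves like a fixed real
    cohort whose stratum mortalities sit on the model curve, with no
    binomial noise on the 23.8% marginal.
    """
    n = len(p)
    order = np.argsort(p, kind="stable")
    cum = np.cumsum(p[order])
    grid = np.floor(cum - rng.random())
    hit = np.diff(np.concatenate(([-1.0], grid))) > 0
    died = np.empty(n, dtype=bool)
    died[order] = hit
    return died


def _make_record(i, age, saps, tiss, n_sec, covid, icu_los, extra_days, admit_day, rng):
    hosp_start = STUDY_START + dt.timedelta(days=int(admit_day))
    pre_delay = int(min(extra_days, rng.integers(0, 3)))
    icu_start = hosp_start + dt.timedelta(days=pre_delay)
    icu_end = icu_start + dt.timedelta(days=int(icu_los))
    hosp_end = hosp_start + dt.timedelta(days=int(icu_los + extra_days))

    n_events = 1 + int(rng.integers(0, 3))
    saps_series, tiss_series = [], []
    for k in range(n_events):
        day = icu_start + dt.timedelta(days=min(k, int(icu_los)))
        if k == 0:
            s_val, t_val = saps, tiss
        else:
            s_val = float(np.clip(round(saps + rng.normal(0.0, 5.0)), 0, SAPS_MAX))
            t_val = float(np.clip(round(tiss + rng.normal(0.0, 3.0)), 0, TISS_MAX))
        saps_series.append((day, s_val))
        tiss_series.append((day, t_val))

    main = [_COVID_MAIN if covid else _MAIN_DIAGNOSES[int(rng.integers(len(_MAIN_DIAGNOSES)))]]
    secondary = list(rng.choice(_SECONDARY_POOL, size=int(n_sec), replace=False))
    return RawPatientRecord(
        patient_id=f"P{i:05d}",
        age=float(age),
        saps_series=saps_series,
        tiss_series=tiss_series,
        main_diagnoses=main,
        secondary_diagnoses=secondary,
        icu_stays=[(icu_start, icu_end)],
        hosp_start=hosp_start,
        hosp_end=hosp_end,
        died=None,  # filled in after calibration
    )


def _corrupt(record: RawPatientRecord, rule_index: int) -> RawPatientRecord:
    """Make a record violate exactly one plausibility rule (cycled)."""
    which = rule_index % 3
    if which == 0:  # two main diagnoses
        return replace(
            record, main_diagnoses=record.main_diagnoses + [_MAIN_DIAGNOSES[0]]
        )
    if which == 1:  # missing SAPS series
        return replace(record, saps_series=[])
    start, end = record.icu_stays[0]  # negative ICU LOS
    return replace(record, icu_stays=[(end + dt.timedelta(days=2), start)])


def generate_cohort(params: GeneratorParams) -> list:
    """Draw ``n_patients + n_implausible`` raw records, reproducibly.

    The death offset is calibrated on the plausible patients' first SAPS
    scores so their empirical mortality targets ``target_mortality``.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    n = params.n_patients + params.n_implausible
    if n == 0:
        return []

    extra_mean = max(params.hosp_los_mean - params.icu_los_mean, 0.5)
    extra_sd = float(np.sqrt(max(params.hosp_los_sd**2 - params.icu_los_sd**2, 1.0)))

    # Gaussian copula: all severity-linked attributes share one latent axis
    # with SAPS (see _SAPS_RHO); marginals below are untouched by it.
    dims = ("saps", "age", "tiss", "secdiag", "icu_los", "extra")
    corr = np.eye(len(dims))
    for j, name in enumerate(dims[1:], start=1):
        corr[0, j] = corr[j, 0] = _SAPS_RHO.get(name, 0.0)
    z = rng.standard_normal((n, len(dims))) @ np.linalg.cholesky(corr).T
    u = sps.norm.cdf(z)

    if params.los_distribution == "lognormal":
        icu_q = _lognormal_dist(params.icu_los_mean, params.icu_los_sd)
        extra_q = _lognormal_dist(extra_mean, extra_sd)
    else:
        icu_q = _matched_truncnorm(params.icu_los_mean, params.icu_los_sd, 0.0, np.inf)
        extra_q = _matched_truncnorm(extra_mean, extra_sd, 0.0, np.inf)

    saps = np.round(_matched_truncnorm(params.saps_mean, params.saps_sd, 0.0, SAPS_MAX).ppf(u[:, 0]))
    age = np.round(_matched_truncnorm(params.age_mean, params.age_sd, 18.0, 100.0).ppf(u[:, 1]))
    tiss = np.round(_matched_truncnorm(params.tiss_mean, params.tiss_sd, 0.0, TISS_MAX).ppf(u[:, 2]))
    sec_d = _matched_truncnorm(params.secdiag_mean, params.secdiag_sd, 0.0, np.inf)
    n_sec = np.clip(np.round(sec_d.ppf(u[:, 3])), 0, len(_SECONDARY_POOL)).astype(int)
    icu_los = np.round(icu_q.ppf(u[:, 4]))
    extra = np.round(extra_q.ppf(u[:, 5]))
    covid = rng.random(n) < params.covid_fraction
    admit_day = rng.integers(0, STUDY_DAYS, size=n)

    records = [
        _make_record(
            i, age[i], saps[i], tiss[i], n_sec[i], covid[i], icu_los[i], extra[i],
            admit_day[i], rng,
        )
        for i in range(n)
    ]

    offset = calibrate_offset(saps[: params.n_patients], params.target_mortality)
    p_death = death_probability(saps, offset)
    died = _systematic_bernoulli(p_death, rng)
    records = [replace(r, died=bool(d)) for r, d in zip(records, died)]

    for j in range(params.n_implausible):
        idx = params.n_patients + j
        records[idx] = _corrupt(records[idx], j)
    return records


def write_export(records: Sequence[RawPatientRecord], path) -> None:
    """Serialize records to the raw-export CSV dialect (lossless round
    trip with :func:`triage_sim.data_prep.parse_export`)."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(EXPORT_COLUMNS)
        for record in records:
            writer.writerow(record_to_row(record))
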