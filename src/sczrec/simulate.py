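"""Synthetic inpatient cohort generator with a planted drug-response structure.

Emits the three raw CSV tables the ingestion module expects, with marginals
matching the development cohort profile it emulates: ~1,152 patients, age
27.9 +/- 6.4 (truncated to the 18-40 inclusion window), 65.8% male,
ethnicity mix 44.4/39.6/8.1/7.9%, visit counts 57.3/21.8/20.9% for 1/2/3
admissions, length of stay averaging 6.6 days with a heavy right tail
(log-normal, sd 10.5), and the printed antipsychotic-prevalence profile
(renormalised to per-visit prescription probabilities).

Each patient belongs to a latent subgroup derived from their demographics
(so similarity in feature space implies similarity in subgroup), and each
(subgroup, drug) pair has a planted response level. Good matches produce
long inter-admission gaps, short stays and no medication switch; bad
matches the opposite — so the affinity score computed downstream recovers
the planted structure, but only through the raw admission records: the
truth file is written separately and nothing in the pipeline reads it.
With ``effect_size = 0`` the structure vanishes and the cohort is pure
noise around the marginals.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .arms import ANTIPSYCHOTICS, NONE_ARM, TREATMENT_ARMS
from .errors import InvalidSpecError

_ETHNICITIES = ("White", "Black/African American", "Hispanic/Latino", "Asian")
_ICD_CODES = ("F20.0", "F20.9", "F25.9", "F20.1", "F20.81")

# Cohort-profile prevalences are per-patient and sum past 1 (patients
# receive several drugs); the generator renormalises them into per-visit
# draws.
_NAMED_PREVALENCE = {
    NONE_ARM: 0.558,
    "risperidone": 0.174,
    "olanzapine": 0.170,
    "haloperidol": 0.151,
    "aripiprazole": 0.096,
    "clozapine": 0.049,
}
_OTHERS_MASS = 0.026


def default_drug_prevalence() -> dict[str, float]:
    prev = dict(_NAMED_PREVALENCE)
    others = [a for a in ANTIPSYCHOTICS if a not in prev]
    for a in others:
        prev[a] = _OTHERS_MASS / len(others)
    total = sum(prev.values())
    return {a: p / total for a, p in prev.items()}


@dataclass
class CohortSpec:
    """Generator parameters; defaults reproduce the development cohort."""

    n_patients: int = 1152
    age_mean: float = 27.9
    age_sd: float = 6.4
    male_fraction: float = 0.658
    ethnicity_probs: tuple[float, float, float, float] = (0.444, 0.396, 0.081, 0.079)
    visit_probs: tuple[float, float, float] = (0.573, 0.218, 0.209)
    los_mean_days: float = 6.6
    los_sd_days: float = 10.5
    drug_prevalence: dict[str, float] = field(default_factory=default_drug_prevalence)
    n_latent_subgroups: int = 4
    effect_size: float = 1.0
    noise_sd: float = 0.10
    subgroup_flip_prob: float = 0.10
    # clinicians prescribe non-randomly: with this probability the drawn
    # drug is restricted to the patient's subgroup-appropriate arms
    prescriber_tilt: float = 0.35
    # patients expected to respond poorly accumulate more admissions: the
    # visit-count multiset is allocated by noisy expected-response rank
    visit_allocation_noise: float = 0.05
    seed: int = 42

    def validate(self) -> None:
        if self.n_patients < 1:
            raise InvalidSpecError("n_patients must be positive")
        for name, probs in (
            ("ethnicity_probs", self.ethnicity_probs),
            ("visit_probs", self.visit_probs),
            ("drug_prevalence", tuple(self.drug_prevalence.values())),
        ):
            if min(probs) < 0 or not math.isclose(sum(probs), 1.0, abs_tol=1e-6):
                raise InvalidSpecError(f"{name} must be non-negative and sum to 1")
        if not 0 <= self.male_fraction <= 1:
            raise InvalidSpecError("male_fraction outside [0, 1]")
        if self.age_sd <= 0 or self.los_mean_days <= 0 or self.los_sd_days <= 0:
            raise InvalidSpecError("scale parameters must be positive")
        if self.n_latent_subgroups < 1:
            raise InvalidSpecError("need at least one latent subgroup")
        if not 0 <= self.prescriber_tilt <= 1:
            raise InvalidSpecError("prescriber_tilt outside [0, 1]")
        if self.visit_allocation_noise < 0:
            raise InvalidSpecError("visit_allocation_noise must be non-negative")
        if set(self.drug_prevalence) - set(TREATMENT_ARMS):
            raise InvalidSpecError("drug_prevalence names an unknown arm")


# response-level geometry: planted good/bad offset and how strongly response
# drives stays, gaps and switches
_RESPONSE_DELTA = 0.35
_LOS_SLOPE = 1.2          # LOS mean multiplier: 1 + slope * (0.5 - r)
_GAP_BASE_DAYS = 30.0
_GAP_SLOPE_DAYS = 150.0   # readmission gap mean: base + slope * r
_SWITCH_BASE = 0.22
_SWITCH_SLOPE = 0.9       # within-visit switch prob: base + slope * (0.5 - r)
_COMORBIDITY_BASE = 1.0
_COMORBIDITY_STEP = 0.8   # Poisson mean grows with subgroup index


def _response_matrix(spec: CohortSpec) -> np.ndarray:
    """Planted expected response per (subgroup, arm): alternating good/bad
    offsets of +/- 0.35 scaled by effect_size, around 0.5."""
    G, D = spec.n_latent_subgroups, len(TREATMENT_ARMS)
    R = np.empty((G, D))
    for g in range(G):
        for d in range(D):
            sign = 1.0 if (g + d) % 2 == 0 else -1.0
            R[g, d] = 0.5 + spec.effect_size * _RESPONSE_DELTA * sign
    return np.clip(R, 0.02, 0.98)


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    cv2 = (sd / mean) ** 2
    sigma2 = math.log1p(cv2)
    return math.log(mean) - sigma2 / 2.0, math.sqrt(sigma2)


def generate(
    spec: CohortSpec,
    out_dir: str | Path | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, dict]:
    """Draw a cohort; optionally write patients/visits/prescriptions CSVs
    plus truth.json into ``out_dir``. Same spec + seed => byte-identical
    output."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    R = _response_matrix(spec)
    arm_index = {a: j for j, a in enumerate(TREATMENT_ARMS)}
    arms = list(spec.drug_prevalence.keys())
    arm_p = np.array([spec.drug_prevalence[a] for a in arms])

    a_std = (18.0 - spec.age_mean) / spec.age_sd
    b_std = (40.0 - spec.age_mean) / spec.age_sd
    base_date = pd.Timestamp("2018-01-01")

    # pass 1: demographics and latent subgroup per patient
    patients, visits, rx = [], [], []
    truth_groups: dict[str, int] = {}
    groups = np.empty(spec.n_patients, dtype=int)
    for i in range(spec.n_patients):
        pid = f"P{i:05d}"
        male = rng.random() < spec.male_fraction
        ethnicity = _ETHNICITIES[rng.choice(4, p=np.asarray(spec.ethnicity_probs))]
        age = int(round(stats.truncnorm.rvs(
            a_std, b_std, loc=spec.age_mean, scale=spec.age_sd, random_state=rng
        )))
        age = min(40, max(18, age))
        group = (2 * int(male) + int(age >= spec.age_mean)) % spec.n_latent_subgroups
        if rng.random() < spec.subgroup_flip_prob:
            group = int(rng.integers(spec.n_latent_subgroups))
        truth_groups[pid] = group
        groups[i] = group
        patients.append(
            {
                "patient_id": pid,
                "gender": "M" if male else "F",
                "ethnicity": ethnicity,
                "age": age,
                "icd_code": _ICD_CODES[int(rng.integers(len(_ICD_CODES)))],
            }
        )

    # visit-count allocation: draw the multiset from the marginal, then hand
    # the larger counts to patients with the worse (noisy) expected response,
    # so admission burden tracks the planted structure while the marginal
    # visit-count distribution is preserved exactly
    counts = 1 + rng.choice(3, size=spec.n_patients, p=np.asarray(spec.visit_probs))
    expected_response = np.array(
        [float(np.dot(arm_p, R[g, [arm_index[a] for a in arms]])) for g in range(R.shape[0])]
    )
    score = expected_response[groups] + rng.normal(0, spec.visit_allocation_noise, spec.n_patients)
    n_visits_by_patient = np.empty(spec.n_patients, dtype=int)
    n_visits_by_patient[np.argsort(score, kind="stable")] = np.sort(counts)[::-1]

    # prescriber tilt operates within antipsychotics only: the medicated /
    # unmedicated split follows the NONE prevalence exactly, so the largest
    # marginal is untouched by subgroup-dependent prescribing
    p_none = spec.drug_prevalence.get(NONE_ARM, 0.0)
    med_arms = [a for a in arms if a != NONE_ARM]
    med_p = np.array([spec.drug_prevalence[a] for a in med_arms])
    med_p = med_p / med_p.sum() if med_p.sum() > 0 else med_p
    good_arms_by_group = [
        [a for a in med_arms if (arm_index[a] + g) % 2 == 0] for g in range(R.shape[0])
    ]
    good_p_by_group = [
        np.array([spec.drug_prevalence[a] for a in ga]) for ga in good_arms_by_group
    ]

    # pass 2: admissions, stays, prescriptions and switches
    for i in range(spec.n_patients):
        pid = patients[i]["patient_id"]
        group = int(groups[i])
        lam = _COMORBIDITY_BASE + _COMORBIDITY_STEP * group
        n_visits = int(n_visits_by_patient[i])
        admit = base_date + pd.Timedelta(days=float(rng.uniform(0, 365)))
        for v in range(1, n_visits + 1):
            good_arms, good_p = good_arms_by_group[group], good_p_by_group[group]
            if rng.random() < p_none or len(med_arms) == 0:
                drug = NONE_ARM
            elif good_p.sum() > 0 and rng.random() < spec.prescriber_tilt:
                drug = good_arms[int(rng.choice(len(good_arms), p=good_p / good_p.sum()))]
            else:
                drug = med_arms[int(rng.choice(len(med_arms), p=med_p))]
            r = float(np.clip(
                R[group, arm_index[drug]] + rng.normal(0, spec.noise_sd), 0.02, 0.98
            ))
            los_target = spec.los_mean_days * max(0.15, 1.0 + _LOS_SLOPE * (0.5 - r))
            mu, sigma = _lognormal_params(los_target, spec.los_sd_days * los_target / spec.los_mean_days)
            los = float(rng.lognormal(mu, sigma))
            los = min(los, 120.0)  # clinically implausible stays truncated
            discharge = admit + pd.Timedelta(days=los)
            visits.append(
                {
                    "patient_id": pid,
                    "admit_time": admit,
                    "discharge_time": discharge,
                    "comorbidity_count": int(rng.poisson(lam)),
                }
            )
            if drug != NONE_ARM:
                rx.append(
                    {
                        "patient_id": pid,
                        "admit_time": admit,
                        "drug": drug,
                        "start_time": admit + pd.Timedelta(days=float(rng.uniform(0.0, 0.1)) * los),
                    }
                )
            # poor response pushes an in-admission medication change; an
            # unmedicated admission stays unmedicated (switches away from
            # NONE only happen across visits)
            p_switch = float(np.clip(_SWITCH_BASE + _SWITCH_SLOPE * (0.5 - r), 0.02, 0.90))
            if drug != NONE_ARM and rng.random() < p_switch:
                pool = [a for a in ANTIPSYCHOTICS if a != drug]
                second = pool[int(rng.integers(len(pool)))]
                rx.append(
                    {
                        "patient_id": pid,
                        "admit_time": admit,
                        "drug": second,
                        "start_time": admit + pd.Timedelta(days=float(rng.uniform(0.35, 0.7)) * los),
                    }
                )
                if rng.random() < p_switch / 3.0:
                    pool2 = [a for a in ANTIPSYCHOTICS if a not in (drug, second)]
                    third = pool2[int(rng.integers(len(pool2)))]
                    rx.append(
                        {
                            "patient_id": pid,
                            "admit_time": admit,
                            "drug": third,
                            "start_time": admit + pd.Timedelta(days=float(rng.uniform(0.75, 0.95)) * los),
                        }
                    )
            gap_mean = _GAP_BASE_DAYS + _GAP_SLOPE_DAYS * r
            gap = float(rng.gamma(2.0, gap_mean / 2.0)) + 1.0
            admit = discharge + pd.Timedelta(days=gap)

    patients_df = pd.DataFrame(patients)
    visits_df = pd.DataFrame(visits)
    rx_df = pd.DataFrame(rx, columns=["patient_id", "admit_time", "drug", "start_time"])
    truth = {
        "subgroups": truth_groups,
        "response_matrix": R.tolist(),
        "arms": list(TREATMENT_ARMS),
        "spec": _spec_dict(spec),
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        _write_csv(patients_df, out / "patients.csv")
        _write_csv(visits_df, out / "visits.csv")
        _write_csv(rx_df, out / "prescriptions.csv")
        (out / "truth.json").write_text(json.dumps(truth, indent=1, sort_keys=True))
    return patients_df, visits_df, rx_df, truth


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df = df.copy()
    for col in df.columns:
        if pd.api.types.is_datetime64_any_dtype(df[col]):
            df[col] = df[col].dt.strftime("%Y-%m-%dT%H:%M:%S")
    df.to_csv(path, index=False)


def _spec_dict(spec: CohortSpec) -> dict:
    d = asdict(spec)
    d["ethnicity_probs"] = list(spec.ethnicity_probs)
    d["visit_probs"] = list(spec.visit_probs)
    return d


# ---------------------------------------------------------------------------
# marginal validation
# ---------------------------------------------------------------------------

def _proportion_z(count: int, n: int, p: float) -> float:
    if n == 0:
        return 0.0
    if p in (0.0, 1.0):
        return 0.0 if count == round(p * n) else float("inf")
    return (count / n - p) / math.sqrt(p * (1 - p) / n)


def validate_marginals(
    patients: pd.DataFrame,
    visits: pd.DataFrame,
    prescriptions: pd.DataFrame,
    spec: CohortSpec,
    z_limit: float = 4.0,
) -> dict:
    """z-test every generated marginal against its specified value.

    The age check compares against the truncated-normal expectation (the
    18-40 window shifts the raw mean); LOS uses the sample standard error
    because of its heavy tail. Returns a report dict; ``passed`` is True
    when every |z| stays within ``z_limit``.
    """
    n = len(patients)
    checks: dict[str, float] = {}
    checks["male_fraction"] = _proportion_z(
        int((patients["gender"] == "M").sum()), n, spec.male_fraction
    )
    for eth, p in zip(_ETHNICITIES, spec.ethnicity_probs):
        checks[f"ethnicity[{eth}]"] = _proportion_z(
            int((patients["ethnicity"] == eth).sum()), n, p
        )
    visit_counts = visits.groupby("patient_id").size()
    for k, p in zip((1, 2, 3), spec.visit_probs):
        checks[f"visits[{k}]"] = _proportion_z(int((visit_counts == k).sum()), n, p)

    a_std = (18.0 - spec.age_mean) / spec.age_sd
    b_std = (40.0 - spec.age_mean) / spec.age_sd
    exp_mean = stats.truncnorm.mean(a_std, b_std, loc=spec.age_mean, scale=spec.age_sd)
    exp_sd = stats.truncnorm.std(a_std, b_std, loc=spec.age_mean, scale=spec.age_sd)
    checks["age_mean"] = float(
        (patients["age"].mean() - exp_mean) / (exp_sd / math.sqrt(n))
    )

    los = (
        (visits["discharge_time"] - visits["admit_time"]).dt.total_seconds() / 86400.0
    )
    checks["los_mean_days"] = float(
        (los.mean() - spec.los_mean_days) / (los.std(ddof=1) / math.sqrt(len(los)))
    )

    # per-visit prescribed drug (first start of the admission; NONE if none)
    first_rx = (
        prescriptions.sort_values("start_time", kind="stable")
        .groupby(["patient_id", "admit_time"])
        .first()["drug"]
        if len(prescriptions)
        else pd.Series(dtype=object)
    )
    keys = list(zip(visits["patient_id"], visits["admit_time"]))
    assigned = pd.Series(
        [first_rx.get(k, NONE_ARM) for k in keys], dtype=object
    )
    n_vis = len(visits)
    for arm, p in spec.drug_prevalence.items():
        checks[f"drug[{arm}]"] = _proportion_z(int((assigned == arm).sum()), n_vis, p)

    worst = max(abs(z) for z in checks.values())
    return {
        "z": checks,
        "worst_abs_z": worst,
        "z_limit": z_limit,
        "passed": bool(worst <= z_limit),
    }
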