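"""Cohort ingestion: cleaning rules, inclusion criteria and consultation assembly.

Raw input is three UTF-8 CSV tables:

    patients.csv       patient_id, gender, ethnicity, age, icd_code
    visits.csv         patient_id, admit_time, discharge_time, comorbidity_count
                       (optional: visit_number, for sources that pre-number
                       admissions; otherwise admissions are numbered by
                       admit-time order)
    prescriptions.csv  patient_id, admit_time, drug, start_time

Cleaning retains patients aged 18-40 with a schizophrenia-spectrum (F2x)
diagnosis, consolidates ethnicity into four categories, caps admission
records at the third visit, and drops patients whose recorded visit
sequence does not start at visit 1. The output is one row per
*consultation* — a (patient, visit) prescribing decision point — carrying
the temporally admissible feature vector for that visit plus the raw
utilisation quantities that feed the affinity score.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .arms import NONE_ARM, TREATMENT_ARMS
from .errors import TemporalLeakageError
from .ethnicity import EXCLUDE, consolidate_ethnicity
from .icd import UnknownCodeError, first_code, is_schizophrenia_spectrum, map_icd9_to_icd10

MAX_VISITS = 3
AGE_MIN, AGE_MAX = 18, 40

SECONDS_PER_DAY = 86400.0

#: Feature schema per visit index. Visit v uses baseline fields plus, for
#: each completed prior visit k, its length of stay, the gap to the next
#: admission, the drug prescribed, and a switch indicator.
BASELINE_FEATURES = ["gender", "ethnicity", "age", "comorbidity_count"]
HISTORY_FEATURES = {
    2: ["los_1", "gap_1_2", "drug_1", "switched_1"],
    3: ["los_2", "gap_2_3", "drug_2", "switched_2"],
}
CATEGORICAL_FEATURES = {"gender", "ethnicity", "drug_1", "drug_2"}

UTIL_COLUMNS = [
    "util_inter_admission_days",
    "util_inter_switch_days",
    "util_los_days",
    "util_visit_count",
    "util_switch_count",
]


def feature_columns(visit_index: int) -> list[str]:
    """Ordered feature names available at the given visit index."""
    cols = list(BASELINE_FEATURES)
    for k in range(2, visit_index + 1):
        cols += HISTORY_FEATURES[k]
    return cols


@dataclass
class ExclusionLog:
    """Per-reason patient exclusion counts; sums reconcile input vs output."""

    counts: dict[str, int] = field(default_factory=dict)

    def add(self, reason: str, n: int = 1) -> None:
        self.counts[reason] = self.counts.get(reason, 0) + n

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def to_text(self) -> str:
        lines = [f"{reason}: {n}" for reason, n in sorted(self.counts.items())]
        lines.append(f"total excluded: {self.total}")
        return "\n".join(lines) + "\n"


def load_raw_tables(patients_csv, visits_csv, prescriptions_csv):
    """Read the three raw CSVs, parsing timestamps as ISO-8601."""
    patients = pd.read_csv(patients_csv, dtype={"patient_id": str})
    visits = pd.read_csv(visits_csv, dtype={"patient_id": str})
    rx = pd.read_csv(prescriptions_csv, dtype={"patient_id": str})
    for col in ("admit_time", "discharge_time"):
        if col in visits:
            visits[col] = pd.to_datetime(visits[col])
    for col in ("admit_time", "start_time"):
        if col in rx:
            rx[col] = pd.to_datetime(rx[col])
    return patients, visits, rx


def apply_inclusion_criteria(
    patients: pd.DataFrame,
    visits: pd.DataFrame,
    dialect_table: dict[str, str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, ExclusionLog]:
    """Apply cleaning and inclusion rules; deterministic given input order.

    Returns (clean patients, capped + indexed visits, exclusion log). The
    visits frame gains a ``visit_index`` column in {1..3}; admissions beyond
    the third are dropped without excluding the patient.
    """
    log = ExclusionLog()
    keep_rows = []
    for _, row in patients.iterrows():
        try:
            code = map_icd9_to_icd10(first_code(row["icd_code"]))
        except UnknownCodeError:
            log.add("unmappable_icd_code")
            continue
        if not is_schizophrenia_spectrum(code):
            log.add("non_f2_diagnosis")
            continue
        age = int(row["age"])
        if not (AGE_MIN <= age <= AGE_MAX):
            log.add("age_outside_18_40")
            continue
        eth = consolidate_ethnicity(row["ethnicity"], dialect_table)
        if eth == EXCLUDE:
            log.add("ethnicity_group_excluded")
            continue
        rec = row.to_dict()
        rec["icd_code"] = code
        rec["ethnicity"] = eth
        rec["age"] = age
        keep_rows.append(rec)
    clean = pd.DataFrame(keep_rows, columns=list(patients.columns))

    visits = visits.sort_values(["patient_id", "admit_time"], kind="stable").copy()
    if "visit_number" in visits.columns:
        visits["visit_index"] = visits["visit_number"].astype(int)
    else:
        visits["visit_index"] = visits.groupby("patient_id").cumcount() + 1

    # Patients whose recorded sequence lacks an initial visit are data-entry
    # artefacts and are excluded outright.
    first_seen = visits.groupby("patient_id")["visit_index"].min()
    broken = set(first_seen[first_seen != 1].index)
    n_broken = len(broken & set(clean["patient_id"]))
    if n_broken:
        log.add("missing_initial_visit", n_broken)
        clean = clean[~clean["patient_id"].isin(broken)]

    no_visits = set(clean["patient_id"]) - set(visits["patient_id"])
    if no_visits:
        log.add("no_visit_records", len(no_visits))
        clean = clean[~clean["patient_id"].isin(no_visits)]

    visits = visits[visits["visit_index"] <= MAX_VISITS]
    visits = visits[visits["patient_id"].isin(set(clean["patient_id"]))]
    if (visits["discharge_time"] < visits["admit_time"]).any():
        raise ValueError("discharge before admission in visits table")
    clean = clean.reset_index(drop=True)
    visits = visits.reset_index(drop=True)
    return clean, visits, log


def build_feature_vector(
    patient: dict | pd.Series,
    history_visits: list[dict],
    visit_index: int,
    current_comorbidity_count: int,
) -> dict:
    """Assemble the temporally admissible feature vector for one consultation.

    ``history_visits`` must contain exactly the patient's completed visits
    with index strictly below ``visit_index`` (each a dict with visit_index,
    admit_time, discharge_time, prescribed_drug, within_visit_switch, and
    for gap computation the next admit time is taken from the following
    history entry or left to the caller via ``next_admit_time``). Supplying
    any visit at or beyond ``visit_index`` raises TemporalLeakageError: the
    current admission contributes only its baseline comorbidity count.
    """
    for h in history_visits:
        if int(h["visit_index"]) >= visit_index:
            raise TemporalLeakageError(
                f"visit {h['visit_index']} supplied while building features for visit {visit_index}"
            )
    vec = {
        "gender": patient["gender"],
        "ethnicity": patient["ethnicity"],
        "age": float(patient["age"]),
        "comorbidity_count": float(current_comorbidity_count),
    }
    hist = sorted(history_visits, key=lambda h: int(h["visit_index"]))
    if visit_index >= 2:
        if len(hist) != visit_index - 1:
            raise TemporalLeakageError(
                f"visit {visit_index} requires {visit_index - 1} prior visits, got {len(hist)}"
            )
        for k in range(1, visit_index):
            h = hist[k - 1]
            los = (h["discharge_time"] - h["admit_time"]).total_seconds() / SECONDS_PER_DAY
            gap = (h["next_admit_time"] - h["discharge_time"]).total_seconds() / SECONDS_PER_DAY
            switched = bool(h["within_visit_switch"])
            if k >= 2:
                switched = switched or (hist[k - 1]["prescribed_drug"] != hist[k - 2]["prescribed_drug"])
            vec[f"los_{k}"] = los
            vec[f"gap_{k}_{k + 1}"] = gap
            vec[f"drug_{k}"] = h["prescribed_drug"]
            vec[f"switched_{k}"] = float(switched)
    return vec


def _initiation_events(patient_visits: pd.DataFrame, patient_rx: pd.DataFrame):
    """Ordered medication-initiation events over the capped visit sequence.

    One event per prescription start; visits without any prescription
    contribute a NONE pseudo-initiation at admission. Consecutive repeats of
    the same drug (continuation across visits) are collapsed.
    """
    events: list[tuple[pd.Timestamp, str, int]] = []
    rx_by_admit = dict(tuple(patient_rx.groupby("admit_time"))) if len(patient_rx) else {}
    for _, vrow in patient_visits.iterrows():
        block = rx_by_admit.get(vrow["admit_time"])
        if block is None or block.empty:
            events.append((vrow["admit_time"], NONE_ARM, int(vrow["visit_index"])))
        else:
            for _, rrow in block.sort_values("start_time", kind="stable").iterrows():
                events.append((rrow["start_time"], str(rrow["drug"]), int(vrow["visit_index"])))
    events.sort(key=lambda e: e[0])
    collapsed = []
    for ev in events:
        if collapsed and collapsed[-1][1] == ev[1]:
            continue
        collapsed.append(ev)
    return collapsed


def _raw_utilization_for_drug(events, drug, visits_sorted) -> dict:
    """Raw quantities for the (patient, drug) instance, capped at 2 switches."""
    n_visits = len(visits_sorted)
    los_days = float(
        sum(
            (v["discharge_time"] - v["admit_time"]).total_seconds() / SECONDS_PER_DAY
            for v in visits_sorted
        )
    )
    if n_visits >= 2:
        inter_adm = float(
            sum(
                (visits_sorted[i + 1]["admit_time"] - visits_sorted[i]["discharge_time"]).total_seconds()
                / SECONDS_PER_DAY
                for i in range(n_visits - 1)
            )
        )
    else:
        inter_adm = np.nan

    i0 = next((i for i, e in enumerate(events) if e[1] == drug), None)
    if i0 is None:
        raise ValueError(f"drug {drug!r} never initiated for this patient")
    subsequent = events[i0 + 1 : i0 + 1 + 2]  # capped at two switches
    switch_count = len(subsequent)
    if switch_count:
        times = [events[i0][0]] + [e[0] for e in subsequent]
        gaps = [
            (times[i + 1] - times[i]).total_seconds() / SECONDS_PER_DAY
            for i in range(len(times) - 1)
        ]
        inter_switch = float(np.mean(gaps))
    else:
        inter_switch = np.nan
    return {
        "util_inter_admission_days": inter_adm,
        "util_inter_switch_days": inter_switch,
        "util_los_days": los_days,
        "util_visit_count": n_visits,
        "util_switch_count": switch_count,
    }


def assemble_consultations(
    patients: pd.DataFrame,
    visits: pd.DataFrame,
    prescriptions: pd.DataFrame,
    log: ExclusionLog | None = None,
) -> pd.DataFrame:
    """Build the consultation table: one row per (patient, visit).

    Each row carries the visit's prescribed drug (first prescription start of
    that admission; NONE when unmedicated), the feature vector admissible at
    that visit, and the raw utilisation quantities of the (patient, drug)
    instance. Unknown drug names are dropped and counted.
    """
    log = log if log is not None else ExclusionLog()
    rx = prescriptions.copy()
    bad = ~rx["drug"].isin(TREATMENT_ARMS)
    if bad.any():
        log.add("unknown_drug_rows", int(bad.sum()))
        rx = rx[~bad]

    rows = []
    rx_by_patient = dict(tuple(rx.groupby("patient_id"))) if len(rx) else {}
    visits_by_patient = dict(tuple(visits.groupby("patient_id")))
    for _, prow in patients.iterrows():
        pid = prow["patient_id"]
        pv = visits_by_patient.get(pid)
        if pv is None:
            continue
        pv = pv.sort_values("visit_index", kind="stable")
        prx = rx_by_patient.get(pid, rx.iloc[0:0])
        events = _initiation_events(pv, prx)
        rx_by_admit = dict(tuple(prx.groupby("admit_time"))) if len(prx) else {}

        vis_records = []
        pv_list = list(pv.itertuples(index=False))
        for i, v in enumerate(pv_list):
            block = rx_by_admit.get(v.admit_time)
            if block is None or block.empty:
                drug, within_switch = NONE_ARM, False
            else:
                ordered = block.sort_values("start_time", kind="stable")
                drug = str(ordered.iloc[0]["drug"])
                within_switch = ordered["drug"].nunique() > 1
            vis_records.append(
                {
                    "visit_index": int(v.visit_index),
                    "admit_time": v.admit_time,
                    "discharge_time": v.discharge_time,
                    "comorbidity_count": int(v.comorbidity_count),
                    "prescribed_drug": drug,
                    "within_visit_switch": within_switch,
                    "next_admit_time": pv_list[i + 1].admit_time if i + 1 < len(pv_list) else None,
                }
            )

        for i, vrec in enumerate(vis_records):
            vidx = vrec["visit_index"]
            history = [dict(h) for h in vis_records[: i]]
            vec = build_feature_vector(prow, history, vidx, vrec["comorbidity_count"])
            util = _raw_utilization_for_drug(events, vrec["prescribed_drug"], vis_records)
            row = {
                "patient_id": pid,
                "visit_index": vidx,
                "admit_time": vrec["admit_time"],
                "drug": vrec["prescribed_drug"],
                **vec,
                **util,
            }
            rows.append(row)

    all_cols = (
        ["patient_id", "visit_index", "admit_time", "drug"]
        + feature_columns(MAX_VISITS)
        + UTIL_COLUMNS
    )
    out = pd.DataFrame(rows)
    for c in all_cols:
        if c not in out.columns:
            out[c] = np.nan
    return out[all_cols]


def load_cohort(patients_csv, visits_csv, prescriptions_csv, dialect_table=None):
    """One-shot: raw CSVs -> (consultations, exclusion log)."""
    patients, visits, rx = load_raw_tables(patients_csv, visits_csv, prescriptions_csv)
    clean, capped, log = apply_inclusion_criteria(patients, visits, dialect_table)
    consultations = assemble_consultations(clean, capped, rx, log)
    return consultations, log


def write_cohort(consultations: pd.DataFrame, path) -> None:
    consultations.to_csv(path, index=False)


def read_cohort(path) -> pd.DataFrame:
    """Read a cohort CSV back with the dtypes the pipeline expects."""
    df = pd.read_csv(path, dtype={"patient_id": str})
    df["admit_time"] = pd.to_datetime(df["admit_time"])
    df["visit_index"] = df["visit_index"].astype(int)
    for col in ("util_visit_count", "util_switch_count"):
        df[col] = df[col].astype(int)
    return df


def drug_affinity_instances(consultations: pd.DataFrame) -> pd.DataFrame:
    """Unique (patient, drug) instances with their raw utilisation rows.

    A patient prescribed the same drug at several visits contributes one
    instance (the utilisation quantities are identical by construction).
    """
    cols = ["patient_id", "drug"] + UTIL_COLUMNS
    return consultations[cols].drop_duplicates(subset=["patient_id", "drug"]).reset_index(drop=True)
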