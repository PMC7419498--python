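"""EMR ingest: cleaning, race resolution, lifetime histories, matched samples.

Input is visit-level delimited text, one row per (patient, visit, diagnosis).
Cleaning follows the rules used for large administrative EMR extracts:

* visits whose every code is a general symptom (ICD-9 chapter 17, 780-799)
  or unclassifiable are removed; on mixed visits the symptom codes
  themselves are dropped, so chapter 17 never reaches the comorbidity stage;
* V- and E-prefixed supplementary codes are outside the 001-999 organ-system
  scheme and are dropped (counted, never silently lost);
* patients recorded with more than one distinct race across visits are
  treated as erroneous and removed entirely, as are patients with no race
  information at all;
* a patient's history is the *set* of distinct 3-digit codes over all their
  visits, so chronic diseases recorded at every encounter count once.

Every dropped row, visit and patient is accounted for in a drop report:
input rows = retained rows + dropped rows, by reason.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .icd9 import SYMPTOM_CHAPTER, chapter_of, try_truncate

__all__ = [
    "DEFAULT_COLUMNS",
    "DropReport",
    "PatientHistory",
    "build_histories",
    "clean_visits",
    "equal_sample",
    "read_histories",
    "read_visits",
    "resolve_race",
    "summarize",
    "write_histories",
]

log = logging.getLogger(__name__)

#: canonical column names; keys are the names used internally, values the
#: default header names expected in input files (override via config)
DEFAULT_COLUMNS = {
    "patient_id": "patient_id",
    "visit_id": "visit_id",
    "visit_index": "visit_index",
    "race": "race",
    "age_at_visit": "age_at_visit",
    "icd9_code": "icd9_code",
}


@dataclass
class PatientHistory:
    """A patient's lifetime set of distinct 3-digit diagnoses."""

    patient_id: str
    group_label: str
    codes: frozenset[str]
    n_visits: int = 0
    ages: tuple[float, ...] = ()


@dataclass
class DropReport:
    """Accounting of every row/visit/patient removed during ingest."""

    input_rows: int = 0
    retained_rows: int = 0
    dropped: dict[str, int] = field(default_factory=dict)

    def add(self, reason: str, n: int) -> None:
        if n:
            self.dropped[reason] = self.dropped.get(reason, 0) + int(n)

    @property
    def dropped_rows(self) -> int:
        return sum(self.dropped.values())

    def to_dict(self) -> dict:
        return {
            "input_rows": self.input_rows,
            "retained_rows": self.retained_rows,
            "dropped_rows": self.dropped_rows,
            "dropped_by_reason": dict(sorted(self.dropped.items())),
        }


def read_visits(path, columns: dict[str, str] | None = None, sep: str | None = None) -> pd.DataFrame:
    """Read a delimited visit file (comma default, tab accepted) and rename
    columns to the canonical names.  A header row is required."""
    colmap = dict(DEFAULT_COLUMNS)
    if columns:
        colmap.update(columns)
    df = pd.read_csv(path, sep=sep, engine="python" if sep is None else "c", dtype={colmap["icd9_code"]: str})
    missing = [v for k, v in colmap.items() if v not in df.columns and k in ("patient_id", "visit_id", "race", "icd9_code")]
    if missing:
        raise ValueError(f"input file missing required columns: {missing}")
    rename = {v: k for k, v in colmap.items() if v in df.columns}
    df = df.rename(columns=rename)
    df["patient_id"] = df["patient_id"].astype(str)
    df["visit_id"] = df["visit_id"].astype(str)
    df["icd9_code"] = df["icd9_code"].astype(str)
    return df


def clean_visits(records: pd.DataFrame, report: DropReport | None = None) -> tuple[pd.DataFrame, DropReport]:
    """Normalise codes to 3 digits and apply the symptom/visit filters.

    Adds a ``code3`` column.  Rows are dropped (and counted) when the code
    is malformed or V/E-prefixed, when it is a chapter-17 symptom code, or
    when the whole visit carried nothing but symptom/unclassifiable codes
    (the visit is then removed in full).
    """
    report = report or DropReport()
    if report.input_rows == 0:
        report.input_rows = len(records)
    df = records.copy()
    code3 = df["icd9_code"].map(lambda c: try_truncate(c))
    malformed = code3.isna()
    ve = df["icd9_code"].str.strip().str.upper().str.match(r"^[VE]\d")
    report.add("code_ve_supplementary", int((malformed & ve).sum()))
    report.add("code_malformed", int((malformed & ~ve).sum()))
    if (malformed & ~ve).any():
        bad = df.loc[malformed & ~ve, "icd9_code"].unique()[:5]
        log.warning("skipped %d rows with malformed codes (e.g. %s)", int((malformed & ~ve).sum()), list(bad))
    df = df[~malformed].copy()
    df["code3"] = code3[~malformed]
    chap = df["code3"].map(chapter_of)
    symptom = chap == SYMPTOM_CHAPTER
    # a visit whose retained rows are all symptoms is a symptom-only visit
    visit_all_symptom = symptom.groupby([df["patient_id"], df["visit_id"]]).transform("all")
    report.add("visit_symptom_only", int((symptom & visit_all_symptom).sum()))
    report.add("code_symptom_on_mixed_visit", int((symptom & ~visit_all_symptom).sum()))
    df = df[~symptom].copy()
    report.retained_rows = len(df)
    return df, report


def resolve_race(records: pd.DataFrame, report: DropReport | None = None) -> tuple[pd.DataFrame, DropReport]:
    """Drop all visits of patients with inconsistent or entirely missing race.

    Race labels are opaque case-normalised strings; a patient with exactly
    one distinct non-missing label is kept (missing entries are filled with
    that label).
    """
    report = report or DropReport()
    if report.input_rows == 0:
        report.input_rows = len(records)
    df = records.copy()
    race = df["race"].astype("string").str.strip()
    race = race.mask(race.isin(["", "nan", "NaN", "None", "NA", "<NA>"]))
    norm = race.str.casefold()
    nunique = norm.groupby(df["patient_id"]).transform("nunique")
    inconsistent = nunique > 1
    missing_only = nunique == 0
    report.add("patient_inconsistent_race", int(inconsistent.sum()))
    report.add("patient_missing_race", int(missing_only.sum()))
    keep = ~(inconsistent | missing_only)
    df = df[keep].copy()
    # fill missing entries with the patient's unique label
    filled = race[keep].groupby(df["patient_id"]).transform("first")
    df["race"] = filled
    report.retained_rows = len(df)
    return df, report


def build_histories(records: pd.DataFrame) -> dict[str, list[PatientHistory]]:
    """Collapse cleaned, race-resolved visit rows to lifetime histories.

    Requires the ``code3`` column produced by :func:`clean_visits`.  Patients
    with an empty retained code set do not appear (their rows were already
    removed by the filters).  Idempotent on its own flattened output.
    """
    if "code3" not in records.columns:
        raise ValueError("records must be cleaned first (missing code3 column)")
    out: dict[str, list[PatientHistory]] = {}
    has_age = "age_at_visit" in records.columns
    grouped = records.groupby("patient_id", sort=True)
    codes_by_patient = grouped["code3"].agg(frozenset)
    race_by_patient = grouped["race"].first()
    visits_by_patient = grouped["visit_id"].nunique()
    if has_age:
        per_visit = records.drop_duplicates(["patient_id", "visit_id"])
        ages_by_patient = per_visit.groupby("patient_id")["age_at_visit"].agg(tuple)
    for pid, codes in codes_by_patient.items():
        if not codes:
            continue
        label = str(race_by_patient[pid])
        hist = PatientHistory(
            patient_id=str(pid),
            group_label=label,
            codes=codes,
            n_visits=int(visits_by_patient[pid]),
            ages=tuple(float(a) for a in ages_by_patient[pid]) if has_age else (),
        )
        out.setdefault(label, []).append(hist)
    return out


def equal_sample(
    histories: dict[str, list[PatientHistory]],
    target_n: int | str = "min-group",
    seed: int = 0,
) -> dict[str, list[PatientHistory]]:
    """Simple random sample without replacement bringing every group to the
    same size (the smallest group's by default, which passes through whole).

    Each group gets an independent random stream derived from ``seed`` and
    the group's rank in sorted label order, so adding a group does not
    perturb another group's sample.
    """
    sizes = {g: len(h) for g, h in histories.items()}
    if target_n == "min-group":
        n = min(sizes.values())
    else:
        n = int(target_n)
        too_small = [g for g, s in sizes.items() if s < n]
        if too_small:
            raise ValueError(f"target_n={n} exceeds group size for {too_small}")
    out = {}
    for gi, label in enumerate(sorted(histories)):
        members = histories[label]
        if len(members) == n:
            out[label] = list(members)
            continue
        rng = np.random.default_rng(np.random.SeedSequence([seed, gi]))
        idx = rng.choice(len(members), size=n, replace=False)
        out[label] = [members[i] for i in sorted(idx)]
    return out


def summarize(
    histories: dict[str, list[PatientHistory]],
    records: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-group cohort summary: patients, mean visits, mean distinct
    diagnoses, mean age per visit, plus categorical proportions (payer,
    region, ...) when the visit table is supplied."""
    rows = []
    for label in sorted(histories):
        hs = histories[label]
        ages = [a for h in hs for a in h.ages]
        rows.append(
            {
                "group": label,
                "n_patients": len(hs),
                "mean_visits_per_patient": float(np.mean([h.n_visits for h in hs])),
                "mean_distinct_diagnoses": float(np.mean([len(h.codes) for h in hs])),
                "mean_age_per_visit": float(np.mean(ages)) if ages else float("nan"),
            }
        )
    table = pd.DataFrame(rows).set_index("group")
    if records is not None:
        for col in ("payer", "region", "bedsize", "visit_type"):
            if col not in records.columns:
                continue
            per_visit = records.drop_duplicates(["patient_id", "visit_id"])
            props = per_visit.groupby("race")[col].value_counts(normalize=True).unstack(fill_value=0.0)
            props.columns = [f"prop_{col}_{c}" for c in props.columns]
            table = table.join(props, how="left")
    return table


def write_histories(histories: dict[str, list[PatientHistory]], path) -> None:
    """Write per-group histories: patient_id, group, ';'-joined sorted codes."""
    rows = [
        (h.patient_id, label, ";".join(sorted(h.codes)), h.n_visits)
        for label in sorted(histories)
        for h in histories[label]
    ]
    pd.DataFrame(rows, columns=["patient_id", "group", "codes", "n_visits"]).to_csv(path, index=False)


def read_histories(path) -> dict[str, list[PatientHistory]]:
    df = pd.read_csv(path, dtype=str)
    out: dict[str, list[PatientHistory]] = {}
    for r in df.itertuples(index=False):
        h = PatientHistory(
            patient_id=str(r.patient_id),
            group_label=str(r.group),
            codes=frozenset(str(r.codes).split(";")),
            n_visits=int(r.n_visits) if hasattr(r, "n_visits") and str(r.n_visits) != "nan" else 0,
        )
        out.setdefault(h.group_label, []).append(h)
    return out
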