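"""Cleaning rules, race resolution, lifetime histories, matched sampling."""

import numpy as np
import pandas as pd
import pytest

from comorbnet import ingest as ing
from comorbnet.synthetic_emr import GroupSpec, ScenarioConfig, generate_patients


def _records(rows):
    return pd.DataFrame(
        rows, columns=["patient_id", "visit_id", "visit_index", "race", "age_at_visit", "icd9_code"]
    )


# ---------------------------------------------------------------------------
# clean_visits
# ---------------------------------------------------------------------------

def test_symptom_only_visit_removed_mixed_visit_trimmed():
    df = _records(
        [
            ("p1", "v1", 1, "White", 40, "780"),      # symptom-only visit: gone
            ("p2", "v2", 1, "White", 40, "780"),      # mixed: 780 dropped,
            ("p2", "v2", 1, "White", 40, "250"),      #   250 retained
            ("p3", "v3", 1, "White", 40, "401"),      # untouched
        ]
    )
    out, report = ing.clean_visits(df)
    assert set(zip(out.patient_id, out.code3)) == {("p2", "250"), ("p3", "401")}
    assert report.dropped["visit_symptom_only"] == 1
    assert report.dropped["code_symptom_on_mixed_visit"] == 1
    assert report.input_rows == report.retained_rows + report.dropped_rows


def test_ve_and_malformed_codes_dropped_and_counted():
    df = _records(
        [
            ("p1", "v1", 1, "W", 40, "V27.0"),
            ("p1", "v1", 1, "W", 40, "E812"),
            ("p1", "v1", 1, "W", 40, "garbage"),
            ("p1", "v1", 1, "W", 40, "250.00"),
        ]
    )
    out, report = ing.clean_visits(df)
    assert list(out.code3) == ["250"]
    assert report.dropped["code_ve_supplementary"] == 2
    assert report.dropped["code_malformed"] == 1


# ---------------------------------------------------------------------------
# resolve_race
# ---------------------------------------------------------------------------

def test_race_resolution_rules():
    df = _records(
        [
            ("keep", "v1", 1, "White", 40, "250"),
            ("keep", "v2", 2, "White", 41, "401"),
            ("case", "v3", 1, "white", 40, "250"),   # case-insensitive match
            ("case", "v4", 2, "White", 41, "401"),
            ("mixed", "v5", 1, "White", 40, "250"),
            ("mixed", "v6", 2, "Asian", 41, "401"),  # inconsistent: dropped
            ("norace", "v7", 1, None, 40, "250"),    # missing everywhere: dropped
            ("partial", "v8", 1, None, 40, "250"),   # one label + missing: kept
            ("partial", "v9", 2, "Asian", 41, "401"),
        ]
    )
    out, report = ing.resolve_race(df)
    assert set(out.patient_id) == {"keep", "case", "partial"}
    assert report.dropped["patient_inconsistent_race"] == 2  # rows of 'mixed'
    assert report.dropped["patient_missing_race"] == 1
    # missing entries filled with the patient's unique label
    assert set(out.loc[out.patient_id == "partial", "race"]) == {"Asian"}
    assert report.input_rows == report.retained_rows + report.dropped_rows


# ---------------------------------------------------------------------------
# build_histories
# ---------------------------------------------------------------------------

def test_lifetime_codes_deduplicated_across_visits():
    df = _records(
        [
            ("p1", "v1", 1, "White", 40, "401.1"),
            ("p1", "v2", 2, "White", 41, "401.9"),
            ("p1", "v2", 2, "White", 41, "250.00"),
            ("p2", "v3", 1, "White", 50, "250"),
        ]
    )
    cleaned, _ = ing.clean_visits(df)
    resolved, _ = ing.resolve_race(cleaned)
    hist = ing.build_histories(resolved)
    by_id = {h.patient_id: h for h in hist["White"]}
    assert by_id["p1"].codes == frozenset({"401", "250"})
    assert by_id["p1"].n_visits == 2
    assert by_id["p2"].codes == frozenset({"250"})
    union = set().union(*(h.codes for h in hist["White"]))
    assert union == {"401", "250"}


def test_toy_file_hand_enumeration(toy_visits_path):
    records = ing.read_visits(toy_visits_path)
    report = ing.DropReport()
    cleaned, report = ing.clean_visits(records, report)
    resolved, report = ing.resolve_race(cleaned, report)
    hist = ing.build_histories(resolved)
    assert {g: len(h) for g, h in hist.items()} == {"White": 4, "Asian": 3}
    white = {h.patient_id: h.codes for h in hist["White"]}
    assert white == {
        "P1": frozenset({"250", "401"}),
        "P2": frozenset({"250"}),
        "P3": frozenset({"250"}),
        "P10": frozenset({"493"}),
    }
    union = {c for hs in hist.values() for h in hs for c in h.codes}
    assert union == {"250", "401", "493", "296", "311", "585"}
    d = report.to_dict()
    assert d["input_rows"] == 20
    assert d["retained_rows"] == 12
    assert d["dropped_by_reason"] == {
        "code_symptom_on_mixed_visit": 1,
        "code_ve_supplementary": 1,
        "patient_inconsistent_race": 2,
        "patient_missing_race": 2,
        "visit_symptom_only": 2,
    }


def test_build_histories_idempotent_on_flattened_output():
    df = _records(
        [
            ("p1", "v1", 1, "White", 40, "401"),
            ("p1", "v2", 2, "White", 41, "250"),
            ("p2", "v3", 1, "Asian", 50, "585"),
        ]
    )
    cleaned, _ = ing.clean_visits(df)
    resolved, _ = ing.resolve_race(cleaned)
    hist = ing.build_histories(resolved)
    flat = pd.DataFrame(
        [
            (h.patient_id, f"{h.patient_id}-flat", 1, h.group_label, 40.0, c, c)
            for hs in hist.values()
            for h in hs
            for c in sorted(h.codes)
        ],
        columns=["patient_id", "visit_id", "visit_index", "race", "age_at_visit", "icd9_code", "code3"],
    )
    again = ing.build_histories(flat)
    assert {
        g: {h.patient_id: h.codes for h in hs} for g, hs in again.items()
    } == {g: {h.patient_id: h.codes for h in hs} for g, hs in hist.items()}


def test_histories_roundtrip_file(tmp_path, toy_visits_path):
    records = ing.read_visits(toy_visits_path)
    cleaned, _ = ing.clean_visits(records)
    resolved, _ = ing.resolve_race(cleaned)
    hist = ing.build_histories(resolved)
    path = tmp_path / "histories.csv"
    ing.write_histories(hist, path)
    back = ing.read_histories(path)
    assert {g: {h.patient_id: h.codes for h in hs} for g, hs in back.items()} == {
        g: {h.patient_id: h.codes for h in hs} for g, hs in hist.items()
    }


# ---------------------------------------------------------------------------
# equal_sample
# ---------------------------------------------------------------------------

def _fake_histories(sizes):
    return {
        g: [
            ing.PatientHistory(f"{g}-{i}", g, frozenset({"250"} if i % 3 else {"250", "401"}))
            for i in range(n)
        ]
        for g, n in sizes.items()
    }


def test_equal_sample_min_group_and_determinism():
    hist = _fake_histories({"A": 1000, "B": 300})
    sampled = ing.equal_sample(hist, "min-group", seed=5)
    assert {g: len(h) for g, h in sampled.items()} == {"A": 300, "B": 300}
    # smallest group passes through whole
    assert [h.patient_id for h in sampled["B"]] == [h.patient_id for h in hist["B"]]
    sampled2 = ing.equal_sample(hist, "min-group", seed=5)
    assert [h.patient_id for h in sampled2["A"]] == [h.patient_id for h in sampled["A"]]
    sampled3 = ing.equal_sample(hist, "min-group", seed=6)
    assert [h.patient_id for h in sampled3["A"]] != [h.patient_id for h in sampled["A"]]


def test_equal_sample_target_too_large_names_group():
    hist = _fake_histories({"A": 1000, "B": 300})
    with pytest.raises(ValueError, match="B"):
        ing.equal_sample(hist, 500, seed=0)


def test_equal_sample_preserves_prevalence_hypergeometrically():
    """Sampled prevalence of a common code stays within 3 hypergeometric SE
    of the full group's in ~all of 100 seeds."""
    N, n = 1000, 200
    hist = _fake_histories({"A": N, "B": n})
    p_full = np.mean([("401" in h.codes) for h in hist["A"]])
    K = int(round(p_full * N))
    se = np.sqrt(n * p_full * (1 - p_full) * (N - n) / (N - 1)) / n
    hits = 0
    for seed in range(100):
        s = ing.equal_sample(hist, "min-group", seed=seed)
        p_hat = np.mean([("401" in h.codes) for h in s["A"]])
        hits += abs(p_hat - p_full) <= 3 * se
    assert hits >= 96


# ---------------------------------------------------------------------------
# summarize
# ---------------------------------------------------------------------------

def test_summary_means_on_tiny_groups():
    hist = {
        "G": [
            ing.PatientHistory("a", "G", frozenset("abcde"), n_visits=3, ages=(40.0, 41.0, 42.0)),
            ing.PatientHistory("b", "G", frozenset("abcdefg"), n_visits=5, ages=(50.0,) * 5),
        ]
    }
    s = ing.summarize(hist)
    assert s.loc["G", "mean_visits_per_patient"] == 4.0
    assert s.loc["G", "mean_distinct_diagnoses"] == 6.0
    assert s.loc["G", "n_patients"] == 2


def test_summary_recovers_generator_visit_mean():
    """With ample diagnoses per patient, post-cleaning mean visits matches
    the generator's visit_count_mean within sampling error."""
    n, vmean = 3000, 4.8
    codes = [f"{c:03d}" for c in range(1, 251)]
    g = GroupSpec("G", n, vmean, 45.0, 15.0, {c: 0.1 for c in codes})
    cfg = ScenarioConfig(code_universe=codes, groups=[g], seed=13)
    df = generate_patients(cfg)
    cleaned, _ = ing.clean_visits(df)
    resolved, _ = ing.resolve_race(cleaned)
    s = ing.summarize(ing.build_histories(resolved))
    se = np.sqrt(vmean - 1) / np.sqrt(n)  # sd of 1+Poisson(vmean-1)
    assert s.loc["G", "mean_visits_per_patient"] == pytest.approx(vmean, abs=2.5 * se)
    assert s.loc["G", "mean_distinct_diagnoses"] == pytest.approx(25.0, rel=0.05)
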