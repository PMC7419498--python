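from pathlib import Path

import numpy as np
import pytest

from comorbnet.ingest import PatientHistory

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture
def toy_visits_path() -> Path:
    """Hand-enumerable 2-group visit file (20 rows, 10 patients).

    Ground truth: after cleaning and race resolution, White retains patients
    P1 {250,401}, P2 {250}, P3 {250}, P10 {493} and Asian retains P6
    {296,311}, P7 {585}, P8 {401}.  Dropped: P4 (inconsistent race), P5
    (missing race), P9 (symptom-only history); 1 V-code row, 3 symptom rows.
    """
    return DATA_DIR / "toy_visits.csv"


def random_histories(
    n_patients: int,
    codes: list[str],
    seed: int,
    group_label: str = "G",
    mean_codes: float = 4.0,
) -> list[PatientHistory]:
    """Random lifetime histories with independent code membership."""
    rng = np.random.default_rng(seed)
    p = min(mean_codes / len(codes), 0.9)
    out = []
    for i in range(n_patients):
        mask = rng.random(len(codes)) < p
        if not mask.any():
            mask[rng.integers(len(codes))] = True
        out.append(
            PatientHistory(
                patient_id=f"{group_label}-{i}",
                group_label=group_label,
                codes=frozenset(c for c, m in zip(codes, mask) if m),
                n_visits=1 + int(rng.poisson(2)),
            )
        )
    return out
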