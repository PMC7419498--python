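"""Synthetic multi-group EMR visit generator with planted comorbidity structure.

Real hospital EMR extracts of the kind this pipeline targets are under
restricted licenses, so every downstream stage is exercised on synthetic
visit-level records whose ground truth is known exactly.  The generator
works in two layers:

1. **Lifetime layer** (:func:`sample_lifetime_sets`): each patient's lifetime
   set of 3-digit diagnoses is drawn directly.  Codes not involved in a
   planted pair are independent Bernoulli draws at their base prevalence.
   Each planted pair ``(a, b, target_joint_prob)`` is drawn from the
   four-point coupling on {both, a-only, b-only, neither} whose joint
   probability equals ``target_joint_prob`` *exactly* and whose marginals
   equal the base prevalences exactly, so the generative Salton cosine index
   of the pair is ``target_joint_prob / sqrt(p_a * p_b)`` in closed form.
   Patients who draw an empty set are redrawn (every retained EMR patient
   has at least one diagnosis); this conditioning scales all event
   probabilities by the same constant and therefore leaves every pair's SCI
   unchanged.

2. **Visit layer** (:func:`generate_patients`): lifetime diagnoses are
   scattered over ``1 + Poisson(visit_count_mean - 1)`` visits such that
   every visit records at least one code (visits beyond the number of
   distinct diagnoses are filled with a general-symptom code, 780-799, as
   real EMRs record symptom-only encounters); chronic codes are re-recorded
   at every visit after their first appearance; recorded code strings
   randomly carry 4th/5th digits to exercise 3-digit truncation.

Planted pairs within a group must use pairwise-disjoint codes; this keeps
all marginals exact.  Higher-order (3+ way) planted dependence is out of
scope.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .icd9 import chapter_of

__all__ = [
    "GroupSpec",
    "ScenarioConfig",
    "ScenarioError",
    "generate_patients",
    "five_group_scenario",
    "plant_block",
    "sample_lifetime_sets",
    "two_group_block_scenario",
    "write_visits_csv",
]

VISIT_COLUMNS = [
    "patient_id",
    "visit_id",
    "visit_index",
    "race",
    "age_at_visit",
    "icd9_code",
    "payer",
    "region",
]

_PAYERS = ("Medicare", "Medicaid", "Private", "Self-pay")
_REGIONS = ("Northeast", "Midwest", "South", "West")


class ScenarioError(ValueError):
    """Invalid or infeasible scenario configuration."""


@dataclass
class GroupSpec:
    """One population group: size, visit behaviour and disease structure.

    ``base_prevalence`` maps 3-digit codes to lifetime marginal
    probabilities; ``planted_pairs`` is a list of ``(code_a, code_b,
    target_joint_prob)`` with exact joint probability guarantees (see module
    docstring).  ``seed`` optionally pins this group's random stream so two
    groups with identical specs and the same seed produce identical
    co-occurrence tables.
    """

    group_label: str
    n_patients: int
    visit_count_mean: float
    age_mean: float
    age_sd: float
    base_prevalence: dict[str, float]
    planted_pairs: list[tuple[str, str, float]] = field(default_factory=list)
    seed: int | None = None

    def validate(self, code_universe: list[str]) -> None:
        universe = set(code_universe)
        if self.n_patients <= 0:
            raise ScenarioError(f"group {self.group_label!r}: n_patients must be positive")
        if self.visit_count_mean < 1.0:
            raise ScenarioError(f"group {self.group_label!r}: visit_count_mean must be >= 1")
        if not set(self.base_prevalence) <= universe:
            extra = sorted(set(self.base_prevalence) - universe)[:5]
            raise ScenarioError(f"group {self.group_label!r}: codes outside universe: {extra}")
        if sum(self.base_prevalence.values()) <= 0:
            raise ScenarioError(f"group {self.group_label!r}: all prevalences are zero")
        seen: set[str] = set()
        for a, b, pj in self.planted_pairs:
            pa = self.base_prevalence.get(a, 0.0)
            pb = self.base_prevalence.get(b, 0.0)
            if pj > min(pa, pb) + 1e-12:
                raise ScenarioError(
                    f"group {self.group_label!r}: planted pair ({a},{b}) infeasible: "
                    f"joint {pj} exceeds a marginal ({pa}, {pb})"
                )
            if pa + pb - pj > 1.0 + 1e-12:
                raise ScenarioError(
                    f"group {self.group_label!r}: planted pair ({a},{b}) infeasible: "
                    f"p_a + p_b - p_joint > 1"
                )
            if a in seen or b in seen or a == b:
                raise ScenarioError(
                    f"group {self.group_label!r}: planted pairs must use disjoint codes; "
                    f"({a},{b}) reuses a code"
                )
            seen.update((a, b))


@dataclass
class ScenarioConfig:
    """A full synthetic scenario: code universe, groups, chronic codes, seed."""

    code_universe: list[str]
    groups: list[GroupSpec]
    chronic_codes: set[str] = field(default_factory=set)
    seed: int = 0

    def validate(self) -> None:
        if not self.code_universe:
            raise ScenarioError("code_universe is empty")
        if len(set(self.code_universe)) != len(self.code_universe):
            raise ScenarioError("code_universe has duplicates")
        labels = [g.group_label for g in self.groups]
        if len(set(labels)) != len(labels):
            raise ScenarioError("group labels must be unique")
        if not set(self.chronic_codes) <= set(self.code_universe):
            raise ScenarioError("chronic_codes must be a subset of code_universe")
        for g in self.groups:
            g.validate(self.code_universe)

    def group_rng(self, group_index: int) -> np.random.Generator:
        g = self.groups[group_index]
        if g.seed is not None:
            return np.random.default_rng(np.random.SeedSequence(g.seed))
        return np.random.default_rng(np.random.SeedSequence([self.seed, group_index]))

    def to_dict(self) -> dict:
        return {
            "code_universe": list(self.code_universe),
            "chronic_codes": sorted(self.chronic_codes),
            "seed": self.seed,
            "groups": [
                {
                    "group_label": g.group_label,
                    "n_patients": g.n_patients,
                    "visit_count_mean": g.visit_count_mean,
                    "age_mean": g.age_mean,
                    "age_sd": g.age_sd,
                    "base_prevalence": g.base_prevalence,
                    "planted_pairs": [list(p) for p in g.planted_pairs],
                    "seed": g.seed,
                }
                for g in self.groups
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioConfig":
        groups = [
            GroupSpec(
                group_label=g["group_label"],
                n_patients=int(g["n_patients"]),
                visit_count_mean=float(g["visit_count_mean"]),
                age_mean=float(g["age_mean"]),
                age_sd=float(g["age_sd"]),
                base_prevalence={str(k): float(v) for k, v in g["base_prevalence"].items()},
                planted_pairs=[(str(a), str(b), float(p)) for a, b, p in g.get("planted_pairs", [])],
                seed=g.get("seed"),
            )
            for g in d["groups"]
        ]
        return cls(
            code_universe=[str(c) for c in d["code_universe"]],
            groups=groups,
            chronic_codes=set(map(str, d.get("chronic_codes", []))),
            seed=int(d.get("seed", 0)),
        )

    @classmethod
    def from_file(cls, path) -> "ScenarioConfig":
        text = open(path).read()
        if str(path).endswith((".yml", ".yaml")):
            import yaml

            return cls.from_dict(yaml.safe_load(text))
        return cls.from_dict(json.loads(text))


# ---------------------------------------------------------------------------
# Lifetime layer
# ---------------------------------------------------------------------------

def sample_lifetime_sets(
    group: GroupSpec,
    code_universe: list[str],
    rng: np.random.Generator,
    n_patients: int | None = None,
) -> np.ndarray:
    """Draw the boolean lifetime-diagnosis matrix (patients x codes).

    Returns an array of shape ``(n_patients, len(code_universe))``; column
    order follows ``code_universe``.  Rows are guaranteed non-empty
    (rejection resampling).
    """
    group.validate(code_universe)
    n = group.n_patients if n_patients is None else int(n_patients)
    k = len(code_universe)
    col = {c: i for i, c in enumerate(code_universe)}
    p = np.array([group.base_prevalence.get(c, 0.0) for c in code_universe])
    planted_idx = {col[a] for a, b, _ in group.planted_pairs} | {
        col[b] for a, b, _ in group.planted_pairs
    }
    indep = np.array([i for i in range(k) if i not in planted_idx], dtype=np.intp)

    def draw(m: int) -> np.ndarray:
        X = np.zeros((m, k), dtype=bool)
        # chunk the independent columns to bound transient memory at large n
        for start in range(0, indep.size, 256):
            blk = indep[start : start + 256]
            X[:, blk] = rng.random((m, blk.size)) < p[blk]
        for a, b, pj in group.planted_pairs:
            ia, ib = col[a], col[b]
            qa, qb = p[ia] - pj, p[ib] - pj
            u = rng.random(m)
            X[:, ia] = u < pj + qa
            X[:, ib] = (u < pj) | ((u >= pj + qa) & (u < pj + qa + qb))
        return X

    X = draw(n)
    while True:
        empty = ~X.any(axis=1)
        if not empty.any():
            return X
        X[empty] = draw(int(empty.sum()))


# ---------------------------------------------------------------------------
# Visit layer
# ---------------------------------------------------------------------------

def _patient_visit_rows(
    pid: str,
    label: str,
    codes: np.ndarray,
    n_visits: int,
    age: float,
    chronic: set[str],
    payer: str,
    region: str,
    rng: np.random.Generator,
    out: list,
) -> None:
    k = codes.size
    # coverage-first assignment: the first min(k, n_visits) visits each get
    # one distinct code; remaining codes land on uniform visits
    order = rng.permutation(k)
    assignment: list[list[str]] = [[] for _ in range(n_visits)]
    n_cover = min(k, n_visits)
    for j in range(n_cover):
        assignment[j].append(codes[order[j]])
    if k > n_visits:
        extra_visits = rng.integers(0, n_visits, size=k - n_visits)
        for j, idx in zip(extra_visits, order[n_visits:]):
            assignment[j].append(codes[idx])
    # surplus visits (more visits than distinct diagnoses) record a
    # general-symptom code only, as real encounters do
    for j in range(n_cover, n_visits):
        assignment[j].append(f"{rng.integers(780, 800):03d}")
    # chronic codes re-recorded on every visit after first appearance
    first_seen = {}
    for j, vcodes in enumerate(assignment):
        for c in vcodes:
            if c in chronic and c not in first_seen:
                first_seen[c] = j
    for c, j0 in first_seen.items():
        for j in range(j0 + 1, n_visits):
            if c not in assignment[j]:
                assignment[j].append(c)
    for j, vcodes in enumerate(assignment):
        vid = f"{pid}-v{j + 1}"
        for c in vcodes:
            # half the recorded strings carry a 4th/5th digit subdivision
            if rng.random() < 0.5:
                raw = f"{c}.{rng.integers(0, 10)}" if rng.random() < 0.7 else f"{c}.{rng.integers(0, 100):02d}"
            else:
                raw = c
            out.append((pid, vid, j + 1, label, age, raw, payer, region))


def generate_patients(config: ScenarioConfig) -> pd.DataFrame:
    """Materialise the scenario as visit-level records (one row per
    patient-visit-diagnosis), deterministically under the scenario seed."""
    config.validate()
    rows: list = []
    for gi, group in enumerate(config.groups):
        rng = config.group_rng(gi)
        X = sample_lifetime_sets(group, config.code_universe, rng)
        n = group.n_patients
        n_visits = 1 + rng.poisson(group.visit_count_mean - 1.0, size=n)
        ages = np.clip(rng.normal(group.age_mean, group.age_sd, size=n), 0.0, 110.0).round(1)
        payers = rng.choice(_PAYERS, size=n)
        regions = rng.choice(_REGIONS, size=n)
        codes_arr = np.asarray(config.code_universe, dtype=object)
        for i in range(n):
            pid = f"{group.group_label}-{i:07d}"
            codes = codes_arr[X[i]]
            _patient_visit_rows(
                pid,
                group.group_label,
                codes,
                int(n_visits[i]),
                float(ages[i]),
                config.chronic_codes,
                str(payers[i]),
                str(regions[i]),
                rng,
                rows,
            )
    return pd.DataFrame(rows, columns=VISIT_COLUMNS)


def write_visits_csv(config: ScenarioConfig, path, sep: str = ",") -> pd.DataFrame:
    """Generate and write the visit table; returns the DataFrame written."""
    df = generate_patients(config)
    df.to_csv(path, sep=sep, index=False)
    return df


# ---------------------------------------------------------------------------
# Scenario builders
# ---------------------------------------------------------------------------

def default_code_universe() -> list[str]:
    """~900 three-digit codes spanning all 18 chapters (001-999, every code
    not ending in 9, giving 899 codes)."""
    return [f"{c:03d}" for c in range(1, 1000) if c % 10 != 9]


def plant_block(
    chapter_a: int,
    chapter_b: int,
    n_pairs: int,
    sci: float,
    prevalence: float,
    code_universe: list[str],
    used: set[str],
) -> tuple[list[tuple[str, str, float]], dict[str, float]]:
    """Build ``n_pairs`` planted pairs between two chapters with a common
    generative SCI.

    Each pair uses fresh codes (not in ``used``) from the two chapter
    ranges, both at ``prevalence``, with joint probability
    ``sci * prevalence`` so the pair's generative Salton cosine index is
    exactly ``sci``.  Returns the pair list and the prevalence overrides.
    """
    pool_a = [c for c in code_universe if chapter_of(c) == chapter_a and c not in used]
    pool_b = [c for c in code_universe if chapter_of(c) == chapter_b and c not in used]
    if chapter_a == chapter_b:
        if len(pool_a) < 2 * n_pairs:
            raise ScenarioError(f"chapter {chapter_a}: not enough free codes for {n_pairs} pairs")
        pool_b = pool_a[n_pairs : 2 * n_pairs]
        pool_a = pool_a[:n_pairs]
    if len(pool_a) < n_pairs or len(pool_b) < n_pairs:
        raise ScenarioError(
            f"chapters ({chapter_a},{chapter_b}): not enough free codes for {n_pairs} pairs"
        )
    pairs = []
    prev = {}
    for a, b in zip(pool_a[:n_pairs], pool_b[:n_pairs]):
        pairs.append((a, b, sci * prevalence))
        prev[a] = prevalence
        prev[b] = prevalence
        used.update((a, b))
    return pairs, prev


def _base_profile(
    code_universe: list[str],
    mean_diagnoses: float,
    rng: np.random.Generator,
    cap: float = 0.03,
) -> dict[str, float]:
    """Heavy-tailed per-code prevalence profile scaled to a target mean
    number of distinct lifetime diagnoses per patient.

    Prevalences are capped (3% by default) and the remaining mass is
    rescaled onto the uncapped codes.  Real EMRs carry a handful of far more
    prevalent categories; the cap keeps the independence background's cosine
    index well below the standard 0.04 cutoff, so planted-structure and
    stability tests measure the method rather than background crossings.
    """
    raw = rng.lognormal(mean=0.0, sigma=0.9, size=len(code_universe))
    p = raw / raw.sum() * mean_diagnoses
    for _ in range(4):
        over = p > cap
        deficit = float((p[over] - cap).sum())
        p[over] = cap
        if deficit <= 1e-12 or over.all():
            break
        p[~over] *= 1.0 + deficit / p[~over].sum()
    return {c: float(v) for c, v in zip(code_universe, p)}


#: chronic conditions re-recorded across visits (diabetes, hypertension,
#: hyperlipidaemia, depression, ischaemic heart disease, asthma, CKD, OA)
DEFAULT_CHRONIC = {"250", "401", "272", "296", "414", "493", "585", "715"}


def five_group_scenario(scale: float = 1.0, seed: int = 0) -> ScenarioConfig:
    """Five unequal population groups emulating a large multi-race EMR.

    Group sizes, mean visits per patient, mean distinct diagnoses and mean
    ages follow the published summary statistics of the study population
    this generator emulates (scaled down in size by ``scale``); each group
    additionally carries planted chapter-block comorbidity structure of
    group-specific strength, strongest for the African American group and
    weakest for the Hispanic group, mirroring the qualitative ordering of
    the real networks.
    """
    universe = default_code_universe()
    profile_rng = np.random.default_rng(np.random.SeedSequence([seed, 9001]))
    # (label, n, visit mean, mean distinct diagnoses, age mean, age sd, blocks)
    # blocks: (chapter_a, chapter_b, n_pairs, sci)
    spec_rows = [
        ("AfricanAmerican", 20000, 4.83, 5.86, 39.93, 19.0,
         [(1, 9, 35, 0.32), (1, 8, 30, 0.35), (1, 11, 25, 0.30), (8, 10, 30, 0.30)]),
        ("White", 30000, 4.694, 5.71, 50.45, 20.0,
         [(5, 9, 25, 0.45), (8, 10, 30, 0.28)]),
        ("Hispanic", 8000, 2.571, 3.32, 28.4, 16.0,
         [(12, 11, 8, 0.18)]),
        ("Asian", 7000, 3.129, 3.78, 43.7, 19.0,
         [(8, 10, 15, 0.25)]),
        ("NativeAmerican", 5000, 3.572, 4.81, 38.55, 18.0,
         [(3, 8, 25, 0.42), (8, 10, 20, 0.25)]),
    ]
    groups = []
    for label, n, vmean, dmean, amean, asd, blocks in spec_rows:
        prev = _base_profile(universe, dmean, profile_rng)
        used: set[str] = set()
        pairs: list[tuple[str, str, float]] = []
        for ca, cb, npairs, sci in blocks:
            blk_pairs, blk_prev = plant_block(ca, cb, npairs, sci, 0.02, universe, used)
            pairs.extend(blk_pairs)
            prev.update(blk_prev)
        groups.append(
            GroupSpec(
                group_label=label,
                n_patients=max(2, int(round(n * scale))),
                visit_count_mean=vmean,
                age_mean=amean,
                age_sd=asd,
                base_prevalence=prev,
                planted_pairs=pairs,
            )
        )
    return ScenarioConfig(
        code_universe=universe,
        groups=groups,
        chronic_codes=set(DEFAULT_CHRONIC) & set(universe),
        seed=seed,
    )


def stability_scenario(seed: int = 0, n_patients: int = 100_000) -> ScenarioConfig:
    """Single-group cohort for subsampling-stability experiments.

    Network stability under subsampling requires every pair's co-occurrence
    threshold ceil(0.04 * sqrt(c_i * c_j)) to stay several Poisson standard
    deviations above the independence background at the *smaller* scale.
    Codes that are too rare cross the cutoff with 2-3 chance co-occurrences;
    codes that are too common have chance co-occurrence rates n*p^2 growing
    faster than the threshold 0.04*n*p.  At a 20%-of-1e5 subsample the
    resolvable band is roughly p in [0.009, 0.011], so this cohort is a
    focused panel: 150 codes at a uniform 0.9% prevalence, 60 of the pairs
    planted with generative SCI 0.3 — far above the cutoff at both scales —
    and the rest an independence background whose chance crossings are rare
    enough to leave the two networks' densities statistically equal.
    """
    universe = [f"{c:03d}" for c in range(1, 1000) if c % 4 == 1][:150]
    prev = {c: 0.009 for c in universe}
    rng_order = np.random.default_rng(np.random.SeedSequence([seed, 9003]))
    order = rng_order.permutation(len(universe))
    pairs = []
    for k in range(60):
        a, b = universe[order[2 * k]], universe[order[2 * k + 1]]
        pairs.append((a, b, 0.3 * 0.009))
    group = GroupSpec(
        group_label="Stability",
        n_patients=n_patients,
        visit_count_mean=3.5,
        age_mean=45.0,
        age_sd=18.0,
        base_prevalence=prev,
        planted_pairs=pairs,
    )
    return ScenarioConfig(code_universe=universe, groups=[group], seed=seed)


def two_group_block_scenario(
    seed: int = 0,
    n_patients: int = 20000,
    n_pairs: int = 50,
    sci: float = 0.25,
    prevalence: float = 0.012,
    chapters: tuple[int, int] = (1, 9),
) -> ScenarioConfig:
    """Two equal groups; only group A carries a planted chapter-pair block.

    Defaults give group A an aggregate organ-level weight of about
    ``n_pairs * sci`` = 12.5 on the planted chapter pair — above the
    standard highlight threshold of 10 — while group B sees only the
    independence background, far below it.
    """
    universe = default_code_universe()
    profile_rng = np.random.default_rng(np.random.SeedSequence([seed, 9002]))
    prev = _base_profile(universe, 9.0, profile_rng)
    used: set[str] = set()
    pairs, blk_prev = plant_block(chapters[0], chapters[1], n_pairs, sci, prevalence, universe, used)
    prev_a = dict(prev)
    prev_a.update(blk_prev)
    prev_b = dict(prev)
    prev_b.update({c: prevalence for c in blk_prev})  # same marginals, no coupling
    mk = lambda label, p, pp: GroupSpec(
        group_label=label,
        n_patients=n_patients,
        visit_count_mean=3.5,
        age_mean=45.0,
        age_sd=18.0,
        base_prevalence=p,
        planted_pairs=pp,
    )
    return ScenarioConfig(
        code_universe=universe,
        groups=[mk("GroupA", prev_a, pairs), mk("GroupB", prev_b, [])],
        chronic_codes=set(DEFAULT_CHRONIC) & set(universe),
        seed=seed,
    )
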