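"""Pairwise lifetime comorbidity statistics and thresholded networks.

For each unordered pair of 3-digit diagnoses (i, j) within one population
group of n patients, with lifetime prevalence counts c_i and c_j and
co-occurrence count c_ij (patients whose lifetime history contains both):

* the edge weight is the **Salton cosine index**,

      SCI_ij = c_ij / sqrt(c_i * c_j),

  the cosine between the two binary indicator vectors.  SCI is invariant
  to uniform replication of the sample — replicating every patient k times
  scales c_i, c_j, c_ij by k and leaves SCI unchanged — which is what makes
  it suitable for comparing groups of very unequal size;

* the **phi coefficient** (Pearson correlation of the two binary
  indicators),

      phi_ij = (n*c_ij - c_i*c_j) / sqrt(c_i*c_j*(n-c_i)*(n-c_j)),

  is used only to calibrate the SCI cutoff: phi's chi-squared significance
  (n*phi^2 against chi2 with 1 df) *does* grow with n, so it cannot serve
  as a size-comparable edge weight, but on the pooled dataset the number of
  phi-significant pairs at the 1% level pins down an SCI cutoff — the value
  at which the number of pairs with SCI >= cutoff equals the number of
  significantly correlated pairs.

Per group, pairs co-occurring less often than the average co-occurring pair
are removed (chance connections), then the cutoff is applied; surviving
pairs are the edges of an undirected weighted network whose node set is all
diagnoses observed in the group (isolated diagnosed codes are tracked).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats

from .ingest import PatientHistory

__all__ = [
    "PAIR_COLUMNS",
    "MultimorbidityNetwork",
    "build_network",
    "calibrate_cutoff",
    "count_pairs",
    "filter_below_average",
    "lifetime_matrix",
    "pair_stats",
    "pair_stats_from_matrix",
    "phi",
    "phi_significant",
    "sci",
]

#: columns of a pair-statistics table (one row per unordered pair, code_i < code_j)
PAIR_COLUMNS = ["code_i", "code_j", "c_i", "c_j", "c_ij", "n", "sci", "phi", "significant"]


# ---------------------------------------------------------------------------
# Counting
# ---------------------------------------------------------------------------

def lifetime_matrix(histories: list[PatientHistory]) -> tuple[sp.csr_matrix, list[str]]:
    """Patients-by-codes binary incidence matrix (CSR) and the code order."""
    codes = sorted({c for h in histories for c in h.codes})
    col = {c: i for i, c in enumerate(codes)}
    indptr = [0]
    indices: list[int] = []
    for h in histories:
        indices.extend(sorted(col[c] for c in h.codes))
        indptr.append(len(indices))
    data = np.ones(len(indices), dtype=np.int64)
    X = sp.csr_matrix((data, indices, indptr), shape=(len(histories), len(codes)))
    return X, codes


def count_pairs(histories: list[PatientHistory]) -> tuple[dict[str, int], dict[tuple[str, str], int], int]:
    """Prevalence and co-occurrence counts over one group's histories.

    Returns ``(prevalence, cooccurrence, n)`` where ``prevalence[i]`` is the
    number of patients whose lifetime set contains code i and
    ``cooccurrence[(i, j)]`` (i < j, only pairs with at least one
    co-occurrence) the number containing both.
    """
    if not histories:
        raise ValueError("histories is empty")
    X, codes = lifetime_matrix(histories)
    prev_arr = np.asarray(X.sum(axis=0)).ravel()
    C = sp.triu(X.T @ X, k=1).tocoo()
    prevalence = {c: int(v) for c, v in zip(codes, prev_arr)}
    cooccurrence = {(codes[i], codes[j]): int(v) for i, j, v in zip(C.row, C.col, C.data)}
    return prevalence, cooccurrence, len(histories)


# ---------------------------------------------------------------------------
# Pair statistics
# ---------------------------------------------------------------------------

def sci(c_ij: int, c_i: int, c_j: int) -> float:
    """Salton cosine index c_ij / sqrt(c_i * c_j) for one pair."""
    if c_i <= 0 or c_j <= 0:
        raise ValueError("prevalence counts must be positive")
    if not 0 <= c_ij <= min(c_i, c_j):
        raise ValueError("require 0 <= c_ij <= min(c_i, c_j)")
    return c_ij / math.sqrt(c_i * c_j)


def phi(c_ij: int, c_i: int, c_j: int, n: int) -> float:
    """Phi coefficient (Pearson correlation of the binary indicators)."""
    if not (0 < c_i < n and 0 < c_j < n):
        raise ValueError("phi undefined for degenerate margins (c in {0, n})")
    num = n * c_ij - c_i * c_j
    den = math.sqrt(c_i * c_j * (n - c_i) * (n - c_j))
    return num / den


def phi_significant(phi_value: float, n: int, alpha: float = 0.01) -> bool:
    """Chi-squared test of association: n * phi^2 against chi2(1 df)."""
    if n < 2:
        raise ValueError("need n >= 2")
    return bool(n * phi_value**2 > stats.chi2.ppf(1.0 - alpha, df=1))


def pair_stats(
    prevalence: dict[str, int],
    cooccurrence: dict[tuple[str, str], int],
    n: int,
    alpha: float = 0.01,
) -> pd.DataFrame:
    """Assemble the pair table (SCI, phi, significance) from counts.

    Only pairs with c_ij >= 1 are tabulated — a pair that never co-occurs
    carries no comorbidity information.  Pairs with degenerate margins
    (a code present in every patient) get phi = NaN and are never flagged
    significant.
    """
    if not cooccurrence:
        return pd.DataFrame(columns=PAIR_COLUMNS)
    keys = sorted(cooccurrence)
    ci = np.array([prevalence[a] for a, _ in keys], dtype=np.float64)
    cj = np.array([prevalence[b] for _, b in keys], dtype=np.float64)
    cij = np.array([cooccurrence[k] for k in keys], dtype=np.float64)
    sci_v = cij / np.sqrt(ci * cj)
    with np.errstate(divide="ignore", invalid="ignore"):
        den = np.sqrt(ci * cj * (n - ci) * (n - cj))
        phi_v = np.where(den > 0, (n * cij - ci * cj) / np.where(den > 0, den, 1.0), np.nan)
    crit = stats.chi2.ppf(1.0 - alpha, df=1)
    sig = np.where(np.isnan(phi_v), False, n * np.nan_to_num(phi_v) ** 2 > crit)
    return pd.DataFrame(
        {
            "code_i": [a for a, _ in keys],
            "code_j": [b for _, b in keys],
            "c_i": ci.astype(np.int64),
            "c_j": cj.astype(np.int64),
            "c_ij": cij.astype(np.int64),
            "n": n,
            "sci": sci_v,
            "phi": phi_v,
            "significant": sig.astype(bool),
        }
    )


def pair_stats_from_matrix(
    X: sp.spmatrix | np.ndarray,
    codes: list[str],
    alpha: float = 0.01,
) -> pd.DataFrame:
    """Pair table straight from a patients-by-codes binary matrix.

    Vectorised path used for large simulated cohorts; identical output to
    :func:`pair_stats` after :func:`count_pairs`.
    """
    Xs = sp.csr_matrix(X, dtype=np.int64)
    n = Xs.shape[0]
    prev = np.asarray(Xs.sum(axis=0)).ravel()
    C = sp.triu(Xs.T @ Xs, k=1).tocoo()
    order = np.lexsort((C.col, C.row))
    i, j, cij = C.row[order], C.col[order], C.data[order].astype(np.float64)
    ci, cj = prev[i].astype(np.float64), prev[j].astype(np.float64)
    sci_v = cij / np.sqrt(ci * cj)
    with np.errstate(divide="ignore", invalid="ignore"):
        den = np.sqrt(ci * cj * (n - ci) * (n - cj))
        phi_v = np.where(den > 0, (n * cij - ci * cj) / np.where(den > 0, den, 1.0), np.nan)
    crit = stats.chi2.ppf(1.0 - alpha, df=1)
    sig = np.where(np.isnan(phi_v), False, n * np.nan_to_num(phi_v) ** 2 > crit)
    codes_arr = np.asarray(codes, dtype=object)
    df = pd.DataFrame(
        {
            "code_i": codes_arr[i],
            "code_j": codes_arr[j],
            "c_i": ci.astype(np.int64),
            "c_j": cj.astype(np.int64),
            "c_ij": cij.astype(np.int64),
            "n": n,
            "sci": sci_v,
            "phi": phi_v,
            "significant": sig.astype(bool),
        }
    )
    # code_i < code_j lexicographically: column order is sorted already
    return df


# ---------------------------------------------------------------------------
# Cutoff calibration and filters
# ---------------------------------------------------------------------------

def calibrate_cutoff(pairs: pd.DataFrame, alpha: float = 0.01) -> float:
    """SCI cutoff at which #{pairs with SCI >= cutoff} equals the number of
    phi-significant pairs at level ``alpha`` — the k-th largest SCI, where k
    is the significant-pair count.  Computed on the pooled (entire) dataset.

    When the k-th largest SCI value is exactly duplicated, no cutoff attains
    the equality; the k-th order statistic is still returned, giving
    #{SCI > cutoff} < k <= #{SCI >= cutoff} with the excess bounded by the
    number of exact ties at the boundary value.
    """
    k = int(pairs["significant"].sum())
    if k == 0:
        raise ValueError("no significant pairs; cannot calibrate cutoff")
    sci_sorted = np.sort(pairs["sci"].to_numpy())[::-1]
    return float(sci_sorted[k - 1])


def filter_below_average(pairs: pd.DataFrame) -> tuple[pd.DataFrame, float]:
    """Remove pairs co-occurring less than the group's average co-occurring
    pair (c_ij < mean of c_ij over pairs with c_ij >= 1); ties at the mean
    are retained.  Returns the filtered table and the mean used."""
    occurring = pairs[pairs["c_ij"] >= 1]
    if occurring.empty:
        return occurring.copy(), float("nan")
    mean_cij = float(occurring["c_ij"].mean())
    return occurring[occurring["c_ij"] >= mean_cij].copy(), mean_cij


# ---------------------------------------------------------------------------
# Network
# ---------------------------------------------------------------------------

@dataclass
class MultimorbidityNetwork:
    """Undirected SCI-weighted comorbidity network for one group.

    ``graph`` contains every diagnosed code as a node (so Table-2-style node
    counts include isolated diagnoses); edges carry the ``sci`` weight plus
    the underlying counts.
    """

    group_label: str
    graph: nx.Graph
    cutoff_used: float
    filter_mean_used: float = float("nan")

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    @property
    def n_isolated(self) -> int:
        return sum(1 for v in self.graph if self.graph.degree(v) == 0)

    @property
    def n_connected_nodes(self) -> int:
        return self.n_nodes - self.n_isolated

    def total_weight(self) -> float:
        return float(sum(d["sci"] for _, _, d in self.graph.edges(data=True)))


def build_network(
    pairs: pd.DataFrame,
    cutoff: float,
    group_label: str = "",
    diagnosed_codes: set[str] | None = None,
    filter_mean: float = float("nan"),
) -> MultimorbidityNetwork:
    """Threshold the (already filtered) pair table at ``cutoff`` (edges kept
    when SCI >= cutoff) and assemble the network.

    ``diagnosed_codes`` supplies the full node set (all codes observed in
    the group); when omitted, the nodes are the endpoints of the retained
    pair table.
    """
    if cutoff < 0:
        raise ValueError("cutoff must be nonnegative")
    g = nx.Graph()
    nodes = diagnosed_codes if diagnosed_codes is not None else set(pairs["code_i"]) | set(pairs["code_j"])
    g.add_nodes_from(sorted(nodes))
    kept = pairs[pairs["sci"] >= cutoff]
    for r in kept.itertuples(index=False):
        g.add_edge(r.code_i, r.code_j, sci=float(r.sci), c_ij=int(r.c_ij), phi=float(r.phi))
    return MultimorbidityNetwork(
        group_label=group_label, graph=g, cutoff_used=float(cutoff), filter_mean_used=filter_mean
    )
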