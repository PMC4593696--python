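"""Rank-based and distance-based statistics for phenotype/environment tables.

Implements the downstream statistical battery from first principles:
Kruskal–Wallis with tie correction, Benjamini–Hochberg FDR adjustment,
pairwise rank-sum comparisons (exact enumeration for small groups, normal
approximation otherwise), PERMANOVA on a distance matrix, and one-way ANOVA
reconstructed from per-group summary statistics (n, mean, sd). The
implementations are deliberately self-contained so they can be cross-checked
against scipy/statsmodels/scikit-bio as independent oracles.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TestResult",
    "AnovaResult",
    "PermanovaResult",
    "kruskal_wallis",
    "kruskal_wallis_table",
    "fdr_adjust",
    "pairwise_rank_tests",
    "permanova",
    "distance_matrix",
    "anova_from_summary",
    "SUBCAUDAL_ORDINAL",
]

#: Ordinal encoding for the categorical subcaudal scale state, fixed so the
#: variable can enter rank tests (present > reduced > absent).
SUBCAUDAL_ORDINAL = {"present": 2, "reduced": 1, "absent": 0}


@dataclass(frozen=True)
class TestResult:
    variable: str
    statistic: float
    p: float
    p_adjusted: float | None
    method: str

    def __post_init__(self) -> None:
        for name, value in (("p", self.p), ("p_adjusted", self.p_adjusted)):
            if value is not None and not (0.0 <= value <= 1.0 + 1e-12):
                raise ValueError(f"{name} out of [0, 1]: {value}")


def _groups(values, group_labels) -> list[np.ndarray]:
    values = np.asarray(values, dtype=float)
    labels = np.asarray(group_labels)
    if len(values) != len(labels):
        raise ValueError("values and group_labels differ in length")
    return [values[labels == g] for g in pd.unique(labels)]


def kruskal_wallis(values, group_labels) -> tuple[float, float]:
    """Kruskal–Wallis H with tie correction; p from χ² with G−1 df."""
    groups = _groups(values, group_labels)
    if len(groups) < 2:
        raise ValueError("Kruskal-Wallis needs at least two groups")
    if any(len(g) == 0 for g in groups):
        raise ValueError("every group needs at least one observation")
    all_values = np.concatenate(groups)
    n = len(all_values)
    ranks = stats.rankdata(all_values)  # average ranks for ties
    h = 0.0
    start = 0
    for g in groups:
        r = ranks[start : start + len(g)]
        h += r.sum() ** 2 / len(g)
        start += len(g)
    h = 12.0 / (n * (n + 1)) * h - 3.0 * (n + 1)
    # tie correction
    _, tie_counts = np.unique(all_values, return_counts=True)
    correction = 1.0 - ((tie_counts**3 - tie_counts).sum()) / (n**3 - n)
    if correction > 0:
        h /= correction
    df = len(groups) - 1
    return float(h), float(stats.chi2.sf(h, df))


def kruskal_wallis_table(
    table: pd.DataFrame,
    variables: Sequence[str],
    group_col: str = "group",
) -> list[TestResult]:
    """KW test per variable with BH-FDR adjustment across the variable set."""
    raw = []
    for var in variables:
        h, p = kruskal_wallis(table[var], table[group_col])
        raw.append((var, h, p))
    adjusted = fdr_adjust([p for _, _, p in raw])
    return [
        TestResult(var, h, p, p_adj, method="kruskal-wallis")
        for (var, h, p), p_adj in zip(raw, adjusted)
    ]


def fdr_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.empty(m)
    adjusted[order] = np.minimum(adjusted_sorted, 1.0)
    return adjusted


def _rank_sum_exact_p(x: np.ndarray, y: np.ndarray) -> float:
    """Exact two-sided rank-sum p by full enumeration (ties allowed)."""
    combined = np.concatenate([x, y])
    ranks = stats.rankdata(combined)
    n1, n = len(x), len(combined)
    w_obs = ranks[:n1].sum()
    expected = n1 * (n + 1) / 2.0
    dev = abs(w_obs - expected) - 1e-9  # guard against float fuzz at ties
    hits = total = 0
    for combo in itertools.combinations(range(n), n1):
        w = ranks[list(combo)].sum()
        total += 1
        if abs(w - expected) >= dev:
            hits += 1
    return hits / total


def _rank_sum_normal_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided rank-sum p, normal approximation with tie correction and
    continuity correction."""
    combined = np.concatenate([x, y])
    ranks = stats.rankdata(combined)
    n1, n2 = len(x), len(y)
    n = n1 + n2
    w = ranks[:n1].sum()
    mu = n1 * (n + 1) / 2.0
    _, tie_counts = np.unique(combined, return_counts=True)
    tie_term = ((tie_counts**3 - tie_counts).sum()) / ((n) * (n - 1))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return 1.0
    z = (abs(w - mu) - 0.5) / math.sqrt(var)
    return float(2 * stats.norm.sf(max(z, 0.0)))


def pairwise_rank_tests(
    values,
    group_labels,
    adjust: bool = True,
    exact_max_n: int = 10,
) -> pd.DataFrame:
    """Two-sided rank-sum test for every unordered group pair.

    Uses exact enumeration when both groups have at most ``exact_max_n``
    observations (mandatory when either group is a singleton), otherwise the
    tie-corrected normal approximation. BH adjustment is applied across the
    pair set when ``adjust`` is true.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(group_labels)
    names = list(pd.unique(labels))
    if len(names) < 2:
        raise ValueError("need at least two groups")
    rows = []
    for g1, g2 in itertools.combinations(names, 2):
        x = values[labels == g1]
        y = values[labels == g2]
        exact = (len(x) <= exact_max_n and len(y) <= exact_max_n) or min(
            len(x), len(y)
        ) == 1
        p = _rank_sum_exact_p(x, y) if exact else _rank_sum_normal_p(x, y)
        w = stats.rankdata(np.concatenate([x, y]))[: len(x)].sum()
        rows.append(
            {
                "group1": g1,
                "group2": g2,
                "statistic": float(w),
                "p": p,
                "method": "exact" if exact else "normal",
            }
        )
    result = pd.DataFrame(rows)
    result["p_adjusted"] = fdr_adjust(result["p"]) if adjust else result["p"]
    return result


# --- PERMANOVA -------------------------------------------------------------


@dataclass(frozen=True)
class PermanovaResult:
    statistic: float  # pseudo-F
    r_squared: float
    p: float
    n_permutations: int


def distance_matrix(table: pd.DataFrame) -> np.ndarray:
    """Euclidean distances on z-standardized columns (the built-in default)."""
    x = table.to_numpy(dtype=float)
    sd = x.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    z = (x - x.mean(axis=0)) / sd
    diff = z[:, None, :] - z[None, :, :]
    return np.sqrt((diff**2).sum(axis=-1))


def _permanova_ss(d2: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """(SS_among, SS_within) from squared distances and labels."""
    n = d2.shape[0]
    iu = np.triu_indices(n, k=1)
    ss_total = d2[iu].sum() / n
    ss_within = 0.0
    for g in np.unique(labels):
        idx = np.flatnonzero(labels == g)
        if len(idx) < 2:
            continue
        sub = d2[np.ix_(idx, idx)]
        ss_within += sub[np.triu_indices(len(idx), k=1)].sum() / len(idx)
    return ss_total - ss_within, ss_within


def permanova(
    distances: np.ndarray | pd.DataFrame,
    group_labels,
    n_permutations: int = 999,
    seed: int | None = None,
) -> PermanovaResult:
    """Permutational multivariate ANOVA on a distance matrix.

    Partitions the total sum of squared distances into among- and
    within-group components; pseudo-F = (SS_A/df_A)/(SS_W/df_W) and
    r² = SS_A/SS_T. Significance is by random label permutation with the
    add-one convention: p = (#{F_perm ≥ F_obs} + 1) / (n_permutations + 1).
    """
    d = np.asarray(distances, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=1e-8):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(d), 0.0, atol=1e-8):
        raise ValueError("distance matrix must have a zero diagonal")
    labels = np.asarray(group_labels)
    if len(labels) != d.shape[0]:
        raise ValueError("one label per distance-matrix row required")
    groups = np.unique(labels)
    if len(groups) < 2:
        raise ValueError("need at least two groups")

    d2 = d**2
    n = d.shape[0]
    df_a = len(groups) - 1
    df_w = n - len(groups)

    def pseudo_f(lab: np.ndarray) -> float:
        ss_a, ss_w = _permanova_ss(d2, lab)
        if ss_w == 0:
            return np.inf if ss_a > 0 else 0.0
        return (ss_a / df_a) / (ss_w / df_w)

    ss_a_obs, ss_w_obs = _permanova_ss(d2, labels)
    ss_total = ss_a_obs + ss_w_obs
    f_obs = pseudo_f(labels)

    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        if pseudo_f(rng.permutation(labels)) >= f_obs - 1e-12:
            hits += 1
    p = (hits + 1) / (n_permutations + 1)
    r2 = ss_a_obs / ss_total if ss_total > 0 else 0.0
    return PermanovaResult(
        statistic=float(f_obs),
        r_squared=float(r2),
        p=float(p),
        n_permutations=n_permutations,
    )


# --- ANOVA from group summaries --------------------------------------------


@dataclass(frozen=True)
class AnovaResult:
    ss_between: float
    ss_within: float
    df_between: int
    df_within: int
    ms_between: float
    ms_within: float
    f: float
    p: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "source": ["between groups", "within groups", "total"],
                "sum_of_squares": [
                    self.ss_between,
                    self.ss_within,
                    self.ss_between + self.ss_within,
                ],
                "df": [self.df_between, self.df_within, self.df_between + self.df_within],
                "mean_square": [self.ms_between, self.ms_within, np.nan],
                "F": [self.f, np.nan, np.nan],
                "p": [self.p, np.nan, np.nan],
            }
        )


def anova_from_summary(groups: Sequence) -> AnovaResult:
    """One-way ANOVA reconstructed from per-group (n, mean, sd) summaries.

    Accepts any objects with ``n``, ``mean`` and ``sd`` attributes (e.g.
    :class:`hybridzone.synthetic_data.GroupSummary`) or ``(n, mean, sd)``
    tuples. Exactly reproduces the raw-data ANOVA whenever the summaries
    were computed (with ddof=1) from raw data.
    """

    def unpack(g):
        if hasattr(g, "n"):
            return int(g.n), float(g.mean), float(g.sd)
        n, mean, sd = g
        return int(n), float(mean), float(sd)

    parsed = [unpack(g) for g in groups]
    if len(parsed) < 2:
        raise ValueError("need at least two groups")
    if any(n < 2 for n, _, _ in parsed):
        raise ValueError("every group needs n >= 2")

    n_total = sum(n for n, _, _ in parsed)
    grand_mean = sum(n * mean for n, mean, _ in parsed) / n_total
    ss_between = sum(n * (mean - grand_mean) ** 2 for n, mean, _ in parsed)
    ss_within = sum((n - 1) * sd**2 for n, _, sd in parsed)
    df_between = len(parsed) - 1
    df_within = n_total - len(parsed)
    ms_between = ss_between / df_between
    ms_within = ss_within / df_within
    if ms_within == 0:
        f = np.inf if ms_between > 0 else 0.0
        p = 0.0 if ms_between > 0 else 1.0
    else:
        f = ms_between / ms_within
        p = float(stats.f.sf(f, df_between, df_within))
    return AnovaResult(
        ss_between=ss_between,
        ss_within=ss_within,
        df_between=df_between,
        df_within=df_within,
        ms_between=ms_between,
        ms_within=ms_within,
        f=float(f),
        p=p,
    )
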