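"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own code paths: exhaustive
enumeration for permutation tests, direct counting for assignment tables.
"""

from __future__ import annotations

import itertools
from math import comb

import numpy as np
from scipy import stats


def kw_statistic(groups: list[np.ndarray]) -> float:
    """Kruskal-Wallis H via the textbook rank formula (tie-corrected)."""
    values = np.concatenate(groups)
    n = len(values)
    ranks = stats.rankdata(values)
    h = 0.0
    start = 0
    for g in groups:
        r = ranks[start : start + len(g)]
        h += r.sum() ** 2 / len(g)
        start += len(g)
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    _, ties = np.unique(values, return_counts=True)
    corr = 1 - (ties**3 - ties).sum() / (n**3 - n)
    return h / corr if corr > 0 else h


def kw_permutation_p(groups: list[np.ndarray]) -> float:
    """Exact permutation p for KW by enumerating all group assignments."""
    values = np.concatenate(groups)
    sizes = [len(g) for g in groups]
    h_obs = kw_statistic(groups)
    n = len(values)
    idx = list(range(n))
    hits = total = 0
    # enumerate distinct assignments: choose indices for each group in turn
    def rec(remaining: list[int], size_idx: int, chosen: list[list[int]]):
        nonlocal hits, total
        if size_idx == len(sizes) - 1:
            parts = chosen + [remaining]
            perm_groups = [values[list(p)] for p in parts]
            total += 1
            if kw_statistic(perm_groups) >= h_obs - 1e-12:
                hits += 1
            return
        for combo in itertools.combinations(remaining, sizes[size_idx]):
            rest = [i for i in remaining if i not in combo]
            rec(rest, size_idx + 1, chosen + [list(combo)])

    rec(idx, 0, [])
    return hits / total


def rank_sum_exact_p(x: np.ndarray, y: np.ndarray) -> float:
    """Exact two-sided rank-sum p by enumeration over label assignments."""
    combined = np.concatenate([x, y])
    ranks = stats.rankdata(combined)
    n1, n = len(x), len(combined)
    w_obs = ranks[:n1].sum()
    expected = n1 * (n + 1) / 2
    dev = abs(w_obs - expected) - 1e-9
    hits = 0
    for combo in itertools.combinations(range(n), n1):
        if abs(ranks[list(combo)].sum() - expected) >= dev:
            hits += 1
    return hits / comb(n, n1)


def permanova_f(d2: np.ndarray, labels: np.ndarray) -> float:
    """Pseudo-F computed directly from the squared-distance decomposition."""
    n = d2.shape[0]
    groups = np.unique(labels)
    iu = np.triu_indices(n, k=1)
    ss_t = d2[iu].sum() / n
    ss_w = 0.0
    for g in groups:
        idx = np.flatnonzero(labels == g)
        sub = d2[np.ix_(idx, idx)]
        ss_w += sub[np.triu_indices(len(idx), k=1)].sum() / len(idx)
    ss_a = ss_t - ss_w
    return (ss_a / (len(groups) - 1)) / (ss_w / (n - len(groups)))


def permanova_exhaustive_p(d: np.ndarray, labels: np.ndarray) -> float:
    """Exact permutation p over every distinct labelling (small n only)."""
    d2 = d**2
    f_obs = permanova_f(d2, labels)
    hits = total = 0
    for perm in set(itertools.permutations(labels)):
        total += 1
        if permanova_f(d2, np.array(perm)) >= f_obs - 1e-12:
            hits += 1
    return hits / total
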