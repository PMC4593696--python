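"""Scoring classifier output against truth and field identifications.

Power of detection for a category is the number of correctly identified
individuals of that category over the true count of that category; accuracy
is the number correctly identified over the total assigned to the category
(undefined when nothing is assigned). The combined ``HYBRID`` category pools
the four admixed classes, with membership q_hybrid = sum of their
posteriors. Also provided: field-vs-genetic concordance, three-category
tallies at a strict threshold, and the mito-nuclear directionality test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .classifier import UNASSIGNED, assign
from .hybridsim import HYBRID_CLASSES, HYBRID_ONLY

__all__ = [
    "power_accuracy",
    "concordance",
    "category_tally",
    "directionality",
    "DirectionalityTable",
]


def power_accuracy(
    truth_labels: pd.Series,
    posteriors: pd.DataFrame,
    thresholds: Sequence[float] = (0.95, 0.9, 0.8, 0.7, 0.6, 0.5),
) -> pd.DataFrame:
    """Power/accuracy per class and threshold, plus the combined HYBRID row.

    ``truth_labels`` maps individual id to one of the six class labels;
    ``posteriors`` is an id-indexed six-class posterior frame (with the
    ``q_*`` columns, as produced by the classifier). An individual counts as
    assigned to a class when that class's membership strictly exceeds the
    threshold; for the HYBRID row the membership is ``q_hybrid`` regardless
    of which admixed subclass dominates. Unassigned individuals count
    against power (they stay in the denominator) and enter no accuracy
    ratio. Accuracy is NaN when a category receives no assignments.
    """
    truth = truth_labels.reindex(posteriors.index)
    if truth.isna().any():
        raise ValueError("truth labels missing for some individuals in posteriors")

    memberships: dict[str, pd.Series] = {c: posteriors[c] for c in HYBRID_CLASSES}
    memberships["HYBRID"] = posteriors["q_hybrid"]
    truth_masks = {c: (truth == c) for c in HYBRID_CLASSES}
    truth_masks["HYBRID"] = truth.isin(HYBRID_ONLY)

    records = []
    for t_q in thresholds:
        if not (0.5 <= t_q <= 1.0):
            raise ValueError(f"threshold {t_q} outside [0.5, 1]")
        for category, membership in memberships.items():
            assigned = membership > t_q
            in_class = truth_masks[category]
            n_true = int(in_class.sum())
            n_assigned = int(assigned.sum())
            n_correct = int((assigned & in_class).sum())
            records.append(
                {
                    "class": category,
                    "T_q": t_q,
                    "power": n_correct / n_true if n_true else np.nan,
                    "accuracy": n_correct / n_assigned if n_assigned else np.nan,
                    "n_true": n_true,
                    "n_assigned": n_assigned,
                    "n_correct": n_correct,
                }
            )
    return pd.DataFrame.from_records(records)


def concordance(field_ids: pd.Series, genetic_categories: pd.Series) -> pd.DataFrame:
    """Field-vs-genetic concordance matrix (percentages).

    Cell (f, g) is the percentage of individuals field-identified as ``f``
    whose genetic category is ``g`` (rows sum to 100). Categories never used
    as a field call give NaN rows (rendered "n.a." in reports).
    """
    field = pd.Series(field_ids)
    genetic = pd.Series(genetic_categories).reindex(field.index)
    if field.empty:
        return pd.DataFrame()
    cats = sorted(set(field.dropna()) | set(genetic.dropna()))
    table = pd.DataFrame(np.nan, index=cats, columns=cats)
    for f in cats:
        mask = field == f
        n_field = int(mask.sum())
        if n_field == 0:
            continue
        for g in cats:
            table.loc[f, g] = 100.0 * int((mask & (genetic == g)).sum()) / n_field
    table.index.name = "field_id"
    table.columns.name = "genetic_id"
    return table


def category_tally(posteriors: pd.DataFrame, t_q: float = 0.95) -> pd.DataFrame:
    """Counts and percentages per {PURE_A, HYBRID, PURE_B, UNASSIGNED}.

    Percentages are over all individuals (assigned plus unassigned),
    reported to one decimal place.
    """
    calls = assign(posteriors, t_q)
    order = ["PURE_A", "HYBRID", "PURE_B", UNASSIGNED]
    counts = calls.value_counts().reindex(order, fill_value=0)
    total = len(calls)
    return pd.DataFrame(
        {
            "count": counts,
            "percent": (100.0 * counts / total).round(1) if total else 0.0,
        }
    )


@dataclass(frozen=True)
class DirectionalityTable:
    """Maternal-species breakdown of nuclear-hybrid individuals.

    ``proportion_a`` is the fraction of hybrids carrying species-A mtDNA
    (species A is their maternal parent); ``p_value`` is the exact two-sided
    binomial test against an even 0.5 split. Both are None when no hybrid
    has an mtDNA call.
    """

    counts: Mapping[str, int]
    n_missing: int
    proportion_a: float | None
    p_value: float | None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"mtdna_species": list(self.counts), "n_hybrids": list(self.counts.values())}
        )


def directionality(
    genetic_categories: pd.Series,
    mtdna_calls: pd.Series,
    hybrid_categories: Sequence[str] = ("HYBRID",) + HYBRID_ONLY,
) -> DirectionalityTable:
    """Cross-tabulate nuclear hybrids by maternal (mtDNA) species.

    Hybrids without an mtDNA call are excluded but counted in ``n_missing``.
    The species treated as "A" for the reported proportion is the
    alphabetically first mtDNA call (matching the marker modules'
    label-ordering convention).
    """
    hybrids = genetic_categories[genetic_categories.isin(hybrid_categories)]
    calls = mtdna_calls.reindex(hybrids.index)
    n_missing = int(calls.isna().sum())
    calls = calls.dropna()
    if calls.empty:
        return DirectionalityTable(
            counts={}, n_missing=n_missing, proportion_a=None, p_value=None
        )
    counts = calls.value_counts().sort_index()
    species_a = counts.index[0]
    k = int(counts[species_a])
    n = int(counts.sum())
    test = stats.binomtest(k, n, p=0.5, alternative="two-sided")
    return DirectionalityTable(
        counts=counts.to_dict(),
        n_missing=n_missing,
        proportion_a=k / n,
        p_value=test.pvalue,
    )
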