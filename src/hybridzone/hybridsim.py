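"""Simulated hybrid genotypes with known truth labels.

Reproduces the validation procedure used to measure hybrid-detection power:
purebred pools are built by random draws from the parental allele pools,
then crossed to create F1, F2 and both backcross classes. Six classes in
total (two purebred, F1, F2, BC toward each parent), each with a known truth
label, form a :class:`ValidationSet` for scoring the classifier.

Loci are treated as unlinked and simulated genotypes are complete-case (no
missing data is generated).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .markers import genotype_loci

__all__ = [
    "HYBRID_CLASSES",
    "HYBRID_ONLY",
    "ValidationSet",
    "build_purebred_pool",
    "cross",
    "simulate_validation_set",
]

#: The six genotype-frequency classes, in canonical order.
HYBRID_CLASSES: tuple[str, ...] = ("PURE_A", "PURE_B", "F1", "F2", "BC_A", "BC_B")

#: The four admixed classes pooled into the combined "hybrid" category.
HYBRID_ONLY: tuple[str, ...] = ("F1", "F2", "BC_A", "BC_B")


@dataclass(frozen=True)
class ValidationSet:
    """Labelled simulated genotypes for power/accuracy evaluation."""

    genotypes: pd.DataFrame  # package CSV dialect plus a "truth" column
    truth: pd.Series  # id -> class label

    def __post_init__(self) -> None:
        missing = set(self.genotypes["id"]) - set(self.truth.index)
        if missing:
            raise ValueError(f"individuals without truth labels: {sorted(missing)[:5]}")

    def class_counts(self) -> pd.Series:
        return self.truth.value_counts()


def _allele_matrix(genotypes: pd.DataFrame, loci: Sequence[str]) -> dict[str, np.ndarray]:
    """Per-locus (n, 2) float arrays of alleles, NaN for missing."""
    out = {}
    for locus in loci:
        out[locus] = genotypes[[f"{locus}_1", f"{locus}_2"]].to_numpy(dtype=float)
    return out


def _empty_table(loci: Sequence[str]) -> dict[str, list]:
    cols: dict[str, list] = {"id": []}
    for locus in loci:
        cols[f"{locus}_1"] = []
        cols[f"{locus}_2"] = []
    return cols


def _finish_table(cols: dict[str, list], loci: Sequence[str]) -> pd.DataFrame:
    table = pd.DataFrame(cols)
    for locus in loci:
        table[f"{locus}_1"] = table[f"{locus}_1"].astype("Int64")
        table[f"{locus}_2"] = table[f"{locus}_2"].astype("Int64")
    return table


def build_purebred_pool(
    parental_genotypes: pd.DataFrame,
    n_out: int,
    seed: int | None = None,
    id_prefix: str = "sim",
) -> pd.DataFrame:
    """Simulate purebred genotypes by pooled-allele draws.

    Each simulated individual's two alleles per locus are independent uniform
    draws from the multiset of non-missing alleles observed in the parental
    sample at that locus.
    """
    rng = np.random.default_rng(seed)
    loci = genotype_loci(parental_genotypes)
    if not loci:
        raise ValueError("parental table has no locus columns")
    pools = {}
    for locus in loci:
        alleles = _allele_matrix(parental_genotypes, [locus])[locus].ravel()
        alleles = alleles[~np.isnan(alleles)].astype(int)
        if alleles.size == 0:
            raise ValueError(f"no observed alleles at locus {locus!r}")
        pools[locus] = alleles

    cols = _empty_table(loci)
    cols["id"] = [f"{id_prefix}_{i + 1:03d}" for i in range(n_out)]
    for locus in loci:
        draws = rng.choice(pools[locus], size=(n_out, 2))
        cols[f"{locus}_1"] = draws[:, 0].tolist()
        cols[f"{locus}_2"] = draws[:, 1].tolist()
    return _finish_table(cols, loci)


def cross(
    pool_1: pd.DataFrame,
    pool_2: pd.DataFrame,
    n_out: int,
    seed: int | None = None,
    id_prefix: str = "cross",
    scheme: str = "individual",
) -> pd.DataFrame:
    """Cross two genotype pools: one gamete from each pool per offspring.

    With the default ``scheme="individual"`` a gamete is drawn by picking a
    pool individual uniformly, then one of its two alleles uniformly (at
    loci where that individual is untyped, the pick is restricted to typed
    individuals). ``scheme="pooled"`` draws the gamete directly from the
    pooled alleles, matching the purebred-construction rule.
    """
    if scheme not in ("individual", "pooled"):
        raise ValueError(f"unknown gamete scheme {scheme!r}")
    rng = np.random.default_rng(seed)
    loci = genotype_loci(pool_1)
    if set(loci) != set(genotype_loci(pool_2)):
        raise ValueError("pools genotyped at different loci")
    if len(pool_1) == 0 or len(pool_2) == 0:
        raise ValueError("both pools must be non-empty")

    mats = (_allele_matrix(pool_1, loci), _allele_matrix(pool_2, loci))
    cols = _empty_table(loci)
    cols["id"] = [f"{id_prefix}_{i + 1:03d}" for i in range(n_out)]
    for locus in loci:
        for k, mat in enumerate(mats):
            alleles = mat[locus]
            if scheme == "pooled":
                flat = alleles.ravel()
                flat = flat[~np.isnan(flat)]
                if flat.size == 0:
                    raise ValueError(f"no observed alleles at locus {locus!r}")
                gametes = rng.choice(flat, size=n_out)
            else:
                typed = np.flatnonzero(~np.isnan(alleles).any(axis=1))
                if typed.size == 0:
                    raise ValueError(f"no typed individuals at locus {locus!r}")
                parents = rng.choice(typed, size=n_out)
                which = rng.integers(0, 2, size=n_out)
                gametes = alleles[parents, which]
            cols[f"{locus}_{k + 1}"] = gametes.astype(int).tolist()
    return _finish_table(cols, loci)


def simulate_validation_set(
    parental_a: pd.DataFrame,
    parental_b: pd.DataFrame,
    n_per_class: int,
    seed: int | None = None,
    scheme: str = "individual",
) -> ValidationSet:
    """Build the six-class labelled validation set (``n_per_class`` each).

    Purebred pools come from pooled-allele draws on each parental sample;
    F1 = pureA × pureB, F2 = F1 × F1, BC_A = F1 × pureA, BC_B = F1 × pureB.
    """
    if isinstance(seed, np.random.SeedSequence):
        seeds = seed.spawn(6)
    else:
        seeds = np.random.SeedSequence(seed).spawn(6)

    pure_a = build_purebred_pool(parental_a, n_per_class, seeds[0], id_prefix="PURE_A")
    pure_b = build_purebred_pool(parental_b, n_per_class, seeds[1], id_prefix="PURE_B")
    f1 = cross(pure_a, pure_b, n_per_class, seeds[2], id_prefix="F1", scheme=scheme)
    f2 = cross(f1, f1, n_per_class, seeds[3], id_prefix="F2", scheme=scheme)
    bc_a = cross(f1, pure_a, n_per_class, seeds[4], id_prefix="BC_A", scheme=scheme)
    bc_b = cross(f1, pure_b, n_per_class, seeds[5], id_prefix="BC_B", scheme=scheme)

    tables = {
        "PURE_A": pure_a,
        "PURE_B": pure_b,
        "F1": f1,
        "F2": f2,
        "BC_A": bc_a,
        "BC_B": bc_b,
    }
    frames = []
    for label in HYBRID_CLASSES:
        table = tables[label].copy()
        table["truth"] = label
        frames.append(table)
    genotypes = pd.concat(frames, ignore_index=True)
    truth = genotypes.set_index("id")["truth"]
    return ValidationSet(genotypes=genotypes, truth=truth)
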