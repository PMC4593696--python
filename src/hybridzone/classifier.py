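"""Bayesian assignment of individuals to six genotype-frequency classes.

The model follows the two-species hybrid-category framework used by the
NewHybrids program: each class is characterized by the expected proportions
(φ_AA, φ_AB, φ_BB) of loci whose two gene copies descend from species pairs
AA, AB and BB. For a genotype (i, j) at one locus with species allele
frequencies f_A and f_B, the class likelihood is

    P(i, j | class) = φ_AA·M(i,j; f_A,f_A) + φ_AB·M(i,j; f_A,f_B)
                      + φ_BB·M(i,j; f_B,f_B),

where M(i,j; p,q) = p_i·q_j + p_j·q_i for i ≠ j and p_i·q_i for i = j.
Loci are assumed unlinked, so multilocus likelihoods are products.

Four inference routes are provided:

* :func:`exact_posterior` — analytic posterior with known (plug-in) allele
  frequencies; the oracle the sampler is validated against.
* :func:`gibbs_classify` — Gibbs sampler integrating over allele-frequency
  uncertainty with a Jeffreys Dirichlet(1/2) prior, using reference parental
  samples (supervised by default).
* :func:`admixture_q` — supervised two-cluster admixture proportion by EM
  (a Structure-style continuous q, not the six-class model).
* :func:`assign` — threshold-based categorical assignment at a cutoff T_q.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .hybridsim import HYBRID_CLASSES, HYBRID_ONLY
from .markers import genotype_loci

__all__ = [
    "HybridClassSpec",
    "CLASS_SPECS",
    "SamplerConfig",
    "genotype_likelihood",
    "plugin_frequencies",
    "exact_posterior",
    "exact_posterior_table",
    "gibbs_classify",
    "admixture_q",
    "assign",
    "UNASSIGNED",
]

UNASSIGNED = "UNASSIGNED"


@dataclass(frozen=True)
class HybridClassSpec:
    """One genotype-frequency class: expected AA/AB/BB locus proportions."""

    label: str
    phi_aa: float
    phi_ab: float
    phi_bb: float

    def __post_init__(self) -> None:
        if abs(self.phi_aa + self.phi_ab + self.phi_bb - 1.0) > 1e-12:
            raise ValueError(f"{self.label}: φ values must sum to 1")

    @property
    def phi(self) -> np.ndarray:
        return np.array([self.phi_aa, self.phi_ab, self.phi_bb])


CLASS_SPECS: dict[str, HybridClassSpec] = {
    "PURE_A": HybridClassSpec("PURE_A", 1.0, 0.0, 0.0),
    "PURE_B": HybridClassSpec("PURE_B", 0.0, 0.0, 1.0),
    "F1": HybridClassSpec("F1", 0.0, 1.0, 0.0),
    "F2": HybridClassSpec("F2", 0.25, 0.5, 0.25),
    "BC_A": HybridClassSpec("BC_A", 0.5, 0.5, 0.0),
    "BC_B": HybridClassSpec("BC_B", 0.0, 0.5, 0.5),
}

#: φ matrix, rows in HYBRID_CLASSES order, columns (AA, AB, BB).
_PHI = np.array([CLASS_SPECS[c].phi for c in HYBRID_CLASSES])


@dataclass(frozen=True)
class SamplerConfig:
    """Gibbs sampler settings.

    Defaults (20 000 sweeps, 2 000 burn-in, 5 chains) are desk-scale: with a
    handful of loci the chain mixes quickly. ``allele_prior`` is the
    symmetric Dirichlet concentration on per-species allele frequencies
    (0.5 = Jeffreys). ``class_prior`` defaults to uniform over the six
    classes. With ``supervised`` (default) the reference individuals are
    hard-assigned to their purebred class, so their gene copies always count
    toward their species' frequencies.
    """

    n_sweeps: int = 20_000
    burn_in: int = 2_000
    n_chains: int = 5
    allele_prior: float = 0.5
    class_prior: Sequence[float] | None = None
    supervised: bool = True
    seed: int | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.burn_in < self.n_sweeps):
            raise ValueError("burn_in must satisfy 0 <= burn_in < n_sweeps")
        if self.allele_prior <= 0:
            raise ValueError("allele_prior concentration must be > 0")
        if self.n_chains < 1:
            raise ValueError("n_chains must be >= 1")

    def prior_vector(self) -> np.ndarray:
        if self.class_prior is None:
            return np.full(len(HYBRID_CLASSES), 1.0 / len(HYBRID_CLASSES))
        prior = np.asarray(self.class_prior, dtype=float)
        if prior.shape != (len(HYBRID_CLASSES),) or (prior < 0).any():
            raise ValueError("class_prior must be six non-negative weights")
        return prior / prior.sum()


# --- single-locus likelihood ----------------------------------------------


def _mating_prob(i: int, j: int, p: Mapping[int, float], q: Mapping[int, float]) -> float:
    """M(i,j; p,q): genotype probability with one copy from p, one from q."""
    pi, pj = p.get(i, 0.0), p.get(j, 0.0)
    qi, qj = q.get(i, 0.0), q.get(j, 0.0)
    if i == j:
        return pi * qi
    return pi * qj + pj * qi


def genotype_likelihood(
    genotype_at_locus: tuple[int, int] | None,
    hybrid_class: HybridClassSpec | str,
    freqs_a: Mapping[int, float],
    freqs_b: Mapping[int, float],
) -> float:
    """Likelihood of one locus genotype under one genotype-frequency class.

    A missing genotype (``None``) returns 1 (uninformative). Alleles absent
    from a frequency mapping have frequency 0.
    """
    if isinstance(hybrid_class, str):
        hybrid_class = CLASS_SPECS[hybrid_class]
    if genotype_at_locus is None:
        return 1.0
    i, j = genotype_at_locus
    return float(
        hybrid_class.phi_aa * _mating_prob(i, j, freqs_a, freqs_a)
        + hybrid_class.phi_ab * _mating_prob(i, j, freqs_a, freqs_b)
        + hybrid_class.phi_bb * _mating_prob(i, j, freqs_b, freqs_b)
    )


# --- plug-in frequencies ---------------------------------------------------


def plugin_frequencies(
    reference: pd.DataFrame,
    loci: Sequence[str] | None = None,
    pseudocount: float = 0.5,
    allele_universe: Mapping[str, Sequence[int]] | None = None,
) -> dict[str, dict[int, float]]:
    """Jeffreys-smoothed allele frequency estimates from a reference sample.

    ``allele_universe`` extends the smoothing support beyond the alleles seen
    in the reference (e.g. to alleles present in the individuals being
    classified), so unseen alleles get small nonzero frequencies instead of
    producing zero likelihoods from sampling noise.
    """
    loci = list(loci) if loci is not None else genotype_loci(reference)
    out: dict[str, dict[int, float]] = {}
    for locus in loci:
        alleles = pd.concat(
            [reference[f"{locus}_1"], reference[f"{locus}_2"]], ignore_index=True
        ).dropna().astype(int)
        counts = alleles.value_counts().to_dict()
        support = set(counts)
        if allele_universe is not None:
            support |= {int(a) for a in allele_universe.get(locus, ())}
        if not support:
            raise ValueError(f"no alleles observed at locus {locus!r}")
        total = len(alleles) + pseudocount * len(support)
        out[locus] = {
            a: (counts.get(a, 0) + pseudocount) / total for a in sorted(support)
        }
    return out


# --- exact posterior -------------------------------------------------------


def _attach_q(posterior: pd.DataFrame) -> pd.DataFrame:
    posterior = posterior.copy()
    posterior["q_pureA"] = posterior["PURE_A"]
    posterior["q_pureB"] = posterior["PURE_B"]
    posterior["q_hybrid"] = posterior[list(HYBRID_ONLY)].sum(axis=1)
    return posterior


def exact_posterior(
    multilocus_genotype: Mapping[str, tuple[int, int] | None],
    freqs_a: Mapping[str, Mapping[int, float]],
    freqs_b: Mapping[str, Mapping[int, float]],
    class_prior: Sequence[float] | None = None,
) -> pd.Series:
    """Analytic six-class posterior with known allele frequencies.

    Loci are independent: posterior ∝ prior × ∏_loci likelihood. An
    individual with no genotyped loci gets the prior back. Raises if every
    class has zero likelihood (impossible genotype under the model).
    """
    prior = (
        np.full(6, 1 / 6)
        if class_prior is None
        else np.asarray(class_prior, dtype=float) / np.sum(class_prior)
    )
    post = prior.copy()
    for locus, genotype in multilocus_genotype.items():
        lik = np.array(
            [
                genotype_likelihood(genotype, label, freqs_a[locus], freqs_b[locus])
                for label in HYBRID_CLASSES
            ]
        )
        post = post * lik
    total = post.sum()
    if total == 0:
        raise ValueError("impossible genotype: zero likelihood under every class")
    return pd.Series(post / total, index=list(HYBRID_CLASSES))


def exact_posterior_table(
    genotypes: pd.DataFrame,
    freqs_a: Mapping[str, Mapping[int, float]],
    freqs_b: Mapping[str, Mapping[int, float]],
    class_prior: Sequence[float] | None = None,
) -> pd.DataFrame:
    """Exact posteriors for every row of a genotype table (id-indexed)."""
    loci = [locus for locus in genotype_loci(genotypes) if locus in freqs_a]
    rows = {}
    for _, row in genotypes.iterrows():
        genotype: dict[str, tuple[int, int] | None] = {}
        for locus in loci:
            a1, a2 = row[f"{locus}_1"], row[f"{locus}_2"]
            genotype[locus] = (
                None if pd.isna(a1) or pd.isna(a2) else (int(a1), int(a2))
            )
        rows[row["id"]] = exact_posterior(genotype, freqs_a, freqs_b, class_prior)
    posterior = pd.DataFrame.from_dict(rows, orient="index")
    posterior.index.name = "id"
    return _attach_q(posterior)


# --- Gibbs sampler ---------------------------------------------------------


def _encode(
    genotypes: pd.DataFrame, loci: Sequence[str], index: Mapping[str, Mapping[int, int]]
) -> tuple[np.ndarray, np.ndarray]:
    """Integer-coded allele matrices (n, L); -1 marks missing."""
    n = len(genotypes)
    g1 = np.full((n, len(loci)), -1, dtype=np.int64)
    g2 = np.full((n, len(loci)), -1, dtype=np.int64)
    for l, locus in enumerate(loci):
        a1 = genotypes[f"{locus}_1"].to_numpy(dtype=float)
        a2 = genotypes[f"{locus}_2"].to_numpy(dtype=float)
        ok = ~(np.isnan(a1) | np.isnan(a2))
        lookup = index[locus]
        g1[ok, l] = [lookup[int(a)] for a in a1[ok]]
        g2[ok, l] = [lookup[int(a)] for a in a2[ok]]
    return g1, g2


def _allele_index(
    tables: Sequence[pd.DataFrame], loci: Sequence[str]
) -> dict[str, dict[int, int]]:
    index: dict[str, dict[int, int]] = {}
    for locus in loci:
        alleles: set[int] = set()
        for table in tables:
            for col in (f"{locus}_1", f"{locus}_2"):
                alleles |= {int(a) for a in table[col].dropna()}
        if not alleles:
            raise ValueError(f"no alleles observed at locus {locus!r}")
        index[locus] = {a: k for k, a in enumerate(sorted(alleles))}
    return index


def _ref_counts(g1: np.ndarray, g2: np.ndarray, n_loci: int, k_max: int) -> np.ndarray:
    counts = np.zeros((n_loci, k_max))
    for g in (g1, g2):
        for l in range(n_loci):
            col = g[:, l]
            col = col[col >= 0]
            np.add.at(counts[l], col, 1.0)
    return counts


def _sample_categorical(weights: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Draw one index per row from unnormalized weights along the last axis."""
    cdf = np.cumsum(weights, axis=-1)
    u = rng.random(weights.shape[:-1])[..., None] * cdf[..., -1:]
    return (u > cdf).sum(axis=-1)


def gibbs_classify(
    genotype_table: pd.DataFrame,
    reference_a: pd.DataFrame,
    reference_b: pd.DataFrame,
    config: SamplerConfig | None = None,
    return_chain_means: bool = False,
) -> pd.DataFrame | tuple[pd.DataFrame, pd.DataFrame]:
    """Six-class posteriors by Gibbs sampling over classes and frequencies.

    Each sweep alternates (a) sampling every target individual's class from
    its exact class-conditional probabilities given the current allele
    frequencies, (b) sampling the latent species-of-origin of each gene copy
    given the class, and (c) sampling per-species per-locus allele
    frequencies from their Dirichlet posterior (Jeffreys concentration plus
    reference gene copies plus the latent-origin copies). Reported
    posteriors are across-chain means of post-burn-in class-indicator
    frequencies; ``return_chain_means`` also returns the per-chain means for
    convergence inspection.

    The contract is a fixed sweep budget — non-convergence is not detected.
    Individuals with no genotyped loci receive the class prior.
    """
    config = config or SamplerConfig()
    loci = genotype_loci(genotype_table)
    for ref in (reference_a, reference_b):
        ref_loci = set(genotype_loci(ref))
        if not set(loci) <= ref_loci:
            raise ValueError("reference tables lack loci present in the targets")
    if len(reference_a) == 0 or len(reference_b) == 0:
        raise ValueError("both reference samples must be non-empty")

    index = _allele_index([genotype_table, reference_a, reference_b], loci)
    k_max = max(len(v) for v in index.values())
    n_loci = len(loci)

    targets = genotype_table
    if not config.supervised:
        # references become ordinary latent-class individuals
        targets = pd.concat([genotype_table, reference_a, reference_b], ignore_index=True)
    g1, g2 = _encode(targets, loci, index)
    n = len(targets)

    if config.supervised:
        ra1, ra2 = _encode(reference_a, loci, index)
        rb1, rb2 = _encode(reference_b, loci, index)
        counts_a0 = _ref_counts(ra1, ra2, n_loci, k_max)
        counts_b0 = _ref_counts(rb1, rb2, n_loci, k_max)
    else:
        counts_a0 = np.zeros((n_loci, k_max))
        counts_b0 = np.zeros((n_loci, k_max))

    allele_mask = np.zeros((n_loci, k_max), dtype=bool)
    for l, locus in enumerate(loci):
        allele_mask[l, : len(index[locus])] = True
    prior_conc = np.where(allele_mask, config.allele_prior, 0.0)

    obs = g1 >= 0
    g1c = np.where(obs, g1, 0)
    g2c = np.where(obs, g2, 0)
    het = (g1c != g2c) & obs
    lidx = np.arange(n_loci)[None, :].repeat(n, axis=0)  # (n, L)

    log_prior = np.log(config.prior_vector())
    n_chains = config.n_chains
    rng = np.random.default_rng(config.seed)

    def sample_freqs(latent_a: np.ndarray, latent_b: np.ndarray):
        conc_a = prior_conc[None] + counts_a0[None] + latent_a
        conc_b = prior_conc[None] + counts_b0[None] + latent_b
        ga = rng.standard_gamma(conc_a)
        gb = rng.standard_gamma(conc_b)
        return (
            ga / np.maximum(ga.sum(-1, keepdims=True), 1e-300),
            gb / np.maximum(gb.sum(-1, keepdims=True), 1e-300),
        )

    zeros = np.zeros((n_chains, n_loci, k_max))
    f_a, f_b = sample_freqs(zeros, zeros)
    post_counts = np.zeros((n_chains, n, len(HYBRID_CLASSES)))
    kept = config.n_sweeps - config.burn_in

    for sweep in range(config.n_sweeps):
        fa_g1 = f_a[:, lidx, g1c]  # (C, n, L)
        fa_g2 = f_a[:, lidx, g2c]
        fb_g1 = f_b[:, lidx, g1c]
        fb_g2 = f_b[:, lidx, g2c]

        m_aa = fa_g1 * fa_g2 * (1 + het)
        m_bb = fb_g1 * fb_g2 * (1 + het)
        m_ab = fa_g1 * fb_g2 + het * fa_g2 * fb_g1
        m = np.stack([m_aa, m_ab, m_bb], axis=-1)  # (C, n, L, 3)
        m[:, ~obs, :] = 1.0  # missing loci are uninformative

        lik = m @ _PHI.T  # (C, n, L, 6)
        loglik = np.log(np.maximum(lik, 1e-300)).sum(axis=2) + log_prior
        loglik -= loglik.max(axis=-1, keepdims=True)
        z = _sample_categorical(np.exp(loglik), rng)  # (C, n)

        if sweep >= config.burn_in:
            c_idx, n_idx = np.indices(z.shape)
            np.add.at(post_counts, (c_idx, n_idx, z), 1.0)

        # latent origin of each locus' gene-copy pair given the class
        origin = _sample_categorical(m * _PHI[z][:, :, None, :], rng)  # (C, n, L)
        # for AB origin, which copy came from species A
        p_first = fa_g1 * fb_g2 / np.maximum(m_ab, 1e-300)
        first_from_a = rng.random(origin.shape) < p_first

        latent_a = np.zeros((n_chains, n_loci, k_max))
        latent_b = np.zeros((n_chains, n_loci, k_max))
        obs3 = obs[None] & (origin >= 0)  # (C, n, L); origin always >= 0
        is_ab = origin == 1
        for g in (g1c, g2c):
            to_a = obs3 & ((origin == 0) | (is_ab & first_from_a))
            to_b = obs3 & ((origin == 2) | (is_ab & ~first_from_a))
            for target, mask in ((latent_a, to_a), (latent_b, to_b)):
                cc, nn, ll = np.nonzero(mask)
                np.add.at(target, (cc, ll, g[nn, ll]), 1.0)
            first_from_a = ~first_from_a  # second copy goes to the other species

        f_a, f_b = sample_freqs(latent_a, latent_b)

    chain_means = post_counts / kept  # (C, n, 6)
    posterior = pd.DataFrame(
        chain_means.mean(axis=0), index=targets["id"], columns=list(HYBRID_CLASSES)
    )
    if not config.supervised:
        posterior = posterior.iloc[: len(genotype_table)]
    posterior = _attach_q(posterior)
    if return_chain_means:
        per_chain = pd.concat(
            {
                c: pd.DataFrame(
                    chain_means[c], index=targets["id"], columns=list(HYBRID_CLASSES)
                )
                for c in range(n_chains)
            },
            names=["chain", "id"],
        )
        return posterior, per_chain
    return posterior


# --- admixture proportion (EM) ---------------------------------------------


def admixture_q(
    genotype_table: pd.DataFrame,
    reference_a: pd.DataFrame,
    reference_b: pd.DataFrame,
    tolerance: float = 1e-6,
    max_iter: int = 500,
) -> pd.DataFrame:
    """Supervised two-cluster admixture proportion q per individual.

    Maximizes ∏_copies [q·f_A(allele) + (1−q)·f_B(allele)] over q ∈ [0,1]
    by EM, with Jeffreys-smoothed plug-in reference frequencies. Returns an
    id-indexed frame with columns ``q``, ``converged`` and ``informative``
    (``informative=False`` flags a flat likelihood, where q = 0.5 is
    returned by convention).
    """
    loci = genotype_loci(genotype_table)
    universe = {
        locus: pd.concat(
            [genotype_table[f"{locus}_1"], genotype_table[f"{locus}_2"]],
            ignore_index=True,
        )
        .dropna()
        .astype(int)
        .tolist()
        for locus in loci
    }
    freqs_a = plugin_frequencies(reference_a, loci, allele_universe=universe)
    freqs_b = plugin_frequencies(reference_b, loci, allele_universe=universe)

    # flatten all gene copies: per copy, (individual index, f_A, f_B)
    idx_list, fa_list, fb_list = [], [], []
    for i, (_, row) in enumerate(genotype_table.iterrows()):
        for locus in loci:
            for col in (f"{locus}_1", f"{locus}_2"):
                allele = row[col]
                if pd.isna(allele):
                    continue
                idx_list.append(i)
                fa_list.append(freqs_a[locus][int(allele)])
                fb_list.append(freqs_b[locus][int(allele)])
    idx = np.array(idx_list, dtype=np.int64)
    fa = np.array(fa_list)
    fb = np.array(fb_list)
    n = len(genotype_table)

    n_copies = np.bincount(idx, minlength=n).astype(float)
    informative = np.zeros(n, dtype=bool)
    if idx.size:
        np.maximum.at(
            informative, idx, np.abs(fa - fb) > 1e-12
        )

    q = np.full(n, 0.5)
    converged = np.zeros(n, dtype=bool)
    for _ in range(max_iter):
        qa = q[idx] * fa
        w = qa / np.maximum(qa + (1 - q[idx]) * fb, 1e-300)
        q_new = q.copy()
        with_copies = n_copies > 0
        sums = np.bincount(idx, weights=w, minlength=n)
        q_new[with_copies] = sums[with_copies] / n_copies[with_copies]
        converged = np.abs(q_new - q) < tolerance
        q = q_new
        if converged.all():
            break
    if not converged.all():
        warnings.warn(
            f"admixture EM: {int((~converged).sum())} individuals not converged "
            f"after {max_iter} iterations",
            RuntimeWarning,
            stacklevel=2,
        )
    return pd.DataFrame(
        {"q": q, "converged": converged, "informative": informative},
        index=pd.Index(genotype_table["id"], name="id"),
    )


# --- threshold assignment ---------------------------------------------------


def _assign_row(row: Mapping[str, float], t_q: float, subclass: bool) -> str:
    if row["q_pureA"] > t_q:
        return "PURE_A"
    if row["q_pureB"] > t_q:
        return "PURE_B"
    if subclass:
        for label in HYBRID_ONLY:
            if label in row and row[label] > t_q:
                return label
    if row["q_hybrid"] > t_q:
        return "HYBRID"
    return UNASSIGNED


def assign(
    posterior: pd.DataFrame | pd.Series | Mapping[str, float],
    t_q: float,
    subclass: bool = False,
) -> pd.Series | str:
    """Categorical assignment at threshold ``t_q`` (strict ``>``).

    For six-class posteriors: PURE_A / PURE_B when the purebred membership
    exceeds the threshold, HYBRID when the combined hybrid membership does
    (with ``subclass=True``, a specific hybrid class when that single class
    exceeds it), otherwise UNASSIGNED. For admixture frames (a ``q``
    column): PURE_A if q > t_q, PURE_B if q < 1−t_q, else HYBRID.

    Thresholds are memberships, so ``t_q`` must lie in [0.5, 1]; above 0.5
    at most one category can exceed it, making the call unambiguous.
    """
    if not (0.5 <= t_q <= 1.0):
        raise ValueError(f"t_q must be in [0.5, 1], got {t_q}")
    if isinstance(posterior, pd.DataFrame):
        if "q" in posterior.columns and "q_hybrid" not in posterior.columns:
            q = posterior["q"]
            out = pd.Series(
                np.where(q > t_q, "PURE_A", np.where(q < 1 - t_q, "PURE_B", "HYBRID")),
                index=posterior.index,
            )
            return out
        table = posterior
        if "q_hybrid" not in table.columns:
            table = _attach_q(table)
        return table.apply(lambda row: _assign_row(row, t_q, subclass), axis=1)
    row = dict(posterior)
    if "q_hybrid" not in row:
        row["q_pureA"] = row["PURE_A"]
        row["q_pureB"] = row["PURE_B"]
        row["q_hybrid"] = sum(row[c] for c in HYBRID_ONLY)
    return _assign_row(row, t_q, subclass)
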