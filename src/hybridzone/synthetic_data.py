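"""Synthetic two-species data generator for the hybrid-zone pipeline.

Emulates the data a two-species crocodile hybrid-zone study produces:

* a reference microsatellite panel mixing species-private ("fixed") loci and
  frequency-variable shared loci,
* aligned mtDNA gene regions with planted fixed inter-species differences
  (barcode sites) and optional within-species background polymorphism,
* Hardy–Weinberg parental genotypes drawn from the panel,
* group-structured phenotypes (head-shape ratios, transverse scale counts,
  subcaudal scale state),
* habitat environments with a salinity contrast plus null climate covariates,
* per-egg mass tables drawn from group summary statistics.

Defaults mirror the study conditions: a seven-locus panel (five private-allele
loci at within-species frequency 0.7 and two shared loci at 0.8/0.2), three
mtDNA regions of 365/319/690 bp carrying 7/4/21 diagnostic sites, and egg
groups with the published n/mean/sd. Every operation takes its seed from its
config (or argument) so identical seeds reproduce identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from scipy import stats

from .markers import DiagnosticSiteSet

__all__ = [
    "SPECIES_A",
    "SPECIES_B",
    "PanelConfig",
    "GenotypePanel",
    "MtdnaConfig",
    "GroupSummary",
    "PhenotypeEffects",
    "EnvironmentConfig",
    "EGG_GROUPS",
    "simulate_panel",
    "simulate_mtdna",
    "simulate_individuals",
    "simulate_phenotypes",
    "simulate_environment",
    "simulate_eggs",
]

#: Default species labels: A is the saltwater-tolerant species (C. acutus
#: analogue), B the freshwater species (C. moreletii analogue).
SPECIES_A = "acutus"
SPECIES_B = "moreletii"

NUCLEOTIDES = np.array(list("ACGT"))


class ConfigError(ValueError):
    """Raised when a generator configuration violates its invariants."""


def _check_prob(name: str, value: float) -> None:
    if not (0.0 <= value <= 1.0):
        raise ConfigError(f"{name} must be in [0, 1], got {value}")


@dataclass(frozen=True)
class PanelConfig:
    """Layout of the reference microsatellite panel.

    ``n_loci_private`` loci each carry one allele private to species A (at
    frequency ``private_allele_freq`` within A), one private to B (same
    frequency within B), and ``alleles_per_locus - 1`` shared alleles holding
    the remaining mass in both species. ``n_loci_variable`` loci share all
    ``alleles_per_locus`` alleles, with the first allele's frequency split
    ``0.5 ± variable_freq_delta/2`` between the species and the remainder
    uniform over the other alleles.
    """

    n_loci_private: int = 5
    private_allele_freq: float = 0.7
    n_loci_variable: int = 2
    variable_freq_delta: float = 0.6
    alleles_per_locus: int = 2
    seed: int | None = None

    def __post_init__(self) -> None:
        _check_prob("private_allele_freq", self.private_allele_freq)
        _check_prob("variable_freq_delta", self.variable_freq_delta)
        if self.n_loci_private + self.n_loci_variable < 1:
            raise ConfigError("panel needs at least one locus")
        if self.alleles_per_locus < 2:
            raise ConfigError("alleles_per_locus must be >= 2")


@dataclass(frozen=True)
class GenotypePanel:
    """Per-locus allele frequency vectors for two parental species.

    ``alleles[locus]`` are integer allele codes (fragment-size surrogates);
    ``freq_a``/``freq_b`` are aligned frequency vectors summing to 1.
    """

    loci: tuple[str, ...]
    alleles: Mapping[str, np.ndarray]
    freq_a: Mapping[str, np.ndarray]
    freq_b: Mapping[str, np.ndarray]
    status: Mapping[str, str]  # "private" | "variable"
    species: tuple[str, str] = (SPECIES_A, SPECIES_B)

    def __post_init__(self) -> None:
        for locus in self.loci:
            for name, freqs in (("A", self.freq_a[locus]), ("B", self.freq_b[locus])):
                if abs(float(np.sum(freqs)) - 1.0) > 1e-9:
                    raise ConfigError(f"{name} frequencies at {locus} do not sum to 1")

    def frequencies(self, species: str) -> Mapping[str, np.ndarray]:
        if species == self.species[0]:
            return self.freq_a
        if species == self.species[1]:
            return self.freq_b
        raise KeyError(species)


def simulate_panel(config: PanelConfig) -> GenotypePanel:
    """Build the reference panel laid out by ``config`` (deterministic)."""
    loci: list[str] = []
    alleles: dict[str, np.ndarray] = {}
    freq_a: dict[str, np.ndarray] = {}
    freq_b: dict[str, np.ndarray] = {}
    status: dict[str, str] = {}

    p = config.private_allele_freq
    for i in range(config.n_loci_private):
        locus = f"locP{i + 1}"
        n_shared = config.alleles_per_locus - 1
        # allele codes: even sizes starting at 150; first two are the
        # species-private alleles, the rest shared
        codes = 150 + 2 * np.arange(2 + n_shared)
        fa = np.concatenate([[p, 0.0], np.full(n_shared, (1 - p) / n_shared)])
        fb = np.concatenate([[0.0, p], np.full(n_shared, (1 - p) / n_shared)])
        loci.append(locus)
        alleles[locus] = codes
        freq_a[locus] = fa
        freq_b[locus] = fb
        status[locus] = "private"

    delta = config.variable_freq_delta
    for i in range(config.n_loci_variable):
        locus = f"locV{i + 1}"
        k = config.alleles_per_locus
        codes = 150 + 2 * np.arange(k)
        hi, lo = 0.5 + delta / 2, 0.5 - delta / 2
        fa = np.concatenate([[hi], np.full(k - 1, lo / (k - 1))])
        fb = np.concatenate([[lo], np.full(k - 1, hi / (k - 1))])
        loci.append(locus)
        alleles[locus] = codes
        freq_a[locus] = fa
        freq_b[locus] = fb
        status[locus] = "variable"

    return GenotypePanel(
        loci=tuple(loci), alleles=alleles, freq_a=freq_a, freq_b=freq_b, status=status
    )


@dataclass(frozen=True)
class MtdnaConfig:
    """Layout of the aligned mtDNA gene regions.

    Defaults plant 7, 4 and 21 fixed inter-species differences in regions of
    365, 319 and 690 bp (a 12S / 16S / control-region panel totalling
    1374 nucleotides). ``background_polymorphism_rate`` is the per-site,
    per-sequence probability of a within-species substitution at
    non-diagnostic sites.
    """

    region_lengths: Mapping[str, int] = field(
        default_factory=lambda: {"12s": 365, "16s": 319, "dloop": 690}
    )
    diagnostic_counts: Mapping[str, int] = field(
        default_factory=lambda: {"12s": 7, "16s": 4, "dloop": 21}
    )
    n_seqs_per_species: int = 10
    background_polymorphism_rate: float = 0.0
    species: tuple[str, str] = (SPECIES_A, SPECIES_B)
    seed: int | None = None

    def __post_init__(self) -> None:
        _check_prob("background_polymorphism_rate", self.background_polymorphism_rate)
        if self.n_seqs_per_species < 1:
            raise ConfigError("n_seqs_per_species must be >= 1")
        for region, count in self.diagnostic_counts.items():
            length = self.region_lengths.get(region)
            if length is None:
                raise ConfigError(f"diagnostic count for unknown region {region!r}")
            if count > length:
                raise ConfigError(
                    f"{region}: {count} diagnostic sites exceed length {length}"
                )


def simulate_mtdna(
    config: MtdnaConfig,
) -> tuple[dict[str, MultipleSeqAlignment], dict[str, DiagnosticSiteSet]]:
    """Generate per-region alignments with planted diagnostic sites.

    Returns ``(alignments, truth)`` where ``truth[region]`` records the
    planted positions and species states. Background polymorphism is applied
    only at non-diagnostic sites, so with rate 0 the planted truth is exactly
    the set of fixed differences present.
    """
    rng = np.random.default_rng(config.seed)
    sp_a, sp_b = config.species
    alignments: dict[str, MultipleSeqAlignment] = {}
    truth: dict[str, DiagnosticSiteSet] = {}

    for region, length in config.region_lengths.items():
        n_diag = config.diagnostic_counts.get(region, 0)
        ancestral = rng.choice(NUCLEOTIDES, size=length)
        positions = np.sort(rng.choice(length, size=n_diag, replace=False))
        states_a = ancestral[positions]
        # pick a different base for species B at each diagnostic site
        states_b = np.empty(n_diag, dtype=states_a.dtype)
        for k, pos in enumerate(positions):
            others = NUCLEOTIDES[NUCLEOTIDES != ancestral[pos]]
            states_b[k] = rng.choice(others)

        seq_a = ancestral.copy()
        seq_b = ancestral.copy()
        seq_b[positions] = states_b

        diag_mask = np.zeros(length, dtype=bool)
        diag_mask[positions] = True
        records = []
        for species, base in ((sp_a, seq_a), (sp_b, seq_b)):
            for i in range(config.n_seqs_per_species):
                seq = base.copy()
                if config.background_polymorphism_rate > 0:
                    hits = (
                        rng.random(length) < config.background_polymorphism_rate
                    ) & ~diag_mask
                    for pos in np.flatnonzero(hits):
                        alternatives = NUCLEOTIDES[NUCLEOTIDES != seq[pos]]
                        seq[pos] = rng.choice(alternatives)
                records.append(
                    SeqRecord(Seq("".join(seq)), id=f"{species}_{i + 1}", description="")
                )
        alignments[region] = MultipleSeqAlignment(records)
        truth[region] = DiagnosticSiteSet(
            region=region,
            species_a=min(sp_a, sp_b),
            species_b=max(sp_a, sp_b),
            positions=tuple(int(p) for p in positions),
            states_a=tuple(states_a if sp_a == min(sp_a, sp_b) else states_b),
            states_b=tuple(states_b if sp_a == min(sp_a, sp_b) else states_a),
        )
    return alignments, truth


def simulate_individuals(
    panel: GenotypePanel, n_per_species: int, seed: int | None = None
) -> pd.DataFrame:
    """Draw Hardy–Weinberg parental genotypes from the panel frequencies.

    Each individual's genotype at each locus is two independent draws from
    its species' allele frequency vector. Returns the package genotype table
    dialect: ``id, species, field_id`` then ``<locus>_1, <locus>_2`` columns.
    """
    if not panel.loci:
        raise ConfigError("empty panel")
    if n_per_species < 1:
        raise ConfigError("n_per_species must be >= 1")
    rng = np.random.default_rng(seed)
    rows: dict[str, list] = {"id": [], "species": [], "field_id": []}
    for locus in panel.loci:
        rows[f"{locus}_1"] = []
        rows[f"{locus}_2"] = []
    for species in panel.species:
        freqs = panel.frequencies(species)
        for i in range(n_per_species):
            ind = f"{species}_{i + 1:03d}"
            rows["id"].append(ind)
            rows["species"].append(species)
            rows["field_id"].append(species)
            for locus in panel.loci:
                a1, a2 = rng.choice(panel.alleles[locus], size=2, p=freqs[locus])
                rows[f"{locus}_1"].append(int(a1))
                rows[f"{locus}_2"].append(int(a2))
    table = pd.DataFrame(rows)
    for locus in panel.loci:
        table[f"{locus}_1"] = table[f"{locus}_1"].astype("Int64")
        table[f"{locus}_2"] = table[f"{locus}_2"].astype("Int64")
    return table


# --- phenotypes -----------------------------------------------------------

#: Hybrid genotype-frequency class labels understood by the phenotype and
#: environment generators (kept in sync with :mod:`hybridzone.hybridsim`).
_PURE_A, _PURE_B = "PURE_A", "PURE_B"
_HYBRID_LABELS = ("F1", "F2", "BC_A", "BC_B")


def _group_kind(label: str) -> str:
    if label == _PURE_A:
        return "A"
    if label == _PURE_B:
        return "B"
    if label in _HYBRID_LABELS:
        return "hybrid"
    raise ValueError(f"unknown class label {label!r}")


@dataclass(frozen=True)
class PhenotypeEffects:
    """Group means/spreads for the morphological variables.

    Continuous variables are normal within group. The defaults give hybrids
    intermediate head-shape ratios and scale counts, overlapping the B
    (Morelet's-type) distribution more than the A (American-type) one — the
    overlap pattern that limits field identification of hybrids. The
    subcaudal scale state is categorical: fixed "absent" for pure A, fixed
    "present" for pure B, and drawn from ``subcaudal_hybrid_probs``
    (present, reduced, absent) for hybrids.
    """

    means: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {
            "head_wl_ratio": {"A": 0.30, "B": 0.38, "hybrid": 0.355},
            "snout_ratio": {"A": 0.55, "B": 0.70, "hybrid": 0.655},
            "transverse_scale_count": {"A": 4.0, "B": 6.0, "hybrid": 5.4},
        }
    )
    sds: Mapping[str, float] = field(
        default_factory=lambda: {
            "head_wl_ratio": 0.02,
            "snout_ratio": 0.04,
            "transverse_scale_count": 0.5,
        }
    )
    subcaudal_hybrid_probs: tuple[float, float, float] = (0.50, 0.45, 0.05)

    def __post_init__(self) -> None:
        if abs(sum(self.subcaudal_hybrid_probs) - 1.0) > 1e-9:
            raise ConfigError("subcaudal_hybrid_probs must sum to 1")

    @classmethod
    def null(cls) -> "PhenotypeEffects":
        """Zero-effect configuration: identical distributions in all groups."""
        base = cls()
        flat = {
            var: {kind: group_means["A"] for kind in ("A", "B", "hybrid")}
            for var, group_means in base.means.items()
        }
        return replace(base, means=flat, subcaudal_hybrid_probs=(1.0, 0.0, 0.0))


def simulate_phenotypes(
    true_class_labels: Sequence[str],
    effects: PhenotypeEffects | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Per-individual phenotype table for the given true class labels."""
    effects = effects or PhenotypeEffects()
    rng = np.random.default_rng(seed)
    kinds = [_group_kind(label) for label in true_class_labels]
    table = pd.DataFrame({"true_class": list(true_class_labels), "group": kinds})
    for var, group_means in effects.means.items():
        mu = np.array([group_means[k] for k in kinds])
        table[var] = rng.normal(mu, effects.sds[var])
    states = []
    for kind in kinds:
        if kind == "A":
            states.append("absent")
        elif kind == "B":
            states.append("present")
        else:
            states.append(
                rng.choice(
                    ["present", "reduced", "absent"], p=effects.subcaudal_hybrid_probs
                )
            )
    table["subcaudal_state"] = states
    return table


# --- environment ----------------------------------------------------------


@dataclass(frozen=True)
class EnvironmentConfig:
    """Habitat salinity contrast plus null climate covariates.

    Pure-A (saltwater species) salinities are uniform on ``salinity_a_range``
    (ppt); pure-B and hybrid salinities on ``salinity_other_range``. The two
    supports are disjoint by default, reflecting the observation that only
    the A species occupies saline habitat. ``n_null_covariates`` standard
    normal climate variables carry no group effect (they exercise the FDR
    behaviour of downstream tests).
    """

    salinity_a_range: tuple[float, float] = (25.0, 40.0)
    salinity_other_range: tuple[float, float] = (0.0, 5.0)
    n_null_covariates: int = 4

    def __post_init__(self) -> None:
        if self.salinity_a_range[0] > self.salinity_a_range[1]:
            raise ConfigError("salinity_a_range must be ordered")
        if self.salinity_other_range[0] > self.salinity_other_range[1]:
            raise ConfigError("salinity_other_range must be ordered")


def simulate_environment(
    true_class_labels: Sequence[str],
    config: EnvironmentConfig | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Per-individual environment table (salinity + null climate covariates)."""
    config = config or EnvironmentConfig()
    rng = np.random.default_rng(seed)
    kinds = [_group_kind(label) for label in true_class_labels]
    n = len(kinds)
    table = pd.DataFrame({"true_class": list(true_class_labels), "group": kinds})
    lo_a, hi_a = config.salinity_a_range
    lo_o, hi_o = config.salinity_other_range
    salinity = np.where(
        np.array(kinds) == "A",
        rng.uniform(lo_a, hi_a, size=n),
        rng.uniform(lo_o, hi_o, size=n),
    )
    table["salinity"] = salinity
    for j in range(config.n_null_covariates):
        table[f"clim{j + 1}"] = rng.normal(size=n)
    return table


# --- eggs -----------------------------------------------------------------


@dataclass(frozen=True)
class GroupSummary:
    """Summary statistics (n, mean, sd) for one nest group."""

    group: str
    n: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ConfigError("group n must be >= 2")
        if self.sd < 0:
            raise ConfigError("sd must be >= 0")


#: Published egg-mass summaries (grams): typical nests of each parental
#: species and the atypical ("hybrid") nests.
EGG_GROUPS: tuple[GroupSummary, ...] = (
    GroupSummary(SPECIES_A, 280, 85.6, 9.7),
    GroupSummary(SPECIES_B, 170, 69.0, 29.4),
    GroupSummary("hybrid", 308, 105.1, 20.3),
)


def simulate_eggs(
    group_summaries: Sequence[GroupSummary] = EGG_GROUPS,
    seed: int | None = None,
) -> pd.DataFrame:
    """Draw per-egg masses per group from a normal truncated at zero."""
    rng = np.random.default_rng(seed)
    frames = []
    for summary in group_summaries:
        if summary.sd == 0:
            masses = np.full(summary.n, summary.mean)
        else:
            a = (0.0 - summary.mean) / summary.sd  # truncate at zero mass
            dist = stats.truncnorm(a=a, b=np.inf, loc=summary.mean, scale=summary.sd)
            masses = dist.rvs(size=summary.n, random_state=rng)
        frames.append(pd.DataFrame({"group": summary.group, "mass": masses}))
    if not frames:
        return pd.DataFrame(columns=["group", "mass"])
    return pd.concat(frames, ignore_index=True)
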