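"""Diagnostic-marker discovery from reference parental samples.

Two marker systems are covered: fixed nucleotide differences between two
species in aligned mtDNA gene regions (barcode sites), and the status of
co-dominant microsatellite loci (species-private alleles, frequency-variable
shared alleles, monomorphism, single-species amplification).

Species are labelled generically ``A`` and ``B`` throughout; the labels are
whatever strings the caller supplies (e.g. ``"acutus"`` / ``"moreletii"``)
and all operations are equivariant under swapping them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "DiagnosticSiteSet",
    "LocusStatus",
    "HaplotypeCall",
    "UNDETERMINED",
    "find_fixed_sites",
    "classify_haplotype",
    "screen_loci",
    "genotype_loci",
]

#: Nucleotide states eligible for diagnostic calls. Columns containing a gap
#: or any ambiguity code in any sequence are excluded (conservative rule).
VALID_STATES = frozenset("ACGT")

UNDETERMINED = "undetermined"


@dataclass(frozen=True)
class DiagnosticSiteSet:
    """Fixed inter-species differences in one aligned gene region.

    ``positions`` are 0-based alignment column indices (strictly increasing);
    use :meth:`to_frame` for a 1-based report.
    """

    region: str
    species_a: str
    species_b: str
    positions: tuple[int, ...]
    states_a: tuple[str, ...]
    states_b: tuple[str, ...]

    def __post_init__(self) -> None:
        if not (len(self.positions) == len(self.states_a) == len(self.states_b)):
            raise ValueError("positions and state tuples must have equal length")
        if any(a == b for a, b in zip(self.states_a, self.states_b)):
            raise ValueError("diagnostic states must differ between species")
        if any(q <= p for p, q in zip(self.positions, self.positions[1:])):
            raise ValueError("positions must be strictly increasing")

    def __len__(self) -> int:
        return len(self.positions)

    def to_frame(self) -> pd.DataFrame:
        """Report table with 1-based positions (biological convention)."""
        return pd.DataFrame(
            {
                "region": self.region,
                "position": [p + 1 for p in self.positions],
                "state_A": self.states_a,
                "state_B": self.states_b,
            }
        )


@dataclass(frozen=True)
class HaplotypeCall:
    """Species call for one sequence against a diagnostic site set."""

    species: str
    match_fraction: float
    n_informative: int


@dataclass(frozen=True)
class LocusStatus:
    """Diagnostic characterization of one co-dominant locus."""

    locus: str
    amplifies_in: str  # "both", a species label, or "neither"
    fixed: bool = False
    variable: bool = False
    monomorphic: bool = False
    private_alleles: Mapping[str, tuple[int, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.monomorphic and (self.fixed or self.variable):
            raise ValueError("a monomorphic locus cannot be fixed or variable")

    @property
    def uninformative(self) -> bool:
        return self.amplifies_in == "neither"


def _alignment_matrix(alignment, species_labels):
    """Coerce an alignment + labels into (char matrix, per-row species)."""
    try:  # Bio.Align.MultipleSeqAlignment or list of SeqRecord
        ids = [rec.id for rec in alignment]
        seqs = [str(rec.seq).upper() for rec in alignment]
    except AttributeError:
        if isinstance(alignment, Mapping):
            ids = list(alignment)
            seqs = [str(alignment[i]).upper() for i in ids]
        else:
            raise TypeError("alignment must be SeqRecords or a mapping id->sequence")
    if isinstance(species_labels, Mapping):
        labels = [species_labels[i] for i in ids]
    else:
        labels = list(species_labels)
        if len(labels) != len(seqs):
            raise ValueError("species_labels length does not match alignment")
    lengths = {len(s) for s in seqs}
    if len(lengths) > 1:
        raise ValueError("ragged alignment: sequences differ in length")
    if not seqs:
        raise ValueError("empty alignment")
    mat = np.array([list(s) for s in seqs])
    return mat, np.asarray(labels, dtype=object)


def find_fixed_sites(alignment, species_labels, region: str = "") -> DiagnosticSiteSet:
    """Locate alignment columns fixed for different states in the two species.

    A column qualifies when every species-A sequence shares one state, every
    species-B sequence shares a different state, and all characters in the
    column are unambiguous nucleotides (no gaps, no IUPAC ambiguity).

    Parameters
    ----------
    alignment
        ``MultipleSeqAlignment``, sequence of ``SeqRecord``, or mapping
        ``id -> sequence string``. All sequences must have equal length.
    species_labels
        Mapping ``id -> species`` or a per-row sequence of species labels.
        Exactly two species, each with at least one sequence.
    region
        Name carried into the returned :class:`DiagnosticSiteSet`.
    """
    mat, labels = _alignment_matrix(alignment, species_labels)
    species = sorted(set(labels))
    if len(species) != 2:
        raise ValueError(f"expected exactly 2 species, got {species}")
    sp_a, sp_b = species
    rows_a = mat[labels == sp_a]
    rows_b = mat[labels == sp_b]
    if rows_a.size == 0 or rows_b.size == 0:
        raise ValueError("each species needs at least one sequence")

    positions, states_a, states_b = [], [], []
    for j in range(mat.shape[1]):
        col = mat[:, j]
        if not VALID_STATES.issuperset(col):
            continue
        ca = set(rows_a[:, j])
        cb = set(rows_b[:, j])
        if len(ca) == 1 and len(cb) == 1 and ca != cb:
            positions.append(j)
            states_a.append(next(iter(ca)))
            states_b.append(next(iter(cb)))
    return DiagnosticSiteSet(
        region=region,
        species_a=sp_a,
        species_b=sp_b,
        positions=tuple(positions),
        states_a=tuple(states_a),
        states_b=tuple(states_b),
    )


def classify_haplotype(sequence, sites: DiagnosticSiteSet) -> HaplotypeCall:
    """Barcode one sequence to species by counting diagnostic-state matches.

    The call is the majority species over informative positions (those where
    the sequence carries one of the two diagnostic states); the match
    fraction is majority count / informative count. Ties and empty site sets
    return :data:`UNDETERMINED`.
    """
    seq = str(sequence).upper()
    if len(sites) == 0:
        return HaplotypeCall(UNDETERMINED, float("nan"), 0)
    if len(seq) < max(sites.positions) + 1:
        raise ValueError("sequence shorter than the diagnostic site span")
    n_a = n_b = 0
    for pos, sa, sb in zip(sites.positions, sites.states_a, sites.states_b):
        state = seq[pos]
        if state == sa:
            n_a += 1
        elif state == sb:
            n_b += 1
    informative = n_a + n_b
    if informative == 0 or n_a == n_b:
        return HaplotypeCall(UNDETERMINED, float("nan"), informative)
    if n_a > n_b:
        return HaplotypeCall(sites.species_a, n_a / informative, informative)
    return HaplotypeCall(sites.species_b, n_b / informative, informative)


def genotype_loci(genotypes: pd.DataFrame) -> list[str]:
    """Locus names inferred from paired ``<locus>_1``/``<locus>_2`` columns."""
    loci = []
    for col in genotypes.columns:
        if col.endswith("_1") and f"{col[:-2]}_2" in genotypes.columns:
            loci.append(col[:-2])
    return loci


def _allele_freqs(genotypes: pd.DataFrame, locus: str) -> pd.Series:
    alleles = pd.concat(
        [genotypes[f"{locus}_1"], genotypes[f"{locus}_2"]], ignore_index=True
    ).dropna()
    if alleles.empty:
        return pd.Series(dtype=float)
    return alleles.astype(int).value_counts(normalize=True).sort_index()


def screen_loci(
    genotypes: pd.DataFrame,
    delta_min: float = 0.3,
    species_col: str = "species",
) -> list[LocusStatus]:
    """Characterize each locus of a two-species reference genotype table.

    Flags, per locus: species-private alleles (``fixed``), shared alleles
    whose between-species frequency difference is at least ``delta_min``
    (``variable``), monomorphism, and single-species amplification (a locus
    entirely missing in one species). A locus missing in both species has
    ``amplifies_in == "neither"`` (uninformative).

    The genotype table uses the package CSV dialect: a ``species`` column and
    two allele columns ``<locus>_1``/``<locus>_2`` per locus, with missing
    alleles as NA.
    """
    species = sorted(genotypes[species_col].dropna().unique())
    if len(species) != 2:
        raise ValueError(f"expected exactly 2 species, got {species}")
    sp_a, sp_b = species
    sub_a = genotypes[genotypes[species_col] == sp_a]
    sub_b = genotypes[genotypes[species_col] == sp_b]

    statuses = []
    for locus in genotype_loci(genotypes):
        fa = _allele_freqs(sub_a, locus)
        fb = _allele_freqs(sub_b, locus)
        if fa.empty and fb.empty:
            statuses.append(LocusStatus(locus, amplifies_in="neither"))
            continue
        if fb.empty:
            statuses.append(LocusStatus(locus, amplifies_in=sp_a))
            continue
        if fa.empty:
            statuses.append(LocusStatus(locus, amplifies_in=sp_b))
            continue
        alleles = fa.index.union(fb.index)
        private_a = tuple(int(a) for a in fa.index.difference(fb.index))
        private_b = tuple(int(a) for a in fb.index.difference(fa.index))
        shared = fa.index.intersection(fb.index)
        monomorphic = len(alleles) == 1
        fixed = bool(private_a or private_b) and not monomorphic
        variable = bool(
            not monomorphic
            and len(shared) > 0
            and (fa[shared] - fb[shared]).abs().max() >= delta_min
        )
        statuses.append(
            LocusStatus(
                locus,
                amplifies_in="both",
                fixed=fixed,
                variable=variable,
                monomorphic=monomorphic,
                private_alleles={sp_a: private_a, sp_b: private_b},
            )
        )
    return statuses
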