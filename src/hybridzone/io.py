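"""Readers/writers for the package's plain-text interchange formats.

* FASTA per gene region (sequence ids ``<species>_<index>``), via Biopython.
* Genotype CSV: ``id,species,field_id`` then ``<locus>_1,<locus>_2`` column
  pairs; missing alleles are empty fields.
* Diagnostic-site CSV: ``region,position,state_A,state_B`` (1-based
  positions, biological convention).
* Posterior CSV: id plus six class columns and the ``q_*`` memberships.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import pandas as pd
from Bio import AlignIO, SeqIO

from .markers import DiagnosticSiteSet, genotype_loci

__all__ = [
    "write_fasta",
    "read_alignment",
    "species_labels_from_ids",
    "write_genotypes",
    "read_genotypes",
    "write_sites",
    "read_sites",
    "write_posteriors",
    "write_concordance",
]


def write_fasta(alignment, path) -> None:
    SeqIO.write(list(alignment), str(path), "fasta")


def read_alignment(path):
    return AlignIO.read(str(path), "fasta")


def species_labels_from_ids(alignment) -> dict[str, str]:
    """Parse species from sequence ids of the form ``<species>_<index>``."""
    labels = {}
    for rec in alignment:
        species, _, suffix = rec.id.rpartition("_")
        if not species or not suffix:
            raise ValueError(f"id {rec.id!r} is not of the form <species>_<index>")
        labels[rec.id] = species
    return labels


def write_genotypes(genotypes: pd.DataFrame, path) -> None:
    genotypes.to_csv(path, index=False)


def read_genotypes(path) -> pd.DataFrame:
    table = pd.read_csv(path)
    for locus in genotype_loci(table):
        for col in (f"{locus}_1", f"{locus}_2"):
            table[col] = table[col].astype("Int64")
    return table


def write_sites(sites: Mapping[str, DiagnosticSiteSet] | DiagnosticSiteSet, path) -> None:
    if isinstance(sites, DiagnosticSiteSet):
        frame = sites.to_frame()
    else:
        frame = pd.concat([s.to_frame() for s in sites.values()], ignore_index=True)
    frame.to_csv(path, index=False)


def read_sites(path) -> dict[str, DiagnosticSiteSet]:
    """Load diagnostic sites; species names are not stored in the CSV, so
    the generic labels ``A``/``B`` are used on read-back."""
    frame = pd.read_csv(path)
    out = {}
    for region, sub in frame.groupby("region", sort=False):
        sub = sub.sort_values("position")
        out[str(region)] = DiagnosticSiteSet(
            region=str(region),
            species_a="A",
            species_b="B",
            positions=tuple(int(p) - 1 for p in sub["position"]),
            states_a=tuple(sub["state_A"]),
            states_b=tuple(sub["state_B"]),
        )
    return out


def write_posteriors(posteriors: pd.DataFrame, path) -> None:
    posteriors.to_csv(path, index=True)


def write_concordance(table: pd.DataFrame, path) -> None:
    """Concordance matrix with undefined cells rendered ``n.a.``."""
    out = table.round(1).astype(object).where(table.notna(), "n.a.")
    out.to_csv(path)


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
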