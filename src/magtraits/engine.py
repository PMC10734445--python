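"""Generic completeness computation and trait calling.

The core rule, applied uniformly across trait categories: a multi-gene
pathway is *present* when the fraction of its distinct member genes found in
a genome reaches the trait's completeness threshold (default 0.5, inclusive)
AND every marker gene is present.  Marker genes — substrate-specific
receptors or diagnostic subunits — are individually required; a genome at or
above threshold but missing a marker is *putative*, mirroring the asterisk
convention used in presence/absence figures.  Copy counts never inflate
completeness (a gene in three copies still counts once), but all evidence,
including below-threshold evidence, is recorded on the call.

Manual per-genome curation is replaced by an explicit override table
(genome_id, trait_id, forced_status, reason) so results stay deterministic
and auditable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .io import (
    CatalogError,
    FormatError,
    GenomeAnnotation,
    Status,
    TraitCall,
    TraitDefinition,
    TraitMatrix,
)

__all__ = [
    "Override",
    "read_overrides",
    "module_completeness",
    "call_trait",
    "build_trait_matrix",
]


@dataclass(frozen=True)
class Override:
    """A forced trait status with a mandatory audit reason."""

    genome_id: str
    trait_id: str
    forced_status: Status
    reason: str

    def __post_init__(self):
        if not self.reason:
            raise ValueError(
                f"override {self.genome_id}/{self.trait_id}: reason must be non-empty"
            )


def read_overrides(path) -> "tuple[Override, ...]":
    """Read an override TSV (genome_id, trait_id, forced_status, reason)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = ("genome_id", "trait_id", "forced_status", "reason")
    for col in required:
        if col not in df.columns:
            raise FormatError(f"override file {path}: missing required column {col!r}")
    out = []
    for row in df.itertuples(index=False):
        out.append(
            Override(row.genome_id, row.trait_id, Status(row.forced_status), row.reason)
        )
    return tuple(out)


def module_completeness(genome: GenomeAnnotation, trait: TraitDefinition) -> float:
    """Fraction of the trait's distinct module genes found in the genome.

    For PFAM-only traits (empty module_genes) the fraction of PFAM markers
    present is returned instead.
    """
    if trait.module_genes:
        hits = sum(1 for ko in trait.module_genes if genome.has_kegg(ko))
        return hits / len(trait.module_genes)
    if trait.pfam_markers:
        hits = sum(1 for pf in trait.pfam_markers if genome.has_pfam(pf))
        return hits / len(trait.pfam_markers)
    raise CatalogError(f"trait {trait.trait_id}: empty module_genes and pfam_markers")


def _markers_present(genome: GenomeAnnotation, trait: TraitDefinition) -> bool:
    return all(genome.has_kegg(ko) for ko in trait.marker_genes) and all(
        genome.has_pfam(pf) for pf in trait.pfam_markers
    )


def _evidence(genome: GenomeAnnotation, trait: TraitDefinition) -> tuple:
    ev = [
        (ko, genome.kegg_counts[ko])
        for ko in trait.module_genes
        if genome.has_kegg(ko)
    ]
    ev.extend(
        (pf, genome.pfam_counts[pf])
        for pf in sorted(trait.pfam_markers)
        if genome.has_pfam(pf)
    )
    return tuple(ev)


def _completeness_status(
    completeness: float, markers_ok: bool, trait: TraitDefinition
) -> Status:
    at_threshold = (
        completeness >= trait.completeness_threshold - 1e-12 and completeness > 0.0
    )
    if at_threshold and markers_ok:
        return Status.PRESENT
    if at_threshold:
        return Status.PUTATIVE
    if trait.report_partial and completeness > 0.0:
        return Status.PUTATIVE
    return Status.ABSENT


def _marker_companion_status(
    genome: GenomeAnnotation, markers_ok: bool, trait: TraitDefinition
) -> Status:
    companions = trait.companion_genes
    has_companion = any(genome.has_kegg(ko) for ko in companions)
    if markers_ok and (has_companion or not companions):
        return Status.PRESENT
    if markers_ok or has_companion:
        return Status.PUTATIVE
    return Status.ABSENT


def call_trait(
    genome: GenomeAnnotation,
    trait: TraitDefinition,
    overrides: Iterable[Override] = (),
) -> TraitCall:
    """Call one trait in one genome; a matching override replaces the status."""
    completeness = module_completeness(genome, trait)
    markers_ok = _markers_present(genome, trait)
    if trait.rule == "marker_companion":
        status = _marker_companion_status(genome, markers_ok, trait)
    else:
        status = _completeness_status(completeness, markers_ok, trait)
    note = ""
    if status is Status.PUTATIVE:
        if not markers_ok:
            note = "marker gene(s) missing"
        elif completeness < trait.completeness_threshold:
            note = "partial pathway below threshold"
    override_applied = False
    for ov in overrides:
        if ov.genome_id == genome.genome_id and ov.trait_id == trait.trait_id:
            status = ov.forced_status
            override_applied = True
            note = f"override: {ov.reason}"
    return TraitCall(
        genome_id=genome.genome_id,
        trait_id=trait.trait_id,
        status=status,
        completeness=completeness,
        evidence=_evidence(genome, trait),
        override_applied=override_applied,
        note=note,
    )


def build_trait_matrix(
    genomes: Mapping[str, GenomeAnnotation],
    catalog: Mapping[str, TraitDefinition],
    overrides: Iterable[Override] = (),
) -> TraitMatrix:
    """Call every catalog trait for every genome.

    Deterministic given its inputs; permuting genome input order only
    permutes rows.  Overrides referencing a trait absent from the catalog
    raise :class:`CatalogError`.
    """
    overrides = tuple(overrides)
    for ov in overrides:
        if ov.trait_id not in catalog:
            raise CatalogError(f"override references unknown trait_id {ov.trait_id!r}")
        if ov.genome_id not in genomes:
            raise CatalogError(f"override references unknown genome_id {ov.genome_id!r}")
    cells = {}
    for gid, genome in genomes.items():
        for tid, trait in catalog.items():
            cells[(gid, tid)] = call_trait(genome, trait, overrides)
    return TraitMatrix(
        genomes=tuple(genomes), traits=tuple(catalog), cells=cells
    )
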