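"""Phosphorus-source disambiguation, vitamin auxotrophy, and interaction traits.

Phosphorus: KEGG annotation cannot separate the phosphonate (phnCDE) from
the phosphite (ptxABC) ABC transporter, so the transporter's substrate is
interpreted from adjacent metabolism genes — phosphite dehydrogenase (ptxD)
points to phosphite, a broad-specificity C-P lyase (phnGHIJKLM) or a
complete substrate-specific 2-aminoethylphosphonate (2-AEP) hydrolysis route
(phnW plus phnX or phnA) points to phosphonate; a transporter with neither
stays ambiguous.

Vitamins (B1 thiamin, B7 biotin, B12 cobalamin): a genome is classified
*auxotroph* iff it lacks the vitamin's biosynthesis pathway but carries an
uptake system (marker binding subunit plus >=1 companion transporter gene);
*prototroph* iff it encodes biosynthesis; *self_and_uptake* for both;
*neither* otherwise.

Interaction traits: AHL (acyl-homoserine lactone) biosynthesis is called
from the luxR-homolog domain PF00765 on a genome gene or a BGC member gene;
quorum-sensing regulation, secretion, motility/adhesion and metal-response
traits are config gene sets evaluated by the generic engine.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

from .engine import call_trait
from .io import GenomeAnnotation, Status, TraitCall, TraitDefinition, load_default_catalog
from .iron import BGCRecord

__all__ = [
    "PProfile",
    "VitaminStatus",
    "call_p_profile",
    "call_vitamin_status",
    "call_interaction_traits",
    "VITAMINS",
]

VITAMINS = ("B1", "B7", "B12")

AHL_PFAM = "PF00765"
PHNW, PHNX, PHNA = "K03430", "K05306", "K19670"

P_TRAIT_IDS = (
    "pst_transporter",
    "pit_transporter",
    "phn_transporter",
    "ptxD",
    "cp_lyase",
    "aep_hydrolysis",
    "phoA",
    "phoX",
    "phoD",
)


@dataclass
class PProfile:
    """Per-genome phosphorus trait statuses and transporter interpretation."""

    genome_id: str
    statuses: "dict[str, Status]"  # one per trait in P_TRAIT_IDS
    phn_transporter_interpretation: str  # phosphonate_linked | phosphite_linked | both | ambiguous | absent
    aep_partial: bool

    def as_row(self) -> dict:
        row = {"genome_id": self.genome_id}
        row.update({t: s.value for t, s in self.statuses.items()})
        row["phn_transporter_interpretation"] = self.phn_transporter_interpretation
        row["aep_partial"] = self.aep_partial
        return row


def _catalog(catalog) -> Mapping[str, TraitDefinition]:
    return catalog if catalog is not None else load_default_catalog()


def call_p_profile(
    genome: GenomeAnnotation, catalog: Optional[Mapping[str, TraitDefinition]] = None
) -> PProfile:
    """Call the phosphorus traits and interpret the phn transporter substrate."""
    catalog = _catalog(catalog)
    statuses = {tid: call_trait(genome, catalog[tid]).status for tid in P_TRAIT_IDS}

    aep_complete = genome.has_kegg(PHNW) and (
        genome.has_kegg(PHNX) or genome.has_kegg(PHNA)
    )
    aep_any = any(genome.has_kegg(ko) for ko in (PHNW, PHNX, PHNA))
    phosphite = statuses["ptxD"] is Status.PRESENT
    phosphonate = statuses["cp_lyase"] is Status.PRESENT or aep_complete

    if statuses["phn_transporter"] is Status.ABSENT:
        interp = "absent"
    elif phosphite and phosphonate:
        interp = "both"
    elif phosphite:
        interp = "phosphite_linked"
    elif phosphonate:
        interp = "phosphonate_linked"
    else:
        interp = "ambiguous"

    return PProfile(
        genome_id=genome.genome_id,
        statuses=statuses,
        phn_transporter_interpretation=interp,
        aep_partial=aep_any and not aep_complete,
    )


@dataclass(frozen=True)
class VitaminStatus:
    """Biosynthesis/uptake statuses and the resulting trophic classification."""

    genome_id: str
    vitamin: str
    biosynthesis: Status
    uptake: Status
    classification: str  # prototroph | auxotroph | self_and_uptake | neither

    def as_row(self) -> dict:
        return {
            "genome_id": self.genome_id,
            "vitamin": self.vitamin,
            "biosynthesis": self.biosynthesis.value,
            "uptake": self.uptake.value,
            "classification": self.classification,
        }


def classify_vitamin(biosynthesis: Status, uptake: Status) -> str:
    """Pure 2x2 classification: auxotroph iff no biosynthesis AND uptake present."""
    bio = biosynthesis is Status.PRESENT
    up = uptake is Status.PRESENT
    if bio and up:
        return "self_and_uptake"
    if bio:
        return "prototroph"
    if up:
        return "auxotroph"
    return "neither"


def call_vitamin_status(
    genome: GenomeAnnotation,
    vitamin: str,
    catalog: Optional[Mapping[str, TraitDefinition]] = None,
) -> VitaminStatus:
    """Classify one genome for one vitamin (B1, B7 or B12)."""
    if vitamin not in VITAMINS:
        raise ValueError(f"unknown vitamin {vitamin!r}; expected one of {VITAMINS}")
    catalog = _catalog(catalog)
    bio = call_trait(genome, catalog[f"vit{vitamin}_biosynthesis"]).status
    up = call_trait(genome, catalog[f"vit{vitamin}_uptake"]).status
    return VitaminStatus(
        genome_id=genome.genome_id,
        vitamin=vitamin,
        biosynthesis=bio,
        uptake=up,
        classification=classify_vitamin(bio, up),
    )


def call_interaction_traits(
    genome: GenomeAnnotation,
    bgcs: Iterable[BGCRecord] = (),
    catalog: Optional[Mapping[str, TraitDefinition]] = None,
) -> "dict[str, TraitCall]":
    """Call all interaction-category traits for one genome.

    The AHL call additionally accepts PF00765 evidence carried on a BGC
    member gene of the same genome (secondary-metabolite screens report the
    domain on the cluster rather than in the per-gene PFAM table).
    """
    catalog = _catalog(catalog)
    calls = {}
    for tid, trait in catalog.items():
        if trait.category != "interaction":
            continue
        calls[tid] = call_trait(genome, trait)
    ahl = calls.get("ahl_biosynthesis")
    if ahl is not None and ahl.status is not Status.PRESENT:
        bgc_count = sum(
            g.pfam_counts.get(AHL_PFAM, 0)
            for bgc in bgcs
            if bgc.genome_id == genome.genome_id
            for g in bgc.genes
        )
        if bgc_count >= 1:
            calls["ahl_biosynthesis"] = TraitCall(
                genome_id=genome.genome_id,
                trait_id="ahl_biosynthesis",
                status=Status.PRESENT,
                completeness=1.0,
                evidence=((AHL_PFAM, bgc_count),),
                note="PF00765 carried on BGC member gene",
            )
    return calls
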