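"""Marker-gene assignment of nitrate/nitrite reductases to N-metabolic pathways.

Nitrate and nitrite reductases participate in three distinct pathways —
assimilatory nitrate reduction to ammonium (ANRA), dissimilatory nitrate
reduction to ammonium (DNRA), and denitrification — and KEGG's pathway map
alone cannot place them, because the reference organism (*E. coli*) is the
exception rather than the rule.  This module implements a deterministic
marker-gene rule set that assigns each reductase gene group in a genome to
at most one pathway:

1. N2 fixation is called only for the full nif module (all four orthologs;
   ``nif_strict=False`` drops the fourth, fixation-associated ortholog).
2. nirS or nirK is the marker for denitrification: its presence calls the
   NO2->NO step and pulls napAB / narGHI (if found) into denitrification
   step NO3->NO2.
3. nrfA (K03385) is the diagnostic for DNRA; nrfH alone is not sufficient.
   With no denitrification marker present, napAB / narGHI are attached to
   DNRA when nrfA is found; a denitrification marker takes precedence.
4. nasA, narB or nirA mark ANRA.  nirBD couples to ANRA only through nasA;
   nirBD alone is an unassigned, putative nitrite reduction.
5. nor genes call the NO->N2O step: present with a denitrification marker,
   putative without one (the norB-plus-nirA host genome case).
6. nosZ calls the terminal N2O->N2 step independently — denitrification is
   modular and a consortium can complete it collectively.
7. Nitrate reductases left unclaimed by rules 2-4 are reported as
   unassigned/putative.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .io import GenomeAnnotation, Status

__all__ = [
    "N_GENE_GROUPS",
    "NGeneInventory",
    "NPathwayProfile",
    "assign_n_pathways",
    "consortium_denitrification_completeness",
    "DENIT_STEPS",
]

#: The 12 nitrogen gene groups and their KEGG orthologs.
N_GENE_GROUPS: "dict[str, tuple]" = {
    "nif": ("K02588", "K02591", "K02586", "K00531"),
    "napAB": ("K02567", "K02568"),
    "narGHI": ("K00370", "K00371", "K00374"),
    "narB": ("K00367",),
    "nasA": ("K00372",),
    "nrfAH": ("K15876", "K03385"),
    "nirA": ("K00366",),
    "nirBD": ("K00362", "K00363"),
    "nirS": ("K15864",),
    "nirK": ("K00368",),
    "norBC": ("K04561", "K02305"),
    "nosZ": ("K00376",),
}

NRFA = "K03385"
NRFH = "K15876"
NORB = "K04561"
NORC = "K02305"

DENIT_STEPS = ("NO3->NO2", "NO2->NO", "NO->N2O", "N2O->N2")


@dataclass(frozen=True)
class NGeneInventory:
    """Copy counts of the 24 nitrogen-cycle orthologs, grouped."""

    counts: Mapping[str, int]

    @classmethod
    def from_genome(cls, genome: GenomeAnnotation) -> "NGeneInventory":
        all_kos = [ko for genes in N_GENE_GROUPS.values() for ko in genes]
        return cls(counts={ko: genome.kegg_counts.get(ko, 0) for ko in all_kos})

    @classmethod
    def from_groups(cls, present_groups: Iterable[str]) -> "NGeneInventory":
        """Inventory with every gene of each named group present once (testing aid)."""
        present = set(present_groups)
        unknown = present - set(N_GENE_GROUPS)
        if unknown:
            raise ValueError(f"unknown nitrogen gene groups: {sorted(unknown)}")
        counts = {}
        for group, genes in N_GENE_GROUPS.items():
            for ko in genes:
                counts[ko] = 1 if group in present else 0
        return cls(counts=counts)

    def gene_present(self, ko: str) -> bool:
        return self.counts.get(ko, 0) >= 1

    def group_fraction(self, group: str) -> float:
        genes = N_GENE_GROUPS[group]
        return sum(1 for ko in genes if self.gene_present(ko)) / len(genes)

    def group_present(self, group: str) -> bool:
        """Group presence under the generic inclusive 50% rule."""
        return self.group_fraction(group) >= 0.5

    def group_any(self, group: str) -> bool:
        return any(self.gene_present(ko) for ko in N_GENE_GROUPS[group])

    def group_all(self, group: str) -> bool:
        return all(self.gene_present(ko) for ko in N_GENE_GROUPS[group])


@dataclass
class NPathwayProfile:
    """Per-genome N-pathway statuses and reductase-to-pathway assignments."""

    genome_id: str
    n2_fixation: Status
    anra: Status
    dnra: Status
    denitrification_steps: tuple  # 4 statuses, order DENIT_STEPS
    reductase_assignments: "dict[str, str]" = field(default_factory=dict)

    def as_row(self) -> "dict[str, str]":
        row = {
            "genome_id": self.genome_id,
            "n2_fixation": self.n2_fixation.value,
            "anra": self.anra.value,
            "dnra": self.dnra.value,
        }
        for label, status in zip(DENIT_STEPS, self.denitrification_steps):
            row[f"denit_{label}"] = status.value
        row["assignments"] = ";".join(
            f"{k}:{v}" for k, v in sorted(self.reductase_assignments.items())
        )
        return row


def assign_n_pathways(
    source, nif_strict: bool = True, genome_id: str = ""
) -> NPathwayProfile:
    """Assign N-cycle gene groups of one genome to pathways.

    ``source`` is a :class:`GenomeAnnotation` or a prebuilt
    :class:`NGeneInventory`.  Output is independent of gene input order and
    every input maps to a profile.
    """
    if isinstance(source, GenomeAnnotation):
        inv = NGeneInventory.from_genome(source)
        genome_id = genome_id or source.genome_id
    else:
        inv = source

    assignments: "dict[str, str]" = {}
    steps = [Status.ABSENT] * 4

    # (1) N2 fixation: full module required.
    nif_required = N_GENE_GROUPS["nif"] if nif_strict else N_GENE_GROUPS["nif"][:3]
    n2 = (
        Status.PRESENT
        if all(inv.gene_present(ko) for ko in nif_required)
        else Status.ABSENT
    )

    # (2) Denitrification marker: nirS or nirK.
    denit_marker = inv.gene_present("K15864") or inv.gene_present("K00368")
    has_nap = inv.group_present("napAB")
    has_nar = inv.group_present("narGHI")
    if denit_marker:
        steps[1] = Status.PRESENT
        for group in ("nirS", "nirK"):
            if inv.group_any(group):
                assignments[group] = "denitrification"
        for group, present in (("napAB", has_nap), ("narGHI", has_nar)):
            if present:
                assignments[group] = "denitrification"
                steps[0] = Status.PRESENT

    # (3) DNRA: nrfA is the diagnostic.
    if inv.gene_present(NRFA):
        dnra = Status.PRESENT
        assignments["nrfAH"] = "DNRA"
        if not denit_marker:
            for group, present in (("napAB", has_nap), ("narGHI", has_nar)):
                if present:
                    assignments[group] = "DNRA"
    else:
        dnra = Status.ABSENT
        if inv.gene_present(NRFH):
            assignments["nrfAH"] = "unassigned/putative"

    # (4) ANRA markers; nirBD couples through nasA only.
    anra = Status.ABSENT
    for group in ("nasA", "narB", "nirA"):
        if inv.group_any(group):
            anra = Status.PRESENT
            assignments[group] = "ANRA"
    if inv.group_present("nirBD"):
        if inv.gene_present("K00372"):
            assignments["nirBD"] = "ANRA"
        else:
            assignments["nirBD"] = "unassigned/putative"
            if anra is Status.ABSENT:
                anra = Status.PUTATIVE

    # (5) NO -> N2O: present only alongside a denitrification marker.
    if inv.group_any("norBC"):
        if denit_marker:
            steps[2] = Status.PRESENT
            assignments["norBC"] = "denitrification"
        else:
            steps[2] = Status.PUTATIVE
            assignments["norBC"] = "unassigned/putative"

    # (6) Terminal step is modular and independent.
    if inv.gene_present("K00376"):
        steps[3] = Status.PRESENT
        assignments["nosZ"] = "denitrification"

    # (7) Unclaimed nitrate reductases.
    for group, present in (("napAB", has_nap), ("narGHI", has_nar)):
        if present and group not in assignments:
            assignments[group] = "unassigned/putative"

    return NPathwayProfile(
        genome_id=genome_id,
        n2_fixation=n2,
        anra=anra,
        dnra=dnra,
        denitrification_steps=tuple(steps),
        reductase_assignments=assignments,
    )


def consortium_denitrification_completeness(
    profiles: Iterable[NPathwayProfile],
) -> "dict":
    """Per-step genome coverage and whether the consortium collectively
    completes the four denitrification steps (each covered by >=1 genome)."""
    profiles = list(profiles)
    if not profiles:
        raise ValueError("no N-pathway profiles supplied")
    coverage = {label: [] for label in DENIT_STEPS}
    for p in profiles:
        for label, status in zip(DENIT_STEPS, p.denitrification_steps):
            if status is Status.PRESENT:
                coverage[label].append(p.genome_id)
    return {
        "step_coverage": coverage,
        "collectively_complete": all(coverage[label] for label in DENIT_STEPS),
    }
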