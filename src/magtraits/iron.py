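"""Fe-uptake repertoire classification and siderophore BGC calling.

Fe-uptake receptors are single-KO markers: ferrous iron (feoB), ferric iron
(afuA), heme (hemR), ferric citrate (fecA), and Fe-siderophore complexes
(fevS).  The siderophore receptor KO does not separate siderophores from
vitamin B12 as a substrate, so any call made from it alone carries an
ambiguity flag.  The TonB/ExbB/ExbD energizing system is graded complete /
partial / absent.

Siderophore biosynthetic gene clusters (BGCs) come in two flavours:

* NIS (NRPS-independent synthetase) clusters are identified by one or more
  iucA/iucC-type domains (PF04183) and typed against a bundled reference
  panel of synthetase exemplars by best global pairwise identity.  The
  bundled panel sequences are synthetic stand-ins (see
  ``data/nis_panel_synthetic.fasta``); a user-supplied panel of real
  synthetase sequences drops in via :func:`load_nis_panel`.  Photolability
  and membrane association are reference metadata, not sequence-derived.
* NRPS clusters are flagged as putative siderophore producers only when a
  TonB-dependent siderophore receptor (SMCOG1082-tagged gene) is co-located
  within the cluster span.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Align import PairwiseAligner, substitution_matrices

from .io import FormatError, GenomeAnnotation, Status

__all__ = [
    "IUC_PFAM",
    "TBDT_TAG",
    "FeUptakeProfile",
    "BGCGene",
    "BGCRecord",
    "SiderophoreCall",
    "NISReference",
    "classify_fe_uptake",
    "load_bgcs",
    "write_bgcs",
    "load_nis_panel",
    "pairwise_identity",
    "call_nis_siderophore",
    "call_nrps_siderophore",
    "call_siderophores",
]

IUC_PFAM = "PF04183"
TBDT_TAG = "TBDT_siderophore_receptor"

FE_RECEPTORS = {
    "fe2": "K04759",
    "fe3": "K02012",
    "heme": "K16087",
    "citrate": "K16091",
    "siderophore": "K02016",
}
TONB_GENES = ("K03832", "K03561", "K03559")

_AA_LETTERS = set("ACDEFGHIKLMNPQRSTVWYBZX*")


@dataclass(frozen=True)
class FeUptakeProfile:
    """Receptor-level Fe-uptake statuses for one genome."""

    genome_id: str
    fe2: Status
    fe3: Status
    heme: Status
    citrate: Status
    siderophore_receptor: Status
    ambiguity_flag: bool
    tonb_system: str  # complete | partial | absent

    def as_row(self) -> dict:
        return {
            "genome_id": self.genome_id,
            "fe2": self.fe2.value,
            "fe3": self.fe3.value,
            "heme": self.heme.value,
            "citrate": self.citrate.value,
            "siderophore_receptor": self.siderophore_receptor.value,
            "siderophore_receptor_ambiguous": self.ambiguity_flag,
            "tonb_system": self.tonb_system,
        }


def classify_fe_uptake(genome: GenomeAnnotation) -> FeUptakeProfile:
    """Call each Fe-uptake receptor from its single KEGG marker.

    The siderophore-receptor call is always flagged ambiguous because its KO
    also covers vitamin-B12 TonB-dependent receptors.
    """
    def status(ko: str) -> Status:
        return Status.PRESENT if genome.has_kegg(ko) else Status.ABSENT

    tonb_hits = sum(1 for ko in TONB_GENES if genome.has_kegg(ko))
    tonb = (
        "complete"
        if tonb_hits == len(TONB_GENES)
        else "partial" if tonb_hits else "absent"
    )
    sid = status(FE_RECEPTORS["siderophore"])
    return FeUptakeProfile(
        genome_id=genome.genome_id,
        fe2=status(FE_RECEPTORS["fe2"]),
        fe3=status(FE_RECEPTORS["fe3"]),
        heme=status(FE_RECEPTORS["heme"]),
        citrate=status(FE_RECEPTORS["citrate"]),
        siderophore_receptor=sid,
        ambiguity_flag=sid is Status.PRESENT,
        tonb_system=tonb,
    )


@dataclass(frozen=True)
class BGCGene:
    gene_id: str
    start: int
    end: int
    pfam_counts: Mapping[str, int] = field(default_factory=dict)
    tags: tuple = ()

    def __post_init__(self):
        object.__setattr__(self, "pfam_counts", dict(self.pfam_counts))
        object.__setattr__(self, "tags", tuple(self.tags))
        if any(v < 0 for v in self.pfam_counts.values()):
            raise ValueError(f"BGC gene {self.gene_id}: negative PFAM count")


@dataclass(frozen=True)
class BGCRecord:
    """A secondary-metabolite cluster with member-gene domain content."""

    genome_id: str
    cluster_id: str
    contig: str
    start: int
    end: int
    cluster_class: str  # NRPS | NIS | other
    genes: tuple = ()
    synthetase_sequences: tuple = ()

    def __post_init__(self):
        object.__setattr__(self, "genes", tuple(self.genes))
        object.__setattr__(
            self, "synthetase_sequences", tuple(self.synthetase_sequences)
        )
        if self.cluster_class not in ("NRPS", "NIS", "other"):
            raise ValueError(
                f"cluster {self.cluster_id}: unknown class {self.cluster_class!r}"
            )
        for g in self.genes:
            if not (self.start <= g.start and g.end <= self.end):
                raise ValueError(
                    f"cluster {self.cluster_id}: gene {g.gene_id} outside cluster span"
                )

    @property
    def iuc_domain_count(self) -> int:
        return sum(g.pfam_counts.get(IUC_PFAM, 0) for g in self.genes)

    @property
    def has_receptor_tag(self) -> bool:
        return any(TBDT_TAG in g.tags for g in self.genes)


@dataclass(frozen=True)
class SiderophoreCall:
    genome_id: str
    cluster_id: str
    kind: str  # NIS | NRPS_putative | none
    iuc_domain_count: int = 0
    nearest_reference: Optional[str] = None
    nearest_identity_pct: Optional[float] = None
    tie_flag: bool = False
    photolabile: bool = False
    membrane_bound: bool = False

    def as_row(self) -> dict:
        return {
            "genome_id": self.genome_id,
            "cluster_id": self.cluster_id,
            "kind": self.kind,
            "iuc_domain_count": self.iuc_domain_count,
            "nearest_reference": self.nearest_reference or "",
            "nearest_identity_pct": (
                "" if self.nearest_identity_pct is None
                else f"{self.nearest_identity_pct:.2f}"
            ),
            "tie_flag": self.tie_flag,
            "photolabile": self.photolabile,
            "membrane_bound": self.membrane_bound,
        }


@dataclass(frozen=True)
class NISReference:
    name: str
    siderophore: str
    sequence: str
    photolabile: bool = False
    membrane_bound: bool = False


# ---------------------------------------------------------------------------
# BGC JSON I/O


def load_bgcs(path) -> "list[BGCRecord]":
    """Load BGC records from the bundled JSON schema (a list of objects)."""
    with open(path, "r", encoding="utf-8") as fh:
        doc = json.load(fh)
    if not isinstance(doc, list):
        raise FormatError(f"BGC file {path}: expected a JSON list of clusters")
    records = []
    for entry in doc:
        genes = tuple(
            BGCGene(
                gene_id=g["gene_id"],
                start=int(g["start"]),
                end=int(g["end"]),
                pfam_counts={k: int(v) for k, v in g.get("pfam_counts", {}).items()},
                tags=tuple(g.get("tags", ())),
            )
            for g in entry.get("genes", ())
        )
        records.append(
            BGCRecord(
                genome_id=entry["genome_id"],
                cluster_id=entry["cluster_id"],
                contig=entry.get("contig", ""),
                start=int(entry["start"]),
                end=int(entry["end"]),
                cluster_class=entry["cluster_class"],
                genes=genes,
                synthetase_sequences=tuple(entry.get("synthetase_sequences", ())),
            )
        )
    return records


def write_bgcs(records: Iterable[BGCRecord], path) -> Path:
    doc = []
    for r in records:
        doc.append(
            {
                "genome_id": r.genome_id,
                "cluster_id": r.cluster_id,
                "contig": r.contig,
                "start": r.start,
                "end": r.end,
                "cluster_class": r.cluster_class,
                "genes": [
                    {
                        "gene_id": g.gene_id,
                        "start": g.start,
                        "end": g.end,
                        "pfam_counts": dict(g.pfam_counts),
                        "tags": list(g.tags),
                    }
                    for g in r.genes
                ],
                "synthetase_sequences": list(r.synthetase_sequences),
            }
        )
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, indent=1)
        fh.write("\n")
    return path


def load_nis_panel(fasta_path=None, metadata_path=None) -> "list[NISReference]":
    """Load the NIS synthetase reference panel (FASTA + metadata TSV).

    Defaults to the bundled synthetic exemplar panel; panel order is the FASTA
    order and breaks identity ties.
    """
    if fasta_path is None:
        fasta_path = Path(resources.files("magtraits.data") / "nis_panel_synthetic.fasta")
        metadata_path = Path(resources.files("magtraits.data") / "nis_panel_synthetic.tsv")
    meta = {}
    if metadata_path is not None:
        mdf = pd.read_csv(metadata_path, sep="\t", dtype=str)
        for row in mdf.itertuples(index=False):
            meta[row.name] = {
                "siderophore": row.siderophore,
                "photolabile": str(row.photolabile).lower() == "true",
                "membrane_bound": str(row.membrane_bound).lower() == "true",
            }
    panel = []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        m = meta.get(rec.id, {})
        panel.append(
            NISReference(
                name=rec.id,
                siderophore=m.get("siderophore", rec.id),
                sequence=str(rec.seq).upper(),
                photolabile=m.get("photolabile", False),
                membrane_bound=m.get("membrane_bound", False),
            )
        )
    return panel


# ---------------------------------------------------------------------------
# Nearest-reference identity


def _make_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    return aligner


def pairwise_identity(seq_a: str, seq_b: str) -> float:
    """Global pairwise identity (%) between two amino-acid sequences.

    Identity = identical columns / alignment columns (gaps included), from a
    global alignment with BLOSUM62, gap open -10, gap extend -0.5.  Symmetric
    by construction (arguments are ordered canonically before aligning) and
    100.0 for identical sequences.
    """
    a, b = (seq_a.upper(), seq_b.upper())
    for s in (a, b):
        if not s:
            raise ValueError("empty sequence")
        bad = set(s) - _AA_LETTERS
        if bad:
            raise ValueError(f"unalignable alphabet: {sorted(bad)}")
    if b < a:
        a, b = b, a
    alignment = _make_aligner().align(a, b)[0]
    c = alignment.counts()
    return 100.0 * c.identities / (c.gaps + c.identities + c.mismatches)


def _nearest_reference(
    sequences: Sequence[str], panel: Sequence[NISReference]
) -> "tuple[Optional[NISReference], Optional[float], bool]":
    if not sequences:
        return None, None, False
    if not panel:
        raise ValueError("NIS reference panel is empty but sequences were supplied")
    best_ref, best_ident, tie = None, None, False
    for ref in panel:  # panel order breaks ties
        ident = max(pairwise_identity(seq, ref.sequence) for seq in sequences)
        if best_ident is None or ident > best_ident + 1e-9:
            best_ref, best_ident, tie = ref, ident, False
        elif abs(ident - best_ident) <= 1e-9:
            tie = True
    return best_ref, best_ident, tie


def call_nis_siderophore(
    bgc: BGCRecord, references: Optional[Sequence[NISReference]] = None
) -> SiderophoreCall:
    """Classify a non-NRPS cluster as NIS iff it carries >=1 iucA/iucC domain.

    When synthetase sequences are supplied, the nearest panel reference by
    global identity is reported along with its photolability / membrane
    metadata; ties on identity are broken by panel order and flagged.
    """
    count = bgc.iuc_domain_count
    if count < 1:
        return SiderophoreCall(bgc.genome_id, bgc.cluster_id, kind="none")
    panel = list(references) if references is not None else load_nis_panel()
    ref, ident, tie = _nearest_reference(bgc.synthetase_sequences, panel)
    return SiderophoreCall(
        genome_id=bgc.genome_id,
        cluster_id=bgc.cluster_id,
        kind="NIS",
        iuc_domain_count=count,
        nearest_reference=ref.name if ref else None,
        nearest_identity_pct=ident,
        tie_flag=tie,
        photolabile=ref.photolabile if ref else False,
        membrane_bound=ref.membrane_bound if ref else False,
    )


def call_nrps_siderophore(bgc: BGCRecord) -> SiderophoreCall:
    """Flag an NRPS cluster as a putative siderophore producer iff a
    TonB-dependent siderophore receptor gene is co-located in the cluster."""
    kind = (
        "NRPS_putative"
        if bgc.cluster_class == "NRPS" and bgc.has_receptor_tag
        else "none"
    )
    return SiderophoreCall(bgc.genome_id, bgc.cluster_id, kind=kind)


def call_siderophores(
    bgcs: Iterable[BGCRecord], references: Optional[Sequence[NISReference]] = None
) -> "list[SiderophoreCall]":
    """Dispatch each cluster to the NIS or NRPS rule; one call per cluster
    (no genome-level collapsing), a pure function of the genome's own BGCs."""
    calls = []
    for bgc in bgcs:
        if bgc.cluster_class == "NRPS":
            calls.append(call_nrps_siderophore(bgc))
        else:
            calls.append(call_nis_siderophore(bgc, references))
    return calls
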