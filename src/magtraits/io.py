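"""Data model and file I/O for genome annotations, trait catalogs and trait matrices.

File contracts
--------------
Annotation TSV
    Tab-delimited, UTF-8, header ``genome_id  gene_id  contig  start  end
    strand  kegg_ids  pfam_ids``.  Coordinates are 1-based inclusive (GFF
    convention).  ``kegg_ids`` / ``pfam_ids`` are semicolon-separated and may
    be empty: HMM- and KO-based annotators can emit several ids per gene, or
    none.  Copy counts for an id are the number of gene records carrying it.

Trait catalog (YAML or JSON)
    A mapping with a ``traits`` list (or a bare list).  Each entry declares
    ``trait_id``, ``category``, ``module_genes`` (KEGG orthologs), optional
    ``marker_genes`` (subset of module genes that are individually required),
    optional ``pfam_markers``, optional ``completeness_threshold`` (default
    0.5, inclusive), optional ``report_partial`` and ``rule`` flags.

Trait matrix TSV
    One row per genome, one column per trait, cells ``P``/``U``/``A``
    (present / putative / absent), with a companion completeness TSV and an
    iTOL-compatible binary-dataset text export.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from functools import cached_property
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

__all__ = [
    "FormatError",
    "CatalogError",
    "Status",
    "GeneRecord",
    "GenomeAnnotation",
    "TraitDefinition",
    "TraitCall",
    "TraitMatrix",
    "read_annotations",
    "write_annotations",
    "read_trait_catalog",
    "load_default_catalog",
    "write_trait_matrix",
    "read_trait_matrix",
    "write_itol_binary",
]

CATEGORIES = ("iron", "phosphorus", "nitrogen", "vitamin", "interaction", "other")

#: Genome-quality presets (completeness_min, redundancy_max) in percent.
#: "methods": 90% completeness and 10% redundancy; "strict": 90% and <5%.
QUALITY_PRESETS = {"methods": (90.0, 10.0), "strict": (90.0, 5.0)}

ANNOTATION_COLUMNS = (
    "genome_id",
    "gene_id",
    "contig",
    "start",
    "end",
    "strand",
    "kegg_ids",
    "pfam_ids",
)


class FormatError(ValueError):
    """Raised for malformed tabular input files."""


class CatalogError(ValueError):
    """Raised for invalid trait-catalog definitions."""


class Status(str, Enum):
    """Trait status: present, putative (evidence but rule not fully met), absent."""

    PRESENT = "present"
    PUTATIVE = "putative"
    ABSENT = "absent"

    @property
    def code(self) -> str:
        return {"present": "P", "putative": "U", "absent": "A"}[self.value]

    @classmethod
    def from_code(cls, code: str) -> "Status":
        try:
            return {"P": cls.PRESENT, "U": cls.PUTATIVE, "A": cls.ABSENT}[code]
        except KeyError:
            raise FormatError(f"unknown status code {code!r}") from None


@dataclass(frozen=True)
class GeneRecord:
    """A single predicted gene with its functional annotation."""

    gene_id: str
    contig: str
    start: int
    end: int
    strand: str
    kegg_ids: frozenset = frozenset()
    pfam_ids: frozenset = frozenset()

    def __post_init__(self):
        if not self.gene_id:
            raise ValueError("gene_id must be non-empty")
        if self.start < 1:
            raise ValueError(f"gene {self.gene_id}: start must be >= 1 (got {self.start})")
        if self.end < self.start:
            raise ValueError(
                f"gene {self.gene_id}: end < start ({self.end} < {self.start})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be '+' or '-'")
        object.__setattr__(self, "kegg_ids", frozenset(self.kegg_ids))
        object.__setattr__(self, "pfam_ids", frozenset(self.pfam_ids))


@dataclass
class GenomeAnnotation:
    """One genome's functional gene content (KEGG/PFAM ids with coordinates)."""

    genome_id: str
    genes: tuple = ()
    taxonomy: str = ""
    completeness_pct: float = 100.0
    redundancy_pct: float = 0.0

    def __post_init__(self):
        if not self.genome_id:
            raise ValueError("genome_id must be non-empty")
        if not 0.0 <= self.completeness_pct <= 100.0:
            raise ValueError(f"{self.genome_id}: completeness_pct outside [0, 100]")
        if self.redundancy_pct < 0.0:
            raise ValueError(f"{self.genome_id}: redundancy_pct must be >= 0")
        self.genes = tuple(self.genes)
        seen = set()
        for g in self.genes:
            if g.gene_id in seen:
                raise FormatError(
                    f"genome {self.genome_id}: duplicate gene_id {g.gene_id!r}"
                )
            seen.add(g.gene_id)

    @cached_property
    def kegg_counts(self) -> Counter:
        c: Counter = Counter()
        for g in self.genes:
            c.update(g.kegg_ids)
        return c

    @cached_property
    def pfam_counts(self) -> Counter:
        c: Counter = Counter()
        for g in self.genes:
            c.update(g.pfam_ids)
        return c

    def has_kegg(self, ko: str) -> bool:
        return self.kegg_counts.get(ko, 0) >= 1

    def has_pfam(self, pf: str) -> bool:
        return self.pfam_counts.get(pf, 0) >= 1

    def is_high_quality(self, preset: str = "methods") -> bool:
        cmin, rmax = QUALITY_PRESETS[preset]
        return self.completeness_pct >= cmin and self.redundancy_pct <= rmax

    def __eq__(self, other):
        if not isinstance(other, GenomeAnnotation):
            return NotImplemented
        return (
            self.genome_id == other.genome_id
            and self.genes == other.genes
            and self.taxonomy == other.taxonomy
            and self.completeness_pct == other.completeness_pct
            and self.redundancy_pct == other.redundancy_pct
        )


@dataclass(frozen=True)
class TraitDefinition:
    """A trait as an ordered KEGG gene set with optional required markers.

    ``rule`` selects how the status is called:

    * ``"completeness"`` (default) — present iff the fraction of distinct
      module genes found is >= ``completeness_threshold`` (inclusive) and
      every marker gene / PFAM marker is present.
    * ``"marker_companion"`` — present iff every marker is present and at
      least one non-marker ("companion") module gene is present; used for
      vitamin-uptake systems where a binding subunit must co-occur with its
      transporter.

    ``report_partial`` marks traits whose below-threshold evidence should be
    reported as putative rather than absent (e.g. incomplete substrate-
    specific phosphonate hydrolysis routes).
    """

    trait_id: str
    category: str
    module_genes: tuple = ()
    marker_genes: frozenset = frozenset()
    pfam_markers: frozenset = frozenset()
    completeness_threshold: float = 0.5
    report_partial: bool = False
    rule: str = "completeness"

    def __post_init__(self):
        if not self.trait_id:
            raise CatalogError("trait_id must be non-empty")
        if self.category not in CATEGORIES:
            raise CatalogError(
                f"trait {self.trait_id}: unknown category {self.category!r}"
            )
        module = tuple(dict.fromkeys(self.module_genes))
        object.__setattr__(self, "module_genes", module)
        object.__setattr__(self, "marker_genes", frozenset(self.marker_genes))
        object.__setattr__(self, "pfam_markers", frozenset(self.pfam_markers))
        if not module and not self.pfam_markers:
            raise CatalogError(
                f"trait {self.trait_id}: module_genes empty and no pfam_markers"
            )
        if not self.marker_genes <= set(module):
            extra = sorted(self.marker_genes - set(module))
            raise CatalogError(
                f"trait {self.trait_id}: marker genes not in module_genes: {extra}"
            )
        if not 0.0 < self.completeness_threshold <= 1.0:
            raise CatalogError(
                f"trait {self.trait_id}: completeness_threshold outside (0, 1]"
            )
        if self.rule not in ("completeness", "marker_companion"):
            raise CatalogError(f"trait {self.trait_id}: unknown rule {self.rule!r}")

    @property
    def companion_genes(self) -> tuple:
        return tuple(g for g in self.module_genes if g not in self.marker_genes)


@dataclass(frozen=True)
class TraitCall:
    """Status of one trait in one genome, with completeness and evidence."""

    genome_id: str
    trait_id: str
    status: Status
    completeness: float
    evidence: tuple = ()
    override_applied: bool = False
    note: str = ""


@dataclass
class TraitMatrix:
    """Genome x trait grid of trait calls."""

    genomes: tuple
    traits: tuple
    cells: dict  # (genome_id, trait_id) -> TraitCall

    def __post_init__(self):
        self.genomes = tuple(self.genomes)
        self.traits = tuple(self.traits)
        expected = {(g, t) for g in self.genomes for t in self.traits}
        if set(self.cells) != expected:
            raise ValueError("trait matrix cells do not cover genomes x traits")

    def __getitem__(self, key) -> TraitCall:
        return self.cells[key]

    def status_frame(self) -> pd.DataFrame:
        data = {
            t: [self.cells[(g, t)].status.code for g in self.genomes]
            for t in self.traits
        }
        return pd.DataFrame(data, index=list(self.genomes)).rename_axis("genome_id")

    def completeness_frame(self) -> pd.DataFrame:
        data = {
            t: [self.cells[(g, t)].completeness for g in self.genomes]
            for t in self.traits
        }
        return pd.DataFrame(data, index=list(self.genomes)).rename_axis("genome_id")

    def __eq__(self, other):
        if not isinstance(other, TraitMatrix):
            return NotImplemented
        if self.genomes != other.genomes or self.traits != other.traits:
            return False
        for key, call in self.cells.items():
            o = other.cells[key]
            if call.status != o.status or abs(call.completeness - o.completeness) > 1e-9:
                return False
        return True


# ---------------------------------------------------------------------------
# Annotation I/O


def _split_ids(raw: str) -> frozenset:
    return frozenset(x.strip() for x in str(raw).split(";") if x.strip())


def read_annotations(path) -> "dict[str, GenomeAnnotation]":
    """Read an annotation TSV into an ordered mapping genome_id -> annotation.

    Gene order is preserved per input order.  Rows with malformed or
    inconsistent coordinates are rejected with their (1-based, header
    included) row number; a missing required column or a duplicate gene_id
    within a genome raises :class:`FormatError`.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ANNOTATION_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"annotation file {path}: missing required column {col!r}")
    genomes: "dict[str, list]" = {}
    for i, row in enumerate(df.itertuples(index=False)):
        rownum = i + 2  # 1-based including header
        try:
            start, end = int(row.start), int(row.end)
        except (TypeError, ValueError):
            raise FormatError(
                f"annotation file {path}: row {rownum}: non-integer coordinates"
            ) from None
        try:
            gene = GeneRecord(
                gene_id=row.gene_id,
                contig=row.contig,
                start=start,
                end=end,
                strand=row.strand,
                kegg_ids=_split_ids(row.kegg_ids),
                pfam_ids=_split_ids(row.pfam_ids),
            )
        except ValueError as exc:
            raise FormatError(f"annotation file {path}: row {rownum}: {exc}") from None
        genomes.setdefault(row.genome_id, []).append(gene)
    out = {}
    for gid, genes in genomes.items():
        out[gid] = GenomeAnnotation(genome_id=gid, genes=tuple(genes))
    return out


def write_annotations(genomes: Mapping[str, GenomeAnnotation], path) -> Path:
    """Write annotations to a TSV readable by :func:`read_annotations`."""
    rows = []
    for genome in genomes.values():
        for g in genome.genes:
            rows.append(
                {
                    "genome_id": genome.genome_id,
                    "gene_id": g.gene_id,
                    "contig": g.contig,
                    "start": g.start,
                    "end": g.end,
                    "strand": g.strand,
                    "kegg_ids": ";".join(sorted(g.kegg_ids)),
                    "pfam_ids": ";".join(sorted(g.pfam_ids)),
                }
            )
    path = Path(path)
    pd.DataFrame(rows, columns=list(ANNOTATION_COLUMNS)).to_csv(
        path, sep="\t", index=False
    )
    return path


# ---------------------------------------------------------------------------
# Trait catalog


def _parse_trait_entry(entry: Mapping) -> TraitDefinition:
    known = {
        "trait_id",
        "category",
        "module_genes",
        "marker_genes",
        "pfam_markers",
        "completeness_threshold",
        "report_partial",
        "rule",
    }
    unknown = set(entry) - known
    if unknown:
        raise CatalogError(
            f"trait {entry.get('trait_id', '?')}: unknown fields {sorted(unknown)}"
        )
    kwargs = dict(entry)
    kwargs["module_genes"] = tuple(entry.get("module_genes") or ())
    kwargs["marker_genes"] = frozenset(entry.get("marker_genes") or ())
    kwargs["pfam_markers"] = frozenset(entry.get("pfam_markers") or ())
    return TraitDefinition(**kwargs)


def read_trait_catalog(path) -> "dict[str, TraitDefinition]":
    """Load a YAML/JSON trait catalog into an ordered mapping trait_id -> definition."""
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    if doc is None:
        raise CatalogError(f"trait catalog {path} is empty")
    entries = doc.get("traits") if isinstance(doc, Mapping) else doc
    if not isinstance(entries, Sequence) or not entries:
        raise CatalogError(f"trait catalog {path}: no trait entries found")
    catalog: "dict[str, TraitDefinition]" = {}
    for entry in entries:
        trait = _parse_trait_entry(entry)
        if trait.trait_id in catalog:
            raise CatalogError(f"duplicate trait_id {trait.trait_id!r}")
        catalog[trait.trait_id] = trait
    return catalog


def default_catalog_path() -> Path:
    return Path(resources.files("magtraits.data") / "catalog.yaml")


def load_default_catalog() -> "dict[str, TraitDefinition]":
    """Load the bundled default trait catalog (Fe/P/N/vitamin/interaction gene sets)."""
    return read_trait_catalog(default_catalog_path())


# ---------------------------------------------------------------------------
# Trait matrix I/O


def write_trait_matrix(
    matrix: TraitMatrix,
    path,
    itol: bool = True,
    itol_values: "tuple[float, float, float]" = (1.0, 0.5, 0.0),
) -> "dict[str, Path]":
    """Write status TSV + companion completeness TSV (+ optional iTOL export).

    Returns the paths written, keyed ``status``, ``completeness``, ``itol``.
    """
    path = Path(path)
    paths = {"status": path}
    matrix.status_frame().to_csv(path, sep="\t")
    comp_path = path.with_suffix(".completeness.tsv")
    matrix.completeness_frame().to_csv(comp_path, sep="\t", float_format="%.6g")
    paths["completeness"] = comp_path
    if itol:
        itol_path = path.with_suffix(".itol.txt")
        write_itol_binary(matrix, itol_path, values=itol_values)
        paths["itol"] = itol_path
    return paths


def write_itol_binary(
    matrix: TraitMatrix,
    path,
    values: "tuple[float, float, float]" = (1.0, 0.5, 0.0),
    label: str = "traits",
) -> Path:
    """Export the matrix as an iTOL binary-dataset text file.

    ``values`` maps (present, putative, absent) onto the numbers written.
    """
    value_of = {
        Status.PRESENT: values[0],
        Status.PUTATIVE: values[1],
        Status.ABSENT: values[2],
    }
    path = Path(path)
    n = len(matrix.traits)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("DATASET_BINARY\nSEPARATOR TAB\n")
        fh.write(f"DATASET_LABEL\t{label}\nCOLOR\t#2166ac\n")
        fh.write("FIELD_SHAPES\t" + "\t".join(["1"] * n) + "\n")
        fh.write("FIELD_LABELS\t" + "\t".join(matrix.traits) + "\n")
        fh.write("DATA\n")
        for g in matrix.genomes:
            vals = [f"{value_of[matrix.cells[(g, t)].status]:g}" for t in matrix.traits]
            fh.write(g + "\t" + "\t".join(vals) + "\n")
    return path


def read_trait_matrix(status_path, completeness_path=None) -> TraitMatrix:
    """Read a status TSV (+ optional companion completeness TSV) back into a matrix."""
    sdf = pd.read_csv(status_path, sep="\t", index_col=0, dtype=str)
    if completeness_path is None:
        completeness_path = Path(status_path).with_suffix(".completeness.tsv")
    cdf = None
    if Path(completeness_path).exists():
        cdf = pd.read_csv(completeness_path, sep="\t", index_col=0)
    genomes = tuple(sdf.index)
    traits = tuple(sdf.columns)
    cells = {}
    for g in genomes:
        for t in traits:
            status = Status.from_code(sdf.loc[g, t])
            comp = float(cdf.loc[g, t]) if cdf is not None else {
                Status.PRESENT: 1.0,
                Status.PUTATIVE: 0.5,
                Status.ABSENT: 0.0,
            }[status]
            cells[(g, t)] = TraitCall(g, t, status, comp)
    return TraitMatrix(genomes=genomes, traits=traits, cells=cells)


def write_json(obj, path) -> Path:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return path
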