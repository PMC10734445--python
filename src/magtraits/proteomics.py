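"""Peptide -> protein -> genome mapping statistics and NSAF normalization.

Spectral counts are credited *without consideration of peptide specificity*:
each peptide's count goes to every protein it matches, so shared peptides
are counted once per match (a ``unique_only`` switch restricts crediting to
single-match peptides for sensitivity analysis).  Two uniqueness statistics
summarize mapping ambiguity: the fraction of peptides matching exactly one
protein, and the fraction whose matched proteins all belong to one genome.

NSAF (normalized spectral abundance factor): saf_i = c_i / L_i with c_i the
protein's summed spectral count and L_i its length in residues; nsaf_i =
saf_i / sum(saf) so the column sums to 1 per sample.  Protein sequence
length is used as the length normalizer (standard NSAF); a switch selects
the summed matched-peptide length instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional

import pandas as pd
from Bio import SeqIO

from .io import FormatError

__all__ = [
    "read_peptides",
    "read_protein_fasta",
    "map_peptides",
    "nsaf",
    "MappingResult",
]


def read_peptides(path) -> pd.DataFrame:
    """Read a peptide TSV (peptide, spectral_count, protein_ids ';'-separated)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("peptide", "spectral_count", "protein_ids"):
        if col not in df.columns:
            raise FormatError(f"peptide file {path}: missing required column {col!r}")
    df["spectral_count"] = df["spectral_count"].astype(int)
    if (df["spectral_count"] < 1).any():
        raise FormatError(f"peptide file {path}: spectral_count must be >= 1")
    df["protein_ids"] = df["protein_ids"].map(
        lambda s: frozenset(x for x in s.split(";") if x)
    )
    if df["protein_ids"].map(len).eq(0).any():
        raise FormatError(f"peptide file {path}: peptide with empty protein match set")
    return df


def read_protein_fasta(path) -> pd.DataFrame:
    """Read a protein FASTA with ``genome_id|protein_id`` headers.

    Returns a frame indexed by protein_id with genome_id and length columns.
    """
    rows = []
    for rec in SeqIO.parse(str(path), "fasta"):
        if "|" not in rec.id:
            raise FormatError(f"protein fasta {path}: header {rec.id!r} lacks genome tag")
        genome_id, protein_id = rec.id.split("|", 1)
        rows.append(
            {"protein_id": protein_id, "genome_id": genome_id, "length": len(rec.seq)}
        )
    return pd.DataFrame(rows).set_index("protein_id")


@dataclass
class MappingResult:
    """Peptide-mapping outcome: per-protein counts plus uniqueness statistics."""

    protein_counts: pd.DataFrame  # index protein_id; genome_id, length, spectral_count
    unique_protein_fraction: float
    single_genome_fraction: float
    n_peptides: int
    total_spectral_counts: int


def map_peptides(
    peptides: pd.DataFrame,
    proteins: pd.DataFrame,
    unique_only: bool = False,
) -> MappingResult:
    """Map peptides onto labelled proteins and accumulate spectral counts.

    ``peptides`` as from :func:`read_peptides`; ``proteins`` indexed by
    protein_id with ``genome_id`` and ``length`` columns.  A peptide
    referencing an unknown protein raises :class:`FormatError`.
    """
    counts = {pid: 0 for pid in proteins.index}
    n_unique = 0
    n_single_genome = 0
    for row in peptides.itertuples(index=False):
        matched = row.protein_ids
        missing = [p for p in matched if p not in counts]
        if missing:
            raise FormatError(
                f"peptide {row.peptide!r} references unknown protein {missing[0]!r}"
            )
        if len(matched) == 1:
            n_unique += 1
        genomes = {proteins.loc[p, "genome_id"] for p in matched}
        if len(genomes) == 1:
            n_single_genome += 1
        if unique_only and len(matched) > 1:
            continue
        for p in matched:
            counts[p] += row.spectral_count
    out = proteins.copy()
    out["spectral_count"] = pd.Series(counts)
    n = len(peptides)
    return MappingResult(
        protein_counts=out,
        unique_protein_fraction=n_unique / n if n else 0.0,
        single_genome_fraction=n_single_genome / n if n else 0.0,
        n_peptides=n,
        total_spectral_counts=int(out["spectral_count"].sum()),
    )


def nsaf(protein_counts: pd.DataFrame) -> "tuple[pd.DataFrame, pd.DataFrame]":
    """Compute SAF/NSAF per protein and summed NSAF per genome.

    ``protein_counts`` is indexed by protein_id with ``genome_id``,
    ``length`` (residues, >= 1) and ``spectral_count`` (>= 0, at least one
    positive) columns.  NSAF sums to 1 over proteins; scale-invariant in the
    counts.
    """
    if (protein_counts["length"] < 1).any():
        raise ValueError("protein length must be >= 1")
    if (protein_counts["spectral_count"] < 0).any():
        raise ValueError("negative spectral counts")
    if not (protein_counts["spectral_count"] > 0).any():
        raise ValueError("all spectral counts are zero")
    out = protein_counts.copy()
    out["saf"] = out["spectral_count"] / out["length"]
    out["nsaf"] = out["saf"] / out["saf"].sum()
    genome = (
        out.groupby("genome_id")["nsaf"].sum().rename("nsaf").to_frame().sort_index()
    )
    return out, genome


def write_nsaf(out: pd.DataFrame, genome: pd.DataFrame, out_dir) -> "dict[str, Path]":
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    p1 = out_dir / "nsaf_proteins.tsv"
    p2 = out_dir / "nsaf_genomes.tsv"
    out.to_csv(p1, sep="\t", float_format="%.8g")
    genome.to_csv(p2, sep="\t", float_format="%.8g")
    return {"proteins": p1, "genomes": p2}
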