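"""Whole-consortium analysis: trait matrix, category profiles, and summary.

Ties the generic engine to the category-specific rule modules: the catalog
trait matrix is computed first, then nitrogen pathway profiles, Fe-uptake
profiles, phosphorus interpretations, vitamin classifications, siderophore
calls and interaction-trait adjustments are derived from the same genomes
and appended as companion tables / derived matrix columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional

import pandas as pd

from .engine import Override, build_trait_matrix
from .io import (
    GenomeAnnotation,
    Status,
    TraitCall,
    TraitDefinition,
    TraitMatrix,
    load_default_catalog,
    write_trait_matrix,
)
from .iron import BGCRecord, FeUptakeProfile, NISReference, call_siderophores, classify_fe_uptake
from .nitrogen import (
    DENIT_STEPS,
    NPathwayProfile,
    assign_n_pathways,
    consortium_denitrification_completeness,
)
from .phosvit import (
    VITAMINS,
    PProfile,
    VitaminStatus,
    call_interaction_traits,
    call_p_profile,
    call_vitamin_status,
)

__all__ = ["AnalysisResult", "analyze", "write_analysis"]

_DERIVED_STATUS_VALUE = {
    Status.PRESENT: 1.0,
    Status.PUTATIVE: 0.5,
    Status.ABSENT: 0.0,
}


@dataclass
class AnalysisResult:
    matrix: TraitMatrix
    derived_matrix: TraitMatrix
    n_profiles: "dict[str, NPathwayProfile]"
    fe_profiles: "dict[str, FeUptakeProfile]"
    p_profiles: "dict[str, PProfile]"
    vitamin_statuses: "dict[str, dict[str, VitaminStatus]]"  # genome -> vitamin -> status
    siderophore_calls: list
    denitrification: dict
    summary: dict


def _derived_cells(
    genome_id: str, n: NPathwayProfile, vits: Mapping[str, VitaminStatus], p: PProfile
) -> "dict[str, Status]":
    cells = {
        "n2_fixation": n.n2_fixation,
        "anra": n.anra,
        "dnra": n.dnra,
    }
    for label, status in zip(DENIT_STEPS, n.denitrification_steps):
        cells[f"denit_{label}"] = status
    for v in VITAMINS:
        cells[f"vit{v}_auxotrophy"] = (
            Status.PRESENT if vits[v].classification == "auxotroph" else Status.ABSENT
        )
    cells["p_reduced_metabolism"] = (
        Status.PRESENT
        if p.phn_transporter_interpretation in ("phosphonate_linked", "phosphite_linked", "both")
        else Status.PUTATIVE if p.phn_transporter_interpretation == "ambiguous"
        else Status.ABSENT
    )
    return cells


def analyze(
    genomes: Mapping[str, GenomeAnnotation],
    catalog: Optional[Mapping[str, TraitDefinition]] = None,
    bgcs: Iterable[BGCRecord] = (),
    overrides: Iterable[Override] = (),
    nis_panel: Optional[Iterable[NISReference]] = None,
    nif_strict: bool = True,
) -> AnalysisResult:
    """Run the full trait analysis for a genome collection."""
    if not genomes:
        raise ValueError("no genomes supplied")
    catalog = catalog if catalog is not None else load_default_catalog()
    bgcs = list(bgcs)
    matrix = build_trait_matrix(genomes, catalog, overrides)

    n_profiles, fe_profiles, p_profiles, vitamin_statuses = {}, {}, {}, {}
    for gid, genome in genomes.items():
        n_profiles[gid] = assign_n_pathways(genome, nif_strict=nif_strict)
        fe_profiles[gid] = classify_fe_uptake(genome)
        p_profiles[gid] = call_p_profile(genome, catalog)
        vitamin_statuses[gid] = {
            v: call_vitamin_status(genome, v, catalog) for v in VITAMINS
        }
        # interaction traits may pick up BGC-borne AHL evidence
        for tid, call in call_interaction_traits(genome, bgcs, catalog).items():
            matrix.cells[(gid, tid)] = call

    siderophore_calls = call_siderophores(
        bgcs, list(nis_panel) if nis_panel is not None else None
    )
    denitrification = consortium_denitrification_completeness(n_profiles.values())

    derived_traits = None
    derived_cells = dict(matrix.cells)
    for gid in genomes:
        extra = _derived_cells(
            gid, n_profiles[gid], vitamin_statuses[gid], p_profiles[gid]
        )
        if derived_traits is None:
            derived_traits = tuple(matrix.traits) + tuple(extra)
        for tid, status in extra.items():
            derived_cells[(gid, tid)] = TraitCall(
                genome_id=gid,
                trait_id=tid,
                status=status,
                completeness=_DERIVED_STATUS_VALUE[status],
            )
    derived_matrix = TraitMatrix(
        genomes=matrix.genomes, traits=derived_traits, cells=derived_cells
    )

    summary = _summarize(
        genomes, matrix, n_profiles, fe_profiles, p_profiles, vitamin_statuses,
        siderophore_calls, denitrification,
    )
    return AnalysisResult(
        matrix=matrix,
        derived_matrix=derived_matrix,
        n_profiles=n_profiles,
        fe_profiles=fe_profiles,
        p_profiles=p_profiles,
        vitamin_statuses=vitamin_statuses,
        siderophore_calls=siderophore_calls,
        denitrification=denitrification,
        summary=summary,
    )


def _summarize(
    genomes, matrix, n_profiles, fe_profiles, p_profiles, vitamin_statuses,
    siderophore_calls, denitrification,
) -> dict:
    n2_fixers = [
        g for g, p in n_profiles.items() if p.n2_fixation is Status.PRESENT
    ]
    auxotrophic = [
        g
        for g, vits in vitamin_statuses.items()
        if any(v.classification == "auxotroph" for v in vits.values())
    ]
    interp_counts: "dict[str, int]" = {}
    for p in p_profiles.values():
        interp_counts[p.phn_transporter_interpretation] = (
            interp_counts.get(p.phn_transporter_interpretation, 0) + 1
        )
    producers = sorted(
        {c.genome_id for c in siderophore_calls if c.kind in ("NIS", "NRPS_putative")}
    )
    ahl_genomes = [
        g
        for g in matrix.genomes
        if matrix.cells[(g, "ahl_biosynthesis")].status is Status.PRESENT
    ] if "ahl_biosynthesis" in matrix.traits else []
    return {
        "n_genomes": len(genomes),
        "n_high_quality": sum(1 for g in genomes.values() if g.is_high_quality()),
        "n2_fixing_genomes": n2_fixers,
        "n_n2_fixers": len(n2_fixers),
        "denitrification_collectively_complete": denitrification[
            "collectively_complete"
        ],
        "n_auxotrophic_any_vitamin": len(auxotrophic),
        "phn_interpretation_counts": interp_counts,
        "siderophore_producers": producers,
        "n_siderophore_producers": len(producers),
        "n_ahl_genomes": len(ahl_genomes),
    }


def render_summary(summary: dict) -> str:
    lines = [
        f"genomes analyzed: {summary['n_genomes']}",
        f"high-quality genomes: {summary['n_high_quality']}",
        f"genomes with full N2-fixation module: {summary['n_n2_fixers']}"
        + (
            f" ({', '.join(summary['n2_fixing_genomes'])})"
            if summary["n2_fixing_genomes"]
            else ""
        ),
        "denitrification collectively complete: "
        + ("yes" if summary["denitrification_collectively_complete"] else "no"),
        f"genomes auxotrophic for >=1 vitamin: {summary['n_auxotrophic_any_vitamin']}",
        "phn transporter interpretations: "
        + ", ".join(
            f"{k}={v}" for k, v in sorted(summary["phn_interpretation_counts"].items())
        ),
        f"siderophore-producing genomes: {summary['n_siderophore_producers']}",
        f"genomes with AHL biosynthesis: {summary['n_ahl_genomes']}",
    ]
    return "\n".join(lines) + "\n"


def write_analysis(result: AnalysisResult, out_dir) -> "dict[str, Path]":
    """Write all report tables (trait matrix, per-category profiles, summary)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = write_trait_matrix(result.matrix, out_dir / "trait_matrix.tsv")
    dm = write_trait_matrix(
        result.derived_matrix, out_dir / "trait_matrix_derived.tsv", itol=True
    )
    paths["derived"] = dm["status"]
    tables = {
        "nitrogen_profiles.tsv": pd.DataFrame(
            [p.as_row() for p in result.n_profiles.values()]
        ),
        "fe_profiles.tsv": pd.DataFrame(
            [p.as_row() for p in result.fe_profiles.values()]
        ),
        "p_profiles.tsv": pd.DataFrame(
            [p.as_row() for p in result.p_profiles.values()]
        ),
        "vitamin_status.tsv": pd.DataFrame(
            [
                v.as_row()
                for vits in result.vitamin_statuses.values()
                for v in vits.values()
            ]
        ),
        "siderophore_calls.tsv": pd.DataFrame(
            [c.as_row() for c in result.siderophore_calls]
        ),
    }
    for name, df in tables.items():
        p = out_dir / name
        df.to_csv(p, sep="\t", index=False)
        paths[name] = p
    sp = out_dir / "summary.txt"
    with open(sp, "w", encoding="utf-8") as fh:
        fh.write(render_summary(result.summary))
    paths["summary"] = sp
    return paths
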