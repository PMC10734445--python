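"""Synthetic consortium generator with planted ground truth.

Produces every input the pipeline consumes — annotation tables, BGC records,
genome sequences, read-count tables, peptide tables — together with truth
sidecars, so every stage is testable without external data.  The generator
emulates the statistical structure of a diazotroph colony metagenome: one
dominant host genome holding ~71% of the reads across three samples, ~51
low-abundance epibiont genomes carrying a configurable trait matrix, per-gene
annotation dropout, decoy KEGG ids, and a host-dominated peptide table.

Planted statuses are constructed to be exactly recoverable by the trait
engine at zero noise: *present* plants the full module, *putative* plants an
at-threshold subset missing one marker (or a below-threshold partial pathway
for report-partial traits), *absent* plants a strictly below-threshold
subset.  Dropout applies per gene, not per trait, so partial pathways arise
naturally once noise is switched on.  All randomness is driven by the
mandatory seed.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import iron
from .io import (
    GeneRecord,
    GenomeAnnotation,
    Status,
    TraitDefinition,
    load_default_catalog,
    write_annotations,
    write_json,
)

__all__ = [
    "SimConfig",
    "SimResult",
    "generate_annotations",
    "random_trait_truth",
    "paper_like_truth",
    "generate_bgcs",
    "generate_sequence_pairs",
    "generate_counts",
    "generate_peptides",
    "simulate_consortium",
    "mutate_dna",
    "mutate_protein",
    "random_dna",
]

DNA = np.array(list("ACGT"))
AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


@dataclass
class SimConfig:
    """Study-structure parameters of the synthetic consortium.

    Defaults mirror the emulated colony data set: 52 genomes, the host
    (genome 1) at a 0.71 read fraction with cross-sample sd 0.06, three
    samples, and zero annotation noise.
    """

    seed: int
    n_genomes: int = 52
    n_samples: int = 3
    host_fraction: float = 0.71
    host_fraction_sd: float = 0.06
    dropout_rate: float = 0.0
    decoy_rate: float = 0.0
    trait_prevalence: float = 0.35
    putative_rate: float = 0.1
    total_reads_per_sample: int = 1_000_000

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for name in ("dropout_rate", "trait_prevalence", "putative_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} outside [0, 1]")
        if self.decoy_rate < 0:  # expected decoy KOs per genome (Poisson mean)
            raise ValueError("decoy_rate must be >= 0")
        if not 0.0 < self.host_fraction < 1.0:
            raise ValueError("host_fraction outside (0, 1)")
        if self.n_genomes < 1 or self.n_samples < 1:
            raise ValueError("n_genomes and n_samples must be >= 1")


def genome_ids(n: int) -> "list[str]":
    return [f"MAG{i:02d}" for i in range(1, n + 1)]


# ---------------------------------------------------------------------------
# Planted trait statuses


def _min_present_hits(trait: TraitDefinition) -> int:
    n = len(trait.module_genes)
    return int(math.ceil(trait.completeness_threshold * n - 1e-9))


def putative_capable(trait: TraitDefinition) -> bool:
    """Whether a putative status can be planted and recovered for this trait."""
    if not trait.module_genes:
        return False  # PFAM-only traits are binary
    if trait.rule == "marker_companion":
        return bool(trait.companion_genes)
    n = len(trait.module_genes)
    if trait.marker_genes and n >= 2 and (n - 1) / n >= trait.completeness_threshold:
        return True
    if trait.report_partial and 1 / n < trait.completeness_threshold:
        return bool(trait.companion_genes)
    return False


def genes_for_status(
    trait: TraitDefinition, status: Status, rng: np.random.Generator
) -> "tuple[tuple, tuple]":
    """KEGG and PFAM ids to emit so the engine recovers ``status`` exactly."""
    module = trait.module_genes
    pfams = tuple(sorted(trait.pfam_markers))
    if status is Status.PRESENT:
        return module, pfams
    if status is Status.PUTATIVE:
        if not putative_capable(trait):
            raise ValueError(
                f"trait {trait.trait_id}: putative status cannot be planted"
            )
        if trait.rule == "marker_companion":
            return trait.companion_genes, pfams
        n = len(module)
        if trait.marker_genes and (n - 1) / n >= trait.completeness_threshold:
            dropped = sorted(trait.marker_genes)[
                int(rng.integers(len(trait.marker_genes)))
            ]
            return tuple(g for g in module if g != dropped), pfams
        # report-partial route: one non-marker gene, below threshold
        choice = trait.companion_genes[int(rng.integers(len(trait.companion_genes)))]
        return (choice,), ()
    # absent
    if not module or trait.report_partial or trait.rule == "marker_companion":
        return (), ()
    max_hits = _min_present_hits(trait) - 1
    k = int(rng.integers(0, max_hits + 1))
    if k == 0:
        return (), ()
    idx = rng.choice(len(module), size=k, replace=False)
    return tuple(module[i] for i in sorted(idx)), ()


def random_trait_truth(
    catalog: Mapping[str, TraitDefinition],
    ids: Sequence[str],
    rng: np.random.Generator,
    prevalence: float = 0.35,
    putative_rate: float = 0.1,
    per_trait_prevalence: Optional[Mapping[str, float]] = None,
) -> pd.DataFrame:
    """Random planted status matrix (genome x trait, values present/putative/absent)."""
    data = {}
    for tid, trait in catalog.items():
        p = (per_trait_prevalence or {}).get(tid, prevalence)
        u = rng.random(len(ids))
        statuses = np.where(u < p, Status.PRESENT.value, Status.ABSENT.value)
        if putative_rate > 0 and putative_capable(trait):
            flip = (u < p) & (rng.random(len(ids)) < putative_rate)
            statuses = np.where(flip, Status.PUTATIVE.value, statuses)
        data[tid] = statuses
    return pd.DataFrame(data, index=list(ids)).rename_axis("genome_id")


def generate_annotations(
    config: SimConfig,
    catalog: Optional[Mapping[str, TraitDefinition]] = None,
    trait_truth: Optional[pd.DataFrame] = None,
    rng: Optional[np.random.Generator] = None,
) -> "tuple[dict, pd.DataFrame]":
    """Emit genome annotations realizing a planted truth matrix.

    Returns (genomes, trait_truth).  At ``dropout_rate=0`` and
    ``decoy_rate=0`` the trait engine reproduces the truth cell-for-cell;
    dropout removes emitted genes independently and decoy KEGG ids are drawn
    from outside every catalog module.
    """
    catalog = catalog if catalog is not None else load_default_catalog()
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    ids = genome_ids(config.n_genomes)
    if trait_truth is None:
        trait_truth = random_trait_truth(
            catalog,
            ids,
            rng,
            prevalence=config.trait_prevalence,
            putative_rate=config.putative_rate,
        )
    else:
        unknown = set(trait_truth.columns) - set(catalog)
        if unknown:
            raise ValueError(f"trait_truth references unknown traits: {sorted(unknown)}")
        ids = list(trait_truth.index)

    all_module_kos = {ko for t in catalog.values() for ko in t.module_genes}
    genomes = {}
    for gid in ids:
        keggs: "list[str]" = []
        pfams: "list[str]" = []
        for tid in trait_truth.columns:
            status = Status(trait_truth.loc[gid, tid])
            ks, ps = genes_for_status(catalog[tid], status, rng)
            keggs.extend(ks)
            pfams.extend(ps)
        n_decoys = int(rng.poisson(config.decoy_rate)) if config.decoy_rate else 0
        for _ in range(n_decoys):
            ko = f"K99{int(rng.integers(0, 1000)):03d}"
            if ko not in all_module_kos:
                keggs.append(ko)
        genes = []
        pos = 1
        idx = 0
        for ko in keggs:
            if config.dropout_rate and rng.random() < config.dropout_rate:
                pos += 1000
                continue
            idx += 1
            genes.append(
                GeneRecord(
                    gene_id=f"{gid}_g{idx:04d}",
                    contig=f"{gid}_c1",
                    start=pos,
                    end=pos + 899,
                    strand="+",
                    kegg_ids=frozenset([ko]),
                )
            )
            pos += 1000
        for pf in pfams:
            if config.dropout_rate and rng.random() < config.dropout_rate:
                pos += 1000
                continue
            idx += 1
            genes.append(
                GeneRecord(
                    gene_id=f"{gid}_g{idx:04d}",
                    contig=f"{gid}_c1",
                    start=pos,
                    end=pos + 899,
                    strand="+",
                    pfam_ids=frozenset([pf]),
                )
            )
            pos += 1000
        genomes[gid] = GenomeAnnotation(genome_id=gid, genes=tuple(genes))
    return genomes, trait_truth


# ---------------------------------------------------------------------------
# Paper-like preset truth


def paper_like_truth(
    catalog: Mapping[str, TraitDefinition],
    n_genomes: int = 52,
    rng: Optional[np.random.Generator] = None,
) -> pd.DataFrame:
    """Demo preset: a host genome with the dominant diazotroph's trait vector
    (full N2-fixation module; phosphate, phosphonate/phosphite transport with
    C-P lyase and phosphite dehydrogenase; B1/B7/B12 biosynthesis; ferrous +
    ferric uptake only with a partial TonB system; assimilatory nitrite
    reduction plus an unassigned NO reductase) and epibionts drawn with
    field-like trait prevalences."""
    rng = rng if rng is not None else np.random.default_rng(0)
    ids = genome_ids(n_genomes)
    host, epibionts = ids[0], ids[1:]
    prevalence = {
        "nif": 0.0,
        "fe2_uptake": 0.8, "fe3_uptake": 0.7, "heme_uptake": 0.5,
        "citrate_uptake": 0.4, "siderophore_uptake": 0.7, "tonb_system": 0.8,
        "pst_transporter": 0.7, "pit_transporter": 0.4, "phn_transporter": 0.47,
        "cp_lyase": 0.3, "ptxD": 0.08, "aep_hydrolysis": 0.14,
        "phoA": 0.4, "phoX": 0.4, "phoD": 0.3,
        "napAB": 0.15, "narGHI": 0.2, "narB": 0.1, "nasA": 0.37,
        "nrfAH": 0.02, "nirA": 0.2, "nirBD": 0.4, "nirS": 0.05, "nirK": 0.15,
        "norBC": 0.2, "nosZ": 0.06,
        "vitB1_biosynthesis": 0.5, "vitB1_uptake": 0.5,
        "vitB7_biosynthesis": 0.5, "vitB7_uptake": 0.5,
        "vitB12_biosynthesis": 0.3, "vitB12_uptake": 0.7,
        "ahl_biosynthesis": 0.29, "quorum_sensing_regulation": 0.3,
        "secretion_sec_srp": 0.8, "pilus_adhesion": 0.5,
        "flagellar_motility": 0.5, "metal_efflux": 0.4, "metal_storage": 0.5,
    }
    truth = random_trait_truth(
        catalog, epibionts, rng, putative_rate=0.1, per_trait_prevalence=prevalence
    )
    host_present = {
        "nif", "pst_transporter", "phn_transporter", "cp_lyase", "ptxD",
        "phoA", "phoX", "vitB1_biosynthesis", "vitB7_biosynthesis",
        "vitB12_biosynthesis", "fe2_uptake", "fe3_uptake", "nirA", "norBC",
        "ahl_biosynthesis", "secretion_sec_srp", "pilus_adhesion",
        "metal_storage",
    }
    host_putative = {"tonb_system"}
    host_row = {
        tid: (
            Status.PRESENT.value
            if tid in host_present
            else Status.PUTATIVE.value if tid in host_putative else Status.ABSENT.value
        )
        for tid in catalog
    }
    truth = pd.concat(
        [pd.DataFrame([host_row], index=[host]).rename_axis("genome_id"), truth]
    )
    return truth


# ---------------------------------------------------------------------------
# Sequence helpers


def random_dna(length: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(DNA, size=length))


def mutate_dna(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Uniform substitutions at ``rate``; substituted sites always change base."""
    arr = np.array(list(seq))
    sites = rng.random(len(arr)) < rate
    for i in np.nonzero(sites)[0]:
        choices = DNA[DNA != arr[i]]
        arr[i] = choices[int(rng.integers(3))]
    return "".join(arr)


def mutate_protein(seq: str, rate: float, rng: np.random.Generator) -> str:
    arr = np.array(list(seq))
    sites = rng.random(len(arr)) < rate
    for i in np.nonzero(sites)[0]:
        choices = AA[AA != arr[i]]
        arr[i] = choices[int(rng.integers(len(choices)))]
    return "".join(arr)


def generate_sequence_pairs(
    targets: Sequence[float],
    length: int,
    rng: np.random.Generator,
) -> "tuple[dict, dict, pd.DataFrame]":
    """Generate (set_a, set_b) sequence pairs at given target identities.

    Each target in (0, 1] yields a random sequence and a copy mutated by
    uniform substitution at rate 1 - identity; the truth frame records the
    realized per-site identity of each ungapped pair.
    """
    seqs_a, seqs_b, rows = {}, {}, []
    for i, ident in enumerate(targets):
        if not 0.0 < ident <= 1.0:
            raise ValueError(f"target identity {ident} outside (0, 1]")
        name = f"pair{i:02d}"
        a = random_dna(length, rng)
        b = mutate_dna(a, 1.0 - ident, rng)
        realized = sum(x == y for x, y in zip(a, b)) / length
        seqs_a[f"{name}_a"] = a
        seqs_b[f"{name}_b"] = b
        rows.append(
            {
                "pair": name,
                "genome_a": f"{name}_a",
                "genome_b": f"{name}_b",
                "target_identity_pct": 100.0 * ident,
                "true_identity_pct": 100.0 * realized,
            }
        )
    return seqs_a, seqs_b, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# BGCs


def generate_bgcs(
    assignments: Sequence["tuple[str, str, Optional[str]]"],
    rng: np.random.Generator,
    panel: Optional[Sequence[iron.NISReference]] = None,
    mutation_rate: float = 0.1,
) -> "tuple[list, list]":
    """Generate BGC records from (genome_id, kind, reference_name) plans.

    ``kind`` is one of ``NIS`` (iuc-domain cluster whose synthetase sequence
    is the named panel reference mutated at ``mutation_rate``),
    ``NRPS_putative`` (NRPS cluster with a co-located TBDT receptor gene),
    ``NRPS_none`` (NRPS without receptor) or ``none`` (other-class decoy).
    Returns (records, truth rows).
    """
    panel = list(panel) if panel is not None else iron.load_nis_panel()
    by_name = {ref.name: ref for ref in panel}
    records, truth = [], []
    counters: "dict[str, int]" = {}
    for genome_id, kind, ref_name in assignments:
        counters[genome_id] = counters.get(genome_id, 0) + 1
        cid = f"{genome_id}_bgc{counters[genome_id]}"
        start = 1000
        genes = []
        seqs: "tuple[str, ...]" = ()
        if kind == "NIS":
            ref = by_name[ref_name]
            genes = [
                iron.BGCGene(f"{cid}_g1", start, start + 999, {iron.IUC_PFAM: 1}),
                iron.BGCGene(f"{cid}_g2", start + 1000, start + 1999, {iron.IUC_PFAM: 1}),
            ]
            seqs = (mutate_protein(ref.sequence, mutation_rate, rng),)
            cls, expected = "NIS", "NIS"
        elif kind in ("NRPS_putative", "NRPS_none"):
            genes = [iron.BGCGene(f"{cid}_g1", start, start + 999, {})]
            if kind == "NRPS_putative":
                genes.append(
                    iron.BGCGene(
                        f"{cid}_g2", start + 1000, start + 1999, {}, (iron.TBDT_TAG,)
                    )
                )
            cls = "NRPS"
            expected = "NRPS_putative" if kind == "NRPS_putative" else "none"
        elif kind == "none":
            genes = [iron.BGCGene(f"{cid}_g1", start, start + 999, {})]
            cls, expected = "other", "none"
        else:
            raise ValueError(f"unknown BGC plan kind {kind!r}")
        records.append(
            iron.BGCRecord(
                genome_id=genome_id,
                cluster_id=cid,
                contig=f"{genome_id}_c1",
                start=1,
                end=start + 3000,
                cluster_class=cls,
                genes=tuple(genes),
                synthetase_sequences=seqs,
            )
        )
        truth.append(
            {
                "genome_id": genome_id,
                "cluster_id": cid,
                "expected_kind": expected,
                "expected_reference": ref_name or "",
            }
        )
    return records, truth


# ---------------------------------------------------------------------------
# Counts and peptides


def generate_counts(
    config: SimConfig, rng: Optional[np.random.Generator] = None
) -> "tuple[pd.DataFrame, pd.DataFrame]":
    """Read-count table: host at host_fraction +/- jitter, Dirichlet epibionts."""
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    ids = genome_ids(config.n_genomes)
    samples = [f"S{i + 1}" for i in range(config.n_samples)]
    rows, truth_rows = [], []
    for s in samples:
        hf = float(
            np.clip(rng.normal(config.host_fraction, config.host_fraction_sd), 0.05, 0.95)
        )
        if config.n_genomes > 1:
            rest = rng.dirichlet(np.ones(config.n_genomes - 1)) * (1.0 - hf)
            fracs = np.concatenate([[hf], rest])
        else:
            fracs = np.array([1.0])
        counts = np.floor(fracs * config.total_reads_per_sample).astype(int)
        counts[0] += config.total_reads_per_sample - counts.sum()
        rows.append(counts)
        truth_rows.append({"sample": s, "host_fraction": counts[0] / counts.sum()})
    counts_df = pd.DataFrame(rows, index=samples, columns=ids).rename_axis("sample")
    return counts_df, pd.DataFrame(truth_rows).set_index("sample")


def generate_peptides(
    genomes: Sequence[str],
    rng: np.random.Generator,
    n_peptides: int = 500,
    unique_fraction: float = 0.916,
    single_genome_fraction: float = 0.927,
    host_count_weight: float = 0.9,
    proteins_per_genome: int = 3,
) -> "tuple[pd.DataFrame, pd.DataFrame, dict]":
    """Peptide table + labelled protein collection with planted uniqueness.

    Exactly ``round(unique_fraction * n)`` peptides map to a single protein
    and ``round(single_genome_fraction * n)`` map within a single genome;
    spectral counts are biased toward the host (first genome) by
    ``host_count_weight``.
    """
    if single_genome_fraction < unique_fraction:
        raise ValueError("single_genome_fraction must be >= unique_fraction")
    host = genomes[0]
    prot_rows = []
    for gid in genomes:
        for j in range(proteins_per_genome):
            prot_rows.append(
                {
                    "protein_id": f"{gid}_p{j + 1}",
                    "genome_id": gid,
                    "length": int(rng.integers(100, 400)),
                }
            )
    proteins = pd.DataFrame(prot_rows).set_index("protein_id")
    host_prots = [p for p in proteins.index if proteins.loc[p, "genome_id"] == host]
    other_prots = [p for p in proteins.index if proteins.loc[p, "genome_id"] != host]

    n_unique = round(unique_fraction * n_peptides)
    n_single_genome = round(single_genome_fraction * n_peptides)
    n_shared_same = n_single_genome - n_unique  # shared within one genome
    pep_rows = []
    for i in range(n_peptides):
        if i < n_unique:
            pool = host_prots if rng.random() < host_count_weight else other_prots
            matched = frozenset([pool[int(rng.integers(len(pool)))]])
        elif i < n_single_genome:
            gid = genomes[int(rng.integers(len(genomes)))]
            prots = [p for p in proteins.index if proteins.loc[p, "genome_id"] == gid]
            pick = rng.choice(len(prots), size=2, replace=False)
            matched = frozenset(prots[j] for j in pick)
        else:
            g1, g2 = rng.choice(len(genomes), size=2, replace=False)
            matched = frozenset(
                [
                    f"{genomes[g1]}_p1",
                    f"{genomes[g2]}_p1",
                ]
            )
        count = int(rng.integers(1, 20))
        pep_rows.append(
            {
                "peptide": f"PEP{i:05d}",
                "spectral_count": count,
                "protein_ids": matched,
            }
        )
    peptides = pd.DataFrame(pep_rows)
    truth = {
        "unique_protein_fraction": n_unique / n_peptides,
        "single_genome_fraction": n_single_genome / n_peptides,
        "n_peptides": n_peptides,
        "n_shared_same_genome": n_shared_same,
    }
    return peptides, proteins, truth


# ---------------------------------------------------------------------------
# Whole-consortium driver


@dataclass
class SimResult:
    """Everything one simulated consortium comprises, plus its planted truth."""

    config: SimConfig
    genomes: "dict[str, GenomeAnnotation]"
    trait_truth: pd.DataFrame
    bgcs: list
    bgc_truth: list
    counts: pd.DataFrame
    counts_truth: pd.DataFrame
    peptides: pd.DataFrame
    proteins: pd.DataFrame
    peptide_truth: dict


def _paper_like_bgc_plan(ids: Sequence[str]) -> "list[tuple]":
    """Four NIS producers, six receptor-coupled NRPS producers, four decoys."""
    nis = [
        (ids[9], "NIS", "petrobactin_synthetase"),
        (ids[22], "NIS", "vibrioferrin_synthetase"),
        (ids[10], "NIS", "vibrioferrin_synthetase"),
        (ids[7], "NIS", "rhizoferrin_synthetase"),
    ]
    nrps = [(ids[i], "NRPS_putative", None) for i in (46, 17, 27, 32, 40, 44)]
    decoys = [
        (ids[3], "NRPS_none", None),
        (ids[5], "NRPS_none", None),
        (ids[12], "none", None),
        (ids[19], "none", None),
    ]
    return nis + nrps + decoys


def simulate_consortium(
    config: SimConfig,
    catalog: Optional[Mapping[str, TraitDefinition]] = None,
    preset: str = "random",
    out_dir=None,
) -> SimResult:
    """Generate a full synthetic consortium (annotations, BGCs, counts, peptides).

    ``preset="paper_like"`` plants the host trait vector and field-like
    epibiont prevalences; ``preset="random"`` draws statuses at the config's
    trait prevalence.  When ``out_dir`` is given, all file contracts plus
    truth sidecars are written there.
    """
    catalog = catalog if catalog is not None else load_default_catalog()
    rng = np.random.default_rng(config.seed)
    ids = genome_ids(config.n_genomes)
    if preset == "paper_like":
        truth = paper_like_truth(catalog, config.n_genomes, rng)
    elif preset == "random":
        truth = None
    else:
        raise ValueError(f"unknown preset {preset!r}")
    genomes, trait_truth = generate_annotations(config, catalog, truth, rng)
    if preset == "paper_like":
        plan = _paper_like_bgc_plan(ids)
    else:
        n_bgc = max(2, config.n_genomes // 10)
        kinds = ["NIS", "NRPS_putative", "NRPS_none", "none"]
        panel = iron.load_nis_panel()
        plan = []
        for i in range(n_bgc):
            kind = kinds[i % len(kinds)]
            ref = panel[int(rng.integers(len(panel)))].name if kind == "NIS" else None
            plan.append((ids[int(rng.integers(len(ids)))], kind, ref))
    bgcs, bgc_truth = generate_bgcs(plan, rng)
    counts, counts_truth = generate_counts(config, rng)
    peptides, proteins, peptide_truth = generate_peptides(ids, rng)
    result = SimResult(
        config=config,
        genomes=genomes,
        trait_truth=trait_truth,
        bgcs=bgcs,
        bgc_truth=bgc_truth,
        counts=counts,
        counts_truth=counts_truth,
        peptides=peptides,
        proteins=proteins,
        peptide_truth=peptide_truth,
    )
    if out_dir is not None:
        write_sim_result(result, out_dir)
    return result


def write_sim_result(result: SimResult, out_dir) -> "dict[str, Path]":
    """Write every simulated file contract plus truth sidecars."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    paths["annotations"] = write_annotations(
        result.genomes, out_dir / "annotations.tsv"
    )
    truth_path = out_dir / "truth_traits.tsv"
    result.trait_truth.to_csv(truth_path, sep="\t")
    paths["trait_truth"] = truth_path
    paths["bgcs"] = iron.write_bgcs(result.bgcs, out_dir / "bgcs.json")
    bt = out_dir / "truth_bgcs.tsv"
    pd.DataFrame(result.bgc_truth).to_csv(bt, sep="\t", index=False)
    paths["bgc_truth"] = bt
    cp = out_dir / "counts.tsv"
    result.counts.to_csv(cp, sep="\t")
    paths["counts"] = cp
    ct = out_dir / "truth_counts.tsv"
    result.counts_truth.to_csv(ct, sep="\t", float_format="%.8g")
    paths["counts_truth"] = ct
    pp = out_dir / "peptides.tsv"
    pep = result.peptides.copy()
    pep["protein_ids"] = pep["protein_ids"].map(lambda s: ";".join(sorted(s)))
    pep.to_csv(pp, sep="\t", index=False)
    paths["peptides"] = pp
    fa = out_dir / "proteins.faa"
    with open(fa, "w", encoding="utf-8") as fh:
        rng = np.random.default_rng(result.config.seed + 1)
        for pid, row in result.proteins.iterrows():
            seq = "".join(rng.choice(AA, size=int(row["length"])))
            fh.write(f">{row['genome_id']}|{pid}\n{seq}\n")
    paths["proteins"] = fa
    write_json(result.peptide_truth, out_dir / "truth_peptides.json")
    paths["peptide_truth"] = out_dir / "truth_peptides.json"
    config_doc = dataclasses.asdict(result.config)
    write_json(config_doc, out_dir / "sim_config.json")
    paths["config"] = out_dir / "sim_config.json"
    return paths
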