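# Methods

`magtraits` infers functional traits of metagenome-assembled genomes (MAGs)
in a phototroph-associated bacterial consortium — one dominant diazotrophic
host plus tens of low-abundance epibionts — from per-genome KEGG/PFAM
annotation tables, secondary-metabolite cluster records, genome sequences,
read counts, and peptide-spectral tables. This note describes the rules, the
numerical choices, and what the synthetic-data tests do and do not show.

## The generic trait rule

A trait is an ordered set of KEGG orthologs (a "module") with an optional
subset of *marker genes* and optional PFAM markers. For a genome `g` and
module `M`:

    completeness(g, M) = |{m in M : copy count of m in g >= 1}| / |M|

Copy counts never inflate completeness — a gene in three copies counts once;
all copies are recorded as evidence on the call. The status is

* **present** — completeness >= threshold (default 0.5, *inclusive*) and
  every marker present;
* **putative** — at/above threshold but missing >= 1 marker, or (for traits
  flagged `report_partial`) any module gene present below threshold;
* **absent** — otherwise.

The inclusive reading of the 50% cutoff is a deliberate choice (the boundary
case "2 of 4 genes" is called present); both the threshold and its
inclusiveness are per-trait configurable in the catalog. Markers encode the
field practice that substrate-specific receptors are the determining factor
for transporter presence. Manual curation is replaced by an override table
(`genome_id`, `trait_id`, `forced_status`, `reason`) — deterministic and
auditable; an override with an empty reason is rejected.

Vitamin-uptake systems use a dedicated `marker_companion` rule: the binding
subunit (thiB/bioY/btuB) must co-occur with at least one companion
transporter gene (thiPQ, bioNM or efcTA1A2, btuF/btuCD). This is not the
generic threshold rule — btuB plus one companion is 2/5 of the module — so
it is a separate, catalog-driven rule rather than a threshold tweak. A
marker without any companion (or vice versa) is putative. For these traits a
"present" call can therefore sit below the generic completeness threshold;
the completeness value is still reported.

## Bundled catalog

`data/catalog.yaml` transcribes 40 traits across five categories (iron,
phosphorus, nitrogen, vitamin, interaction). Two pinning decisions:

* **narGHI vs nasA.** The nitrate-reductase range "K00370–K00374" spans both
  dissimilatory (narGHI) and assimilatory (nasA, K00372) subunits. The
  catalog pins narGHI = {K00370, K00371, K00374} and carries nasA = K00372
  as its own trait, since nasA is the ANRA marker and must be separable.
* **Cobalamin biosynthesis.** The cobinamide-to-cobalamin module is pinned
  to the standard eight orthologs (K00798, K19221, K02232, K00768, K02225,
  K02227, K02231, K19712) in a versioned data file.

The 2-AEP hydrolysis trait records the acetaldehyde (phnWX) and acetate
(phnWA) routes; the glycine route is excluded for lack of stable ortholog
ids. phnW is its marker and the trait is `report_partial`, so a lone
hydrolase is reported putative rather than absent — partial pathways are a
documented feature of real consortia.

## Nitrogen pathway assignment

Nitrate/nitrite reductases occur in ANRA, DNRA and denitrification alike, so
KEGG mapping alone cannot place them. The assignment rules, applied in
order (each gene group ends up in at most one pathway):

1. N2 fixation requires the full nif module (all four listed orthologs;
   `nif_strict=False` relaxes the fourth, fixation-associated one).
2. nirS/nirK are the denitrification markers: marker present ⇒ NO2→NO step
   present, and napAB/narGHI are pulled into denitrification (NO3→NO2).
3. nrfA is the DNRA diagnostic; nrfH alone is not sufficient (decided — the
   literature diagnostic is nrfA). napAB/narGHI attach to DNRA only when
   nrfA is present *and* no denitrification marker is; the marker wins.
4. nasA/narB/nirA mark ANRA. nirBD couples to ANRA only via nasA; nirBD
   alone is "unassigned/putative" nitrite reduction, and the genome's ANRA
   status becomes putative.
5. nor genes: NO→N2O present with a denitrification marker, putative
   without one (covers the host's norB-plus-nirA configuration). The
   putative reading is used even when both nor subunits are present but no
   marker is — markers are determining.
6. nosZ calls the terminal step unconditionally: denitrification is modular
   and a consortium completes it collectively
   (`consortium_denitrification_completeness` reports per-step genome
   coverage; only *present* steps count toward collective completeness).
7. Unclaimed nitrate reductases are reported "unassigned/putative".

Multi-gene groups (napAB, narGHI, nirBD, nrfAH, norBC) are present under the
same inclusive 50% rule as everywhere else. The whole rule set is verified
exhaustively against an independently coded oracle over all 4096 group
presence/absence combinations.

## Iron and siderophores

Fe-uptake receptors are single-ortholog markers (feoB, afuA, hemR, fecA,
fevS). The fevS (K02016) call always carries an ambiguity flag because that
ortholog does not separate siderophore from vitamin-B12 receptors. The
TonB/ExbB/ExbD system is graded complete / partial / absent.

NIS-type clusters are called from iucA/iucC domains (PF04183): one or more
domains across the cluster's genes ⇒ NIS, with the domain count reported.
Typing replaces phylogenetic clustering with a nearest-reference assignment:
each supplied synthetase sequence is globally aligned (Biopython
`PairwiseAligner`, BLOSUM62, gap open −10, extend −0.5 — pinned for
reproducibility) against a reference panel, and the best identity wins;
exact ties break by panel order and are flagged. Identity is computed as
identical columns over alignment columns (gaps included), and symmetry is
enforced by canonical argument ordering. The bundled panel
(`nis_panel_synthetic.fasta`) contains *synthetic* stand-in sequences for
the petrobactin/vibrioferrin/rhizoferrin/aerobactin exemplar types — real
synthetase sequences drop in via the same FASTA + metadata contract.
Photolability and membrane association are reference metadata, never
sequence-derived. NRPS clusters are putative siderophore producers only
when a TonB-dependent siderophore receptor gene (SMCOG1082 tag) lies within
the cluster span. Calls are per cluster; a genome with several clusters gets
several calls (no collapsing — decided, since summarization rules differ by
downstream use).

## Phosphorus and vitamins

The phnCDE/ptxABC transporter is substrate-ambiguous, so its interpretation
comes from adjacent metabolism: ptxD ⇒ phosphite-linked; C-P lyase present
or a complete 2-AEP route (phnW + phnX|phnA) ⇒ phosphonate-linked; both ⇒
both; transporter with neither ⇒ ambiguous; no transporter ⇒ absent (the
interpretation qualifies the transporter, not the genome). The
interpretation is monotone: adding metabolism genes never moves a genome
toward ambiguous.

Vitamin classification is a pure function of the (biosynthesis, uptake)
status pair: **auxotroph** ⇔ biosynthesis not present AND uptake present;
prototroph / self_and_uptake / neither fill the remaining cells. Putative
biosynthesis counts as "not present" — auxotrophy is only asserted when an
uptake system is unambiguously there.

## Consortium-level computations

**Relative abundance** is the per-sample fraction of reads per genome with a
cross-sample mean ± sd (sample sd, ddof = 1, matching the "71% ± 6" form of
three-sample summaries).

**ANI** is a MinHash bottom-sketch estimator over canonical
(strand-collapsed, since MAG contig orientation is arbitrary) k-mers, k = 16
and 5000 hashes by default, hashed with a seeded splitmix64. With Jaccard
similarity j of the merged bottom sketch, the k-mer survival probability is
w = 2j/(1+j) and the identity estimate is ANI = 100·w^(1/k). This is the
exact (Poisson-model) form of the Mash-distance relation; the familiar
first-order form 100·(1 + ln(w)/k) agrees near 100% identity but carries a
~0.5 pp downward bias at 90%, so the exact form is used. On synthetic
ungapped pairs the estimator's bias is below 0.05 pp across 90–100%
identity; single-pair errors are sketch-sampling noise with sd ≈ 0.1–0.25 pp.
j = 0 maps to 0.0 and the estimate is clamped to 100. Sequences must be
at least 10·k long and k must lie in [11, 31].

**Re-occurrence** uses strict `ANI > 97.5` (a pair at exactly 97.5 does not
re-occur), with one-to-one best-hit matching by greedy descending-ANI
assignment; exact ANI ties are flagged rather than resolved, because a
genome near the clustering threshold can legitimately match two partners.
`find_reoccurring` also accepts a precomputed identity matrix so output of
full-genome ANI tools can replace the sketch estimator.

## Proteomics

Peptide counts are credited without consideration of peptide specificity —
each peptide's spectral count goes to every matched protein (a
`unique_only` switch restricts crediting to single-match peptides). Two
statistics summarize ambiguity: the fraction of peptides matching exactly
one protein and the fraction matching within a single genome. NSAF uses
protein sequence length as the normalizer (saf = c/L, nsaf = saf/Σsaf; the
"matched-peptide length" reading is available as a sensitivity switch by
supplying alternative lengths in the protein table). Input tables are
assumed FDR-filtered upstream.

## Synthetic data and what it shows

The generator plants a status for every (genome, trait) cell and emits gene
records realizing it: present ⇒ full module; putative ⇒ an at-threshold
subset missing one marker (or a lone below-threshold gene for
report-partial traits); absent ⇒ a random strictly-below-threshold subset.
Catalog module gene sets are disjoint, so cells are independent. Dropout is
per *gene*, so partial pathways arise naturally; decoy orthologs are drawn
from outside every module. Read counts put the host at a 0.71 fraction with
cross-sample sd 0.06 over three samples (the emulated study structure) and
Dirichlet-distributed epibionts over one million reads per sample; the
peptide table plants the uniqueness fractions (defaults 0.916 / 0.927) with
~90% of counts on host proteins. The `paper_like` preset fixes the host
trait vector and field-like epibiont prevalences for demos.

What passing tests show: the rule implementations are exactly the documented
rules, recovery is exact when data match the rules' assumptions, and the
pipeline is deterministic. What they do not show: robustness to real
annotation error modes (systematically missed gene families, chimeric bins,
paralog confusion), which are not modelled beyond uniform dropout and
decoys.

## Problem sizes and numerical notes

Test and acceptance runs use 52 genomes × 40 traits for recovery, 4096
nitrogen rule combinations, ~370 engine subsets, 20 mutated panel sequences
for NIS typing, and 20 sequence pairs of 40 kb for ANI — sizes chosen so
the full suite runs in seconds while every enumeration stays exhaustive.
Floating-point threshold comparisons use a 1e-12 slack so exact boundary
fractions (2/4 at 0.5) are never lost to rounding. All tabular output is
UTF-8 TSV; matrices export alongside an iTOL binary-dataset text file with
present/putative/absent mapped to 1/0.5/0 (configurable).

## Known limitations

* Trait calls are presence-level genomic potential, not activity; AHL
  functionality (binding-residue level) is out of scope.
* The sketch ANI estimator assumes ungapped divergence; indel-rich or
  repeat-rich genomes should use a dedicated ANI tool via the identity-matrix
  input.
* The bundled NIS panel is synthetic; type labels on real data require a
  real synthetase panel.
* The genome-quality flag defaults to 90% completeness / 10% redundancy,
  with a "strict" preset (<5% redundancy) available.
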