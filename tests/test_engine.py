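"""Generic trait engine: completeness, marker rules, overrides, invariants."""

from itertools import combinations

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from magtraits.engine import Override, build_trait_matrix, call_trait, module_completeness
from magtraits.io import CatalogError, Status, TraitDefinition

from conftest import make_genome

B1 = ("K00946", "K00788", "K03149", "K00941", "K03147")


class TestModuleCompleteness:
    def test_two_of_five_genes(self, catalog):
        genome = make_genome(kegg=["K00946", "K00788"])
        assert module_completeness(genome, catalog["vitB1_biosynthesis"]) == pytest.approx(0.4)

    def test_empty_genome_is_zero(self, catalog):
        assert module_completeness(make_genome(), catalog["vitB1_biosynthesis"]) == 0.0

    def test_copy_counts_do_not_inflate(self, catalog):
        genome = make_genome(kegg=B1, copies=3)
        assert module_completeness(genome, catalog["vitB1_biosynthesis"]) == 1.0


class TestCallTrait:
    def test_thiamin_uptake_marker_plus_transporter_present(self, catalog):
        genome = make_genome(kegg=["K02064", "K02063", "K02062"])
        assert call_trait(genome, catalog["vitB1_uptake"]).status is Status.PRESENT

    def test_transporter_without_marker_not_present(self, catalog):
        genome = make_genome(kegg=["K02063", "K02062"])
        call = call_trait(genome, catalog["vitB1_uptake"])
        assert call.status is not Status.PRESENT

    def test_override_forces_status_and_flags(self, catalog):
        genome = make_genome(kegg=B1)
        ov = Override("g1", "vitB1_biosynthesis", Status.ABSENT, "curator decision")
        call = call_trait(genome, catalog["vitB1_biosynthesis"], [ov])
        assert call.status is Status.ABSENT and call.override_applied

    def test_override_requires_reason(self):
        with pytest.raises(ValueError):
            Override("g1", "t1", Status.ABSENT, "")

    def test_half_threshold_boundary_four_gene_module(self):
        """Brute force over all 16 subsets of a 4-gene module at threshold 0.5."""
        trait = TraitDefinition(
            trait_id="t", category="other",
            module_genes=("K1", "K2", "K3", "K4"),
        )
        for r in range(5):
            for subset in combinations(trait.module_genes, r):
                status = call_trait(make_genome(kegg=subset), trait).status
                expected = Status.PRESENT if r >= 2 else Status.ABSENT
                assert status is expected, (subset, status)

    def test_evidence_recorded_below_threshold(self, catalog):
        genome = make_genome(kegg=["K00946"])
        call = call_trait(genome, catalog["vitB1_biosynthesis"])
        assert call.status is Status.ABSENT
        assert call.evidence == (("K00946", 1),)

    def test_report_partial_yields_putative(self, catalog):
        genome = make_genome(kegg=["K03430"])  # phnW alone
        call = call_trait(genome, catalog["aep_hydrolysis"])
        assert call.status is Status.PUTATIVE


class TestBuildMatrix:
    def test_one_genome_every_cell_populated(self, catalog):
        matrix = build_trait_matrix({"g1": make_genome("g1")}, catalog)
        assert set(matrix.cells) == {("g1", t) for t in catalog}

    def test_permuting_genomes_only_permutes_rows(self, catalog):
        a = make_genome("gA", kegg=B1)
        b = make_genome("gB", kegg=["K02064", "K02063"])
        m1 = build_trait_matrix({"gA": a, "gB": b}, catalog)
        m2 = build_trait_matrix({"gB": b, "gA": a}, catalog)
        for key in m1.cells:
            assert m1.cells[key].status == m2.cells[key].status

    def test_override_with_unknown_trait_rejected(self, catalog):
        ov = Override("g1", "no_such_trait", Status.PRESENT, "typo")
        with pytest.raises(CatalogError, match="no_such_trait"):
            build_trait_matrix({"g1": make_genome("g1")}, catalog, [ov])


MODULE = ("K1", "K2", "K3", "K4", "K5", "K6")


@settings(derandomize=True, max_examples=150)
@given(
    base=st.sets(st.sampled_from(MODULE), max_size=5),
    extra=st.sampled_from(MODULE),
    markers=st.sets(st.sampled_from(MODULE), max_size=2),
    threshold=st.sampled_from([0.25, 0.5, 0.75, 1.0]),
)
def test_adding_genes_is_monotone(base, extra, markers, threshold):
    """Adding a gene never decreases completeness nor demotes present to absent."""
    trait = TraitDefinition(
        trait_id="t", category="other", module_genes=MODULE,
        marker_genes=frozenset(markers), completeness_threshold=threshold,
    )
    before = call_trait(make_genome(kegg=sorted(base)), trait)
    after = call_trait(make_genome(kegg=sorted(base | {extra})), trait)
    assert after.completeness >= before.completeness
    rank = {Status.ABSENT: 0, Status.PUTATIVE: 1, Status.PRESENT: 2}
    assert rank[after.status] >= rank[before.status]


@settings(derandomize=True, max_examples=60)
@given(
    n=st.integers(min_value=1, max_value=6),
    threshold=st.sampled_from([0.3, 0.5, 0.75, 1.0]),
)
def test_threshold_boundary_is_inclusive(n, threshold):
    """Exactly ceil(threshold*n) distinct genes -> present; one fewer -> not."""
    import math

    module = tuple(f"K{i}" for i in range(n))
    trait = TraitDefinition(
        trait_id="t", category="other", module_genes=module,
        completeness_threshold=threshold,
    )
    k = math.ceil(threshold * n - 1e-9)
    assert call_trait(make_genome(kegg=module[:k]), trait).status is Status.PRESENT
    if k > 1:
        assert (
            call_trait(make_genome(kegg=module[: k - 1]), trait).status
            is Status.ABSENT
        )
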