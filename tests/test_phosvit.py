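"""Phosphorus interpretation, vitamin classification, interaction traits."""

from itertools import product

import pytest

from magtraits.io import Status
from magtraits.iron import BGCGene, BGCRecord
from magtraits.phosvit import (
    VITAMINS,
    call_interaction_traits,
    call_p_profile,
    call_vitamin_status,
    classify_vitamin,
)

from conftest import make_genome

PHN_CDE = ["K02041", "K02042", "K02044"]
CP_LYASE = ["K06162", "K06163", "K06164", "K06165", "K06166", "K05780", "K05781"]
B12_BIO = ["K00798", "K19221", "K02232", "K00768", "K02225", "K02227", "K02231", "K19712"]


class TestPhosphorusProfile:
    def test_cp_lyase_links_transporter_to_phosphonate(self, catalog):
        p = call_p_profile(make_genome(kegg=PHN_CDE + CP_LYASE), catalog)
        assert p.phn_transporter_interpretation == "phosphonate_linked"

    def test_ptxd_links_transporter_to_phosphite(self, catalog):
        p = call_p_profile(make_genome(kegg=PHN_CDE + ["K18916"]), catalog)
        assert p.phn_transporter_interpretation == "phosphite_linked"

    def test_both_sources(self, catalog):
        p = call_p_profile(make_genome(kegg=PHN_CDE + CP_LYASE + ["K18916"]), catalog)
        assert p.phn_transporter_interpretation == "both"

    def test_transporter_alone_stays_ambiguous(self, catalog):
        p = call_p_profile(make_genome(kegg=PHN_CDE), catalog)
        assert p.phn_transporter_interpretation == "ambiguous"

    def test_phnw_alone_partial_not_phosphonate_linked(self, catalog):
        p = call_p_profile(make_genome(kegg=["K03430"]), catalog)
        assert p.aep_partial
        assert p.statuses["aep_hydrolysis"] is Status.PUTATIVE
        assert p.phn_transporter_interpretation == "absent"

    def test_complete_aep_route_counts_as_phosphonate(self, catalog):
        p = call_p_profile(make_genome(kegg=PHN_CDE + ["K03430", "K05306"]), catalog)
        assert p.phn_transporter_interpretation == "phosphonate_linked"
        assert not p.aep_partial

    def test_interpretation_monotone_in_evidence(self, catalog):
        """Adding ptxD or C-P lyase genes never moves toward ambiguous."""
        order = {"ambiguous": 0, "phosphite_linked": 1, "phosphonate_linked": 1, "both": 2}
        base = call_p_profile(make_genome(kegg=PHN_CDE), catalog)
        for extra in (["K18916"], CP_LYASE, ["K18916"] + CP_LYASE):
            more = call_p_profile(make_genome(kegg=PHN_CDE + extra), catalog)
            assert (
                order[more.phn_transporter_interpretation]
                >= order[base.phn_transporter_interpretation]
            )

    def test_alkaline_phosphatases_independent(self, catalog):
        p = call_p_profile(make_genome(kegg=["K01077"]), catalog)
        assert p.statuses["phoA"] is Status.PRESENT
        assert p.statuses["phoX"] is Status.ABSENT
        assert p.statuses["phoD"] is Status.ABSENT


class TestVitamins:
    def test_host_prototroph_for_all_three(self, catalog):
        kegg = (
            list(catalog["vitB1_biosynthesis"].module_genes)
            + list(catalog["vitB7_biosynthesis"].module_genes)
            + B12_BIO
        )
        genome = make_genome(kegg=kegg)
        for v in VITAMINS:
            assert call_vitamin_status(genome, v, catalog).classification == "prototroph"

    def test_b12_uptake_without_biosynthesis_is_auxotroph(self, catalog):
        genome = make_genome(kegg=["K16092", "K06074", "K06073"])  # btuB + btuCD
        status = call_vitamin_status(genome, "B12", catalog)
        assert status.uptake is Status.PRESENT
        assert status.classification == "auxotroph"

    def test_neither_biosynthesis_nor_uptake_is_not_auxotroph(self, catalog):
        status = call_vitamin_status(make_genome(), "B7", catalog)
        assert status.classification == "neither"

    def test_unknown_vitamin_rejected(self, catalog):
        with pytest.raises(ValueError):
            call_vitamin_status(make_genome(), "B6", catalog)

    @pytest.mark.parametrize("bio,up", list(product([True, False], repeat=2)))
    def test_two_by_two_truth_table(self, bio, up):
        """auxotroph iff biosynthesis missing AND uptake present."""
        b = Status.PRESENT if bio else Status.ABSENT
        u = Status.PRESENT if up else Status.ABSENT
        cls = classify_vitamin(b, u)
        assert (cls == "auxotroph") == (not bio and up)
        assert (cls == "prototroph") == (bio and not up)
        assert (cls == "self_and_uptake") == (bio and up)
        assert (cls == "neither") == (not bio and not up)

    def test_marker_without_companion_is_putative_uptake(self, catalog):
        genome = make_genome(kegg=["K16092"])  # btuB alone
        status = call_vitamin_status(genome, "B12", catalog)
        assert status.uptake is Status.PUTATIVE
        assert status.classification == "neither"


class TestInteractions:
    def test_pf00765_gene_calls_ahl(self, catalog):
        calls = call_interaction_traits(make_genome(pfam=["PF00765"]), (), catalog)
        assert calls["ahl_biosynthesis"].status is Status.PRESENT

    def test_quorum_regulator_independent_of_ahl(self, catalog):
        calls = call_interaction_traits(make_genome(kegg=["K07782"]), (), catalog)
        assert calls["quorum_sensing_regulation"].status is Status.PRESENT
        assert calls["ahl_biosynthesis"].status is Status.ABSENT

    def test_empty_genome_all_interaction_traits_absent(self, catalog):
        calls = call_interaction_traits(make_genome(), (), catalog)
        assert all(c.status is Status.ABSENT for c in calls.values())

    def test_bgc_borne_pf00765_counts_for_ahl(self, catalog):
        bgc = BGCRecord(
            "g1", "b1", "c1", 1, 2000, "other",
            genes=(BGCGene("x", 10, 999, {"PF00765": 1}),),
        )
        calls = call_interaction_traits(make_genome("g1"), [bgc], catalog)
        assert calls["ahl_biosynthesis"].status is Status.PRESENT

    def test_other_genomes_bgc_does_not_leak(self, catalog):
        bgc = BGCRecord(
            "g2", "b1", "c1", 1, 2000, "other",
            genes=(BGCGene("x", 10, 999, {"PF00765": 1}),),
        )
        calls = call_interaction_traits(make_genome("g1"), [bgc], catalog)
        assert calls["ahl_biosynthesis"].status is Status.ABSENT
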