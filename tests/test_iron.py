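"""Fe-uptake classification and siderophore BGC calling."""

import numpy as np
import pytest

from magtraits.io import Status
from magtraits.iron import (
    BGCGene,
    BGCRecord,
    IUC_PFAM,
    TBDT_TAG,
    call_nis_siderophore,
    call_nrps_siderophore,
    call_siderophores,
    classify_fe_uptake,
    load_bgcs,
    load_nis_panel,
    pairwise_identity,
    write_bgcs,
)
from magtraits.simulate import mutate_protein

from conftest import make_genome


def make_bgc(cluster_class="NIS", pfam_counts=None, tags=(), seqs=(), genome_id="g1"):
    genes = [BGCGene("b_g1", 100, 999, pfam_counts or {}, tuple(tags))]
    return BGCRecord(
        genome_id=genome_id,
        cluster_id="b1",
        contig="c1",
        start=1,
        end=5000,
        cluster_class=cluster_class,
        genes=tuple(genes),
        synthetase_sequences=tuple(seqs),
    )


class TestFeUptake:
    def test_inorganic_only_genome(self):
        profile = classify_fe_uptake(make_genome(kegg=["K04759", "K02012"]))
        assert profile.fe2 is Status.PRESENT and profile.fe3 is Status.PRESENT
        assert profile.heme is Status.ABSENT
        assert profile.citrate is Status.ABSENT
        assert profile.siderophore_receptor is Status.ABSENT
        assert not profile.ambiguity_flag

    def test_siderophore_receptor_always_flagged_ambiguous(self):
        profile = classify_fe_uptake(make_genome(kegg=["K02016"]))
        assert profile.siderophore_receptor is Status.PRESENT
        assert profile.ambiguity_flag

    def test_empty_genome_all_absent(self):
        profile = classify_fe_uptake(make_genome())
        assert profile.tonb_system == "absent"
        assert profile.fe2 is Status.ABSENT

    @pytest.mark.parametrize(
        "kos,expected",
        [
            (["K03832", "K03561", "K03559"], "complete"),
            (["K03832"], "partial"),
            ([], "absent"),
        ],
    )
    def test_tonb_grading(self, kos, expected):
        assert classify_fe_uptake(make_genome(kegg=kos)).tonb_system == expected


class TestPairwiseIdentity:
    def test_self_identity_is_100(self):
        panel = load_nis_panel()
        assert pairwise_identity(panel[0].sequence, panel[0].sequence) == 100.0

    def test_symmetry(self):
        panel = load_nis_panel()
        a, b = panel[0].sequence, panel[1].sequence
        assert pairwise_identity(a, b) == pairwise_identity(b, a)

    def test_unalignable_alphabet_rejected(self):
        with pytest.raises(ValueError, match="alphabet"):
            pairwise_identity("MKT1", "MKT")

    def test_identity_decreases_with_mutation_load(self):
        """More substitutions never raise identity to the source (in expectation)."""
        panel = load_nis_panel()
        src = panel[0].sequence
        means = []
        for rate in (0.05, 0.15, 0.30):
            idents = []
            for seed in range(5):
                rng = np.random.default_rng(seed)
                idents.append(pairwise_identity(mutate_protein(src, rate, rng), src))
            means.append(np.mean(idents))
        assert means[0] > means[1] > means[2]


class TestNISCalling:
    def test_zero_iuc_domains_is_none(self):
        call = call_nis_siderophore(make_bgc(pfam_counts={}), load_nis_panel())
        assert call.kind == "none"

    def test_iuc_count_summed_across_genes(self):
        bgc = BGCRecord(
            "g1", "b1", "c1", 1, 5000, "NIS",
            genes=(
                BGCGene("x1", 10, 999, {IUC_PFAM: 1}),
                BGCGene("x2", 1000, 1999, {IUC_PFAM: 1}),
            ),
        )
        call = call_nis_siderophore(bgc, load_nis_panel())
        assert call.kind == "NIS" and call.iuc_domain_count == 2

    def test_nearest_reference_recovered_after_mutation(self):
        panel = load_nis_panel()
        rng = np.random.default_rng(11)
        seq = mutate_protein(panel[0].sequence, 0.10, rng)
        call = call_nis_siderophore(
            make_bgc(pfam_counts={IUC_PFAM: 2}, seqs=[seq]), panel
        )
        assert call.nearest_reference == panel[0].name
        assert call.photolabile == panel[0].photolabile
        assert call.nearest_identity_pct > 80.0

    def test_nearest_reference_matches_brute_force_argmax(self):
        panel = load_nis_panel()
        rng = np.random.default_rng(2)
        seq = mutate_protein(panel[2].sequence, 0.10, rng)
        best = max(panel, key=lambda r: pairwise_identity(seq, r.sequence))
        call = call_nis_siderophore(
            make_bgc(pfam_counts={IUC_PFAM: 1}, seqs=[seq]), panel
        )
        assert call.nearest_reference == best.name


class TestNRPSCalling:
    def test_receptor_coupled_nrps_is_putative_producer(self):
        call = call_nrps_siderophore(make_bgc("NRPS", tags=[TBDT_TAG]))
        assert call.kind == "NRPS_putative"

    def test_nrps_without_receptor_is_none(self):
        assert call_nrps_siderophore(make_bgc("NRPS")).kind == "none"

    def test_non_nrps_with_receptor_tag_is_none(self):
        assert call_nrps_siderophore(make_bgc("other", tags=[TBDT_TAG])).kind == "none"

    def test_calls_depend_only_on_own_bgcs(self):
        bgcs = [
            make_bgc("NRPS", tags=[TBDT_TAG], genome_id="gA"),
            make_bgc("NRPS", genome_id="gB"),
        ]
        calls = {c.genome_id: c.kind for c in call_siderophores(bgcs)}
        assert calls == {"gA": "NRPS_putative", "gB": "none"}


class TestBGCValidation:
    def test_gene_outside_span_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            BGCRecord(
                "g1", "b1", "c1", 100, 200, "NIS",
                genes=(BGCGene("x", 10, 50, {}),),
            )

    def test_json_round_trip(self, tmp_path):
        bgc = make_bgc("NRPS", tags=[TBDT_TAG])
        path = write_bgcs([bgc], tmp_path / "bgcs.json")
        again = load_bgcs(path)
        assert again == [bgc]
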