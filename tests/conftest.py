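import pytest

from magtraits.io import GeneRecord, GenomeAnnotation, load_default_catalog


def make_genome(genome_id="g1", kegg=(), pfam=(), copies=1):
    """Build a genome carrying one gene per KEGG/PFAM id (``copies`` each)."""
    genes = []
    pos = 1
    idx = 0
    for ko in kegg:
        for _ in range(copies):
            idx += 1
            genes.append(
                GeneRecord(
                    gene_id=f"{genome_id}_g{idx}",
                    contig="c1",
                    start=pos,
                    end=pos + 899,
                    strand="+",
                    kegg_ids=frozenset([ko]),
                )
            )
            pos += 1000
    for pf in pfam:
        for _ in range(copies):
            idx += 1
            genes.append(
                GeneRecord(
                    gene_id=f"{genome_id}_g{idx}",
                    contig="c1",
                    start=pos,
                    end=pos + 899,
                    strand="+",
                    pfam_ids=frozenset([pf]),
                )
            )
            pos += 1000
    return GenomeAnnotation(genome_id=genome_id, genes=tuple(genes))


@pytest.fixture(scope="session")
def catalog():
    return load_default_catalog()
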