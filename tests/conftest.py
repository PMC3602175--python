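import pytest

from chlorocomp.synthetic import SyntheticDesign, generate_genome_set


@pytest.fixture(scope="session")
def small_design():
    return SyntheticDesign.simple(
        seed=7, n_per_group=2, n_core=10, n_group_specific=1, n_opposite=1,
        n_scattered=3, n_singleton=2, mean_gene_length_codons=120,
        substitution_rate=0.08)


@pytest.fixture(scope="session")
def small_genome_set(small_design):
    return generate_genome_set(small_design)


@pytest.fixture(scope="session")
def small_family_run(small_genome_set):
    """Clustering pipeline output on the small synthetic set (internal engine)."""
    from chlorocomp import families

    genomes, truth = small_genome_set
    proteomes = {g.genome_id: g.proteins() for g in genomes}
    famset, hits = families.cluster_proteomes(proteomes)
    return genomes, truth, proteomes, famset, hits
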