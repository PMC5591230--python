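import pytest

from asmbench import simgenome


@pytest.fixture(scope="session")
def toy_genome():
    return simgenome.generate_reference(10_000, gc=0.5, seed=11)


@pytest.fixture(scope="session")
def toy_gene_model(toy_genome):
    return simgenome.generate_gene_model(toy_genome, n_genes=3, seed=12)


@pytest.fixture(scope="session")
def toy_truth(toy_genome, toy_gene_model):
    return simgenome.sample_truth_variants(
        toy_genome, toy_gene_model, n_snv=40, n_indel=4,
        het_fraction=0.5, min_spacing=150, seed=13,
    )


@pytest.fixture(scope="session")
def toy_template(toy_genome, toy_truth):
    return simgenome.build_diploid_template(toy_genome, toy_truth, seed=14)
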