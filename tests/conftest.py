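import pytest

import moarank as mr
from moarank.synthetic import FixtureSpec, generate_fixture


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    """Noise-free synthetic universe with planted ground truth (seed 1)."""
    d = tmp_path_factory.mktemp("fixture")
    truth = generate_fixture(FixtureSpec(seed=1), d)
    return d, truth


@pytest.fixture(scope="session")
def universe(fixture_dir):
    """The fixture directory loaded through the package's own readers."""
    d, truth = fixture_dir
    return {
        "dir": d,
        "truth": truth,
        "expr": mr.read_expression_table(
            d / "expression.tsv", truth.case_ids, truth.control_ids
        ),
        "interactome": mr.read_interactome(d / "interactome.tsv"),
        "tfmap": mr.read_tf_targets(d / "tf_targets.tsv"),
        "disease": mr.read_gene_list(d / "disease_genes.txt"),
        "catalog": mr.read_drug_catalog(d / "drug_catalog.tsv"),
        "instances": mr.read_instance_profiles(
            d / "instance_zscores.tsv", d / "instance_metadata.tsv"
        ),
        "screen": mr.read_screening_table(d / "screening.tsv"),
    }


@pytest.fixture(scope="session")
def pnet(universe):
    return mr.build_pnet(
        universe["expr"], universe["interactome"], universe["tfmap"], universe["disease"]
    )
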