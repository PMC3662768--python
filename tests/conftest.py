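import pytest

from venomics.synthetic import ScenarioConfig, generate_scenario


@pytest.fixture(scope="session")
def small_scenario():
    """A reduced scenario reused across tests (generation is deterministic)."""
    cfg = ScenarioConfig(
        seed=7, n_body_genes=300, n_venom_genes=20, n_artifact_contigs=150
    )
    return generate_scenario(cfg)


@pytest.fixture
def tiny_fasta(tmp_path):
    path = tmp_path / "tiny.fasta"
    path.write_text(">t1\nATGAAATAG\n>t2\nacgtacgtacgt\n")
    return path
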