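import pytest

from charkit import synthetic_data as sim


@pytest.fixture(scope="session")
def two_type_family():
    """A 28-read clone family with one functional and one helix-scrambled type."""
    specs = (
        sim.ITSTypeSpec(kind="functional"),
        sim.ITSTypeSpec(kind="helix3_scrambled", helix3_scramble=True,
                        n_divergent_sites=12),
    )
    spec = sim.ITSSimSpec(accession="SYN1", type_specs=specs,
                          reads_per_accession=28, read_error_rate=0.0, seed=11)
    reads, truths = sim.gen_its_family(spec)
    return reads, truths
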