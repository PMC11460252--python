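import pytest

from ssvdecon import build_panel, build_synthetic_references

#: compact reference sizes for unit tests (the generator's default sizes are
#: used where composition accuracy against a printed table is at stake)
SMALL_SIZES = {
    "producer_genome": 12_000,
    "rAAV_genome": 2_300,
    "plasmid_backbone": 1_200,
    "helper_plasmid": 1_500,
    "repcap_plasmid": 1_500,
    "ecoli_genome": 1_500,
    "baculovirus": 1_200,
    "lambda_spike": 1_500,
    "foreign": 1_500,
}


@pytest.fixture(scope="session")
def refs_small():
    return build_synthetic_references(seed=11, sizes=SMALL_SIZES)


@pytest.fixture(scope="session")
def panel_small(refs_small):
    return build_panel([r for r in refs_small if r.species_label != "foreign"])
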