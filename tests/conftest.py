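import pytest

from rdnahet import (
    HeterogeneityModel,
    evolve_haplotypes,
    make_reference_unit,
)

#: Desk-scale unit used across tests: ITS = 592 bp like a realistic fungal
#: barcode region, flanked by short partial coding regions.
SMALL_REGIONS = {"18S": 300, "ITS1": 200, "5.8S": 160, "ITS2": 232, "28S": 300}


@pytest.fixture(scope="session")
def unit():
    return make_reference_unit(SMALL_REGIONS, gc=0.5, seed=11)


@pytest.fixture(scope="session")
def hapset(unit):
    """Four ITS-divergent haplotypes over 20 copies (min frequency 0.1)."""
    model = HeterogeneityModel(
        mode="accumulated_mutation",
        n_haplotypes=4,
        region_rates={"ITS": 0.0065, "18S": 0.0005, "28S": 0.0005},
        indel_rate=0.0005,
    )
    return evolve_haplotypes(unit, model, seed=12)


@pytest.fixture(scope="session")
def its_hapset(unit):
    """Heterogeneity confined to the ITS (all arms can see every true site)."""
    model = HeterogeneityModel(
        mode="accumulated_mutation",
        n_haplotypes=4,
        region_rates={"ITS": 0.0063},
        indel_rate=2.5e-4,
        indel_region="ITS",
    )
    return evolve_haplotypes(unit, model, seed=13)
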