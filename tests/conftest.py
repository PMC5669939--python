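import pytest

from evcargo.reference_io import HairpinRecord, MatureRecord
from evcargo.simulate import SimConfig


TOY_MATURE = "TAGCTAGCATCGGATCCGATCG"
TOY_HAIRPIN = "ACGTACGTTAGCTAGCATCGGATCCGATCGTTAGCAACGT"


@pytest.fixture
def toy_reference():
    """One mature embedded at (8, 30) on a 40-nt hairpin."""
    hairpin = HairpinRecord(id="hp1", sequence=TOY_HAIRPIN)
    mature = MatureRecord(
        id="mirA", sequence=TOY_MATURE, hairpin_id="hp1", start=8, end=30
    )
    return [mature], [hairpin]


@pytest.fixture
def small_sim_config():
    """A small but fully structured study: 4 groups x 2 replicates."""
    return SimConfig(
        seed=11,
        n_groups=4,
        n_replicates=2,
        n_mirnas=30,
        n_shared_core=10,
        n_group_specific=2,
        reads_per_sample=2000,
        n_snornas=12,
    )
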