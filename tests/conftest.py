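import numpy as np
import pytest

from rootforage.fixtures import FixtureSpec, gen_trait_table
from rootforage.trait_data import TraitRecord, TraitTable, translate_table

CANON_V = "umol g-1 min-1"
CANON_K = "uM"


def record(species="Hordeum vulgare", nutrient="NO3", basis="dry",
           v_max=0.5, v_max_units=CANON_V, k_m=50.0, k_m_units=CANON_K,
           study_id="study01", family=""):
    return TraitRecord(species=species, nutrient=nutrient, basis=basis,
                       v_max=v_max, v_max_units=v_max_units,
                       k_m=k_m, k_m_units=k_m_units,
                       study_id=study_id, family=family)


@pytest.fixture
def toy_table():
    """Three canonical-unit records across species and nutrients."""
    return TraitTable.from_records([
        record(species="Hordeum vulgare", v_max=0.5, k_m=50.0),
        record(species="Triticum aestivum", v_max=1.0, k_m=1.0, study_id="study02"),
        record(species="Zea mays", nutrient="NH4", v_max=2.0, k_m=100.0,
               study_id="study03"),
    ])


@pytest.fixture
def synthetic_table():
    """Default-condition synthetic literature table (seeded)."""
    return gen_trait_table(FixtureSpec(seed=42))


@pytest.fixture
def synthetic_translated(synthetic_table):
    return translate_table(synthetic_table)


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)
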