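import numpy as np
import pytest

from dietniche import (
    DietDataset,
    PreyItem,
    PreyTaxon,
    Sex,
    StomachSample,
    default_study_config,
    generate,
)


def make_item(order="Coleoptera", category="Carabidae", length=2.0, width=1.0):
    return PreyItem(PreyTaxon(order, category), length, width)


def make_sample(sample_id, species="Microhyla heymonsi", items=(), sex=Sex.FEMALE,
                svl=23.0, hl=7.0, mw=6.0, bm=1.8):
    return StomachSample(sample_id=sample_id, species=species, sex=sex,
                         svl_mm=svl, hl_mm=hl, mw_mm=mw, bm_g=bm, items=list(items))


@pytest.fixture
def tiny_dataset():
    """Two species, four stomachs (one empty), three prey categories."""
    return DietDataset([
        make_sample("A1", "Sp. alpha", [make_item("Isoptera", "Termitidae", 3.0, 1.0),
                                        make_item("Isoptera", "Termitidae", 2.0, 1.0),
                                        make_item("Coleoptera", "Carabidae", 4.0, 2.0)]),
        make_sample("A2", "Sp. alpha", [make_item("Isoptera", "Termitidae", 2.5, 1.5)]),
        make_sample("B1", "Sp. beta", [make_item("Hymenoptera", "Formicidae", 1.0, 0.5),
                                       make_item("Coleoptera", "Carabidae", 2.0, 1.0)]),
        make_sample("B2", "Sp. beta", []),
    ])


@pytest.fixture(scope="session")
def study_dataset():
    """Study-shaped synthetic dataset (26/42/48 stomachs), fixed seed."""
    return generate(default_study_config(seed=20260921))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
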