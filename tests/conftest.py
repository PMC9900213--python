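import numpy as np
import pytest

from phoskin.curation import build_pools, split_dataset
from phoskin.encoding import Vocabulary
from phoskin.nn.transformer import ModelConfig, TransformerEncoder
from phoskin.records import PeptideWindow, SubstrateRecord
from phoskin.synthetic import SyntheticKinomeConfig, default_grammars, generate_dataset


def pytest_collection_modifyitems(items):
    """Run the expensive end-to-end acceptance checks after the unit suite."""
    items.sort(key=lambda item: item.path.name == "test_acceptance.py")


@pytest.fixture(scope="session")
def vocab() -> Vocabulary:
    return Vocabulary()


@pytest.fixture(scope="session")
def small_dataset():
    """A small but complete synthetic dataset shared across read-only tests."""
    cfg = SyntheticKinomeConfig(
        kinases_per_family=2,
        n_substrates=60,
        substrate_length=200,
        min_family_positives=25,
        max_family_positives=60,
        seed=11,
    )
    return generate_dataset(cfg)


@pytest.fixture(scope="session")
def small_split(small_dataset):
    positives, pools = build_pools(small_dataset.annotations, small_dataset.substrates)
    split = split_dataset(positives, pools, min_positives=20, seed=11)
    return positives, pools, split


@pytest.fixture()
def tiny_model():
    return TransformerEncoder(ModelConfig(n_layers=2, n_heads=4, embed_dim=32, ffn_dim=64, max_len=128), seed=0)


@pytest.fixture()
def peptide():
    return PeptideWindow(residues="AKRRASVAGNP", source_substrate_id="S1", site_position=40)


def make_substrate(seq: str, sid: str = "S1") -> SubstrateRecord:
    return SubstrateRecord(substrate_id=sid, sequence=seq)
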