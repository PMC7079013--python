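import numpy as np
import pandas as pd
import pytest

from endemix import SimConfig, simulate_community
from endemix.records import OrderAlignment, SpecimenRecord, TopHit


@pytest.fixture(scope="session")
def small_community():
    """A compact synthetic community shared by read-only tests."""
    cfg = SimConfig(
        n_orders=4,
        n_endemic_species=6,
        n_introduced_species=6,
        n_unknown_species=4,
        rng_seed=11,
    )
    return simulate_community(cfg)


@pytest.fixture
def toy_alignment():
    return OrderAlignment(
        order="Diptera",
        ids=["a", "b", "c"],
        seqs=["ACGTACGTAC", "ACGTACGTAT", "ACGTTCGTAT"],
    )


def make_record(sid="x1", order="Diptera", seq="ACGT" * 100, **kw):
    return SpecimenRecord(specimen_id=sid, order=order, sequence=seq, **kw)


def make_tophit(identity, species=None, genus=None, family=None, order=None):
    return TopHit(
        identity=identity, species=species, genus=genus, family=family, order=order
    )


@pytest.fixture
def table3_counts():
    """Per-order contingency counts of predicted labels within known
    statuses, as published for the island arthropod training data set."""
    labels = ["GLMM-Native", "GLMM-Nonnative", "GLMM-Undet", "NA"]
    cols = pd.MultiIndex.from_tuples(
        [("introduced", l) for l in labels] + [("endemic", l) for l in labels]
    )
    rows = {
        "Araneae": [6, 0, 0, 0, 7, 0, 0, 3],
        "Blattodea": [0, 1, 0, 0, 0, 0, 0, 0],
        "Coleoptera": [0, 7, 0, 4, 0, 2, 0, 0],
        "Diptera": [3, 4, 3, 3, 1, 0, 1, 0],
        "Hemiptera": [2, 10, 2, 5, 1, 2, 0, 2],
        "Hymenoptera": [3, 22, 1, 9, 0, 1, 1, 0],
        "Lepidoptera": [9, 3, 2, 1, 13, 5, 3, 0],
        "Neuroptera": [0, 0, 0, 0, 0, 0, 0, 0],
        "Odonata": [0, 0, 0, 0, 2, 0, 0, 0],
        "Psocoptera": [0, 0, 0, 0, 0, 0, 0, 1],
        "Thysanoptera": [0, 2, 0, 0, 0, 0, 0, 0],
    }
    return pd.DataFrame.from_dict(rows, orient="index", columns=cols)
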