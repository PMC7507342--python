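import re

import pytest

from lanthiseek.mining import KnownCoreDB, mine
from lanthiseek.reference import load_known_cores, load_table1_cores
from lanthiseek.synthetic_data import GenomeSpec, generate_proteome

RL6_CORE = "ITSVSLCTPGCKTGALMGCNMKTASCGCHVHVSK"
RL8_CORE = "VTSKSLCTPGCKTGILQTCAIKSATCGCSIHIGK"


@pytest.fixture(scope="session")
def table1():
    """Published core-peptide table with parsed Ser+Thr capacities."""
    df = load_table1_cores()
    df = df.assign(
        capacity=[int(re.search(r"\((\d+)\)", m).group(1)) for m in df["modification"]]
    )
    return df


@pytest.fixture(scope="session")
def known_db():
    return KnownCoreDB(tuple(load_known_cores()))


@pytest.fixture(scope="session")
def default_proteome():
    """The default seeded synthetic proteome: 3 plants, 200 decoys."""
    spec = GenomeSpec()
    records, annotations, truth = generate_proteome(spec)
    return spec, records, annotations, truth


@pytest.fixture(scope="session")
def mined_default(default_proteome, known_db):
    _, records, annotations, truth = default_proteome
    return mine(records, annotations, known_db), truth
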