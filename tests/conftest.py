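import json
import random
from pathlib import Path

import pytest

from grass.synthetic_fixtures import worked_example_fixtures

FIXTURES = Path(__file__).parent / "fixtures"


@pytest.fixture(scope="session")
def example1():
    return worked_example_fixtures()["example1"].data


@pytest.fixture(scope="session")
def example2():
    return worked_example_fixtures()["example2"].data


@pytest.fixture(scope="session")
def example1_file_bytes():
    return (FIXTURES / "example1.fa").read_bytes()


@pytest.fixture(scope="session")
def example1_expected():
    return json.loads((FIXTURES / "example1.expected.json").read_text())


def random_core(rng: random.Random, max_len: int = 60) -> str:
    """A random core-alphabet string, occasionally degenerate in alphabet."""
    alphabet = "ACGTN"
    if rng.random() < 0.2:  # degenerate: subset alphabet
        k = rng.randint(1, 5)
        alphabet = "".join(rng.sample("ACGTN", k))
    return "".join(rng.choice(alphabet) for _ in range(rng.randint(0, max_len)))
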