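import numpy as np
import pandas as pd
import pytest

from fiberdeg.catalog import (
    BondID,
    EnzymeDef,
    FiberDef,
    load_default_catalogs,
)
from fiberdeg.simulate import make_toy_fixture


@pytest.fixture(scope="session")
def default_catalogs():
    return load_default_catalogs()


@pytest.fixture()
def minimal_fixture():
    return make_toy_fixture("minimal")


def random_bond(rng: np.random.Generator) -> BondID:
    sugars = ["Glc", "Fru", "Gal", "Xyl", "Man"]
    return BondID(
        anomeric=rng.choice(["a", "b"]),
        donor_pos=int(rng.integers(1, 7)),
        acceptor_pos=int(rng.integers(1, 7)),
        donor_sugar=str(rng.choice(sugars)),
        acceptor_sugar=str(rng.choice(sugars)),
    )


def random_catalog(
    rng: np.random.Generator, n_fibers: int, n_enzymes: int, max_bonds: int = 4
):
    """A random small fiber/enzyme catalog pair for oracle tests."""
    fibers = [
        FiberDef(
            f"fiber{j}",
            f"F{j}",
            frozenset(random_bond(rng) for _ in range(int(rng.integers(1, max_bonds + 1)))),
        )
        for j in range(n_fibers)
    ]
    enzymes = [
        EnzymeDef(
            f"3.2.1.{i + 1}",
            frozenset(random_bond(rng) for _ in range(int(rng.integers(1, max_bonds + 1)))),
        )
        for i in range(n_enzymes)
    ]
    return fibers, enzymes


@pytest.fixture()
def two_group_cohort():
    return make_toy_fixture("two_group_cohort", seed=7)


def write_fasta(path, records):
    with open(path, "w") as fh:
        for acc, seq in records:
            fh.write(f">{acc}\n{seq}\n")


def write_meta(path, rows):
    pd.DataFrame(rows, columns=["accession", "ecs", "source"]).to_csv(
        path, sep="\t", index=False
    )
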