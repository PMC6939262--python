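from pathlib import Path

import numpy as np
import pytest

from kincare.pedigree import Pedigree, MALE, FEMALE

DATA = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def toy_dir() -> Path:
    return DATA / "toy"


def build_pedigree(rows):
    """rows: (id, sire, dam, sex) tuples; None for missing parents."""
    return Pedigree(
        sire={r[0]: r[1] for r in rows},
        dam={r[0]: r[2] for r in rows},
        sex={r[0]: r[3] for r in rows},
    )


@pytest.fixture
def sib_pedigree():
    """Founders A, B; full siblings S, D; X an offspring of the sib mating."""
    return build_pedigree([
        ("A", None, None, MALE),
        ("B", None, None, FEMALE),
        ("S", "A", "B", MALE),
        ("D", "A", "B", FEMALE),
        ("X", "S", "D", MALE),
    ])


@pytest.fixture
def chain_pedigree():
    """Founder F0 with a chain of outbred descendants via unrelated mates."""
    rows = [("F0", None, None, MALE), ("U0", None, None, FEMALE)]
    parent, parent_is_male = "F0", True
    for g in range(1, 5):
        mate = f"U{g - 1}"
        child = f"C{g}"
        sire, dam = (parent, mate) if parent_is_male else (mate, parent)
        parent_is_male = not parent_is_male  # alternate sexes down the chain
        rows.append((child, sire, dam, MALE if parent_is_male else FEMALE))
        rows.append((f"U{g}", None, None, MALE if not parent_is_male else FEMALE))
        parent = child
    return build_pedigree(rows)


@pytest.fixture
def looped_pedigree():
    """Four generations of repeated full-sib matings: heavily inbred loops."""
    rows = [("M0", None, None, MALE), ("W0", None, None, FEMALE)]
    for g in range(1, 5):
        rows.append((f"M{g}", f"M{g - 1}", f"W{g - 1}", MALE))
        rows.append((f"W{g}", f"M{g - 1}", f"W{g - 1}", FEMALE))
    return build_pedigree(rows)


def random_pedigree(rng: np.random.Generator, n: int = 50) -> Pedigree:
    """Random genealogy: founders plus individuals whose parents are drawn
    from earlier individuals (or left missing), producing loops, half-sib
    structure and the occasional single-parent record."""
    n_founders = int(rng.integers(6, 13))
    rows = []
    males, females = [], []
    for k in range(n):
        ident = f"I{k:03d}"
        if k < n_founders:
            sire = dam = None
        else:
            sire = males[int(rng.integers(len(males)))] if rng.random() < 0.92 else None
            dam = females[int(rng.integers(len(females)))] if rng.random() < 0.92 else None
        sex = MALE if rng.random() < 0.5 else FEMALE
        (males if sex == MALE else females).append(ident)
        rows.append((ident, sire, dam, sex))
    return build_pedigree(rows)
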