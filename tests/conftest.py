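import os
import sys

import numpy as np
import pytest

sys.path.insert(0, os.path.dirname(__file__))

from pedlion.pedigree import Pedigree, PedigreeRecord


def make_ped(rows, reference=()):
    """Build a Pedigree from (id, sire, dam[, sex]) tuples; '0' means missing."""
    recs = []
    for row in rows:
        rid, sire, dam = row[:3]
        sex = row[3] if len(row) > 3 else "unknown"
        recs.append(PedigreeRecord(
            id=rid,
            sire=None if sire in ("0", None) else sire,
            dam=None if dam in ("0", None) else dam,
            sex=sex,
            is_reference=rid in reference,
        ))
    return Pedigree(recs)


@pytest.fixture
def full_sib_ped():
    """A, B founders; C, D full sibs; E their offspring (F_E = 0.25)."""
    return make_ped([
        ("A", "0", "0", "male"),
        ("B", "0", "0", "female"),
        ("C", "A", "B", "male"),
        ("D", "A", "B", "female"),
        ("E", "C", "D", "male"),
    ])


def random_pedigree(rng: np.random.Generator, n_max: int = 12,
                    p_parents: float = 0.7) -> Pedigree:
    """Random acyclic pedigree: each animal may draw parents among earlier
    animals of the right sex, giving full/half sibs and inbred loops."""
    n = int(rng.integers(2, n_max + 1))
    sexes, recs = [], []
    for i in range(n):
        sex = "male" if rng.random() < 0.5 else "female"
        males = [j for j in range(i) if sexes[j] == "male"]
        females = [j for j in range(i) if sexes[j] == "female"]
        sire = dam = None
        if males and females and rng.random() < p_parents:
            sire = f"I{int(rng.choice(males))}"
            dam = f"I{int(rng.choice(females))}"
        sexes.append(sex)
        recs.append(PedigreeRecord(id=f"I{i}", sire=sire, dam=dam, sex=sex))
    return Pedigree(recs)
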