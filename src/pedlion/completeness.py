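"""Pedigree completeness: how much of each animal's ancestry is recorded.

Four per-animal measures are computed, all counting only *known* ancestors
(recorded, non-phantom animals):

* ``max_gen`` — generations separating the animal from its furthest known
  ancestor (founders are generation 0).
* ``full_gen`` — deepest generation g such that every one of the 2^g ancestor
  slots in generations 1..g is filled by a known animal.
* ``equiv_gen`` — equivalent complete generations, the sum of (1/2)^n over
  all known ancestors with n the generation distance (each path counted).
* ``pci`` — pedigree completeness index at depth d: the harmonic mean
  2·Cp·Cm/(Cp+Cm) of the paternal and maternal line scores, where each line
  score is the mean over generations 1..d of the proportion of known
  ancestors in that generation of that line.

The per-generation profile (share of known ancestors by ancestor generation,
averaged over a group of animals) is the curve conventionally plotted for a
studbook and its reference population.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .pedigree import Pedigree, PedigreeError

__all__ = [
    "CompletenessRecord",
    "max_generations",
    "full_generations",
    "equivalent_generations",
    "pci",
    "completeness_table",
    "completeness_profile",
]

DEFAULT_PCI_DEPTH = 5


@dataclass(frozen=True)
class CompletenessRecord:
    id: str
    max_gen: int
    full_gen: int
    equiv_gen: float
    pci: float


def _known_parent_arrays(ped: Pedigree) -> tuple[np.ndarray, np.ndarray]:
    """Parent index arrays with phantom parents mapped to -1 (unknown)."""
    phantom = np.array([r.is_phantom for r in ped.records])
    sk = ped.sire_idx.copy()
    dk = ped.dam_idx.copy()
    for arr in (sk, dk):
        m = arr >= 0
        arr[m & phantom[np.where(m, arr, 0)]] = -1
    return sk, dk


def _per_animal_arrays(ped: Pedigree) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    sk, dk = _known_parent_arrays(ped)
    n = len(ped)
    mg = np.zeros(n, dtype=np.int64)
    fg = np.zeros(n, dtype=np.int64)
    eg = np.zeros(n, dtype=float)
    for i in ped.topological_order:
        s, d = sk[i], dk[i]
        if s >= 0 or d >= 0:
            mg[i] = 1 + max(mg[s] if s >= 0 else 0, mg[d] if d >= 0 else 0)
        if s >= 0 and d >= 0:
            fg[i] = 1 + min(fg[s], fg[d])
        acc = 0.0
        for p in (s, d):
            if p >= 0:
                acc += 0.5 * (1.0 + eg[p])
        eg[i] = acc
    return mg, fg, eg


def _known_counts(ped: Pedigree, max_depth: int) -> np.ndarray:
    """K[i, g] = number of known ancestors of i among its 2^g slots at depth g."""
    sk, dk = _known_parent_arrays(ped)
    n = len(ped)
    K = np.zeros((n, max_depth + 1), dtype=np.int64)
    K[:, 0] = 1  # the animal itself (all records are "known" as focal animals)
    for g in range(1, max_depth + 1):
        prev = K[:, g - 1]
        ks = np.where(sk >= 0, prev[np.where(sk >= 0, sk, 0)], 0)
        kd = np.where(dk >= 0, prev[np.where(dk >= 0, dk, 0)], 0)
        K[:, g] = ks + kd
    return K


def max_generations(ped: Pedigree, animal: str | None = None):
    """Generations to the furthest known ancestor (founders: 0)."""
    mg, _, _ = _per_animal_arrays(ped)
    if animal is not None:
        return int(mg[ped.index(animal)])
    return pd.Series(mg[[ped.index(a) for a in ped.real_ids]], index=list(ped.real_ids))


def full_generations(ped: Pedigree, animal: str | None = None):
    """Deepest generation with every ancestor slot filled by a known animal."""
    _, fg, _ = _per_animal_arrays(ped)
    if animal is not None:
        return int(fg[ped.index(animal)])
    return pd.Series(fg[[ped.index(a) for a in ped.real_ids]], index=list(ped.real_ids))


def equivalent_generations(ped: Pedigree, animal: str | None = None):
    """Sum of (1/2)^n over all known ancestors, per path."""
    _, _, eg = _per_animal_arrays(ped)
    if animal is not None:
        return float(eg[ped.index(animal)])
    return pd.Series(eg[[ped.index(a) for a in ped.real_ids]], index=list(ped.real_ids))


def pci(ped: Pedigree, animal: str | None = None, depth: int = DEFAULT_PCI_DEPTH):
    """Pedigree completeness index: harmonic mean of the parental line scores.

    A line whose parent is unrecorded scores 0, and the harmonic mean with a
    zero is 0 — one fully unknown line voids the index.
    """
    if depth < 1:
        raise PedigreeError(f"pci depth must be >= 1, got {depth}")
    K = _known_counts(ped, depth - 1)
    sk, dk = _known_parent_arrays(ped)

    def line_score(parent: int) -> float:
        if parent < 0:
            return 0.0
        # generation i of the focal animal = depth i-1 of the parent
        props = [K[parent, g] / (2 ** g) for g in range(depth)]
        return float(np.mean(props))

    def one(i: int) -> float:
        cp, cm = line_score(int(sk[i])), line_score(int(dk[i]))
        if cp + cm == 0.0:
            return 0.0
        return 2.0 * cp * cm / (cp + cm)

    if animal is not None:
        return one(ped.index(animal))
    return pd.Series(
        [one(ped.index(a)) for a in ped.real_ids], index=list(ped.real_ids)
    )


def completeness_table(ped: Pedigree, ids=None, depth: int = DEFAULT_PCI_DEPTH) -> pd.DataFrame:
    """Per-animal table of all four completeness measures."""
    ids = list(ids) if ids is not None else list(ped.real_ids)
    mg, fg, eg = _per_animal_arrays(ped)
    pc = pci(ped, depth=depth)
    idx = [ped.index(a) for a in ids]
    return pd.DataFrame(
        {
            "max_gen": mg[idx],
            "full_gen": fg[idx],
            "equiv_gen": eg[idx],
            "pci": [pc[a] for a in ids],
        },
        index=ids,
    )


def completeness_profile(ped: Pedigree, ids=None, max_depth: int = 7) -> pd.DataFrame:
    """Mean proportion of known ancestors per ancestor generation 1..max_depth."""
    ids = list(ids) if ids is not None else list(ped.real_ids)
    if not ids:
        raise PedigreeError("completeness profile needs a non-empty id set")
    K = _known_counts(ped, max_depth)
    idx = [ped.index(a) for a in ids]
    gens = np.arange(1, max_depth + 1)
    props = K[idx, 1:] / (2.0 ** gens)
    return pd.DataFrame(
        {"generation": gens, "prop_known": props.mean(axis=0)}
    )
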