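"""Mating-plan construction: AR-threshold groups and minimum-kinship pairs.

Candidates are first partitioned by average relatedness (AR), a long-term
inbreeding proxy: animals with AR below the low threshold (default 4%)
carry the rarest ancestry and are the preferred breeders; the middle band
(up to 12.5%, boundaries inclusive) may supplement them; animals above it
are over-represented and excluded.

Pairs are then recommended by matching males to females with minimal
pairwise kinship, since the kinship of a pair equals the inbreeding
coefficient of their prospective offspring exactly.  The default matcher is
a transparent greedy sweep over pairs sorted by kinship; an exact
minimum-sum matching is available for small candidate sets.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .kinship import relationship_matrix
from .pedigree import Pedigree, PedigreeError

__all__ = ["MatingGroups", "PairRecommendation", "classify_by_ar", "recommend_pairs"]

DEFAULT_AR_LOW = 0.04
DEFAULT_AR_HIGH = 0.125
DEFAULT_KINSHIP_CEILING = 0.0625   # first-cousin level


@dataclass
class MatingGroups:
    group1: tuple[str, ...]   # AR < low: preferred breeders
    group2: tuple[str, ...]   # low <= AR <= high: usable supplements
    group3: tuple[str, ...]   # AR > high: over-represented, excluded
    low: float
    high: float


@dataclass
class PairRecommendation:
    pairs: pd.DataFrame                     # male, female, kinship, predicted_F
    excluded: list[tuple[str, str, str]] = field(default_factory=list)  # (m, f, reason)

    def __len__(self) -> int:
        return len(self.pairs)


def classify_by_ar(ar: pd.Series, low: float = DEFAULT_AR_LOW,
                   high: float = DEFAULT_AR_HIGH) -> MatingGroups:
    """Partition candidates by AR; boundary values go to the middle group."""
    if not (0.0 < low < high < 1.0):
        raise PedigreeError(f"need 0 < low < high < 1, got low={low}, high={high}")
    g1 = tuple(ar.index[ar < low])
    g2 = tuple(ar.index[(ar >= low) & (ar <= high)])
    g3 = tuple(ar.index[ar > high])
    return MatingGroups(group1=g1, group2=g2, group3=g3, low=low, high=high)


def recommend_pairs(ped: Pedigree, candidates=None, *,
                    max_uses: int = 1,
                    max_kinship: float = DEFAULT_KINSHIP_CEILING,
                    same_location: bool = False,
                    method: str = "greedy") -> PairRecommendation:
    """Recommend male-female pairs with minimal kinship.

    Constraints: each animal appears in at most *max_uses* pairs, pair
    kinship must stay below *max_kinship* (predicted offspring F), and with
    *same_location* only co-located pairs are feasible.  ``method="exact"``
    solves the minimum-total-kinship matching by enumeration (candidate sets
    up to 10 x 10).
    """
    if candidates is None:
        candidates = sorted(ped.reference_ids) or list(ped.real_ids)
    candidates = list(candidates)
    males = [a for a in candidates if ped.record(a).sex == "male"]
    females = [a for a in candidates if ped.record(a).sex == "female"]
    if not males or not females:
        return PairRecommendation(pairs=_empty_pairs(),
                                  excluded=[("", "", "no sexed candidates")])
    ids, A = relationship_matrix(ped, males + females)
    pos = {a: k for k, a in enumerate(ids)}

    feasible: list[tuple[float, str, str]] = []
    excluded: list[tuple[str, str, str]] = []
    for m in males:
        for f in females:
            c = A[pos[m], pos[f]] / 2.0
            if same_location and ped.record(m).location != ped.record(f).location:
                excluded.append((m, f, "different location"))
                continue
            if c >= max_kinship:
                excluded.append((m, f, f"kinship {c:.4f} >= ceiling {max_kinship:.4f}"))
                continue
            feasible.append((c, m, f))

    if method == "greedy":
        chosen = _greedy_match(feasible, max_uses)
    elif method == "exact":
        if len(males) > 10 or len(females) > 10:
            raise PedigreeError("exact matching is limited to 10 x 10 candidates")
        chosen = _exact_match(feasible, males, females, max_uses)
    else:
        raise PedigreeError(f"unknown matching method {method!r}")

    chosen.sort(key=lambda t: (t[0], t[1], t[2]))
    df = pd.DataFrame(
        [{"male": m, "female": f, "kinship": c, "predicted_F": c} for c, m, f in chosen],
        columns=["male", "female", "kinship", "predicted_F"],
    )
    return PairRecommendation(pairs=df, excluded=excluded)


def _empty_pairs() -> pd.DataFrame:
    return pd.DataFrame(columns=["male", "female", "kinship", "predicted_F"])


def _greedy_match(feasible, max_uses):
    uses: dict[str, int] = {}
    chosen = []
    for c, m, f in sorted(feasible, key=lambda t: (t[0], t[1], t[2])):
        if uses.get(m, 0) < max_uses and uses.get(f, 0) < max_uses:
            chosen.append((c, m, f))
            uses[m] = uses.get(m, 0) + 1
            uses[f] = uses.get(f, 0) + 1
    return chosen


def _exact_match(feasible, males, females, max_uses):
    """Maximum-cardinality, minimum-total-kinship matching by enumeration."""
    if max_uses != 1:
        raise PedigreeError("exact matching supports max_uses=1 only")
    cost = {(m, f): c for c, m, f in feasible}
    best: list[tuple[float, str, str]] = []
    best_key = (0, 0.0)
    short, long_, flip = (males, females, False) if len(males) <= len(females) \
        else (females, males, True)
    for combo in itertools.permutations(long_, len(short)):
        pairs = []
        total = 0.0
        for a, b in zip(short, combo):
            m, f = (b, a) if flip else (a, b)
            if (m, f) in cost:
                pairs.append((cost[(m, f)], m, f))
                total += cost[(m, f)]
        key = (len(pairs), -total)
        if key > best_key:
            best_key = key
            best = pairs
    return best
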