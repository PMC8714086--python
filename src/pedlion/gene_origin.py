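"""Probability-of-gene-origin parameters and diversity-loss partitioning.

Given a reference population (the living, analysed subset), the expected
genetic contribution q_k of each founder k — phantom founders included — is
obtained by gene-flow recursion: an animal's gene pool is half its sire's
plus half its dam's, and contributions are averaged over reference animals,
so that sum_k q_k = 1 exactly.

Derived parameters:

* effective number of founders      fe = 1 / sum_k q_k^2
* effective number of ancestors     fa = 1 / sum_j p_j^2, where p_j are the
  *marginal* contributions of ancestors picked greedily: each round selects
  the ancestor explaining the largest share of the reference gene pool not
  already explained by previously selected ancestors (whose parent links are
  masked).  fa is sensitive to bottlenecks; fa <= fe <= f always.
* founder genome equivalents        fg, either deterministically as
  1/(2*fbar) with fbar the mean co-ancestry over all reference pairs
  (self pairs included), or by Monte-Carlo gene dropping: two unique alleles
  per founder are segregated through the pedigree, r_j is the mean fraction
  of founder j's alleles surviving in the reference, and
  fg = 1 / sum_j (q_j^2 / r_j).

Retained diversity and its loss partition:

    GD  = 1 - 1/(2 fg)        total retained diversity
    GD* = 1 - 1/(2 fe)        retained if only founder imbalance acted
    loss_total   = 1 - GD  =  loss_founder + loss_drift
    loss_founder = 1 - GD*
    loss_drift   = GD* - GD   (drift + bottlenecks since the founders)
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .kinship import relationship_matrix
from .pedigree import Pedigree, PedigreeError

__all__ = [
    "GeneOriginReport",
    "founder_contributions",
    "effective_founders",
    "effective_ancestors",
    "founder_genome_equivalents",
    "diversity_loss",
    "gene_origin_report",
]

MARGINAL_TOL = 1e-9


def _reference_ids(ped: Pedigree, reference) -> list[str]:
    if reference is None:
        reference = sorted(ped.reference_ids)
        if not reference:
            raise PedigreeError("pedigree has no reference animals and none were given")
    else:
        reference = list(reference)
        if not reference:
            raise PedigreeError("reference set must be non-empty")
    for a in reference:
        ped.index(a)
    return reference


def founder_contributions(ped: Pedigree, reference=None) -> pd.Series:
    """Expected contribution of every founder (phantoms included) to the
    reference gene pool; sums to 1 exactly."""
    reference = _reference_ids(ped, reference)
    founders = [ped.records[i].id for i in ped.topological_order
                if ped.sire_idx[i] < 0 and ped.dam_idx[i] < 0]
    fpos = {f: k for k, f in enumerate(founders)}
    nf = len(founders)
    # downward gene flow: contribution vector per animal, topological order
    contrib: dict[int, np.ndarray] = {}
    for i in ped.topological_order:
        s, d = int(ped.sire_idx[i]), int(ped.dam_idx[i])
        if s < 0 and d < 0:
            v = np.zeros(nf)
            v[fpos[ped.records[i].id]] = 1.0
        else:
            v = 0.5 * contrib[s] + 0.5 * contrib[d]
        contrib[i] = v
    q = np.zeros(nf)
    for a in reference:
        q += contrib[ped.index(a)]
    q /= len(reference)
    return pd.Series(q, index=founders)


def effective_founders(q: pd.Series) -> float:
    """fe = 1 / sum q^2 (maximal, = number of founders, at equal shares)."""
    q = np.asarray(q, dtype=float)
    if q.size == 0:
        raise PedigreeError("empty founder-contribution vector")
    return float(1.0 / np.sum(q ** 2))


def effective_ancestors(ped: Pedigree, reference=None,
                        tol: float = MARGINAL_TOL) -> tuple[float, pd.Series, int]:
    """Greedy marginal-contribution selection of ancestors.

    Returns (fa, ordered marginal contributions p_j, n50) where n50 is the
    smallest number of selected ancestors jointly explaining half the
    reference gene pool.  Ties break by topological order then id.
    """
    reference = _reference_ids(ped, reference)
    ref_idx = [ped.index(a) for a in reference]
    topo = list(ped.topological_order)
    rank = {i: k for k, i in enumerate(topo)}
    n = len(ped)

    # candidates: founders in the reference, plus every proper ancestor of a
    # reference animal
    candidates: set[int] = set()
    for i in ref_idx:
        for p in (int(ped.sire_idx[i]), int(ped.dam_idx[i])):
            if p >= 0:
                candidates.add(p)
        if ped.sire_idx[i] < 0 and ped.dam_idx[i] < 0:
            candidates.add(i)
    closure = {ped.index(a) for a in ped.ancestor_closure(
        [ped.records[i].id for i in candidates])} if candidates else set()
    candidates |= closure

    selected: list[int] = []
    marginals: list[float] = []
    w0 = np.zeros(n)
    for i in ref_idx:
        w0[i] += 1.0 / len(ref_idx)

    while True:
        remaining = [c for c in candidates if c not in selected]
        if not remaining:
            break
        sel = set(selected)
        # weight reaching each animal along upward lineages avoiding the
        # selected ancestors below it (selected ancestors absorb)
        arrived = w0.copy()
        for i in reversed(topo):
            if arrived[i] == 0.0 or i in sel:
                continue
            s, d = int(ped.sire_idx[i]), int(ped.dam_idx[i])
            if s < 0 and d < 0:
                continue
            arrived[s] += 0.5 * arrived[i]
            arrived[d] += 0.5 * arrived[i]
        # probability the lineage continuing upward from each animal also
        # avoids every selected ancestor
        avoid_up = np.ones(n)
        for i in topo:
            s, d = int(ped.sire_idx[i]), int(ped.dam_idx[i])
            if s < 0 and d < 0:
                continue
            a_s = 0.0 if s in sel else avoid_up[s]
            a_d = 0.0 if d in sel else avoid_up[d]
            avoid_up[i] = 0.5 * a_s + 0.5 * a_d
        marginal = arrived * avoid_up
        best = max(remaining, key=lambda c: (marginal[c], -rank[c], ped.records[c].id))
        if marginal[best] < tol:
            break
        selected.append(best)
        marginals.append(float(marginal[best]))

    p = pd.Series(marginals, index=[ped.records[i].id for i in selected])
    fa = float(1.0 / np.sum(p.to_numpy() ** 2))
    cum = np.cumsum(p.to_numpy())
    hits = np.nonzero(cum >= 0.5 - 1e-12)[0]
    n50 = int(hits[0]) + 1 if hits.size else len(p)
    return fa, p, n50


def _gene_drop_retention(ped: Pedigree, ref_idx: list[int], founders: list[int],
                         replicates: int, rng: np.random.Generator,
                         chunk: int = 20_000) -> np.ndarray:
    """Mean fraction of each founder's two unique alleles surviving in the
    reference, over Monte-Carlo Mendelian segregations."""
    topo = list(ped.topological_order)
    fpos = {i: k for k, i in enumerate(founders)}
    n = len(ped)
    retained_sum = np.zeros(len(founders))
    done = 0
    while done < replicates:
        r = min(chunk, replicates - done)
        alleles = np.zeros((n, 2, r), dtype=np.int32)
        for i in topo:
            s, d = int(ped.sire_idx[i]), int(ped.dam_idx[i])
            if s < 0 and d < 0:
                alleles[i, 0, :] = 2 * fpos[i]
                alleles[i, 1, :] = 2 * fpos[i] + 1
            else:
                pick_s = rng.integers(0, 2, size=r)
                pick_d = rng.integers(0, 2, size=r)
                alleles[i, 0, :] = alleles[s, pick_s, np.arange(r)]
                alleles[i, 1, :] = alleles[d, pick_d, np.arange(r)]
        ref_alleles = alleles[ref_idx].reshape(-1, r)  # (2*nref, r)
        for k in range(len(founders)):
            # count distinct surviving alleles (0, 1 or 2) per replicate
            a0 = (ref_alleles == 2 * k).any(axis=0)
            a1 = (ref_alleles == 2 * k + 1).any(axis=0)
            retained_sum[k] += (a0.astype(float) + a1.astype(float)).sum() / 2.0
        done += r
    return retained_sum / replicates


def founder_genome_equivalents(ped: Pedigree, reference=None, method: str = "coancestry",
                               replicates: int = 10_000, seed: int | None = None) -> float:
    """Founder genome equivalents fg.

    method="coancestry" (deterministic): fg = 1/(2*fbar), fbar the mean
    co-ancestry over all reference pairs including self-co-ancestries.
    method="genedrop" (Monte-Carlo): fg = 1 / sum_j q_j^2 / r_j with allele
    retention r_j estimated over *replicates* gene drops.
    """
    reference = _reference_ids(ped, reference)
    if method == "coancestry":
        _, A = relationship_matrix(ped, reference)
        fbar = float(A.mean()) / 2.0
        return math.inf if fbar == 0.0 else 1.0 / (2.0 * fbar)
    if method == "genedrop":
        if replicates < 1:
            raise PedigreeError("gene-drop needs replicates >= 1")
        q = founder_contributions(ped, reference)
        founders = [ped.index(f) for f in q.index]
        rng = np.random.default_rng(seed)
        r = _gene_drop_retention(ped, [ped.index(a) for a in reference],
                                 founders, replicates, rng)
        qv = q.to_numpy()
        active = qv > 0.0
        r = r[active]
        qv = qv[active]
        # a founder with expected contribution > 0 retains alleles in some
        # replicate almost surely; floor protects against sampling flukes
        r = np.maximum(r, 1.0 / (2.0 * replicates))
        return float(1.0 / np.sum(qv ** 2 / r))
    raise PedigreeError(f"unknown founder-genome-equivalents method {method!r}")


@dataclass
class GeneOriginReport:
    n_ref: int
    f: int
    q_founder: pd.Series
    fe: float
    marginal: pd.Series
    fa: float
    n50: int
    fg_coancestry: float
    fg_genedrop: float | None
    genedrop_replicates: int | None
    genedrop_seed: int | None
    GD: float = field(init=False)
    GDstar: float = field(init=False)
    loss_total: float = field(init=False)
    loss_founder: float = field(init=False)
    loss_drift: float = field(init=False)

    def __post_init__(self) -> None:
        gd = diversity_loss(self.fe, self.fg_coancestry)
        self.GD = gd["GD"]
        self.GDstar = gd["GDstar"]
        self.loss_total = gd["loss_total"]
        self.loss_founder = gd["loss_founder"]
        self.loss_drift = gd["loss_drift"]

    def summary_frame(self) -> pd.DataFrame:
        rows = {
            "n": self.n_ref,
            "f": self.f,
            "fe": self.fe,
            "fa": self.fa,
            "fg": self.fg_coancestry,
            "n50": self.n50,
        }
        return pd.DataFrame({"value": rows})


def diversity_loss(fe: float, fg: float) -> dict[str, float]:
    """Retained diversity GD / GD* and the founder-imbalance vs drift split."""
    if fe <= 0 or fg <= 0:
        raise PedigreeError("fe and fg must be positive")
    gd = 1.0 - 1.0 / (2.0 * fg)
    gdstar = 1.0 - 1.0 / (2.0 * fe)
    return {
        "GD": gd,
        "GDstar": gdstar,
        "loss_total": 1.0 - gd,
        "loss_founder": 1.0 - gdstar,
        "loss_drift": gdstar - gd,
    }


def gene_origin_report(ped: Pedigree, reference=None, *, genedrop: bool = False,
                       replicates: int = 10_000, seed: int | None = None) -> GeneOriginReport:
    reference = _reference_ids(ped, reference)
    q = founder_contributions(ped, reference)
    fe = effective_founders(q)
    fa, marginal, n50 = effective_ancestors(ped, reference)
    fg_c = founder_genome_equivalents(ped, reference, method="coancestry")
    fg_g = None
    if genedrop:
        fg_g = founder_genome_equivalents(ped, reference, method="genedrop",
                                          replicates=replicates, seed=seed)
    return GeneOriginReport(
        n_ref=len(reference), f=int((q > 0).sum()), q_founder=q, fe=fe,
        marginal=marginal, fa=fa, n50=n50, fg_coancestry=fg_c,
        fg_genedrop=fg_g,
        genedrop_replicates=replicates if genedrop else None,
        genedrop_seed=seed if genedrop else None,
    )
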