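"""Additive relationship machinery and common-ancestor diversity parameters.

The numerator relationship matrix A is built with the tabular method over a
topological order: for animal x with parents s and d,

    a_xy = (a_sy + a_dy) / 2        for y ordered before x,
    a_xx = 1 + a_sd / 2,

with unrecorded parents contributing 0.  From A follow the inbreeding
coefficient F_i = a_ii - 1, the co-ancestry (kinship) c_ij = a_ij / 2 (equal
to the inbreeding of a prospective offspring of i and j), and the average
relatedness AR_i = (1/2n) sum_j a_ij over the n analysed animals.

Rates and effective size:

* individual increase in inbreeding  dF_i = 1 - (1 - F_i)^(1/(t_i - 1)),
  with t_i the animal's equivalent complete generations (undefined, and
  excluded from averages, when t_i <= 1);
* realised effective size from inbreeding  Ne = 1 / (2 * mean dF);
* pairwise increase in co-ancestry  dc_jk = 1 - (1 - c_jk)^(1/((g_j+g_k)/2))
  over reference pairs, and  Nec = 1 / (2 * mean dc).

The generation-mean form  dF = (Fbar_t - Fbar_{t-1}) / (1 - Fbar_{t-1})  is
exposed separately; studbook reports commonly print one or the other without
saying which.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import completeness as _comp
from .pedigree import Pedigree, PedigreeError

__all__ = [
    "KinshipSummary",
    "NeEstimates",
    "relationship_matrix",
    "kinship_summary",
    "inbreeding",
    "average_relatedness",
    "delta_f_individual",
    "delta_f_from_means",
    "delta_f_generations",
    "ne_from_delta_f",
    "ne_from_coancestry",
    "ne_estimates",
    "inbreeding_classes",
]

DEFAULT_F_CLASS_EDGES = (0.0, 0.01, 0.13, 1.0)


@dataclass
class KinshipSummary:
    """Relationship matrix over an analysis set plus derived per-animal values."""

    ids: tuple[str, ...]          # analysis set, in pedigree record order
    A: np.ndarray                 # additive relationship over ids
    F: pd.Series                  # inbreeding, a_ii - 1
    AR: pd.Series                 # average relatedness within the analysis set
    dF: pd.Series                 # individual increase in inbreeding (NaN if t<=1)
    t: pd.Series                  # equivalent complete generations

    def coancestry(self, a: str, b: str) -> float:
        i, j = self.ids.index(a), self.ids.index(b)
        return float(self.A[i, j] / 2.0)

    def per_animal(self) -> pd.DataFrame:
        return pd.DataFrame({"F": self.F, "AR": self.AR, "dF": self.dF, "t": self.t})


@dataclass
class NeEstimates:
    ne_deltaF: float
    ne_coancestry: float
    n_deltaF: int          # animals entering the dF mean
    n_pairs: int           # pairs entering the dc mean

    def to_dict(self) -> dict:
        return {
            "ne_deltaF": self.ne_deltaF,
            "ne_coancestry": self.ne_coancestry,
            "n_deltaF": self.n_deltaF,
            "n_pairs": self.n_pairs,
        }


def _analysis_ids(ped: Pedigree, ids) -> list[str]:
    if ids is None:
        return list(ped.real_ids)
    ids = list(ids)
    for a in ids:
        ped.index(a)  # raises on unknown
    return ids


def _tabular_A(ped: Pedigree, need: set[int]) -> tuple[list[int], np.ndarray]:
    """A over the ancestor closure of *need*, in topological order."""
    order = [i for i in ped.topological_order if i in need]
    pos = {i: k for k, i in enumerate(order)}
    m = len(order)
    A = np.zeros((m, m))
    for k, i in enumerate(order):
        s, d = int(ped.sire_idx[i]), int(ped.dam_idx[i])
        sp = pos.get(s, -1)
        dp = pos.get(d, -1)
        row = np.zeros(k)
        if sp >= 0:
            row += 0.5 * A[sp, :k]
        if dp >= 0:
            row += 0.5 * A[dp, :k]
        A[k, :k] = row
        A[:k, k] = row
        A[k, k] = 1.0 + (0.5 * A[sp, dp] if sp >= 0 and dp >= 0 else 0.0)
    return order, A


def relationship_matrix(ped: Pedigree, ids=None) -> tuple[list[str], np.ndarray]:
    """Additive relationship matrix over *ids* (default: all real animals).

    Ancestors outside *ids* are used in the recursion but not returned.
    """
    ids = _analysis_ids(ped, ids)
    need = {ped.index(a) for a in ped.ancestor_closure(ids)}
    order, A = _tabular_A(ped, need)
    pos = {ped.records[i].id: k for k, i in enumerate(order)}
    sel = [pos[a] for a in ids]
    return ids, A[np.ix_(sel, sel)]


def kinship_summary(ped: Pedigree, ids=None) -> KinshipSummary:
    ids, A = relationship_matrix(ped, ids)
    n = len(ids)
    F = pd.Series(np.diag(A) - 1.0, index=ids)
    AR = pd.Series(A.sum(axis=1) / (2.0 * n), index=ids)
    t_all = _comp.equivalent_generations(ped)
    t = t_all.reindex(ids)
    with np.errstate(invalid="ignore"):
        dF = 1.0 - (1.0 - F) ** (1.0 / (t - 1.0))
    dF[t <= 1.0] = np.nan
    return KinshipSummary(ids=tuple(ids), A=A, F=F, AR=AR, dF=dF, t=t)


def inbreeding(ped: Pedigree, ids=None) -> pd.Series:
    """Per-animal inbreeding coefficient F = a_ii - 1 (tabular method)."""
    ids, A = relationship_matrix(ped, ids)
    return pd.Series(np.diag(A) - 1.0, index=ids)


def average_relatedness(ped: Pedigree, ids=None) -> pd.Series:
    """AR_i = mean additive relationship of i to the analysis set, halved."""
    ids, A = relationship_matrix(ped, ids)
    return pd.Series(A.sum(axis=1) / (2.0 * len(ids)), index=ids)


def delta_f_individual(ped: Pedigree, ids=None) -> pd.Series:
    """dF_i = 1 - (1-F_i)^(1/(t_i-1)); NaN where t_i <= 1 (excluded from means)."""
    return kinship_summary(ped, ids).dF


def delta_f_from_means(means) -> np.ndarray:
    """Generation-mean rate (Fbar_t - Fbar_{t-1}) / (1 - Fbar_{t-1}) per step."""
    means = np.asarray(list(means), dtype=float)
    if means.size < 2:
        raise PedigreeError("need mean F for at least two generations")
    prev, cur = means[:-1], means[1:]
    return (cur - prev) / (1.0 - prev)


def delta_f_generations(ped: Pedigree, ids=None) -> np.ndarray:
    """Generation-mean rates over discrete generations (rounded equivalent
    complete generations); one value per successive generation pair."""
    summ = kinship_summary(ped, ids)
    gen = summ.t.round().astype(int)
    means = summ.F.groupby(gen).mean().sort_index()
    return delta_f_from_means(means.to_numpy())


def ne_from_delta_f(ped: Pedigree, reference=None) -> tuple[float, int]:
    """Realised Ne from the mean individual increase in inbreeding.

    Returns (Ne, number of animals with a defined dF).  Ne is inf when the
    mean increase is zero.
    """
    if reference is None:
        reference = sorted(ped.reference_ids) or None
    dF = delta_f_individual(ped, reference).dropna()
    if dF.empty:
        raise PedigreeError("no animal with a defined individual increase in inbreeding")
    mean = float(dF.mean())
    ne = math.inf if mean == 0.0 else 1.0 / (2.0 * mean)
    return ne, int(dF.size)


def ne_from_coancestry(ped: Pedigree, reference=None) -> tuple[float, int]:
    """Realised Ne from the pairwise increase in co-ancestry.

    All unordered reference pairs j<k enter with exponent 1/((g_j+g_k)/2),
    g the equivalent complete generations; pairs with a non-positive mean
    generation are excluded.  Returns (Ne, number of pairs used).
    """
    if reference is None:
        reference = sorted(ped.reference_ids) or None
    ids, A = relationship_matrix(ped, reference)
    if len(ids) < 2:
        raise PedigreeError("co-ancestry Ne needs at least two animals")
    g = _comp.equivalent_generations(ped).reindex(ids).to_numpy()
    C = A / 2.0
    n = len(ids)
    iu, ju = np.triu_indices(n, k=1)
    gm = (g[iu] + g[ju]) / 2.0
    keep = gm > 0.0
    if not keep.any():
        raise PedigreeError("no reference pair with positive mean generation count")
    c = C[iu[keep], ju[keep]]
    dc = 1.0 - (1.0 - c) ** (1.0 / gm[keep])
    mean = float(dc.mean())
    ne = math.inf if mean == 0.0 else 1.0 / (2.0 * mean)
    return ne, int(keep.sum())


def ne_estimates(ped: Pedigree, reference=None) -> NeEstimates:
    ne_f, n_f = ne_from_delta_f(ped, reference)
    ne_c, n_c = ne_from_coancestry(ped, reference)
    return NeEstimates(ne_deltaF=ne_f, ne_coancestry=ne_c, n_deltaF=n_f, n_pairs=n_c)


def inbreeding_classes(F: pd.Series, sex: pd.Series | None = None,
                       edges=DEFAULT_F_CLASS_EDGES) -> pd.DataFrame:
    """Counts of animals per inbreeding class (optionally split by sex).

    Default classes: F in [0, 0.01) (effectively non-inbred), [0.01, 0.13),
    and [0.13, 1] (highly inbred).
    """
    edges = tuple(edges)
    if list(edges) != sorted(set(edges)):
        raise PedigreeError(f"class edges must be strictly increasing, got {edges!r}")
    labels = [f"[{lo:g}, {hi:g})" for lo, hi in zip(edges[:-1], edges[1:])]
    labels[-1] = labels[-1][:-1] + "]"
    binned = pd.cut(F, bins=list(edges), labels=labels, right=False,
                    include_lowest=True)
    # close the top bin
    binned[F >= edges[-2]] = labels[-1]
    if sex is None:
        counts = binned.value_counts().reindex(labels, fill_value=0)
        return counts.rename("count").to_frame()
    df = pd.DataFrame({"class": binned, "sex": sex.reindex(F.index)})
    out = df.groupby(["class", "sex"], observed=False).size().unstack(fill_value=0)
    return out.reindex(labels, fill_value=0)
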