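"""Subpopulation structure from pedigree co-ancestry: FST, dendrogram, PCA.

Subpopulations are the groups of animals per holding location (countries in
a studbook).  For groups i and j the mean pairwise co-ancestry f_ij is the
average of c_xy = a_xy/2 over all cross pairs; within-group means include
self-co-ancestries (1+F_x)/2, so a singleton group is well defined.

Differentiation uses the Nei-minimum-distance form on co-ancestries,

    D_ij  = (f_ii + f_jj)/2 - f_ij,
    FST_ij = D_ij / (1 - (f_ii + f_jj)/2),

which lies in [0, 1]: 0 for identical groups, 1 for fixed, unrelated ones.
The FST matrix feeds an average-linkage (UPGMA) dendrogram.  Individual
substructure comes from the eigen-decomposition of the double-centered
relationship matrix (principal components of genetic similarity).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy as _hier
from scipy.spatial.distance import squareform

from .kinship import relationship_matrix
from .pedigree import Pedigree, PedigreeError

__all__ = [
    "StructureReport",
    "PCAResult",
    "subpop_coancestry",
    "pairwise_fst",
    "fst_dendrogram",
    "relationship_pca",
    "ar_heatmap_matrix",
    "structure_report",
]


@dataclass
class PCAResult:
    coords: pd.DataFrame          # animals x components, scaled by sqrt(eigenvalue)
    explained: np.ndarray         # variance fraction of every component (sums to 1)

    @property
    def k(self) -> int:
        return self.coords.shape[1]


@dataclass
class StructureReport:
    groups: dict[str, tuple[str, ...]]
    coancestry_means: pd.DataFrame
    fst_pairwise: pd.DataFrame
    newick: str
    pca: PCAResult
    heatmap: pd.DataFrame
    heatmap_order: tuple[str, ...]
    fst_estimator: str = "nei-minimum-distance/coancestry"


def _grouping_dict(ped: Pedigree, grouping) -> dict[str, list[str]]:
    """Normalise a grouping (mapping id->label, or None for location column)."""
    groups: dict[str, list[str]] = {}
    dropped = []
    if grouping is None:
        for rec in ped.records:
            if rec.is_phantom:
                continue
            if rec.location is None:
                dropped.append(rec.id)
                continue
            groups.setdefault(rec.location, []).append(rec.id)
    else:
        for animal, label in dict(grouping).items():
            ped.index(animal)
            groups.setdefault(str(label), []).append(animal)
    groups = {k: v for k, v in sorted(groups.items()) if v}
    if not groups:
        raise PedigreeError("no non-empty group to analyse")
    return groups


def subpop_coancestry(ped: Pedigree, grouping=None) -> pd.DataFrame:
    """Mean pairwise co-ancestry between (and within) groups.

    Within-group means run over the full submatrix including the diagonal
    self-co-ancestries (1+F)/2.
    """
    groups = _grouping_dict(ped, grouping)
    ids = sorted({a for v in groups.values() for a in v})
    got, A = relationship_matrix(ped, ids)
    pos = {a: k for k, a in enumerate(got)}
    C = A / 2.0
    labels = list(groups)
    out = np.zeros((len(labels), len(labels)))
    for i, gi in enumerate(labels):
        pi = [pos[a] for a in groups[gi]]
        for j, gj in enumerate(labels):
            pj = [pos[a] for a in groups[gj]]
            out[i, j] = C[np.ix_(pi, pj)].mean()
    return pd.DataFrame(out, index=labels, columns=labels)


def pairwise_fst(coancestry_means: pd.DataFrame) -> pd.DataFrame:
    """Nei minimum distance normalised to Wright's fixation index, in [0, 1].

    Pairs whose mean self-co-ancestry reaches 1 (fully inbred, fixed groups)
    are undefined and reported as NaN.
    """
    f = coancestry_means.to_numpy(dtype=float)
    labels = list(coancestry_means.index)
    s = len(labels)
    fst = np.zeros((s, s))
    for i in range(s):
        for j in range(s):
            if i == j:
                continue
            half = (f[i, i] + f[j, j]) / 2.0
            d = half - f[i, j]
            denom = 1.0 - half
            fst[i, j] = np.nan if denom == 0.0 else min(1.0, max(0.0, d / denom))
    return pd.DataFrame(fst, index=labels, columns=labels)


def _tree_to_newick(node, labels, parent_height: float) -> str:
    height = node.dist / 2.0  # ultrametric height of this node
    length = parent_height - height
    if node.is_leaf():
        return f"{labels[node.id]}:{length:.6g}"
    left = _tree_to_newick(node.left, labels, height)
    right = _tree_to_newick(node.right, labels, height)
    return f"({left},{right}):{length:.6g}"


def fst_dendrogram(fst: pd.DataFrame) -> tuple[str, np.ndarray]:
    """UPGMA tree over the FST matrix, returned as (Newick string, linkage).

    Deterministic for a fixed label order (labels are sorted upstream);
    missing FST entries are an error naming the offending pairs.
    """
    labels = list(fst.index)
    if len(labels) < 2:
        raise PedigreeError("dendrogram needs at least two groups")
    m = fst.to_numpy(dtype=float).copy()
    bad = [(labels[i], labels[j]) for i, j in zip(*np.nonzero(np.isnan(m))) if i < j]
    if bad:
        raise PedigreeError(f"FST undefined for pairs {bad!r}")
    np.fill_diagonal(m, 0.0)
    Z = _hier.linkage(squareform(m, checks=False), method="average")
    root = _hier.to_tree(Z)
    newick = f"({_tree_to_newick(root.left, labels, root.dist / 2.0)},"\
             f"{_tree_to_newick(root.right, labels, root.dist / 2.0)});"
    return newick, Z


def relationship_pca(ped: Pedigree, reference=None, k: int = 2) -> PCAResult:
    """Principal components of the double-centered relationship matrix.

    Coordinates are eigenvectors scaled by the square root of their
    eigenvalue, so Euclidean distances embed genetic dissimilarity.
    """
    if k < 1:
        raise PedigreeError("need at least one principal component")
    if reference is None:
        reference = sorted(ped.reference_ids) or None
    ids, A = relationship_matrix(ped, reference)
    n = len(ids)
    if n < 2:
        raise PedigreeError("PCA needs at least two animals")
    if k > n:
        k = n
    J = np.eye(n) - np.ones((n, n)) / n
    B = J @ A @ J
    B = (B + B.T) / 2.0
    vals, vecs = np.linalg.eigh(B)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    total = vals.clip(min=0.0).sum()
    explained = vals.clip(min=0.0) / total if total > 0 else np.zeros_like(vals)
    coords = vecs[:, :k] * np.sqrt(vals[:k].clip(min=0.0))
    cols = [f"PC{i + 1}" for i in range(k)]
    return PCAResult(coords=pd.DataFrame(coords, index=ids, columns=cols),
                     explained=explained)


def ar_heatmap_matrix(ped: Pedigree, reference=None) -> tuple[pd.DataFrame, tuple[str, ...]]:
    """Pairwise relationship submatrix ordered by UPGMA leaf order.

    The ordering clusters related animals together, the layout used for a
    relatedness heatmap; values are the raw additive relationships.
    """
    if reference is None:
        reference = sorted(ped.reference_ids) or None
    ids, A = relationship_matrix(ped, reference)
    if len(ids) < 2:
        raise PedigreeError("heatmap needs at least two animals")
    C = A / 2.0
    d = 1.0 - C
    np.fill_diagonal(d, 0.0)
    d = np.maximum(d, 0.0)
    Z = _hier.linkage(squareform((d + d.T) / 2.0, checks=False), method="average")
    leaf_order = _hier.leaves_list(Z)
    ordered = [ids[i] for i in leaf_order]
    M = pd.DataFrame(A, index=ids, columns=ids).loc[ordered, ordered]
    return M, tuple(ordered)


def structure_report(ped: Pedigree, grouping=None, reference=None, k: int = 2) -> StructureReport:
    groups = _grouping_dict(ped, grouping)
    f = subpop_coancestry(ped, grouping)
    fst = pairwise_fst(f)
    newick, _ = fst_dendrogram(fst)
    pca = relationship_pca(ped, reference, k=k)
    heat, order = ar_heatmap_matrix(ped, reference)
    return StructureReport(
        groups={g: tuple(v) for g, v in groups.items()},
        coancestry_means=f,
        fst_pairwise=fst,
        newick=newick,
        pca=pca,
        heatmap=heat,
        heatmap_order=order,
    )
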