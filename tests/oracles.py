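"""Independent brute-force oracles for the tabular kinship machinery.

Wright's path-counting formulation: the co-ancestry of x and y is the sum,
over every common ancestor A and every pair of upward paths x->A and y->A
sharing no animal but A, of (1/2)^(n1+n2+1) * (1 + F_A); the inbreeding of
an animal is the co-ancestry of its parents.  Paths are enumerated
explicitly (networkx simple paths on the child->parent graph), which is
exponential but exact — usable only on small pedigrees, and entirely
independent of the tabular recursion it checks.
"""

from __future__ import annotations

import networkx as nx

from pedlion.pedigree import Pedigree


class PathOracle:
    def __init__(self, ped: Pedigree):
        self.ped = ped
        g = nx.DiGraph()
        g.add_nodes_from(range(len(ped)))
        for i in range(len(ped)):
            for p in (ped.sire_idx[i], ped.dam_idx[i]):
                if p >= 0:
                    g.add_edge(i, int(p))  # child -> parent (upward)
        self.g = g
        self._anc: dict[int, frozenset[int]] = {}
        self._paths: dict[tuple[int, int], list[list[int]]] = {}
        self._F: dict[int, float] = {}

    def ancestors(self, i: int) -> frozenset[int]:
        if i not in self._anc:
            self._anc[i] = frozenset(nx.descendants(self.g, i)) | {i}
        return self._anc[i]

    def paths(self, src: int, dst: int) -> list[list[int]]:
        key = (src, dst)
        if key not in self._paths:
            if src == dst:
                self._paths[key] = [[src]]
            else:
                self._paths[key] = [list(p) for p in nx.all_simple_paths(self.g, src, dst)]
        return self._paths[key]

    def coancestry(self, x: int, y: int) -> float:
        if x == y:
            return (1.0 + self.F(x)) / 2.0
        total = 0.0
        for a in self.ancestors(x) & self.ancestors(y):
            fa = self.F(a)
            for p1 in self.paths(x, a):
                s1 = set(p1)
                for p2 in self.paths(y, a):
                    if s1 & set(p2) == {a}:
                        n1, n2 = len(p1) - 1, len(p2) - 1
                        total += 0.5 ** (n1 + n2 + 1) * (1.0 + fa)
        return total

    def F(self, i: int) -> float:
        if i not in self._F:
            s, d = int(self.ped.sire_idx[i]), int(self.ped.dam_idx[i])
            if s < 0 or d < 0 or self.ped.records[s].is_phantom or self.ped.records[d].is_phantom:
                self._F[i] = 0.0 if s < 0 or d < 0 else self.coancestry(s, d)
            else:
                self._F[i] = self.coancestry(s, d)
        return self._F[i]

    def relationship(self, x: int, y: int) -> float:
        return 2.0 * self.coancestry(x, y) if x != y else 1.0 + self.F(x)


def equiv_generations_pathsum(ped: Pedigree, animal: str) -> float:
    """Equivalent complete generations by explicit path enumeration: every
    upward path of length L to a known (non-phantom) ancestor adds (1/2)^L."""
    total = 0.0
    stack = [(ped.index(animal), 0)]
    while stack:
        i, depth = stack.pop()
        for p in (int(ped.sire_idx[i]), int(ped.dam_idx[i])):
            if p >= 0 and not ped.records[p].is_phantom:
                total += 0.5 ** (depth + 1)
                stack.append((p, depth + 1))
    return total
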