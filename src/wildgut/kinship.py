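"""Pedigree path-counting relatedness.

The kinship index between two individuals is computed by enumerating every
genetic path that ascends from one individual to a common ancestor (the
apex) and descends to the other, and summing ``(1/2)**N`` over paths, where
``N`` is the number of edges on the path.  Maternal relatedness is the same
sum restricted to paths made entirely of dam (mother) edges.

Path legality follows the classical path-counting construction:

* paths are simple (no individual repeated),
* strictly ascend child->parent to a single apex, then strictly descend,
* two paths are distinct iff their edge sets differ.

Either leg may be empty, so a direct ancestor is itself the apex (a
parent-offspring pair has the single path with ``N = 1`` and contribution
one half).  On pedigrees without inbreeding the path sum equals the
coefficient of relationship (twice the kinship coefficient).  On inbred
pedigrees this is the literal path sum, without Wright's ``(1 + F)`` apex
correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError
from .io import PedigreeRecord

SIRE = "sire"
DAM = "dam"


@dataclass(frozen=True)
class GeneticPath:
    """One ascend-then-descend path between two individuals.

    ``nodes`` runs from the first individual up to the apex and down to the
    second; ``apex_index`` locates the apex within ``nodes``.
    """

    nodes: tuple[str, ...]
    apex_index: int

    @property
    def apex(self) -> str:
        return self.nodes[self.apex_index]

    @property
    def n_edges(self) -> int:
        return len(self.nodes) - 1

    @property
    def contribution(self) -> float:
        return 0.5 ** self.n_edges


class PedigreeGraph:
    """Directed acyclic child->parent graph with sire/dam edge labels."""

    def __init__(self, records: list[PedigreeRecord]):
        self._parents: dict[str, dict[str, str]] = {}
        for rec in records:
            if rec.individual_id in self._parents:
                raise ValidationError(
                    f"individual {rec.individual_id!r} declared twice"
                )
            entry: dict[str, str] = {}
            if rec.sire_id is not None:
                entry[SIRE] = rec.sire_id
            if rec.dam_id is not None:
                entry[DAM] = rec.dam_id
            self._parents[rec.individual_id] = entry
        # implicit founders for referenced-only parents
        for entry in list(self._parents.values()):
            for p in entry.values():
                self._parents.setdefault(p, {})
        self._check_acyclic()

    # -- basic accessors ---------------------------------------------------

    @property
    def individuals(self) -> list[str]:
        return list(self._parents)

    def __contains__(self, individual: str) -> bool:
        return individual in self._parents

    def parents(self, individual: str) -> dict[str, str]:
        """Mapping edge-label -> parent id (may be empty)."""
        try:
            return self._parents[individual]
        except KeyError:
            raise KeyError(f"unknown individual {individual!r}") from None

    def ancestors(self, individual: str) -> set[str]:
        """All proper ancestors."""
        out: set[str] = set()
        stack = list(self.parents(individual).values())
        while stack:
            x = stack.pop()
            if x not in out:
                out.add(x)
                stack.extend(self._parents.get(x, {}).values())
        return out

    def _check_acyclic(self) -> None:
        state: dict[str, int] = {}

        def visit(x: str) -> None:
            state[x] = 1
            for p in self._parents[x].values():
                s = state.get(p, 0)
                if s == 1:
                    raise ValidationError(f"pedigree cycle through {p!r}")
                if s == 0:
                    visit(p)
            state[x] = 2

        for ind in self._parents:
            if state.get(ind, 0) == 0:
                visit(ind)

    def topological_order(self) -> list[str]:
        """Founders first, every child after both parents."""
        order: list[str] = []
        state: dict[str, int] = {}

        def visit(x: str) -> None:
            state[x] = 1
            for p in self._parents[x].values():
                if state.get(p, 0) == 0:
                    visit(p)
            state[x] = 2
            order.append(x)

        for ind in self._parents:
            if state.get(ind, 0) == 0:
                visit(ind)
        return order

    # -- path enumeration --------------------------------------------------

    def _ascending_chains(self, start: str, maternal_only: bool):
        """Every chain start -> ... -> ancestor (including the trivial chain)."""
        chains: list[tuple[str, ...]] = []

        def extend(chain: tuple[str, ...]) -> None:
            chains.append(chain)
            parents = self._parents[chain[-1]]
            labels = (DAM,) if maternal_only else (SIRE, DAM)
            for lab in labels:
                p = parents.get(lab)
                if p is not None and p not in chain:
                    extend(chain + (p,))

        extend((start,))
        return chains

    def enumerate_paths(
        self, a: str, b: str, maternal_only: bool = False
    ) -> list[GeneticPath]:
        """All distinct simple ascend-then-descend paths between a and b."""
        if a == b:
            raise ValidationError("path enumeration requires two distinct individuals")
        for x in (a, b):
            if x not in self._parents:
                raise KeyError(f"unknown individual {x!r}")
        up_a = self._ascending_chains(a, maternal_only)
        up_b = self._ascending_chains(b, maternal_only)
        by_apex: dict[str, list[tuple[str, ...]]] = {}
        for chain in up_b:
            by_apex.setdefault(chain[-1], []).append(chain)
        paths: list[GeneticPath] = []
        for chain_a in up_a:
            apex = chain_a[-1]
            for chain_b in by_apex.get(apex, ()):
                if len(chain_a) == 1 and len(chain_b) == 1:
                    continue  # would be the empty path a==b; a != b makes it unreachable
                if set(chain_a[:-1]) & set(chain_b[:-1]):
                    continue  # not simple
                nodes = chain_a + tuple(reversed(chain_b[:-1]))
                paths.append(GeneticPath(nodes, apex_index=len(chain_a) - 1))
        paths.sort(key=lambda p: p.nodes)
        return paths

    # -- relatedness -------------------------------------------------------

    def kinship_index(self, a: str, b: str) -> float:
        """Sum of (1/2)^N over all genetic paths between a and b."""
        return sum(p.contribution for p in self.enumerate_paths(a, b))

    def maternal_relatedness(self, a: str, b: str) -> float:
        """Path sum restricted to dam edges only."""
        return sum(
            p.contribution for p in self.enumerate_paths(a, b, maternal_only=True)
        )


@dataclass
class RelatednessMatrix:
    """Symmetric genetic (K) and maternal (M) relatedness over individuals."""

    individual_ids: list[str]
    K: np.ndarray
    M: np.ndarray
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._index = {ind: i for i, ind in enumerate(self.individual_ids)}

    def k(self, a: str, b: str) -> float:
        return float(self.K[self._index[a], self._index[b]])

    def m(self, a: str, b: str) -> float:
        return float(self.M[self._index[a], self._index[b]])


def relatedness_matrix(
    ped: PedigreeGraph, ids: list[str], allow_missing: bool = True
) -> RelatednessMatrix:
    """Pairwise K and M over ``ids``; diagonal fixed at 1 by convention.

    Individuals absent from the pedigree are treated as isolated founders
    (relatedness 0 to everyone) when ``allow_missing`` is true; otherwise
    they raise ``KeyError``.
    """
    n = len(ids)
    if len(set(ids)) != n:
        raise ValidationError("duplicate individual ids")
    K = np.eye(n)
    M = np.eye(n)
    present = []
    for ind in ids:
        if ind in ped:
            present.append(True)
        elif allow_missing:
            present.append(False)
        else:
            raise KeyError(f"unknown individual {ind!r}")
    for i in range(n):
        if not present[i]:
            continue
        for j in range(i + 1, n):
            if not present[j]:
                continue
            K[i, j] = K[j, i] = ped.kinship_index(ids[i], ids[j])
            M[i, j] = M[j, i] = ped.maternal_relatedness(ids[i], ids[j])
    return RelatednessMatrix(list(ids), K, M)
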