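"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive and independent of the package's own
algorithms: exhaustive simple-path enumeration on small pedigrees, the
recursive kinship coefficient, gene-dropping Monte Carlo, and per-branch
UniFrac / Faith's PD tabulation on small trees.
"""

from __future__ import annotations

import numpy as np


# ---------------------------------------------------------------------------
# Pedigree oracles.  A pedigree here is a dict: individual -> (sire, dam),
# parents None when unknown.
# ---------------------------------------------------------------------------


def brute_force_paths(ped: dict, a: str, b: str, maternal_only: bool = False):
    """All simple ascend-then-descend paths between a and b, by exhaustive
    undirected simple-path search plus a direction-pattern filter."""
    edges = {}  # (child, parent) -> label
    for child, (sire, dam) in ped.items():
        if sire is not None:
            edges[(child, sire)] = "sire"
        if dam is not None:
            edges[(child, dam)] = "dam"
    adjacency: dict[str, set[str]] = {}
    for child, parent in edges:
        adjacency.setdefault(child, set()).add(parent)
        adjacency.setdefault(parent, set()).add(child)

    results = []

    def walk(path):
        node = path[-1]
        if node == b and len(path) > 1:
            results.append(tuple(path))
            return
        for nxt in adjacency.get(node, ()):
            if nxt not in path:
                walk(path + [nxt])

    walk([a])

    def is_legal(path):
        went_down = False
        for x, y in zip(path, path[1:]):
            if (x, y) in edges:  # ascending: y is parent of x
                if went_down:
                    return False
                if maternal_only and edges[(x, y)] != "dam":
                    return False
            else:  # descending: x is parent of y
                went_down = True
                if maternal_only and edges[(y, x)] != "dam":
                    return False
        return True

    return sorted(p for p in results if is_legal(p))


def brute_force_kinship(ped: dict, a: str, b: str, maternal_only=False) -> float:
    return sum(
        0.5 ** (len(p) - 1) for p in brute_force_paths(ped, a, b, maternal_only)
    )


def recursive_relationship(ped: dict, a: str, b: str) -> float:
    """Twice the recursive kinship coefficient (non-inbred convention)."""
    depth_cache: dict[str, int] = {}

    def depth(x):
        if x not in depth_cache:
            parents = [p for p in ped.get(x, (None, None)) if p is not None]
            depth_cache[x] = 0 if not parents else 1 + max(depth(p) for p in parents)
        return depth_cache[x]

    cache: dict[tuple[str, str], float] = {}

    def phi(x, y):
        if x == y:
            return 0.5
        key = (x, y) if x <= y else (y, x)
        if key in cache:
            return cache[key]
        # recurse on the individual that cannot be an ancestor of the other
        if depth(x) < depth(y):
            x, y = y, x
        sire, dam = ped.get(x, (None, None))
        val = 0.5 * (
            (phi(sire, y) if sire is not None else 0.0)
            + (phi(dam, y) if dam is not None else 0.0)
        )
        cache[key] = val
        return val

    return 2.0 * phi(a, b)


def gene_dropping(
    ped: dict, a: str, b: str, n_rep: int = 200_000, seed: int = 0
) -> tuple[float, float]:
    """Monte-Carlo coefficient of relationship (2 * kinship coefficient).

    Founders carry two globally unique allele labels; each meiosis transmits
    one uniformly at random.  Returns (estimate, standard error of the
    estimate)."""
    rng = np.random.default_rng(seed)
    order = []
    seen = set()

    def visit(x):
        if x in seen:
            return
        seen.add(x)
        for p in ped.get(x, (None, None)):
            if p is not None:
                visit(p)
        order.append(x)

    for x in ped:
        visit(x)

    alleles: dict[str, np.ndarray] = {}
    label = 0
    for x in order:
        sire, dam = ped.get(x, (None, None))
        cols = []
        for parent in (sire, dam):
            if parent is None:
                cols.append(np.full(n_rep, label))
                label += 1
            else:
                pick = rng.integers(2, size=n_rep)
                cols.append(alleles[parent][np.arange(n_rep), pick])
        alleles[x] = np.column_stack(cols)

    aa, bb = alleles[a], alleles[b]
    # kinship coefficient: P(random allele of a IBD random allele of b)
    share = np.zeros(n_rep)
    for i in range(2):
        for j in range(2):
            share += (aa[:, i] == bb[:, j]).astype(float)
    phi_rep = share / 4.0
    r = 2.0 * phi_rep
    return float(r.mean()), float(r.std(ddof=1) / np.sqrt(n_rep))


def random_pedigree(
    n_founders: int, n_offspring: int, seed: int, non_inbred: bool = True
) -> dict:
    """Random generation-free pedigree; with ``non_inbred`` mates are only
    paired when their recursive kinship is zero."""
    rng = np.random.default_rng(seed)
    ped: dict = {}
    males, females = [], []
    for i in range(n_founders):
        name = f"F{i}"
        ped[name] = (None, None)
        (males if i % 2 == 0 else females).append(name)
    made = 0
    attempts = 0
    while made < n_offspring and attempts < 50 * n_offspring:
        attempts += 1
        if not males or not females:
            break
        sire = males[rng.integers(len(males))]
        dam = females[rng.integers(len(females))]
        if sire == dam:
            continue
        if non_inbred and recursive_relationship(ped, sire, dam) > 0:
            continue
        name = f"O{made}"
        ped[name] = (sire, dam)
        (males if rng.random() < 0.5 else females).append(name)
        made += 1
    return ped


# ---------------------------------------------------------------------------
# Tree oracles.  Trees are skbio TreeNode; samples are dicts taxon -> count.
# ---------------------------------------------------------------------------


def branch_table(tree):
    """(length, leaf set) per non-root branch."""
    out = []
    for node in tree.traverse(include_self=False):
        leaves = {t.name for t in node.tips()} or {node.name}
        out.append((float(node.length), leaves))
    return out


def brute_force_faith_pd(tree, observed: set) -> float:
    return sum(l for l, leaves in branch_table(tree) if leaves & observed)


def brute_force_unifrac(tree, counts_a: dict, counts_b: dict, mode: str) -> float:
    ta, tb = sum(counts_a.values()), sum(counts_b.values())
    num = den = 0.0
    for l, leaves in branch_table(tree):
        pa = sum(counts_a.get(x, 0) for x in leaves) / ta
        pb = sum(counts_b.get(x, 0) for x in leaves) / tb
        if mode == "unweighted":
            if (pa > 0) != (pb > 0):
                num += l
            if pa > 0 or pb > 0:
                den += l
        elif mode == "weighted_raw":
            num += l * abs(pa - pb)
            den = 1.0
        elif mode == "weighted_normalized":
            num += l * abs(pa - pb)
            den += l * (pa + pb)
        else:
            raise ValueError(mode)
    return num / den if den else 0.0
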