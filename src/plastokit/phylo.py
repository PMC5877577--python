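"""Distance-based phylogeny: p-distances, neighbor joining, and bootstrap
support on concatenated alignments.

Canonical NJ with the Q-criterion; joins are deterministic, with ties broken
by the lexicographically smallest taxon pair under each candidate node.
Negative branch lengths are clamped to zero and the deficit moved to the
sister branch, the usual convention.  Bootstrap support resamples alignment
columns with replacement, rebuilds the NJ tree per replicate, and maps split
frequencies onto the full-data tree.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class DistanceMatrix:
    taxa: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.taxa)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape does not match taxa")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix is not symmetric")
        if np.any(np.diag(self.d) != 0):
            raise ValueError("distance matrix diagonal must be zero")
        if np.any(self.d < 0):
            raise ValueError("distances must be nonnegative")


@dataclass
class Node:
    """A node of an unrooted tree, stored with an arbitrary internal root."""

    name: str | None = None
    children: list[tuple["Node", float]] = field(default_factory=list)
    support: float | None = None

    def leaves(self) -> list[str]:
        if not self.children:
            return [self.name]
        out = []
        for child, _ in self.children:
            out.extend(child.leaves())
        return out

    def newick(self, digits: int = 6) -> str:
        return self._nwk(digits) + ";"

    def _nwk(self, digits: int) -> str:
        if not self.children:
            name = self.name or ""
            if any(c in name for c in " ():,;"):
                name = f"'{name}'"
            return name
        inner = ",".join(
            f"{child._nwk(digits)}:{round(bl, digits)}" for child, bl in self.children
        )
        label = "" if self.support is None else f"{self.support:g}"
        return f"({inner}){label}"

    def splits(self) -> set[frozenset]:
        """Non-trivial splits (as the smaller-side leaf set is ambiguous on an
        unrooted tree, a split is the frozenset of leaves on the child side)."""
        all_leaves = frozenset(self.leaves())
        out: set[frozenset] = set()

        def visit(node: Node):
            side = frozenset(node.leaves())
            if 1 < len(side) < len(all_leaves) - 1:
                out.add(min(side, all_leaves - side, key=sorted))
            for child, _ in node.children:
                visit(child)

        for child, _ in self.children:
            visit(child)
        return out


def p_distance_matrix(names: list[str], rows: list[str]) -> DistanceMatrix:
    """Pairwise proportion of differing sites over gap-free, non-N columns."""
    if len(rows) < 3:
        raise ValueError("need at least three rows")
    arr = np.frombuffer("".join(rows).encode(), dtype="S1").reshape(len(rows), -1)
    n = len(rows)
    d = np.zeros((n, n))
    valid_base = (arr != b"-") & (arr != b"N")
    for i in range(n):
        for j in range(i + 1, n):
            ok = valid_base[i] & valid_base[j]
            total = int(ok.sum())
            if total == 0:
                raise ValueError(
                    f"no comparable sites between {names[i]} and {names[j]}"
                )
            diff = int((arr[i][ok] != arr[j][ok]).sum())
            d[i, j] = d[j, i] = diff / total
    return DistanceMatrix(taxa=list(names), d=d)


def neighbor_joining(dm: DistanceMatrix) -> Node:
    """Canonical neighbor joining.

    Returns an unrooted tree represented with a root of degree 3 (or 2 for
    the final join of a 4-taxon step); for 3 taxa the unique star with fitted
    lengths is returned.
    """
    taxa = list(dm.taxa)
    n = len(taxa)
    if n < 3:
        raise ValueError("neighbor joining needs at least three taxa")
    d = dm.d.astype(float).copy()
    nodes: list[Node] = [Node(name=t) for t in taxa]
    # sort key for deterministic tie-breaks: lexicographically smallest leaf
    labels: list[str] = [min(nd.leaves()) for nd in nodes]

    active = list(range(n))
    dist = {(i, j): d[i, j] for i in range(n) for j in range(n)}

    next_id = n
    store: dict[int, Node] = {i: nodes[i] for i in range(n)}
    lab: dict[int, str] = {i: labels[i] for i in range(n)}

    def D(i, j):
        return dist[(i, j)] if (i, j) in dist else dist[(j, i)]

    while len(active) > 3:
        m = len(active)
        totals = {i: sum(D(i, k) for k in active if k != i) for i in active}
        best = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * D(i, j) - totals[i] - totals[j]
                pair_key = tuple(sorted((lab[i], lab[j])))
                cand = (q, pair_key)
                if best is None or cand < best[0]:
                    best = (cand, i, j)
        _, i, j = best
        dij = D(i, j)
        li = 0.5 * dij + (totals[i] - totals[j]) / (2 * (m - 2))
        lj = dij - li
        li, lj = _clamp_pair(li, lj)
        new = Node(children=[(store[i], li), (store[j], lj)])
        lab[next_id] = min(lab[i], lab[j])
        store[next_id] = new
        for k in active:
            if k in (i, j):
                continue
            dist[(next_id, k)] = 0.5 * (D(i, k) + D(j, k) - dij)
        active = [k for k in active if k not in (i, j)] + [next_id]
        next_id += 1

    # final star of the last three nodes
    i, j, k = sorted(active, key=lambda x: lab[x])
    li = 0.5 * (D(i, j) + D(i, k) - D(j, k))
    lj = 0.5 * (D(i, j) + D(j, k) - D(i, k))
    lk = 0.5 * (D(i, k) + D(j, k) - D(i, j))
    root = Node(
        children=[
            (store[i], max(li, 0.0)),
            (store[j], max(lj, 0.0)),
            (store[k], max(lk, 0.0)),
        ]
    )
    return root


def _clamp_pair(li: float, lj: float) -> tuple[float, float]:
    """Clamp negative branch lengths to 0, moving the deficit to the sister."""
    if li < 0:
        lj += li
        li = 0.0
    if lj < 0:
        li += lj
        lj = 0.0
    return max(li, 0.0), max(lj, 0.0)


def bootstrap_support(
    names: list[str],
    rows: list[str],
    replicates: int = 1000,
    seed: int = 0,
) -> Node:
    """NJ tree from the full alignment with bootstrap supports on internal
    splits (percent of replicates containing the split)."""
    if replicates < 1:
        raise ValueError("need at least one replicate")
    full = neighbor_joining(p_distance_matrix(names, rows))
    target_splits = full.splits()
    counts = {s: 0 for s in target_splits}
    rng = np.random.default_rng(seed)
    ncols = len(rows[0])
    arr = np.array([list(r) for r in rows])
    for _ in range(replicates):
        idx = rng.integers(0, ncols, size=ncols)
        sampled = ["".join(row) for row in arr[:, idx]]
        try:
            rep = neighbor_joining(p_distance_matrix(names, sampled))
        except ValueError:
            continue
        rep_splits = rep.splits()
        for s in target_splits:
            if s in rep_splits:
                counts[s] += 1

    def annotate(node: Node, all_leaves: frozenset):
        for child, _ in node.children:
            side = frozenset(child.leaves())
            if 1 < len(side) < len(all_leaves) - 1:
                key = min(side, all_leaves - side, key=sorted)
                child.support = round(100.0 * counts[key] / replicates, 1)
            annotate(child, all_leaves)

    annotate(full, frozenset(full.leaves()))
    return full


def root_at_outgroup(tree: Node, outgroup: str) -> Node:
    """Display-rooting only: return the tree re-listed so the outgroup leaf is
    the first child of the root (topology unchanged)."""
    def has_leaf(node: Node) -> bool:
        return outgroup in node.leaves()

    tree.children.sort(key=lambda c: (not has_leaf(c[0]), min(c[0].leaves())))
    return tree
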