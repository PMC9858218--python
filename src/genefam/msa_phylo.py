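"""Progressive multiple alignment, Jukes-Cantor distances and UPGMA trees.

The phylogeny stack is deliberately self-contained and deterministic:

* a guide tree from UPGMA on 3-mer count distances;
* profile-profile Needleman-Wunsch merges with sum-of-pairs scoring;
* Jukes-Cantor distances ``d = -b ln(1 - p/b)`` with ``b = 19/20`` for
  proteins and ``3/4`` for nucleotides, pairwise deletion for gaps;
* UPGMA with size-weighted averaging, node height = join distance / 2,
  and ties broken by the lexicographically smallest member id, so the
  same input always yields the same Newick string.

Trees produced by UPGMA are ultrametric (all leaves equidistant from the
root); cutting the k-1 highest joins partitions the leaves into k groups.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np


@dataclass
class Msa:
    """An alignment: parallel lists of ids and equal-length gapped rows."""

    ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows differ in length")
        if self.rows and len({len(r) for r in self.rows}) != 1:
            raise ValueError("alignment rows differ in length")

    def ungapped(self, i: int) -> str:
        return self.rows[i].replace("-", "")


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distances with a saturation mask."""

    ids: list[str]
    d: np.ndarray
    saturated: np.ndarray = None

    def __post_init__(self) -> None:
        n = len(self.ids)
        self.d = np.asarray(self.d, dtype=float)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape mismatch")
        if self.saturated is None:
            self.saturated = np.zeros((n, n), dtype=bool)
        if not np.allclose(self.d, self.d.T, equal_nan=True):
            raise ValueError("distance matrix not symmetric")


@dataclass
class TreeNode:
    """A rooted binary (ultrametric) tree node."""

    height: float
    children: tuple["TreeNode", "TreeNode"] | tuple = ()
    leaf_id: str | None = None

    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf():
            return [self.leaf_id]
        out: list[str] = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def min_leaf(self) -> str:
        return min(self.leaves())

    def to_newick(self) -> str:
        """Newick with canonical child ordering (by smallest leaf id)."""
        return self._newick_inner() + ";"

    def _newick_inner(self) -> str:
        if self.is_leaf():
            return self.leaf_id
        kids = sorted(self.children, key=lambda c: c.min_leaf())
        parts = [f"{c._newick_inner()}:{self.height - c.height:.6f}"
                 for c in kids]
        return "(" + ",".join(parts) + ")"


# ---------------------------------------------------------------------------
# Progressive MSA
# ---------------------------------------------------------------------------

def kmer_distance_matrix(ids: Sequence[str], seqs: Sequence[str],
                         k: int = 3) -> DistanceMatrix:
    """1 - fractional shared k-mer count; cheap guide-tree distance."""
    k = max(1, min(k, min(len(s) for s in seqs)))
    counts = []
    for s in seqs:
        c: dict[str, int] = {}
        for i in range(len(s) - k + 1):
            w = s[i:i + k]
            c[w] = c.get(w, 0) + 1
        counts.append(c)
    n = len(seqs)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            shared = sum(min(v, counts[j].get(w, 0))
                         for w, v in counts[i].items())
            denom = min(len(seqs[i]), len(seqs[j])) - k + 1
            d[i, j] = d[j, i] = 1.0 - shared / denom
    return DistanceMatrix(list(ids), d)


def _profile_align(rows_a: list[str], rows_b: list[str],
                   sub: Mapping[tuple[str, str], float],
                   gap: float) -> tuple[list[str], list[str]]:
    """Needleman-Wunsch on two profiles with sum-of-pairs column scores."""
    na, nb = len(rows_a[0]), len(rows_b[0])
    cols_a = ["".join(r[i] for r in rows_a) for i in range(na)]
    cols_b = ["".join(r[j] for r in rows_b) for j in range(nb)]

    def col_score(ca: str, cb: str) -> float:
        s = 0.0
        for x in ca:
            for y in cb:
                if x == "-" or y == "-":
                    s -= gap if (x == "-") != (y == "-") else 0.0
                else:
                    s += sub[(x, y)]
        return s

    gap_a = gap * len(rows_a)  # cost of a gap column against profile A rows
    gap_b = gap * len(rows_b)
    F = np.zeros((na + 1, nb + 1))
    ptr = np.zeros((na + 1, nb + 1), dtype=np.int8)  # 0 diag, 1 up, 2 left
    for i in range(1, na + 1):
        F[i, 0] = -gap_b * i
        ptr[i, 0] = 1
    for j in range(1, nb + 1):
        F[0, j] = -gap_a * j
        ptr[0, j] = 2
    for i in range(1, na + 1):
        for j in range(1, nb + 1):
            cand = (F[i - 1, j - 1] + col_score(cols_a[i - 1], cols_b[j - 1]),
                    F[i - 1, j] - gap_b,
                    F[i, j - 1] - gap_a)
            best = max(cand)
            ptr[i, j] = cand.index(best)
            F[i, j] = best
    out_a: list[list[str]] = [[] for _ in rows_a]
    out_b: list[list[str]] = [[] for _ in rows_b]
    i, j = na, nb
    while i > 0 or j > 0:
        move = ptr[i, j]
        if move == 0:
            for r, row in zip(out_a, rows_a):
                r.append(row[i - 1])
            for r, row in zip(out_b, rows_b):
                r.append(row[j - 1])
            i -= 1
            j -= 1
        elif move == 1:
            for r, row in zip(out_a, rows_a):
                r.append(row[i - 1])
            for r in out_b:
                r.append("-")
            i -= 1
        else:
            for r in out_a:
                r.append("-")
            for r, row in zip(out_b, rows_b):
                r.append(row[j - 1])
            j -= 1
    return (["".join(reversed(r)) for r in out_a],
            ["".join(reversed(r)) for r in out_b])


def progressive_msa(sequences: Mapping[str, str],
                    matrix: Mapping[tuple[str, str], float] | None = None,
                    gap: float = 4.0, guide_k: int = 3) -> Msa:
    """Progressive alignment along a UPGMA guide tree on k-mer distances."""
    ids = list(sequences)
    if not ids:
        raise ValueError("no sequences")
    if len(ids) == 1:
        return Msa(ids, [sequences[ids[0]]])
    if matrix is None:
        from .pairwise_dup import _default_matrix
        matrix = _default_matrix()
    guide = upgma(kmer_distance_matrix(ids, [sequences[i] for i in ids],
                                       k=guide_k))

    def merge(node: TreeNode) -> tuple[list[str], list[str]]:
        if node.is_leaf():
            return [node.leaf_id], [sequences[node.leaf_id]]
        kids = sorted(node.children, key=lambda c: c.min_leaf())
        ids_a, rows_a = merge(kids[0])
        ids_b, rows_b = merge(kids[1])
        rows_a, rows_b = _profile_align(rows_a, rows_b, matrix, gap)
        return ids_a + ids_b, rows_a + rows_b

    out_ids, out_rows = merge(guide)
    # restore input order
    order = {pid: i for i, pid in enumerate(out_ids)}
    return Msa(ids, [out_rows[order[pid]] for pid in ids])


# ---------------------------------------------------------------------------
# Jukes-Cantor distances
# ---------------------------------------------------------------------------

def jc_distance(msa: Msa, mode: str = "protein") -> DistanceMatrix:
    """Jukes-Cantor corrected distances with pairwise deletion.

    ``p`` is the mismatch fraction over columns where both rows carry a
    residue; ``d = -b ln(1 - p/b)``.  Pairs with ``p >= b`` are flagged
    saturated (distance set to inf).
    """
    if mode == "protein":
        b = 19.0 / 20.0
    elif mode == "nucleotide":
        b = 3.0 / 4.0
    else:
        raise ValueError(f"unknown mode {mode!r}")
    n = len(msa.ids)
    d = np.zeros((n, n))
    sat = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(i + 1, n):
            comparable = mismatch = 0
            for x, y in zip(msa.rows[i], msa.rows[j]):
                if x != "-" and y != "-":
                    comparable += 1
                    if x != y:
                        mismatch += 1
            if comparable == 0:
                raise ValueError(
                    f"no comparable columns between {msa.ids[i]} and {msa.ids[j]}")
            p = mismatch / comparable
            if p >= b:
                d[i, j] = d[j, i] = math.inf
                sat[i, j] = sat[j, i] = True
            else:
                d[i, j] = d[j, i] = -b * math.log(1.0 - p / b)
    return DistanceMatrix(list(msa.ids), d, sat)


# ---------------------------------------------------------------------------
# UPGMA
# ---------------------------------------------------------------------------

def upgma(dm: DistanceMatrix) -> TreeNode:
    """UPGMA clustering: join the closest pair, size-weighted averaging.

    Deterministic: distance ties break on the lexicographically smallest
    member ids of the candidate clusters.
    """
    n = len(dm.ids)
    if n < 2:
        raise ValueError("UPGMA needs at least two taxa")
    if dm.saturated is not None and dm.saturated.any():
        raise ValueError("distance matrix contains saturated entries")
    nodes: dict[int, TreeNode] = {
        i: TreeNode(0.0, leaf_id=dm.ids[i]) for i in range(n)}
    sizes = {i: 1 for i in range(n)}
    reps = {i: dm.ids[i] for i in range(n)}
    dist = {frozenset((i, j)): float(dm.d[i, j])
            for i in range(n) for j in range(i + 1, n)}
    active = set(range(n))
    next_idx = n
    while len(active) > 1:
        best = None
        for key, dij in dist.items():
            i, j = sorted(key, key=lambda x: reps[x])
            cand = (dij, reps[i], reps[j])
            if best is None or cand < best[0]:
                best = (cand, i, j)
        (dij, _, _), i, j = best
        node = TreeNode(dij / 2.0, children=(nodes[i], nodes[j]))
        for other in active - {i, j}:
            dio = dist.pop(frozenset((i, other)))
            djo = dist.pop(frozenset((j, other)))
            new_d = (dio * sizes[i] + djo * sizes[j]) / (sizes[i] + sizes[j])
            dist[frozenset((next_idx, other))] = new_d
        dist.pop(frozenset((i, j)))
        nodes[next_idx] = node
        sizes[next_idx] = sizes[i] + sizes[j]
        reps[next_idx] = min(reps[i], reps[j])
        active -= {i, j}
        active.add(next_idx)
        for k in (i, j):
            del nodes[k], sizes[k], reps[k]
        next_idx += 1
    return nodes[active.pop()]


def cut_groups(tree: TreeNode, k: int) -> list[list[str]]:
    """Partition leaves into k groups by removing the k-1 highest joins.

    Groups are returned sorted by their smallest leaf id.
    """
    n_leaves = len(tree.leaves())
    if not 1 <= k <= n_leaves:
        raise ValueError(f"k must be in [1, {n_leaves}]")
    parts = [tree]
    while len(parts) < k:
        # split the subtree with the highest join; ties by smallest leaf id
        idx = min((i for i in range(len(parts)) if not parts[i].is_leaf()),
                  key=lambda i: (-parts[i].height, parts[i].min_leaf()))
        node = parts.pop(idx)
        parts.extend(node.children)
    groups = [sorted(p.leaves()) for p in parts]
    return sorted(groups, key=lambda g: g[0])


# ---------------------------------------------------------------------------
# Shared k-mer summary (qualitative stand-in for motif discovery)
# ---------------------------------------------------------------------------

def shared_kmer_report(subfamily_sequences: Mapping[str, Mapping[str, str]],
                       k: int = 10, top: int = 5) -> dict[str, list[tuple[str, int]]]:
    """Per subfamily, the top substrings of length k ranked by how many
    members contain them (ties broken lexicographically)."""
    report: dict[str, list[tuple[str, int]]] = {}
    for label in sorted(subfamily_sequences):
        seqs = subfamily_sequences[label]
        counts: dict[str, int] = {}
        for seq in seqs.values():
            present = {seq[i:i + k] for i in range(len(seq) - k + 1)}
            for w in present:
                counts[w] = counts.get(w, 0) + 1
        ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
        report[label] = ranked[:top]
    return report
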