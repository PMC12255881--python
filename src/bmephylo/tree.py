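"""Unrooted binary trees, path-length matrices, and balanced tree lengths.

The central objects of balanced minimum evolution (BME) inference:

* :class:`DistanceMatrix` — a symmetric matrix of evolutionary distance
  estimates between ``n`` taxa.
* :class:`UnrootedBinaryTree` (UBT) — a leaf-labelled unrooted tree whose
  internal nodes all have degree 3; the search space of BME has
  ``(2n-5)!!`` such topologies.
* :class:`PathLengthMatrix` (PLM) — the integer matrix ``tau`` whose entry
  ``tau[i, j]`` counts the edges on the unique leaf path between taxa ``i``
  and ``j`` of a UBT.

The BME tree length of a topology is

    ell(tau) = sum_{i != j} d_ij * 2**(-tau_ij)

(sum over *ordered* pairs), and the inference problem is to minimise it
over all UBTs.  A square integer matrix is the PLM of some UBT exactly
when it satisfies a small family of conditions: symmetry and range,
metricity, per-row Kraft equalities ``sum_j 2**-tau_ij = 1/2``, a strong
four-point trichotomy on every leaf triple, and the "UBT manifold"
identity ``sum_{i != j} tau_ij 2**-tau_ij = 2n - 3``.  :func:`validate_plm`
checks each family; :func:`plm_to_tree` inverts a valid PLM back to its
(unique) topology by iteratively collapsing cherries.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Iterator, Sequence, Union

import numpy as np

__all__ = [
    "DistanceMatrix",
    "UnrootedBinaryTree",
    "PathLengthMatrix",
    "PartialTree",
    "PLMValidation",
    "TreeStructureError",
    "tree_to_plm",
    "validate_plm",
    "plm_to_tree",
    "bme_length",
    "generalized_tree_length",
    "enumerate_ubts",
    "canonical_signature",
    "num_ubts",
    "write_newick",
    "read_newick",
]


class TreeStructureError(ValueError):
    """A graph handed in as a tree violates UBT structure."""


# ---------------------------------------------------------------------------
# distance matrices
# ---------------------------------------------------------------------------

class DistanceMatrix:
    """Symmetric matrix of pairwise dissimilarities over labelled taxa.

    Parameters
    ----------
    values : (n, n) array_like
        Symmetric, zero diagonal, non-negative entries.
    taxa : sequence of str, optional
        Distinct labels; defaults to ``t1 ... tn``.
    require_positive : bool
        Demand strictly positive off-diagonal entries (the biological
        contract).  Synthetic generators keep this on; reduced matrices
        built during agglomeration keep it off for robustness.
    """

    __slots__ = ("values", "taxa")

    def __init__(self, values, taxa: Sequence[str] | None = None,
                 require_positive: bool = True):
        values = np.asarray(values, dtype=float)
        if values.ndim != 2 or values.shape[0] != values.shape[1]:
            raise ValueError("distance matrix must be square")
        n = values.shape[0]
        if n < 3:
            raise ValueError(f"need at least 3 taxa, got {n}")
        if not np.allclose(values, values.T, atol=1e-8):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.abs(np.diag(values)) > 0):
            raise ValueError("distance matrix diagonal must be zero")
        off = values[~np.eye(n, dtype=bool)]
        if np.any(off < 0):
            raise ValueError("distances must be non-negative")
        if require_positive and np.any(off == 0):
            i, j = np.argwhere((values == 0) & ~np.eye(n, dtype=bool))[0]
            raise ValueError(
                f"off-diagonal distance d[{i},{j}] is zero; "
                "biological distance matrices must be strictly positive")
        if taxa is None:
            taxa = tuple(f"t{k + 1}" for k in range(n))
        else:
            taxa = tuple(str(t) for t in taxa)
            if len(taxa) != n:
                raise ValueError("taxa/matrix size mismatch")
            if len(set(taxa)) != n:
                raise ValueError("taxa labels must be distinct")
        # symmetrise exactly so downstream arithmetic is order-insensitive
        object.__setattr__(self, "values", (values + values.T) / 2.0)
        object.__setattr__(self, "taxa", taxa)

    def __setattr__(self, *a):  # immutable surface
        raise AttributeError("DistanceMatrix is immutable")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def subset_first(self, n: int) -> "DistanceMatrix":
        """Leading principal ``n x n`` submatrix with its labels."""
        if n > self.n:
            raise ValueError(f"cannot take first {n} taxa of {self.n}")
        return DistanceMatrix(self.values[:n, :n], self.taxa[:n],
                              require_positive=False)

    def __repr__(self):
        return f"DistanceMatrix(n={self.n}, taxa={self.taxa[:3]}...)"


# ---------------------------------------------------------------------------
# unrooted binary trees
# ---------------------------------------------------------------------------

class UnrootedBinaryTree:
    """Leaf-labelled unrooted binary tree.

    Leaves are integers ``0..n-1`` (indices into ``taxa``); internal nodes
    are arbitrary larger integers.  ``adjacency`` maps node -> frozenset of
    neighbours.  Validation enforces: connected, acyclic, ``n`` leaves of
    degree 1, ``n - 2`` internal nodes of degree 3, hence ``2n - 3`` edges.
    """

    __slots__ = ("taxa", "adjacency", "_plm")

    def __init__(self, adjacency: dict[int, Iterable[int]],
                 taxa: Sequence[str] | None = None, validate: bool = True):
        adj = {u: frozenset(vs) for u, vs in adjacency.items()}
        leaves = sorted(u for u, vs in adj.items() if len(vs) == 1)
        n = len(leaves)
        if taxa is None:
            taxa = tuple(f"t{k + 1}" for k in range(n))
        else:
            taxa = tuple(str(t) for t in taxa)
        if validate:
            self._validate(adj, leaves, taxa)
        object.__setattr__(self, "adjacency", adj)
        object.__setattr__(self, "taxa", taxa)
        object.__setattr__(self, "_plm", None)

    def __setattr__(self, *a):
        raise AttributeError("UnrootedBinaryTree is immutable")

    @staticmethod
    def _validate(adj, leaves, taxa):
        n = len(leaves)
        if n < 3:
            raise TreeStructureError(f"need >= 3 leaves, found {n}")
        if leaves != list(range(n)):
            raise TreeStructureError(
                f"leaves must be labelled 0..{n - 1}, found {leaves}")
        if len(taxa) != n:
            raise TreeStructureError("taxa/leaf count mismatch")
        for u, vs in adj.items():
            if u in vs:
                raise TreeStructureError(f"self-loop at node {u}")
            deg = len(vs)
            if u < n and deg != 1:
                raise TreeStructureError(f"leaf {u} has degree {deg}")
            if u >= n and deg != 3:
                raise TreeStructureError(f"internal node {u} has degree {deg}")
            for v in vs:
                if v not in adj or u not in adj[v]:
                    raise TreeStructureError(f"edge {u}-{v} is not mutual")
        if len(adj) != 2 * n - 2:
            raise TreeStructureError(
                f"expected {2 * n - 2} nodes, found {len(adj)}")
        n_edges = sum(len(vs) for vs in adj.values()) // 2
        if n_edges != 2 * n - 3:
            raise TreeStructureError(
                f"expected {2 * n - 3} edges, found {n_edges}")
        # connectivity (acyclicity follows from node/edge counts)
        seen = {leaves[0]}
        stack = [leaves[0]]
        while stack:
            u = stack.pop()
            for v in adj[u]:
                if v not in seen:
                    seen.add(v)
                    stack.append(v)
        if len(seen) != len(adj):
            missing = sorted(set(adj) - seen)[0]
            raise TreeStructureError(f"tree is disconnected at node {missing}")

    @property
    def n(self) -> int:
        return len(self.taxa)

    def edges(self) -> Iterator[tuple[int, int]]:
        for u, vs in self.adjacency.items():
            for v in vs:
                if u < v:
                    yield (u, v)

    def path_lengths(self) -> np.ndarray:
        """Integer matrix of edge counts between all leaf pairs (BFS)."""
        n = self.n
        tau = np.zeros((n, n), dtype=int)
        for src in range(n):
            dist = {src: 0}
            q = deque([src])
            while q:
                u = q.popleft()
                for v in self.adjacency[u]:
                    if v not in dist:
                        dist[v] = dist[u] + 1
                        q.append(v)
            for leaf in range(n):
                tau[src, leaf] = dist[leaf]
        return tau

    def splits(self) -> frozenset[frozenset[int]]:
        """Nontrivial leaf bipartitions, each as the side without leaf 0."""
        n = self.n
        out = set()
        for u, v in self.edges():
            if u < n or v < n:
                continue  # trivial split
            side = self._component(v, without=u)
            leaf_side = frozenset(x for x in side if x < n)
            if 0 in leaf_side:
                leaf_side = frozenset(range(n)) - leaf_side
            out.add(leaf_side)
        return frozenset(out)

    def _component(self, start: int, without: int) -> set[int]:
        seen = {start}
        stack = [start]
        while stack:
            u = stack.pop()
            for v in self.adjacency[u]:
                if v != without and v not in seen:
                    seen.add(v)
                    stack.append(v)
        return seen

    def __repr__(self):
        return f"UnrootedBinaryTree(n={self.n})"


# ---------------------------------------------------------------------------
# path-length matrices and validation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PLMValidation:
    """Per-condition-family report of a path-length-matrix check."""

    shape_ok: bool          # zero diagonal, symmetric, entries in [2, n-1]
    metric_ok: bool         # tau_1i + tau_1j >= 2 + tau_ij and permutations
    kraft_ok: bool          # every row of 2**-tau sums to exactly 1/2
    four_point_ok: bool     # exactly one strong four-point case per triple
    manifold_ok: bool       # sum_{i != j} tau_ij 2**-tau_ij == 2n - 3
    messages: tuple[str, ...] = ()

    @property
    def valid(self) -> bool:
        return (self.shape_ok and self.metric_ok and self.kraft_ok
                and self.four_point_ok and self.manifold_ok)

    def __bool__(self) -> bool:
        return self.valid


class PathLengthMatrix:
    """Thin wrapper over an integer matrix of leaf-path edge counts."""

    __slots__ = ("values",)

    def __init__(self, values):
        values = np.asarray(values)
        if values.ndim != 2 or values.shape[0] != values.shape[1]:
            raise ValueError("PLM must be square")
        object.__setattr__(self, "values", values)

    def __setattr__(self, *a):
        raise AttributeError("PathLengthMatrix is immutable")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def validate(self) -> PLMValidation:
        return validate_plm(self.values)

    def __eq__(self, other):
        other = other.values if isinstance(other, PathLengthMatrix) else other
        return np.array_equal(self.values, other)

    def __hash__(self):
        return hash(self.values.tobytes())

    def __repr__(self):
        return f"PathLengthMatrix(n={self.n})"


MatrixLike = Union[np.ndarray, PathLengthMatrix, Sequence[Sequence[float]]]


def _as_array(m: MatrixLike) -> np.ndarray:
    if isinstance(m, PathLengthMatrix):
        return m.values
    return np.asarray(m)


def tree_to_plm(tree: UnrootedBinaryTree) -> PathLengthMatrix:
    """Path-length matrix of a UBT: entry (i, j) counts edges on the i-j path."""
    if tree._plm is None:
        object.__setattr__(tree, "_plm", PathLengthMatrix(tree.path_lengths()))
    return tree._plm


def validate_plm(m: MatrixLike, tol: float = 1e-9) -> PLMValidation:
    """Check whether an integer matrix encodes the PLM of some UBT.

    Reports pass/fail per condition family; ``.valid`` is the conjunction.
    Integer input is checked with exact dyadic arithmetic (powers of two
    and their small sums are exact in binary floating point); ``tol`` only
    applies if a float matrix is passed.
    """
    tau = _as_array(m)
    if tau.ndim != 2 or tau.shape[0] != tau.shape[1]:
        raise ValueError("input must be a square matrix")
    n = tau.shape[0]
    if n < 3:
        raise ValueError("PLM order must be >= 3")
    exact = np.issubdtype(tau.dtype, np.integer)
    if not exact:
        if not np.allclose(tau, np.round(tau), atol=tol):
            return PLMValidation(False, False, False, False, False,
                                 ("entries are not integers",))
        tau = np.round(tau).astype(int)
    msgs: list[str] = []

    off = ~np.eye(n, dtype=bool)
    shape_ok = (np.all(np.diag(tau) == 0) and np.array_equal(tau, tau.T)
                and np.all(tau[off] >= 2) and np.all(tau[off] <= n - 1))
    if not shape_ok:
        msgs.append("shape/range conditions failed "
                    "(diagonal, symmetry, or entries outside [2, n-1])")

    # metricity anchored at taxon 0 (the paper's taxon 1)
    metric_ok = True
    for i, j in combinations(range(1, n), 2):
        if tau[0, i] + tau[0, j] < 2 + tau[i, j] or \
           tau[0, i] + tau[i, j] < 2 + tau[0, j] or \
           tau[0, j] + tau[i, j] < 2 + tau[0, i]:
            metric_ok = False
            msgs.append(f"metric condition failed on triple (0,{i},{j})")
            break

    pow2 = np.where(off, np.exp2(-tau.astype(float)), 0.0)
    row = pow2.sum(axis=1)
    kraft_ok = bool(np.all(row == 0.5)) if exact else \
        bool(np.all(np.abs(row - 0.5) <= tol))
    if not kraft_ok:
        bad = int(np.argmax(np.abs(row - 0.5)))
        msgs.append(f"Kraft equality failed: row {bad} of 2**-tau sums "
                    f"to {row[bad]!r}, expected 0.5")

    manifold = float((tau * pow2).sum())
    manifold_ok = manifold == 2 * n - 3 if exact else \
        abs(manifold - (2 * n - 3)) <= tol
    if not manifold_ok:
        msgs.append(f"manifold identity failed: sum tau*2**-tau = {manifold}, "
                    f"expected {2 * n - 3}")

    four_ok = True
    for j, p, q in combinations(range(1, n), 3):
        s1 = tau[0, j] + tau[p, q]
        s2 = tau[0, p] + tau[j, q]
        s3 = tau[0, q] + tau[j, p]
        holds = ((s1 + 2 <= s2 and s2 == s3)
                 + (s2 + 2 <= s1 and s1 == s3)
                 + (s3 + 2 <= s1 and s1 == s2))
        if holds != 1:
            four_ok = False
            msgs.append("strong four-point condition failed on triple "
                        f"(0,{j},{p},{q}): sums {s1},{s2},{s3}")
            break

    return PLMValidation(bool(shape_ok), metric_ok, kraft_ok, four_ok,
                         manifold_ok, tuple(msgs))


# ---------------------------------------------------------------------------
# tree length
# ---------------------------------------------------------------------------

def bme_length(d: DistanceMatrix | np.ndarray, m: MatrixLike) -> float:
    """Balanced tree length: ordered-pair sum of ``d_ij * 2**-tau_ij``.

    ``m`` may hold fractional entries (LP estimates); only the diagonal is
    ignored.
    """
    dv = d.values if isinstance(d, DistanceMatrix) else np.asarray(d, float)
    tau = _as_array(m).astype(float)
    if dv.shape != tau.shape:
        raise ValueError(f"order mismatch: d is {dv.shape}, tau is {tau.shape}")
    off = ~np.eye(dv.shape[0], dtype=bool)
    return float((dv[off] * np.exp2(-tau[off])).sum())


# ---------------------------------------------------------------------------
# partial trees (agglomeration forests)
# ---------------------------------------------------------------------------

# A cluster is either a leaf index (int) or a pair (left, right) of clusters;
# merging two clusters creates their common-ancestor node.
Cluster = Union[int, tuple]


def cluster_leaves(c: Cluster) -> Iterator[int]:
    if isinstance(c, int):
        yield c
    else:
        yield from cluster_leaves(c[0])
        yield from cluster_leaves(c[1])


def cluster_signature(c: Cluster):
    if isinstance(c, int):
        return c
    return frozenset((cluster_signature(c[0]), cluster_signature(c[1])))


@dataclass(frozen=True)
class PartialTree:
    """Star of cluster subtrees around a central node ``mu``.

    ``clusters`` are the current agglomeration clusters; each non-singleton
    cluster is a rooted binary merge tree whose root (the cluster's common
    ancestor) attaches to ``mu``.  At step ``r = 1`` all clusters are
    singletons (``s_ij = 2`` for every pair); when only three clusters
    remain the star is a valid UBT.
    """

    n: int
    clusters: tuple[Cluster, ...]

    def __post_init__(self):
        leaves = sorted(x for c in self.clusters for x in cluster_leaves(c))
        if leaves != list(range(self.n)):
            raise TreeStructureError("clusters do not partition the taxa")

    def to_graph(self) -> dict[int, set[int]]:
        """Adjacency of the star-of-clusters tree (mu = node ``2n - 3``)."""
        adj: dict[int, set[int]] = {}
        mu = 2 * self.n - 3
        adj[mu] = set()
        next_id = [self.n]

        def build(c: Cluster) -> int:
            if isinstance(c, int):
                adj.setdefault(c, set())
                return c
            root = next_id[0]
            next_id[0] += 1
            adj[root] = set()
            for child in c:
                cid = build(child)
                adj[root].add(cid)
                adj[cid].add(root)
            return root

        for c in self.clusters:
            cid = build(c)
            adj[mu].add(cid)
            adj[cid].add(mu)
        return adj

    def to_tree(self, taxa: Sequence[str] | None = None) -> UnrootedBinaryTree:
        if len(self.clusters) != 3:
            raise TreeStructureError(
                f"partial tree with {len(self.clusters)} clusters is not a UBT")
        adj = self.to_graph()
        # relabel internal ids contiguously n..2n-3
        internal = sorted(u for u in adj if u >= self.n)
        remap = {u: u for u in adj if u < self.n}
        remap.update({u: self.n + k for k, u in enumerate(internal)})
        adj2 = {remap[u]: {remap[v] for v in vs} for u, vs in adj.items()}
        return UnrootedBinaryTree(adj2, taxa)

    def topological_distances(self) -> np.ndarray:
        """Leaf-pair edge counts ``s_ij`` on the current star tree."""
        adj = self.to_graph()
        n = self.n
        s = np.zeros((n, n), dtype=int)
        for src in range(n):
            dist = {src: 0}
            q = deque([src])
            while q:
                u = q.popleft()
                for v in adj[u]:
                    if v not in dist:
                        dist[v] = dist[u] + 1
                        q.append(v)
            for leaf in range(n):
                s[src, leaf] = dist[leaf]
        return s


def generalized_tree_length(t: PartialTree, d: DistanceMatrix | np.ndarray) -> float:
    """Balanced length of a partial (star-of-clusters) tree.

    Direct evaluation of the product-form tree length: for each ordered
    leaf pair, ``d_ij`` is weighted by ``prod (delta(k) - 1)**-1`` over the
    internal nodes ``k`` of the i-j path, where ``delta`` is the node
    degree.  A global factor 1/2 puts the result on the canonical
    ordered-pair scale, so on a completed UBT it equals :func:`bme_length`.
    """
    dv = d.values if isinstance(d, DistanceMatrix) else np.asarray(d, float)
    if dv.shape[0] != t.n:
        raise ValueError("distance matrix / partial tree order mismatch")
    adj = t.to_graph()
    deg = {u: len(vs) for u, vs in adj.items()}
    total = 0.0
    for i in range(t.n):
        # BFS recording paths from leaf i
        parent = {i: None}
        q = deque([i])
        while q:
            u = q.popleft()
            for v in adj[u]:
                if v not in parent:
                    parent[v] = u
                    q.append(v)
        for j in range(t.n):
            if j == i:
                continue
            w = 1.0
            u = parent[j]
            while u is not None and u != i:
                w /= deg[u] - 1
                u = parent[u]
            total += dv[i, j] * w
    return total / 2.0


# ---------------------------------------------------------------------------
# enumeration, reconstruction, signatures
# ---------------------------------------------------------------------------

def num_ubts(n: int) -> int:
    """(2n-5)!! — the number of leaf-labelled UBTs on n taxa."""
    out = 1
    for k in range(3, 2 * n - 4, 2):
        out *= k
    return out


def enumerate_ubts(n: int, taxa: Sequence[str] | None = None
                   ) -> Iterator[UnrootedBinaryTree]:
    """Yield every leaf-labelled UBT on ``n`` taxa exactly once.

    Stepwise leaf insertion: leaf ``k`` is grafted into every edge of
    every tree on leaves ``0..k-1``, in taxa order, giving a deterministic
    sequence of ``(2n-5)!!`` trees.  Guarded to ``n <= 9`` (2 027 025
    trees at n=9) because the count grows as a double factorial.
    """
    if not 3 <= n <= 9:
        raise ValueError(
            f"enumerate_ubts supports 3 <= n <= 9 (got {n}): the number of "
            "topologies (2n-5)!! grows too fast for exhaustive enumeration")

    def grow(adj: dict[int, set[int]], k: int, next_internal: int):
        if k == n:
            yield UnrootedBinaryTree({u: frozenset(v) for u, v in adj.items()},
                                     taxa, validate=False)
            return
        edges = [(u, v) for u in sorted(adj) for v in sorted(adj[u]) if u < v]
        for u, v in edges:
            w = next_internal
            adj[u].remove(v); adj[v].remove(u)
            adj[w] = {u, v, k}
            adj[u].add(w); adj[v].add(w)
            adj[k] = {w}
            yield from grow(adj, k + 1, next_internal + 1)
            del adj[k], adj[w]
            adj[u].discard(w); adj[v].discard(w)
            adj[u].add(v); adj[v].add(u)

    base = {0: {n}, 1: {n}, 2: {n}, n: {0, 1, 2}}
    yield from grow(base, 3, n + 1)


def plm_to_tree(m: MatrixLike, taxa: Sequence[str] | None = None
                ) -> UnrootedBinaryTree:
    """Reconstruct the unique UBT whose path-length matrix is ``m``.

    Iteratively merges a pair of active nodes at topological distance 2
    (a cherry) and reduces the matrix by ``tau_vk = tau_ik - 1``; a valid
    PLM always exposes a cherry and satisfies ``tau_ik == tau_jk`` for the
    merged pair, so failure of either signals "not a PLM".
    """
    tau = _as_array(m)
    if not np.issubdtype(tau.dtype, np.integer):
        if not np.allclose(tau, np.round(tau), atol=1e-9):
            raise ValueError("not a PLM: entries are not integers")
        tau = np.round(tau).astype(int)
    n = tau.shape[0]
    if tau.shape != (n, n) or n < 3:
        raise ValueError("PLM must be square of order >= 3")
    clusters: list[Cluster] = list(range(n))
    t = tau.copy()
    while len(clusters) > 3:
        m_ = len(clusters)
        cherry = None
        for i in range(m_):
            for j in range(i + 1, m_):
                if t[i, j] == 2:
                    cherry = (i, j)
                    break
            if cherry:
                break
        if cherry is None:
            raise ValueError("not a PLM: no pair at topological distance 2")
        i, j = cherry
        rest = [k for k in range(m_) if k not in (i, j)]
        if any(t[i, k] != t[j, k] for k in rest):
            raise ValueError(
                "not a PLM: inconsistent reduction (tau_ik != tau_jk for a "
                "cherry {i,j})")
        new_row = np.array([t[i, k] - 1 for k in rest])
        if np.any(new_row < 2) and len(rest) > 2:
            pass  # entries of 2 are fine; < 2 impossible since t >= 2 and t[i,k] >= 3 unless cherry
        keep = np.ix_(rest, rest)
        t2 = np.zeros((m_ - 1, m_ - 1), dtype=int)
        t2[:-1, :-1] = t[keep]
        t2[-1, :-1] = new_row
        t2[:-1, -1] = new_row
        merged = (clusters[i], clusters[j])
        clusters = [clusters[k] for k in rest] + [merged]
        t = t2
    if not np.all(t[~np.eye(len(clusters), dtype=bool)] == 2):
        raise ValueError("not a PLM: final three nodes not mutually adjacent")
    return PartialTree(n, tuple(clusters)).to_tree(taxa)


def canonical_signature(t: UnrootedBinaryTree | PartialTree):
    """Hashable token equal for leaf-label-isomorphic structures.

    UBTs: the set of nontrivial leaf bipartitions (splits), the standard
    topology identifier.  Partial trees: the set of recursive cluster
    shapes, stable across merge orders that build the same forest.
    """
    if isinstance(t, UnrootedBinaryTree):
        return ("ubt", t.splits())
    if isinstance(t, PartialTree):
        return ("forest", frozenset(cluster_signature(c) for c in t.clusters))
    raise TypeError(f"unsupported structure {type(t)!r}")


# ---------------------------------------------------------------------------
# Newick
# ---------------------------------------------------------------------------

def write_newick(tree: UnrootedBinaryTree, branch_lengths: bool = False) -> str:
    """Newick string with a trifurcating root at an internal node.

    The root is the internal node adjacent to the first taxon; branch
    lengths are omitted by default (or written as 1 when requested).
    """
    root = next(iter(tree.adjacency[0]))
    bl = ":1" if branch_lengths else ""

    def emit(u: int, parent: int) -> str:
        if u < tree.n:
            return _quote(tree.taxa[u]) + bl
        kids = [emit(v, u) for v in sorted(tree.adjacency[u]) if v != parent]
        return "(" + ",".join(kids) + ")" + bl

    kids = [emit(v, root) for v in sorted(tree.adjacency[root])]
    return "(" + ",".join(kids) + ");"


def _quote(label: str) -> str:
    if any(c in label for c in " \t()[]:;,'"):
        return "'" + label.replace("'", "''") + "'"
    return label


def read_newick(text: str) -> UnrootedBinaryTree:
    """Parse a Newick string into an unrooted binary tree.

    Uses dendropy for parsing; a bifurcating (rooted-style) top node is
    suppressed so rooted and trifurcating representations of the same
    topology load identically.  Taxa are ordered alphabetically.
    """
    import dendropy

    dt = dendropy.Tree.get(data=text, schema="newick")
    labels = sorted(lf.taxon.label for lf in dt.leaf_node_iter())
    index = {lab: k for k, lab in enumerate(labels)}
    n = len(labels)
    adj: dict[int, set[int]] = {}
    next_id = [n]
    node_id: dict = {}

    def get_id(nd):
        if nd not in node_id:
            if nd.is_leaf():
                node_id[nd] = index[nd.taxon.label]
                adj.setdefault(node_id[nd], set())
            else:
                node_id[nd] = next_id[0]
                next_id[0] += 1
                adj.setdefault(node_id[nd], set())
        return node_id[nd]

    for edge in dt.preorder_edge_iter():
        if edge.tail_node is None:
            continue
        u, v = get_id(edge.tail_node), get_id(edge.head_node)
        adj[u].add(v)
        adj[v].add(u)
    # suppress degree-2 nodes (rooted representation)
    for u in [u for u, vs in adj.items() if len(vs) == 2]:
        a, b = sorted(adj[u])
        adj[a].discard(u); adj[b].discard(u)
        adj[a].add(b); adj[b].add(a)
        del adj[u]
    # relabel internal nodes contiguously
    internal = sorted(u for u in adj if u >= n)
    remap = {u: u for u in adj if u < n}
    remap.update({u: n + k for k, u in enumerate(internal)})
    adj = {remap[u]: {remap[v] for v in vs} for u, vs in adj.items()}
    return UnrootedBinaryTree(adj, labels)
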