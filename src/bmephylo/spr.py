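"""Subtree pruning and regrafting (SPR) local search on the BME length.

An SPR move detaches a subtree at an edge and reattaches it onto another
edge of the remaining tree; the neighborhood of a tree is every distinct
topology reachable by one such move.  `run_spr` performs best-improvement
hill climbing: each sweep evaluates the balanced length of the whole
neighborhood (O(n^2) topologies, each re-scored from its path-length
matrix) and moves to the best strictly-improving neighbor until a local
optimum is reached.
"""

from __future__ import annotations

from typing import Iterator

from .tree import (DistanceMatrix, UnrootedBinaryTree, bme_length,
                   tree_to_plm)

__all__ = ["spr_neighbors", "run_spr"]


def _copy_adj(tree: UnrootedBinaryTree) -> dict[int, set[int]]:
    return {u: set(vs) for u, vs in tree.adjacency.items()}


def _normalize(adj: dict[int, set[int]], n: int) -> dict[int, set[int]]:
    internal = sorted(u for u in adj if u >= n)
    remap = {u: u for u in adj if u < n}
    remap.update({u: n + k for k, u in enumerate(internal)})
    return {remap[u]: {remap[v] for v in vs} for u, vs in adj.items()}


def spr_neighbors(tree: UnrootedBinaryTree
                  ) -> Iterator[UnrootedBinaryTree]:
    """Yield every distinct tree one SPR move away (the tree itself excluded)."""
    n = tree.n
    if n < 4:
        return
    seen = {tree.splits()}
    base = tree.adjacency
    # directed edge (u, v): prune the component of u after deleting u-v
    for u in base:
        for v in base[u]:
            if v < n:
                continue  # the kept side must contain an edge to regraft on
            adj = _copy_adj(tree)
            adj[u].discard(v)
            adj[v].discard(u)
            a, b = sorted(adj[v])     # suppress the degree-2 junction v
            adj[a].discard(v); adj[b].discard(v)
            adj[a].add(b); adj[b].add(a)
            del adj[v]
            pruned = _component(adj, u)
            kept_edges = [(x, y) for x in adj for y in adj[x]
                          if x < y and x not in pruned and y not in pruned]
            for x, y in kept_edges:
                if {x, y} == {a, b}:
                    continue  # regrafting here recreates the input
                adj2 = {k: set(vs) for k, vs in adj.items()}
                adj2[x].discard(y); adj2[y].discard(x)
                w = max(adj2) + 1
                adj2[w] = {x, y, u}
                adj2[x].add(w); adj2[y].add(w)
                adj2[u].add(w)
                cand = UnrootedBinaryTree(_normalize(adj2, n), tree.taxa,
                                          validate=False)
                token = cand.splits()
                if token not in seen:
                    seen.add(token)
                    yield cand


def _component(adj: dict[int, set[int]], start: int) -> set[int]:
    seen = {start}
    stack = [start]
    while stack:
        x = stack.pop()
        for y in adj[x]:
            if y not in seen:
                seen.add(y)
                stack.append(y)
    return seen


def run_spr(tree: UnrootedBinaryTree, d: DistanceMatrix,
            rel_tol: float = 1e-12) -> tuple[UnrootedBinaryTree, float]:
    """Best-improvement SPR hill climbing; monotone non-increasing length.

    Stops when no neighbor improves the balanced length by more than
    ``rel_tol`` relatively (guards against float cycling).  Returns the
    local optimum and its length.
    """
    current = tree
    cur_len = bme_length(d, tree_to_plm(tree))
    while True:
        best, best_len = None, cur_len
        for cand in spr_neighbors(current):
            ln = bme_length(d, tree_to_plm(cand))
            if ln < best_len:
                best, best_len = cand, ln
        if best is None or best_len >= cur_len * (1.0 - rel_tol):
            return current, cur_len
        current, cur_len = best, best_len
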