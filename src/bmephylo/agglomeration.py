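"""Stepwise cluster-merging tree construction: NJ and LP-guided LPNJ.

Both methods start from a star of ``n`` singleton clusters around a
central node and perform ``n - 3`` merges; each merge creates the common
ancestor of the two merged clusters and the reduced distance of the new
ancestor to every other cluster is the plain average of its parents'
distances.  They differ only in pair selection:

* NJ picks ``argmin (|N|-2) d_ij - sum_k (d_ik + d_jk)`` — the classical
  Q-criterion, a greedy minimisation of the balanced tree length.
* LPNJ solves an LP relaxation of the BME formulation on the current
  reduced matrix and merges the pair with the smallest fractional path
  length estimate ``tau~_pq``.  If the LP were replaced by the exact
  integer optimum at every step, this scheme would provably return an
  optimal tree; the LP estimate is a cheap surrogate for it.

The running tree length is maintained incrementally: ``lhat`` (the
within-cluster part of the balanced length) grows by ``d_pq / 2`` at each
merge, and the full partial-tree length is
``lhat + sum_{i<j} d_ij / (|N| - 1)`` on the canonical ordered-pair scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, NamedTuple

import numpy as np

from .lp import (FormulationOptions, GUIDANCE_DEFAULTS, solve_integer,
                 solve_relaxation)
from .tree import (Cluster, DistanceMatrix, PartialTree, UnrootedBinaryTree,
                   bme_length, tree_to_plm)

__all__ = [
    "AgglomerationState",
    "AgglomerationResult",
    "initial_state",
    "nj_pair_selection",
    "nj_reduce",
    "run_nj",
    "lpnj_pair_selection",
    "run_lpnj",
]


@dataclass(frozen=True)
class AgglomerationState:
    """State after ``r - 1`` merges: active clusters and reduced matrix.

    ``D`` is the ``m x m`` reduced distance matrix over the current
    cluster ancestors (``m = n - r + 1``); ``lhat`` accumulates the
    within-cluster part of the balanced tree length.
    """

    taxa: tuple[str, ...]
    r: int
    clusters: tuple[Cluster, ...]
    D: np.ndarray
    lhat: float

    @property
    def m(self) -> int:
        return len(self.clusters)

    @property
    def n(self) -> int:
        return len(self.taxa)

    @property
    def row_sums(self) -> np.ndarray:
        return self.D.sum(axis=1)

    @property
    def total_sum(self) -> float:
        """Sum of d_ij over unordered active pairs."""
        return float(self.D.sum()) / 2.0

    @property
    def partial_tree(self) -> PartialTree:
        return PartialTree(self.n, self.clusters)

    def tree_length(self) -> float:
        """Balanced length of the current star-of-clusters tree."""
        return self.lhat + self.total_sum / (self.m - 1)


class AgglomerationResult(NamedTuple):
    tree: UnrootedBinaryTree
    length: float


def initial_state(d: DistanceMatrix) -> AgglomerationState:
    return AgglomerationState(d.taxa, 1, tuple(range(d.n)), d.values.copy(),
                              0.0)


def nj_pair_selection(state: AgglomerationState) -> tuple[int, int]:
    """Q-criterion argmin; ties broken lexicographically by index pair."""
    D, m = state.D, state.m
    R = state.row_sums
    Q = (m - 2) * D - R[:, None] - R[None, :]
    np.fill_diagonal(Q, np.inf)
    k = int(np.argmin(Q))  # row-major scan = lexicographic tie-break
    i, j = divmod(k, m)
    return (i, j) if i < j else (j, i)


def nj_reduce(state: AgglomerationState, pair: tuple[int, int]
              ) -> AgglomerationState:
    """Merge a cluster pair, averaging distances to the new ancestor."""
    i, j = sorted(pair)
    D, m = state.D, state.m
    keep = [k for k in range(m) if k not in (i, j)]
    newD = np.zeros((m - 1, m - 1))
    newD[:-1, :-1] = D[np.ix_(keep, keep)]
    avg = (D[i, keep] + D[j, keep]) / 2.0
    newD[-1, :-1] = avg
    newD[:-1, -1] = avg
    clusters = tuple(state.clusters[k] for k in keep) + \
        ((state.clusters[i], state.clusters[j]),)
    return AgglomerationState(state.taxa, state.r + 1, clusters, newD,
                              state.lhat + D[i, j] / 2.0)


def _finalize(state: AgglomerationState, d: DistanceMatrix
              ) -> AgglomerationResult:
    tree = state.partial_tree.to_tree(state.taxa)
    return AgglomerationResult(tree, bme_length(d, tree_to_plm(tree)))


def run_nj(d: DistanceMatrix) -> AgglomerationResult:
    """Neighbor joining; returns the tree and its balanced length."""
    state = initial_state(d)
    while state.m > 3:
        state = nj_reduce(state, nj_pair_selection(state))
    return _finalize(state, d)


def lpnj_pair_selection(state: AgglomerationState, tau_tilde: np.ndarray,
                        tol: float = 1e-9) -> tuple[int, int]:
    """Pair with the smallest fractional path-length estimate.

    Ties (within ``tol``) go to the smaller reduced distance, then to the
    lexicographically smallest index pair.
    """
    m = state.m
    best = None
    tmin = np.inf
    for i in range(m):
        for j in range(i + 1, m):
            if tau_tilde[i, j] < tmin - tol:
                tmin = tau_tilde[i, j]
                best = (i, j)
            elif tau_tilde[i, j] <= tmin + tol:
                if state.D[i, j] < state.D[best] - tol:
                    best = (i, j)
    assert best is not None
    return best


def _reduced_matrix(state: AgglomerationState) -> DistanceMatrix:
    labels = tuple(f"c{k}" for k in range(state.m))
    return DistanceMatrix(state.D, labels, require_positive=False)


def run_lpnj(d: DistanceMatrix, opts: FormulationOptions | None = None,
             guide: Literal["relaxation", "integer"] = "relaxation"
             ) -> AgglomerationResult:
    """LP-guided neighbor joining.

    At every step an LP relaxation (options default to the guidance
    configuration: no Buneman, truncated L, exponent shift) is solved on
    the reduced matrix and the pair with minimal ``tau~`` is merged using
    the NJ distance reduction.  ``guide="integer"`` substitutes the exact
    integer optimum for the relaxation (optimal-tree oracle at small n).

    Raises
    ------
    RuntimeError
        If a guidance solve fails, reporting the step and solver status.
    """
    opts = opts or GUIDANCE_DEFAULTS
    state = initial_state(d)
    while state.m > 3:
        dr = _reduced_matrix(state)
        if guide == "integer":
            iopts = FormulationOptions(relax_integrality=False,
                                       time_limit=opts.time_limit)
            sol, plm = solve_integer(dr, iopts)
            if plm is None:
                raise RuntimeError(
                    f"guidance ILP failed at step {state.r}: {sol.status}")
            tau = plm.values.astype(float)
        else:
            sol = solve_relaxation(dr, opts)
            if sol.status != "optimal":
                raise RuntimeError(
                    f"guidance LP failed at step {state.r}: {sol.status}")
            tau = sol.tau_tilde
        state = nj_reduce(state, lpnj_pair_selection(state, tau))
    return _finalize(state, d)
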