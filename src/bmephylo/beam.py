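"""Beam search over agglomeration merge sequences.

Instead of committing to one greedy merge per step, a beam of width ``B``
keeps the ``B`` best partial trees at every level, expanding each over
all cluster pairs and ranking children by either

* ``rank_nj`` — the exact balanced length of the child partial tree,
  computed incrementally from the parent's bookkeeping sums (BeamNJ); or
* ``rank_lpnj`` — a lower estimate of the best completable tree length,
  based on the parent's LP relaxation value plus the pair's increment
  ``d_pq/2 - d_pq * 2**-(tau~_pq - 1)`` (BeamLPNJ).  Pairs at fractional
  distance 2 incur zero increment, mimicking the cherry merges of an
  exact path-length matrix.

With ``B = 1`` the NJ ranking reproduces plain neighbor joining exactly
(shared tie-break), and the LPNJ ranking gives the distance-weighted
variant of LPNJ.  Children reaching the same forest through different
merge orders are deduplicated by canonical signature before truncation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .agglomeration import (AgglomerationState, initial_state, nj_reduce)
from .lp import FormulationOptions, GUIDANCE_DEFAULTS, solve_relaxation
from .spr import run_spr
from .tree import (DistanceMatrix, UnrootedBinaryTree, bme_length,
                   cluster_signature, tree_to_plm)

__all__ = ["BeamCandidate", "rank_nj", "rank_lpnj", "run_beam", "BeamResult"]


@dataclass
class BeamCandidate:
    """One partial tree kept in the beam."""

    state: AgglomerationState
    score: float
    lineage: tuple[tuple[int, int], ...] = ()
    lower_estimate: float | None = None   # lhat + LP value (BeamLPNJ)
    tau_tilde: np.ndarray | None = None   # guidance estimates on state.D


@dataclass(frozen=True)
class BeamResult:
    tree: UnrootedBinaryTree
    length: float


def rank_nj(parent: BeamCandidate, pair: tuple[int, int]) -> float:
    """Balanced length of the child partial tree after merging ``pair``.

    Incremental form: with S the unordered-pair sum of the reduced matrix
    and R the row sums, the child's length is
    ``lhat + d_pq/2 + (S - (R_p + R_q)/2) / (m - 2)``.
    """
    st = parent.state
    p, q = pair
    R = st.row_sums
    return (st.lhat + st.D[p, q] / 2.0
            + (st.total_sum - (R[p] + R[q]) / 2.0) / (st.m - 2))


def rank_lpnj(parent: BeamCandidate, pair: tuple[int, int],
              tau_tilde: np.ndarray | None = None) -> float:
    """Lower-estimate ranking for BeamLPNJ.

    ``parent.lower_estimate`` must hold ``lhat + (LP value on the parent's
    reduced matrix)``; the merge adds ``d_pq/2 - d_pq * 2**-(tau~_pq-1)``.
    """
    tau = tau_tilde if tau_tilde is not None else parent.tau_tilde
    if tau is None or parent.lower_estimate is None:
        raise ValueError("rank_lpnj requires the parent's LP estimates")
    p, q = pair
    dpq = parent.state.D[p, q]
    return parent.lower_estimate + dpq / 2.0 - dpq * 2.0 ** -(tau[p, q] - 1.0)


def _attach_lp(cand: BeamCandidate, opts: FormulationOptions) -> bool:
    """Solve the guidance LP on a candidate's reduced matrix."""
    from .agglomeration import _reduced_matrix
    sol = solve_relaxation(_reduced_matrix(cand.state), opts)
    if sol.status != "optimal":
        return False
    cand.tau_tilde = sol.tau_tilde
    cand.lower_estimate = cand.state.lhat + sol.objective_value
    return True


def run_beam(d: DistanceMatrix, B: int = 15,
             mode: Literal["nj", "lpnj"] = "nj",
             opts: FormulationOptions | None = None,
             dedup: bool = True, spr: bool = False) -> list[BeamResult]:
    """Width-``B`` beam search; returns up to ``B`` trees sorted by length.

    In ``lpnj`` mode one guidance LP is solved per beam member per step;
    members whose LP fails are dropped with a warning rather than scored
    on stale estimates.  Final lengths are recomputed exactly from each
    tree's path-length matrix, and ``spr=True`` refines every finalist by
    SPR local search before sorting.
    """
    if B < 1:
        raise ValueError("beam width must be >= 1")
    opts = opts or GUIDANCE_DEFAULTS
    n = d.n
    beam = [BeamCandidate(initial_state(d), 0.0)]
    for _ in range(n - 3):
        expansions: list[tuple[float, int, int, int]] = []
        live: list[BeamCandidate] = []
        for cand in beam:
            if mode == "lpnj" and not _attach_lp(cand, opts):
                import warnings
                warnings.warn(
                    f"guidance LP failed at step {cand.state.r}; "
                    "candidate dropped", RuntimeWarning, stacklevel=2)
                continue
            ci = len(live)
            live.append(cand)
            m = cand.state.m
            for i in range(m):
                for j in range(i + 1, m):
                    score = (rank_nj(cand, (i, j)) if mode == "nj"
                             else rank_lpnj(cand, (i, j)))
                    expansions.append((score, ci, i, j))
        if not live:
            raise RuntimeError("all beam candidates lost to solver failures")
        expansions.sort()
        children: list[BeamCandidate] = []
        seen: set = set()
        for score, ci, i, j in expansions:
            parent = live[ci]
            if dedup:
                sigs = [cluster_signature(c) for k, c in
                        enumerate(parent.state.clusters) if k not in (i, j)]
                sigs.append(frozenset((
                    cluster_signature(parent.state.clusters[i]),
                    cluster_signature(parent.state.clusters[j]))))
                token = frozenset(sigs)
                if token in seen:
                    continue
                seen.add(token)
            children.append(BeamCandidate(
                nj_reduce(parent.state, (i, j)), score,
                parent.lineage + ((i, j),)))
            if len(children) == B:
                break
        beam = children
    out = []
    seen_final: set = set()
    for cand in beam:
        tree = cand.state.partial_tree.to_tree(d.taxa)
        if spr:
            tree, length = run_spr(tree, d)
        else:
            length = bme_length(d, tree_to_plm(tree))
        token = tree.splits()
        if token in seen_final:
            continue
        seen_final.add(token)
        out.append(BeamResult(tree, length))
    out.sort(key=lambda r: (r.length, sorted(map(sorted, r.tree.splits()))))
    return out
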