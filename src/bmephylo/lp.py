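"""Linear / integer programming formulation of balanced minimum evolution.

The BME problem is encoded with assignment variables ``x[i,j,l] = 1`` iff
the leaf path between taxa ``i`` and ``j`` has ``l`` edges, ``l`` ranging
over ``L = [2, lmax]``.  The constraint families are:

* assignment — each pair takes exactly one path length;
* Kraft — each row of ``2**-tau`` sums to 1/2 (internal degree-3 budget);
* triangle — path lengths are metric with slack 2, anchored at taxon 0;
* Buneman — big-M coupled indicator variables ``y`` enforcing the strong
  four-point trichotomy on every leaf triple (these make the integer
  model exact);
* manifold — ``sum_{i != j} tau_ij 2**-tau_ij = 2n - 3``.

With all families on, integer solutions are exactly the path-length
matrices of unrooted binary trees, so the integer optimum solves BME.
Dropping integrality gives LP relaxations whose values are lower bounds on
the optimal tree length; dropping Buneman (and optionally triangle) and
truncating ``L`` gives the cheaper relaxations used to guide heuristics.

Solving is delegated to HiGHS through :func:`scipy.optimize.linprog` /
:func:`scipy.optimize.milp`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from itertools import combinations
from typing import Literal

import numpy as np
from scipy.optimize import Bounds, LinearConstraint, linprog, milp
from scipy.sparse import csr_matrix

from .tree import DistanceMatrix, PathLengthMatrix

__all__ = [
    "FormulationOptions",
    "LPSolution",
    "BMEFormulation",
    "build_formulation",
    "solve_relaxation",
    "solve_integer",
    "lower_bound",
    "resolve_max_pathlen",
    "GUIDANCE_DEFAULTS",
    "BOUND_OPTIONS",
]


@dataclass(frozen=True)
class FormulationOptions:
    """Configuration of the BME formulation and its relaxations.

    max_pathlen
        ``"full"`` uses ``L = [2, n-1]``; ``"reduced"`` truncates to
        ``ceil(log2(n-1))**2`` (falling back to full when that is not an
        actual reduction or ``n < 5``); an explicit integer must lie in
        ``[3, n-1]``.  Truncated ``L`` speeds up guidance LPs but is not a
        guaranteed lower bound, so bound computations always use full L.
    exponent_shift
        Rescale the objective (and the dyadic constraint rows) by
        ``2**lmax`` so coefficients become integers; values are de-scaled
        on output.  Improves solver numerics for truncated ``L``.
    lp_method
        HiGHS variant for continuous solves: ``highs-ds`` (deterministic
        dual simplex, default) or ``highs-ipm`` (faster on large bounds).
    """

    include_buneman: bool = True
    include_triangle: bool = True
    relax_integrality: bool = True
    max_pathlen: Literal["full", "reduced"] | int = "full"
    exponent_shift: bool = False
    time_limit: float | None = None
    lp_method: str = "highs-ds"


#: Guidance-LP defaults for LPNJ / BeamLPNJ: Buneman off, reduced L,
#: exponent shift on; triangle off (the "-Tri" variant).
GUIDANCE_DEFAULTS = FormulationOptions(
    include_buneman=False, include_triangle=False, relax_integrality=True,
    max_pathlen="reduced", exponent_shift=True)

#: Lower-bound LP: full L, triangle on, Buneman off.
BOUND_OPTIONS = FormulationOptions(
    include_buneman=False, include_triangle=True, relax_integrality=True,
    max_pathlen="full", exponent_shift=False, lp_method="highs-ipm")


@dataclass(frozen=True)
class LPSolution:
    """Solution of a BME formulation (relaxed or integer).

    ``tau_tilde`` holds the (possibly fractional) path-length estimates
    ``tau_ij = sum_l l * x_ijl``; ``objective_value`` is on the canonical
    ordered-pair scale regardless of ``exponent_shift``.
    """

    tau_tilde: np.ndarray
    objective_value: float
    status: Literal["optimal", "infeasible", "limit", "failed"]
    is_integral: bool

    @property
    def ok(self) -> bool:
        return self.status == "optimal"


def resolve_max_pathlen(n: int, max_pathlen) -> int:
    """Concrete upper end of L for an order-n instance."""
    full = n - 1
    if max_pathlen == "full":
        return full
    if max_pathlen == "reduced":
        red = math.ceil(math.log2(n - 1)) ** 2
        if n < 5 or red < 4 or red >= full:
            return full
        return red
    lmax = int(max_pathlen)
    if lmax < 3 or lmax > full:
        raise ValueError(
            f"max_pathlen={lmax} invalid for n={n}: must be in [3, {full}]")
    return lmax


class BMEFormulation:
    """Sparse matrices of one instantiated formulation.

    Variables: ``x`` blocks of size ``|L|`` per unordered pair (pairs in
    lexicographic order), then ``y`` triples when Buneman is included.
    """

    def __init__(self, d: DistanceMatrix, opts: FormulationOptions):
        self.d = d
        self.opts = opts
        n = d.n
        self.n = n
        self.lmax = resolve_max_pathlen(n, opts.max_pathlen)
        self.L = list(range(2, self.lmax + 1))
        nl = len(self.L)
        self.pairs = list(combinations(range(n), 2))
        self.pair_index = {p: k for k, p in enumerate(self.pairs)}
        self.n_x = len(self.pairs) * nl
        self.triples = (list(combinations(range(1, n), 3))
                        if opts.include_buneman else [])
        # y variables per unordered triple {j,p,q}: order (y_{pq}^j, y_{jq}^p, y_{jp}^q)
        self.n_y = 3 * len(self.triples)
        self.n_var = self.n_x + self.n_y
        self.scale = float(2 ** self.lmax) if opts.exponent_shift else 1.0
        self._build()

    # -- variable helpers ---------------------------------------------------

    def xvar(self, i: int, j: int, l: int) -> int:
        if i > j:
            i, j = j, i
        return self.pair_index[(i, j)] * len(self.L) + (l - 2)

    def yvar(self, pq: tuple[int, int], j: int) -> int:
        trip = tuple(sorted((j, *pq)))
        base = self.n_x + 3 * self.triples.index(trip)
        # position: which element of the sorted triple is the "j" (with 1)
        return base + trip.index(j)

    def _tau_terms(self, i, j, coef, rows, cols, vals, r):
        for l in self.L:
            rows.append(r)
            cols.append(self.xvar(i, j, l))
            vals.append(coef * l)

    # -- construction -------------------------------------------------------

    def _build(self):
        n, L, nl = self.n, self.L, len(self.L)
        d = self.d.values
        sc = self.scale
        c = np.zeros(self.n_var)
        for (i, j), k in self.pair_index.items():
            for l in L:
                # ordered-pair objective: both (i,j) and (j,i) contribute
                c[k * nl + (l - 2)] = 2.0 * d[i, j] * sc * 2.0 ** (-l)
        self.c = c

        rows, cols, vals, beq = [], [], [], []
        r = 0
        # assignment (one length per pair)
        for k in range(len(self.pairs)):
            for l in L:
                rows.append(r); cols.append(k * nl + (l - 2)); vals.append(1.0)
            beq.append(1.0)
            r += 1
        # Kraft equalities
        for i in range(n):
            for j in range(n):
                if j == i:
                    continue
                for l in L:
                    rows.append(r)
                    cols.append(self.xvar(i, j, l))
                    vals.append(sc * 2.0 ** (-l))
            beq.append(sc * 0.5)
            r += 1
        # UBT manifold (ordered-pair sum)
        for k in range(len(self.pairs)):
            for l in L:
                rows.append(r)
                cols.append(k * nl + (l - 2))
                vals.append(2.0 * l * sc * 2.0 ** (-l))
        beq.append((2 * n - 3) * sc)
        r += 1
        # Buneman choice rows: the three indicators of a triple sum to 1
        for t_idx in range(len(self.triples)):
            base = self.n_x + 3 * t_idx
            for k in range(3):
                rows.append(r); cols.append(base + k); vals.append(1.0)
            beq.append(1.0)
            r += 1
        self.A_eq = csr_matrix((vals, (rows, cols)), shape=(r, self.n_var))
        self.b_eq = np.asarray(beq)

        rows, cols, vals, bub = [], [], [], []
        r = 0
        if self.opts.include_triangle:
            # tau_0i + tau_0j - tau_ij >= 2 and the two rotations
            for i, j in combinations(range(1, n), 2):
                for (a, b), (cc, dd), (e, f) in (
                        ((0, i), (0, j), (i, j)),
                        ((0, i), (i, j), (0, j)),
                        ((0, j), (i, j), (0, i))):
                    self._tau_terms(a, b, -1.0, rows, cols, vals, r)
                    self._tau_terms(cc, dd, -1.0, rows, cols, vals, r)
                    self._tau_terms(e, f, 1.0, rows, cols, vals, r)
                    bub.append(-2.0)
                    r += 1
        if self.opts.include_buneman:
            bigm = 2 * n - 2
            for j, p, q in self.triples:
                for (jj, pp, qq) in ((j, p, q), (j, q, p), (p, j, q),
                                     (p, q, j), (q, j, p), (q, p, j)):
                    # tau_0j + tau_pq >= 2(1 - y_{jp}^q) + tau_0p + tau_jq
                    #                    - (2n-2) y_{pq}^j
                    self._tau_terms(0, jj, -1.0, rows, cols, vals, r)
                    self._tau_terms(pp, qq, -1.0, rows, cols, vals, r)
                    self._tau_terms(0, pp, 1.0, rows, cols, vals, r)
                    self._tau_terms(jj, qq, 1.0, rows, cols, vals, r)
                    rows.append(r); cols.append(self.yvar((jj, pp), qq))
                    vals.append(-2.0)
                    rows.append(r); cols.append(self.yvar((pp, qq), jj))
                    vals.append(-float(bigm))
                    bub.append(-2.0)
                    r += 1
        if r:
            self.A_ub = csr_matrix((vals, (rows, cols)), shape=(r, self.n_var))
            self.b_ub = np.asarray(bub)
        else:
            self.A_ub = None
            self.b_ub = None

    # -- extraction / embedding --------------------------------------------

    def tau_from_x(self, x: np.ndarray) -> np.ndarray:
        n, nl = self.n, len(self.L)
        tau = np.zeros((n, n))
        lvec = np.asarray(self.L, dtype=float)
        for (i, j), k in self.pair_index.items():
            t = float(lvec @ x[k * nl:(k + 1) * nl])
            tau[i, j] = tau[j, i] = t
        return tau

    def embed_plm(self, tau) -> np.ndarray:
        """0/1 variable vector of a concrete PLM (feasibility embedding).

        Raises if some entry of ``tau`` falls outside L.  For Buneman
        models the indicator of each triple is set from the strong
        four-point case that holds.
        """
        tau = tau.values if isinstance(tau, PathLengthMatrix) else np.asarray(tau)
        x = np.zeros(self.n_var)
        for i, j in self.pairs:
            l = int(tau[i, j])
            if l not in self.L:
                raise ValueError(f"tau[{i},{j}]={l} outside L=[2,{self.lmax}]")
            x[self.xvar(i, j, l)] = 1.0
        for j, p, q in self.triples:
            s1 = tau[0, j] + tau[p, q]
            s2 = tau[0, p] + tau[j, q]
            s3 = tau[0, q] + tau[j, p]
            if s1 + 2 <= s2 and s2 == s3:
                x[self.yvar((p, q), j)] = 1.0
            elif s2 + 2 <= s1 and s1 == s3:
                x[self.yvar((j, q), p)] = 1.0
            elif s3 + 2 <= s1 and s1 == s2:
                x[self.yvar((j, p), q)] = 1.0
            else:
                raise ValueError(f"no four-point case holds on ({j},{p},{q})")
        return x

    def check_feasible(self, x: np.ndarray, tol: float = 1e-9) -> bool:
        if np.any(x < -tol) or np.any(x > 1 + tol):
            return False
        if np.max(np.abs(self.A_eq @ x - self.b_eq)) > tol * max(1.0, self.scale):
            return False
        if self.A_ub is not None and np.max(self.A_ub @ x - self.b_ub) > tol:
            return False
        return True


def build_formulation(d: DistanceMatrix,
                      opts: FormulationOptions | None = None) -> BMEFormulation:
    """Instantiate the formulation for a distance matrix."""
    return BMEFormulation(d, opts or FormulationOptions())


_LP_STATUS = {0: "optimal", 1: "limit", 2: "infeasible", 3: "failed",
              4: "failed"}


def _solve(form: BMEFormulation, integer: bool) -> tuple[LPSolution, np.ndarray | None]:
    opts = form.opts
    if integer:
        constraints = [LinearConstraint(form.A_eq, form.b_eq, form.b_eq)]
        if form.A_ub is not None:
            constraints.append(
                LinearConstraint(form.A_ub, -np.inf, form.b_ub))
        milp_opts = {}
        if opts.time_limit is not None:
            milp_opts["time_limit"] = opts.time_limit
        res = milp(form.c, constraints=constraints,
                   integrality=np.ones(form.n_var),
                   bounds=Bounds(0, 1), options=milp_opts)
        status = _LP_STATUS.get(res.status, "failed")
    else:
        lp_opts = {}
        if opts.time_limit is not None:
            lp_opts["time_limit"] = opts.time_limit
        res = linprog(form.c, A_ub=form.A_ub, b_ub=form.b_ub,
                      A_eq=form.A_eq, b_eq=form.b_eq, bounds=(0, 1),
                      method=opts.lp_method, options=lp_opts)
        status = _LP_STATUS.get(res.status, "failed")
    if res.x is None:
        return LPSolution(np.empty((form.n, form.n)), math.nan, status,
                          False), None
    x = np.asarray(res.x)
    tau = form.tau_from_x(x)
    frac = np.max(np.abs(x - np.round(x))) if x.size else 0.0
    value = float(res.fun) / form.scale
    return LPSolution(tau, value, status, bool(frac < 1e-6)), x


def solve_relaxation(d: DistanceMatrix,
                     opts: FormulationOptions | None = None) -> LPSolution:
    """Solve the LP relaxation; returns fractional tau estimates and value."""
    opts = opts or FormulationOptions()
    if not opts.relax_integrality:
        opts = replace(opts, relax_integrality=True)
    sol, _ = _solve(build_formulation(d, opts), integer=False)
    return sol


def solve_integer(d: DistanceMatrix,
                  opts: FormulationOptions | None = None
                  ) -> tuple[LPSolution, PathLengthMatrix | None]:
    """Solve the integer model (exact for the full constraint set).

    Intended as an optimality oracle at small n; the returned PLM is the
    rounded optimal ``tau`` (``None`` if the solve did not finish).
    """
    if opts is None:
        opts = FormulationOptions(relax_integrality=False)
    sol, x = _solve(build_formulation(d, opts), integer=True)
    if x is None or sol.status != "optimal":
        return sol, None
    return sol, PathLengthMatrix(np.round(sol.tau_tilde).astype(int))


def lower_bound(d: DistanceMatrix,
                opts: FormulationOptions | None = None) -> float:
    """Lower bound on the optimal BME tree length.

    The LP relaxation of the full-L formulation without Buneman
    constraints (triangle inequalities kept), on the canonical scale.
    """
    sol = solve_relaxation(d, opts or BOUND_OPTIONS)
    if sol.status != "optimal":
        raise RuntimeError(f"lower-bound LP did not solve: {sol.status}")
    return sol.objective_value
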