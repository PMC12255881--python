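"""Synthetic benchmark generators and distance-matrix / tree I/O.

Two synthetic families mirror the benchmark conditions used to study the
heuristics:

* RDSM ("Set C") — symmetric random doubly stochastic matrices with zero
  diagonal, produced by symmetric Sinkhorn–Knopp balancing of a uniform
  (0, 1) symmetric start;
* RIM ("Set D") — symmetric random integer matrices with off-diagonal
  entries uniform on {1, ..., 10} and zero diagonal.

Both are pure functions of ``(n, seed)``.  PHYLIP square distance
matrices are the on-disk interchange format; Newick (via
:mod:`bmephylo.tree`) carries trees.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .tree import DistanceMatrix

__all__ = [
    "gen_rdsm",
    "gen_rim",
    "read_phylip_dist",
    "write_phylip_dist",
    "subset_first_n",
    "instance_seed",
]

SET_CODES = {"C": 1, "D": 2}


def instance_seed(master_seed: int, set_name: str, n: int, replicate: int) -> int:
    """Deterministic per-instance seed derived from a master seed.

    Spawned through :class:`numpy.random.SeedSequence` so every instance
    of a benchmark suite is reproducible from one integer.
    """
    code = SET_CODES.get(set_name, 99)
    ss = np.random.SeedSequence([int(master_seed), code, int(n), int(replicate)])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def gen_rdsm(n: int, seed: int, tol: float = 1e-8,
             max_sweeps: int = 100_000) -> DistanceMatrix:
    """Symmetric random doubly stochastic matrix with zero diagonal.

    Starts from symmetric uniform(0, 1) draws with a zero diagonal and
    applies symmetric Sinkhorn–Knopp scaling (divide by the geometric
    mean of the two row sums) until every row sum is 1 within ``tol``.
    """
    if n < 3:
        raise ValueError("need n >= 3")
    rng = np.random.default_rng(seed)
    a = rng.uniform(0.0, 1.0, size=(n, n))
    a = (a + a.T) / 2.0
    np.fill_diagonal(a, 0.0)
    for _ in range(max_sweeps):
        r = a.sum(axis=1)
        if np.max(np.abs(r - 1.0)) <= tol:
            break
        a /= np.sqrt(np.outer(r, r))
        a = (a + a.T) / 2.0
        np.fill_diagonal(a, 0.0)
    else:
        resid = float(np.max(np.abs(a.sum(axis=1) - 1.0)))
        raise RuntimeError(
            f"Sinkhorn-Knopp did not converge in {max_sweeps} sweeps "
            f"(residual {resid:.3e})")
    return DistanceMatrix(a)


def gen_rim(n: int, seed: int) -> DistanceMatrix:
    """Symmetric random integer matrix, off-diagonals uniform on 1..10."""
    if n < 3:
        raise ValueError("need n >= 3")
    rng = np.random.default_rng(seed)
    a = rng.integers(1, 11, size=(n, n)).astype(float)
    a = np.triu(a, 1)
    a = a + a.T
    return DistanceMatrix(a)


def subset_first_n(d: DistanceMatrix, n: int) -> DistanceMatrix:
    """Leading principal submatrix over the first ``n`` taxa."""
    return d.subset_first(n)


def write_phylip_dist(d: DistanceMatrix, path) -> None:
    """PHYLIP square distance matrix: count line, then label + row."""
    lines = [f"    {d.n}"]
    width = max(10, max(len(t) for t in d.taxa) + 2)
    for i, taxon in enumerate(d.taxa):
        row = "  ".join(f"{x:.9f}" for x in d.values[i])
        lines.append(f"{taxon:<{width}}{row}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_phylip_dist(path) -> DistanceMatrix:
    """Parse a PHYLIP square distance matrix (whitespace separated).

    Raises :class:`ValueError` with a line number on ragged rows,
    asymmetry beyond 1e-6, or a nonzero diagonal.
    """
    text = Path(path).read_text()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise ValueError(f"{path}: empty file")
    try:
        n = int(lines[0].split()[0])
    except (ValueError, IndexError):
        raise ValueError(f"{path}:1: expected taxon count, got {lines[0]!r}")
    if len(lines) != n + 1:
        raise ValueError(
            f"{path}: expected {n} matrix rows, found {len(lines) - 1}")
    taxa, rows = [], []
    for k, ln in enumerate(lines[1:], start=2):
        parts = ln.split()
        if len(parts) != n + 1:
            raise ValueError(
                f"{path}:{k}: expected label + {n} values, got "
                f"{len(parts) - 1} values")
        taxa.append(parts[0])
        try:
            rows.append([float(x) for x in parts[1:]])
        except ValueError as e:
            raise ValueError(f"{path}:{k}: non-numeric entry ({e})")
    vals = np.asarray(rows)
    if np.max(np.abs(vals - vals.T)) > 1e-6:
        i, j = np.unravel_index(int(np.argmax(np.abs(vals - vals.T))),
                                vals.shape)
        raise ValueError(
            f"{path}: matrix asymmetric at ({i + 2},{j + 1}): "
            f"{vals[i, j]} vs {vals[j, i]}")
    if np.any(np.abs(np.diag(vals)) > 1e-12):
        i = int(np.argmax(np.abs(np.diag(vals))))
        raise ValueError(f"{path}:{i + 2}: nonzero diagonal entry")
    return DistanceMatrix(vals, taxa, require_positive=False)
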