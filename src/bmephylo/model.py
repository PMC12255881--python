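"""Model / results interface for balanced minimum evolution inference.

`BME` wraps a distance matrix the way a statistical model wraps its data:
``fit`` runs a chosen heuristic (NJ, LPNJ, or their beam-search variants,
optionally SPR-refined) and returns a :class:`BMEResults` holding the
inferred topology, its balanced tree length, optionally the LP lower
bound with the resulting optimality gap, and a ``summary()`` table.

Example
-------
>>> from bmephylo import BME
>>> from bmephylo.instance_io import gen_rim
>>> model = BME(gen_rim(10, seed=42))
>>> res = model.fit(method="beamnj", beam_width=15, compute_bound=True)
>>> print(res.summary())          # doctest: +SKIP
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from . import agglomeration, beam
from .lp import BOUND_OPTIONS, FormulationOptions, lower_bound
from .evaluation import optimality_gap
from .instance_io import read_phylip_dist
from .spr import run_spr
from .tree import DistanceMatrix, UnrootedBinaryTree, write_newick

__all__ = ["BME", "BMEResults"]

_METHODS = ("nj", "lpnj", "beamnj", "beamlpnj")


class BME:
    """Balanced minimum evolution model over a distance matrix."""

    def __init__(self, distances: DistanceMatrix | np.ndarray,
                 taxa=None):
        if not isinstance(distances, DistanceMatrix):
            distances = DistanceMatrix(distances, taxa)
        self.distances = distances

    @classmethod
    def from_dataframe(cls, df) -> "BME":
        """Square pandas DataFrame with taxa as both index and columns."""
        if list(df.index) != list(df.columns):
            raise ValueError("DataFrame index and columns must match")
        return cls(DistanceMatrix(df.to_numpy(dtype=float),
                                  [str(c) for c in df.columns]))

    @classmethod
    def from_phylip(cls, path) -> "BME":
        return cls(read_phylip_dist(path))

    @property
    def n(self) -> int:
        return self.distances.n

    def lower_bound(self, opts: FormulationOptions | None = None) -> float:
        """LP lower bound on the optimal balanced tree length."""
        return lower_bound(self.distances, opts)

    def fit(self, method: str = "beamnj", beam_width: int = 15,
            triangle: bool = False, spr: bool = False,
            max_pathlen="reduced", compute_bound: bool = False,
            time_limit: float | None = None) -> "BMEResults":
        """Infer a phylogeny.

        Parameters
        ----------
        method : {'nj', 'lpnj', 'beamnj', 'beamlpnj'}
        beam_width : int
            Beam width B for the beam methods.
        triangle : bool
            Keep the triangle inequalities in the guidance LP (the
            "+Tri" variants of the LP-guided methods).
        spr : bool
            Refine with SPR local search (beam finalists are each
            refined before choosing the best).
        max_pathlen : 'full' | 'reduced' | int
            Path-length range of the guidance LP.
        compute_bound : bool
            Also solve the lower-bound LP and report the optimality gap.
        """
        if method not in _METHODS:
            raise ValueError(f"method must be one of {_METHODS}")
        d = self.distances
        gopts = FormulationOptions(
            include_buneman=False, include_triangle=triangle,
            relax_integrality=True, max_pathlen=max_pathlen,
            exponent_shift=True, time_limit=time_limit)
        candidates: tuple = ()
        if method == "nj":
            tree, length = agglomeration.run_nj(d)
            if spr:
                tree, length = run_spr(tree, d)
        elif method == "lpnj":
            tree, length = agglomeration.run_lpnj(d, gopts)
            if spr:
                tree, length = run_spr(tree, d)
        else:
            mode = "nj" if method == "beamnj" else "lpnj"
            results = beam.run_beam(d, B=beam_width, mode=mode, opts=gopts,
                                    spr=spr)
            tree, length = results[0].tree, results[0].length
            candidates = tuple((r.tree, r.length) for r in results)
        bound = gap = None
        if compute_bound:
            from dataclasses import replace
            bound = self.lower_bound(
                BOUND_OPTIONS if time_limit is None else
                replace(BOUND_OPTIONS, time_limit=time_limit))
            gap = optimality_gap(length, bound)
        return BMEResults(model=self, method=method, beam_width=beam_width,
                          triangle=triangle, spr=spr, tree=tree,
                          tree_length=length, lower_bound=bound,
                          gap_pct=gap, candidates=candidates)


@dataclass(frozen=True)
class BMEResults:
    """Fitted phylogeny with its length, bound, and diagnostics."""

    model: BME
    method: str
    beam_width: int
    triangle: bool
    spr: bool
    tree: UnrootedBinaryTree
    tree_length: float
    lower_bound: float | None = None
    gap_pct: float | None = None
    candidates: tuple = ()

    @property
    def n(self) -> int:
        return self.model.n

    def newick(self) -> str:
        return write_newick(self.tree)

    def to_json(self) -> str:
        out = {"method": self.method, "n": self.n,
               "tree_length": self.tree_length, "newick": self.newick()}
        if self.method.startswith("beam"):
            out["beam_width"] = self.beam_width
        if self.method in ("lpnj", "beamlpnj"):
            out["triangle"] = self.triangle
        out["spr"] = self.spr
        if self.lower_bound is not None:
            out["lower_bound"] = self.lower_bound
            out["gap_pct"] = self.gap_pct
        return json.dumps(out, indent=2)

    def summary(self) -> str:
        label = self.method.upper()
        if self.method.startswith("beam"):
            label += f" (B={self.beam_width})"
        if self.spr:
            label += " + SPR"
        lines = [
            "Balanced Minimum Evolution Results",
            "=" * 44,
            f"{'Method:':<26}{label}",
            f"{'No. taxa:':<26}{self.n}",
            f"{'Tree length:':<26}{self.tree_length:.6f}",
        ]
        if self.lower_bound is not None:
            lines += [
                f"{'LP lower bound:':<26}{self.lower_bound:.6f}",
                f"{'Optimality gap (%):':<26}{self.gap_pct:.3f}",
            ]
        if self.candidates:
            lines.append(f"{'Beam finalists kept:':<26}{len(self.candidates)}")
        lines += ["-" * 44, "Newick:", self.newick()]
        return "\n".join(lines)
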