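"""Optimality-gap evaluation and the benchmark experiment runner.

For each instance the quality of a heuristic tree is measured as the
percentage optimality gap against the LP lower bound (full path-length
range, triangle inequalities, no Buneman constraints):

    gap = 100 * (tree length - bound) / bound.

:func:`run_experiment` regenerates synthetic benchmark suites (RDSM /
RIM), runs every configured method on every instance, and aggregates the
mean gap per (method, set) plus the percentage of instances on which each
method attains the best length among the configured methods (ties all
credited).
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import agglomeration, beam
from .lp import BOUND_OPTIONS, FormulationOptions, GUIDANCE_DEFAULTS, lower_bound
from .instance_io import gen_rdsm, gen_rim, instance_seed
from .spr import run_spr
from .tree import DistanceMatrix

__all__ = ["optimality_gap", "MethodSpec", "ExperimentConfig",
           "run_experiment", "run_method"]


def optimality_gap(length: float, bound: float) -> float:
    """Percentage gap of a tree length over a positive lower bound."""
    if not bound > 0:
        raise ValueError(f"lower bound must be positive, got {bound}")
    if length < 0:
        raise ValueError(f"tree length must be non-negative, got {length}")
    return 100.0 * (length - bound) / bound


@dataclass(frozen=True)
class MethodSpec:
    """One heuristic configuration to benchmark."""

    kind: str                 # 'nj' | 'lpnj' | 'beamnj' | 'beamlpnj'
    beam_width: int = 1
    triangle: bool = False    # guidance-LP triangle inequalities (+Tri/-Tri)
    spr: bool = False

    @property
    def label(self) -> str:
        base = {"nj": "NJ", "lpnj": "LPNJ", "beamnj": "BeamNJ",
                "beamlpnj": "BeamLPNJ"}[self.kind]
        if self.kind.startswith("beam"):
            base += f"(B={self.beam_width})"
        if self.kind == "beamlpnj" or self.kind == "lpnj":
            base += "+Tri" if self.triangle else "-Tri"
        if self.spr:
            base += "+SPR"
        return base


@dataclass(frozen=True)
class ExperimentConfig:
    """Benchmark grid: sets, sizes, replicates, methods, master seed."""

    methods: tuple[MethodSpec, ...] = (MethodSpec("nj"),
                                       MethodSpec("beamnj", 15))
    sets: tuple[str, ...] = ("C", "D")
    n_grid: tuple[int, ...] = tuple(range(10, 55, 5))
    replicates: int = 10
    master_seed: int = 1
    lp_time_limit: float | None = None

    @classmethod
    def from_json(cls, path) -> "ExperimentConfig":
        raw = json.loads(Path(path).read_text())
        methods = tuple(MethodSpec(**m) for m in raw.pop("methods"))
        raw = {k: tuple(v) if isinstance(v, list) else v
               for k, v in raw.items()}
        return cls(methods=methods, **raw)


def _generate(set_name: str, n: int, seed: int) -> DistanceMatrix:
    if set_name == "C":
        return gen_rdsm(n, seed)
    if set_name == "D":
        return gen_rim(n, seed)
    raise ValueError(f"unknown synthetic set {set_name!r}")


def run_method(spec: MethodSpec, d: DistanceMatrix,
               lp_time_limit: float | None = None) -> float:
    """Run one heuristic on one instance; returns the tree length."""
    gopts = FormulationOptions(
        include_buneman=False, include_triangle=spec.triangle,
        relax_integrality=True, max_pathlen="reduced", exponent_shift=True,
        time_limit=lp_time_limit)
    if spec.kind == "nj":
        tree, length = agglomeration.run_nj(d)
    elif spec.kind == "lpnj":
        tree, length = agglomeration.run_lpnj(d, gopts)
    elif spec.kind in ("beamnj", "beamlpnj"):
        mode = "nj" if spec.kind == "beamnj" else "lpnj"
        results = beam.run_beam(d, B=spec.beam_width, mode=mode, opts=gopts,
                                spr=spec.spr)
        return results[0].length
    else:
        raise ValueError(f"unknown method kind {spec.kind!r}")
    if spec.spr:
        _, length = run_spr(tree, d)
    return length


def run_experiment(config: ExperimentConfig
                   ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the configured benchmark; returns (per-instance, aggregate) tables.

    The per-instance table is tidy: one row per (set, n, replicate,
    method) with the tree length, LP lower bound, percentage gap, per-run
    provenance (seed, elapsed time) and an error column (solver failures
    are recorded and excluded from aggregates).  The aggregate table
    holds, per (method, set), the mean gap and the percentage of
    instances where the method attains the minimum length among the
    configured methods (ties all credited).
    """
    bound_opts = BOUND_OPTIONS
    if config.lp_time_limit is not None:
        from dataclasses import replace
        bound_opts = replace(bound_opts, time_limit=config.lp_time_limit)
    rows = []
    for set_name in config.sets:
        for n in config.n_grid:
            for rep in range(config.replicates):
                seed = instance_seed(config.master_seed, set_name, n, rep)
                d = _generate(set_name, n, seed)
                try:
                    bound = lower_bound(d, bound_opts)
                except RuntimeError as e:
                    rows.append(dict(set=set_name, n=n, replicate=rep,
                                     seed=seed, method="__bound__",
                                     length=np.nan, bound=np.nan,
                                     gap_pct=np.nan, seconds=np.nan,
                                     error=str(e)))
                    continue
                for spec in config.methods:
                    t0 = time.perf_counter()
                    try:
                        length = run_method(spec, d, config.lp_time_limit)
                        err = ""
                    except RuntimeError as e:
                        length, err = np.nan, str(e)
                    rows.append(dict(
                        set=set_name, n=n, replicate=rep, seed=seed,
                        method=spec.label, length=length, bound=bound,
                        gap_pct=(optimality_gap(length, bound)
                                 if err == "" else np.nan),
                        seconds=time.perf_counter() - t0, error=err))
    table = pd.DataFrame(rows)
    ok = table[(table.method != "__bound__") & (table.error == "")].copy()
    # best-percentage: per instance, all methods within 1e-9 of the min
    agg_rows = []
    for (set_name, method), grp in ok.groupby(["set", "method"]):
        inst = ok[ok.set == set_name]
        mins = inst.groupby(["n", "replicate"]).length.transform("min")
        inst = inst.assign(is_best=inst.length <= mins * (1 + 1e-9))
        best_pct = 100.0 * inst[inst.method == method].is_best.mean()
        n_failed = int(((table.set == set_name) & (table.method == method)
                        & (table.error != "")).sum())
        agg_rows.append(dict(set=set_name, method=method,
                             mean_gap_pct=float(grp.gap_pct.mean()),
                             best_pct=float(best_pct),
                             n_instances=len(grp), n_failed=n_failed))
    agg = pd.DataFrame(agg_rows).sort_values(["set", "method"]
                                             ).reset_index(drop=True)
    return table, agg


def write_reports(table: pd.DataFrame, agg: pd.DataFrame,
                  config: ExperimentConfig, out_dir) -> None:
    """Write tidy TSVs plus a JSON report with full provenance."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table.to_csv(out / "instances.tsv", sep="\t", index=False)
    agg.to_csv(out / "aggregate.tsv", sep="\t", index=False)
    report = {
        "config": {**asdict(config),
                   "methods": [asdict(m) for m in config.methods]},
        "aggregate": agg.to_dict(orient="records"),
    }
    (out / "report.json").write_text(json.dumps(report, indent=2))
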