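"""Replicated experiments on randomly generated PBNs.

Two harnesses mirror the published experimental design:

* the *reduction* experiment measures the percentage of states removed by the
  threshold rule on perturbed PBNs (no control nodes, ``xi = 1-(1-p)^n``,
  recurrent states and the initial state preserved);

* the *control* experiment draws PBNs with ``m`` of the ``n`` nodes acting as
  controls (so ``n - m`` internal genes), solves the minimax problem with
  ``C(z) = z`` on the original and the reduced network and checks the values
  agree.

Each replicate is seeded independently from (seed, replicate index) so any
reported row can be replayed in isolation.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .control import ControlProblem, compare_original_reduced
from .generate import generate_random_pbn
from .model import ControlledTransitionModel
from .reduction import (
    ReductionConfig,
    critical_states,
    reduce_network,
    reduction_rate,
)


@dataclass
class ExperimentSpec:
    """Design of one experiment cell: network size ``n`` (total nodes),
    ``m`` control nodes, ``N`` BNs / candidate functions per gene, maximum
    in-degree ``K``, perturbation ``p``, horizon ``M`` and replicate count."""

    n: int
    m: int = 0
    N: int = 4
    K: int = 2
    p: float = 0.0
    M: int = 20
    replicates: int = 10
    seed: int = 0
    structure: str | None = None  # default depends on the harness
    z0: int = 1


def _replicate_rng(spec: ExperimentSpec, r: int) -> np.random.Generator:
    return np.random.default_rng([spec.seed, r])


def run_reduction_experiment(spec: ExperimentSpec) -> pd.DataFrame:
    """Reduction rates for perturbed PBNs; one row per replicate.

    Random PBNs of ``N`` equiprobable constituent BNs with no control nodes;
    the perturbed matrix is built, non-critical states with truncated inflow
    at or below ``1-(1-p)^n`` are iteratively deleted, and the deleted
    percentage of the ``2**n`` states is recorded.
    """
    structure = spec.structure or "constituents"
    rows = []
    for r in range(spec.replicates):
        pbn = generate_random_pbn(
            spec.n, spec.m, spec.N, spec.K,
            seed=_replicate_rng(spec, r), structure=structure, p=spec.p,
        )
        model = ControlledTransitionModel.from_pbn(pbn)
        t0 = time.perf_counter()
        preserve = critical_states(model, spec.z0)
        result = reduce_network(model, ReductionConfig(preserve=preserve))
        elapsed = time.perf_counter() - t0
        rows.append({
            "replicate": r,
            "size_original": model.n_states,
            "size_reduced": result.n_kept,
            "reduction_rate": reduction_rate(result, spec.n),
            "iterations": max((it for _, it in result.deleted), default=0),
            "time_reduce": elapsed,
        })
    return pd.DataFrame(rows)


def run_control_experiment(spec: ExperimentSpec) -> pd.DataFrame:
    """Original-vs-reduced minimax control; one row per replicate.

    ``spec.n`` counts all nodes: ``m`` of them are controls, leaving
    ``n - m`` internal genes (network size ``2**(n-m)``).  Terminal cost is
    ``C(z) = z``.  The ``equal`` column asserts the reduced-network value
    matches the original one.
    """
    structure = spec.structure or "constituents"
    n_int = spec.n - spec.m
    if n_int < 1:
        raise ValueError("need at least one internal node (n > m)")
    rows = []
    for r in range(spec.replicates):
        pbn = generate_random_pbn(
            n_int, spec.m, spec.N, spec.K,
            seed=_replicate_rng(spec, r), structure=structure, p=spec.p,
        )
        problem = ControlProblem.identity_cost(n_int, spec.M, spec.z0)
        report = compare_original_reduced(pbn, problem)
        rows.append({
            "replicate": r,
            "size_original": report["size_original"],
            "size_reduced": report["size_reduced"],
            "cost_original": report["value_original"],
            "cost_reduced": report["value_reduced"],
            "equal": report["equal"],
            "time_original": report["time_original"],
            "time_reduced": report["time_reduced"],
        })
    return pd.DataFrame(rows)


def summarize(report: pd.DataFrame) -> dict:
    """Mean of the numeric columns plus the all-replicates-equal flag."""
    out = {c: float(report[c].mean()) for c in report.columns
           if c != "replicate" and report[c].dtype != bool}
    if "equal" in report:
        out["all_equal"] = bool(report["equal"].all())
    return out
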