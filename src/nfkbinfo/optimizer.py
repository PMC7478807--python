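"""Simulated-annealing maximization of mutual information over gene parameters.

Proposals perturb one uniformly chosen parameter at a time by the
multiplicative rule

    param' = param + param * (-1)^b * delta * u,   b in {0, 1}, u ~ U(0, 1)

with step amplitude delta (default 5%).  Acceptance is Metropolis with a
geometrically cooled temperature; improving moves are always accepted.  No
box constraints are imposed during the search, but proposals that violate
model validity (e.g. a Hill coefficient below 1) are resampled.  A run
terminates once the change in the accepted objective stays below ``dmi_tol``
(default 1e-2 bits) for ``window`` consecutive accepted iterations, or at
``max_iter``.  Repeated runs restart from independent uniform guesses and
are summarized per parameter (mean, sd) and as aligned objective traces.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .gene_expression import (
    GENE_PARAM_NAMES,
    GeneParamRanges,
    GeneParams,
    draw_guess_params,
)

__all__ = [
    "SAConfig",
    "OptimizationResult",
    "RepeatedRunsSummary",
    "propose_step",
    "acceptance_probability",
    "accept",
    "optimize_mi",
    "repeated_optimizations",
]


@dataclass(frozen=True)
class SAConfig:
    """Annealing settings.

    delta : maximum fractional step per move (0 < delta < 1)
    dmi_tol : termination threshold on the accepted-objective change (bits)
    window : consecutive accepted iterations the threshold must hold
    t_init : initial temperature (bits)
    cooling : geometric temperature factor per iteration (0 < cooling < 1)
    max_iter : iteration cap
    n_runs : repeated independent runs for the summary
    log10_steps : apply the step rule to log10(param) instead of param
    """

    delta: float = 0.05
    dmi_tol: float = 1e-2
    window: int = 10
    t_init: float = 0.1
    cooling: float = 0.995
    max_iter: int = 2000
    n_runs: int = 4
    log10_steps: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.delta < 1:
            raise ValueError("require 0 < delta < 1")
        if self.dmi_tol <= 0:
            raise ValueError("dmi_tol must be positive")
        if not 0 < self.cooling < 1:
            raise ValueError("require 0 < cooling < 1")
        if self.t_init <= 0 or self.window < 1 or self.max_iter < 1 or self.n_runs < 1:
            raise ValueError("t_init > 0, window >= 1, max_iter >= 1, n_runs >= 1")


@dataclass
class OptimizationResult:
    """Full SA trace plus the best accepted state of one run."""

    trace: pd.DataFrame
    best_params: GeneParams
    best_mi_bits: float
    run_id: int
    seed: int | None
    terminated_by: str

    @property
    def accepted_mi(self) -> np.ndarray:
        """Objective of the current (accepted) state after each iteration."""
        return self.trace["current_mi_bits"].to_numpy()


@dataclass
class RepeatedRunsSummary:
    """Cross-run aggregate: per-parameter statistics and aligned MI traces."""

    runs: list[OptimizationResult]
    param_mean: dict[str, float]
    param_sd: dict[str, float]
    trace_mean: np.ndarray
    trace_sd: np.ndarray
    best_run_id: int

    @property
    def best(self) -> OptimizationResult:
        return next(r for r in self.runs if r.run_id == self.best_run_id)


def propose_step(
    p: GeneParams,
    delta: float,
    rng: np.random.Generator,
    log10_steps: bool = False,
    max_resample: int = 100,
) -> GeneParams:
    """Perturb one uniformly chosen parameter; resample while invalid."""
    arr = p.as_array()
    for _ in range(max_resample):
        j = int(rng.integers(len(arr)))
        sign = -1.0 if rng.integers(2) else 1.0
        u = float(rng.random())
        new = arr.copy()
        if log10_steps:
            new[j] = arr[j] * 10.0 ** (sign * delta * u)
        else:
            new[j] = arr[j] * (1.0 + sign * delta * u)
        try:
            return GeneParams.from_array(new)
        except ValueError:
            continue
    raise RuntimeError("could not draw a valid proposal (parameters near domain edge)")


def acceptance_probability(delta_mi: float, temperature: float) -> float:
    """Metropolis probability of accepting a move with objective change delta_mi."""
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    if delta_mi >= 0:
        return 1.0
    return math.exp(delta_mi / temperature)


def accept(delta_mi: float, temperature: float, rng: np.random.Generator) -> bool:
    prob = acceptance_probability(delta_mi, temperature)
    return prob >= 1.0 or float(rng.random()) < prob


def optimize_mi(
    objective: Callable[[GeneParams], float],
    guess: GeneParams,
    cfg: SAConfig = SAConfig(),
    rng: np.random.Generator | int | None = None,
    run_id: int = 0,
) -> OptimizationResult:
    """One annealing run maximizing ``objective`` from ``guess``."""
    seed = rng if isinstance(rng, (int, np.integer)) else None
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng

    current = guess
    try:
        current_mi = float(objective(guess))
    except Exception as exc:
        raise RuntimeError(
            f"objective failed at the initial guess {guess.as_dict()}"
        ) from exc
    best, best_mi = current, current_mi
    temperature = cfg.t_init
    stall = 0
    terminated_by = "max_iter"
    records = []
    for it in range(1, cfg.max_iter + 1):
        proposal = propose_step(current, cfg.delta, rng, cfg.log10_steps)
        try:
            mi = float(objective(proposal))
        except Exception as exc:
            raise RuntimeError(
                f"objective failed at iteration {it} for parameters "
                f"{proposal.as_dict()}"
            ) from exc
        accepted = accept(mi - current_mi, temperature, rng)
        if accepted:
            dmi = abs(mi - current_mi)
            current, current_mi = proposal, mi
            if current_mi > best_mi:
                best, best_mi = current, current_mi
            stall = stall + 1 if dmi < cfg.dmi_tol else 0
        records.append(
            {
                "iteration": it,
                **{f"prop_{k}": v for k, v in proposal.as_dict().items()},
                "mi_bits": mi,
                "accepted": accepted,
                "temperature": temperature,
                "current_mi_bits": current_mi,
                "best_mi_bits": best_mi,
            }
        )
        if stall >= cfg.window:
            terminated_by = "dmi_converged"
            break
        temperature *= cfg.cooling
    return OptimizationResult(
        trace=pd.DataFrame.from_records(records),
        best_params=best,
        best_mi_bits=best_mi,
        run_id=run_id,
        seed=seed if isinstance(seed, int) else None,
        terminated_by=terminated_by,
    )


def repeated_optimizations(
    objective: Callable[[GeneParams], float],
    ranges: GeneParamRanges,
    cfg: SAConfig = SAConfig(),
    rng: np.random.Generator | int | None = None,
    guesses: Sequence[GeneParams] | None = None,
) -> RepeatedRunsSummary:
    """n_runs independent annealing runs from uniform random guesses.

    Traces are aligned per iteration, shorter runs padded with their final
    accepted objective; parameter statistics are over the per-run optima.
    """
    seed_seq = np.random.SeedSequence(rng) if isinstance(rng, (int, np.integer)) else (
        np.random.SeedSequence() if rng is None else None
    )
    if seed_seq is not None:
        child_rngs = [np.random.default_rng(s) for s in seed_seq.spawn(cfg.n_runs)]
    else:
        child_rngs = [rng for _ in range(cfg.n_runs)]  # shared generator

    runs: list[OptimizationResult] = []
    for i in range(cfg.n_runs):
        g = guesses[i] if guesses is not None else draw_guess_params(ranges, child_rngs[i])
        runs.append(optimize_mi(objective, g, cfg, child_rngs[i], run_id=i))

    longest = max(len(r.trace) for r in runs)
    aligned = np.empty((cfg.n_runs, longest))
    for i, r in enumerate(runs):
        mi = r.accepted_mi
        aligned[i, : len(mi)] = mi
        aligned[i, len(mi):] = mi[-1]
    best_vals = {
        name: np.array([getattr(r.best_params, name) for r in runs])
        for name in GENE_PARAM_NAMES
    }
    best_run = max(runs, key=lambda r: r.best_mi_bits)
    return RepeatedRunsSummary(
        runs=runs,
        param_mean={k: float(v.mean()) for k, v in best_vals.items()},
        param_sd={
            k: float(v.std(ddof=1)) if cfg.n_runs > 1 else 0.0
            for k, v in best_vals.items()
        },
        trace_mean=aligned.mean(axis=0),
        trace_sd=aligned.std(axis=0, ddof=1) if cfg.n_runs > 1 else np.zeros(longest),
        best_run_id=best_run.run_id,
    )
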