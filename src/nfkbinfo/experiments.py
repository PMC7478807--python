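"""Experiment orchestrations: sweeps, comparisons, and summary metrics.

Every experiment here composes the pipeline stages — NFkB ensemble
generation, gene-expression simulation, MI estimation — into a paired,
seeded computation.  A-vs-B comparisons (nominal vs optimized parameters,
CV sweeps of a single parameter, etc.) reuse one frozen noise realization
so that differences reflect the quantity being varied rather than
estimator or sampling variance.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd

from .gene_expression import (
    GENE_PARAM_NAMES,
    GeneParamRanges,
    GeneParams,
    DEFAULT_RANGES,
    draw_guess_params,
    nominal_params,
    simulate_expression_ensemble,
)
from .infotheory import DEFAULT_K, DEFAULT_TIMEPOINTS, embed_timepoints, mutual_information
from .synthetic_nfkb import (
    StimulusPanel,
    TrajectoryEnsemble,
    generate_ensemble,
    normalize_ensemble,
)

__all__ = [
    "SweepResult",
    "SpecificityResult",
    "make_mi_objective",
    "mi_vs_cv_sweep",
    "mi_distribution_over_geneparams",
    "parameter_combination_analysis",
    "single_param_variability_sweep",
    "expression_variability_metric",
    "ligand_specificity",
]

STAGES = ("encoding", "gene_noiseless", "gene_noisy")


@dataclass
class SweepResult:
    """MI along one swept axis for one pipeline stage."""

    axis_name: str
    axis_values: np.ndarray
    mi_mean: np.ndarray
    mi_sd: np.ndarray
    n_reps: int
    stage: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                self.axis_name: self.axis_values,
                "mi_mean_bits": self.mi_mean,
                "mi_sd_bits": self.mi_sd,
                "n_reps": self.n_reps,
                "stage": self.stage,
            }
        )


@dataclass
class SpecificityResult:
    """Euclidean separation of scaled per-ligand mean responses."""

    per_ligand: dict[str, float]
    mean: float
    sd: float
    condition: str = ""

    def to_record(self) -> dict:
        return {
            "per_ligand": self.per_ligand,
            "mean": self.mean,
            "sd": self.sd,
            "condition": self.condition,
        }


def _mi_of(ens: TrajectoryEnsemble, k: int, timepoints) -> float:
    return mutual_information(embed_timepoints(ens, timepoints), k).mi_bits


def make_mi_objective(
    nfkb: TrajectoryEnsemble,
    cv: float,
    noisy: bool,
    rng: np.random.Generator | int | None = None,
    k: int = DEFAULT_K,
    timepoints=DEFAULT_TIMEPOINTS,
    freeze_noise: bool = True,
):
    """Build the SA objective: GeneParams -> MI(ligand; gene output) in bits.

    With ``freeze_noise`` (the default) the per-cell standard-normal draws
    behind the log-normal parameter noise are fixed once, so the objective
    is deterministic in the parameters (common random numbers); otherwise
    noise is redrawn at every evaluation.
    """
    if not nfkb.normalized:
        raise ValueError("objective requires a normalized NFkB ensemble")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    frozen_z = rng.standard_normal((nfkb.n_cells, 6)) if (noisy and freeze_noise) else None

    def objective(params: GeneParams) -> float:
        gene = simulate_expression_ensemble(
            nfkb, params, cv=cv, noisy=noisy, rng=rng, noise_z=frozen_z
        )
        return _mi_of(gene, k, timepoints)

    return objective


def mi_vs_cv_sweep(
    cv_grid,
    n_cells: int = 1000,
    stages=STAGES,
    gene_ref: GeneParams | None = None,
    reps: int = 3,
    rng: np.random.Generator | int | None = None,
    panel: StimulusPanel | None = None,
    k: int = DEFAULT_K,
    timepoints=DEFAULT_TIMEPOINTS,
) -> dict[str, SweepResult]:
    """MI as a function of extrinsic-noise CV for each pipeline stage.

    Per CV value and replicate: one NFkB ensemble is generated at that CV,
    the encoding MI is computed on it, and the same (paired) ensemble
    drives the noise-free and noisy gene models; the noisy gene model uses
    the same CV for its parameters.
    """
    cv_grid = np.asarray(cv_grid, dtype=float)
    if np.any(cv_grid <= 0) or np.any(cv_grid >= 1):
        raise ValueError("cv values must lie in (0, 1)")
    panel = StimulusPanel() if panel is None else panel
    gene_ref = nominal_params() if gene_ref is None else gene_ref
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng

    mis = {s: np.empty((len(cv_grid), reps)) for s in stages}
    for i, cv in enumerate(cv_grid):
        for r in range(reps):
            ens = normalize_ensemble(generate_ensemble(panel, n_cells, cv, rng=rng))
            if "encoding" in stages:
                mis["encoding"][i, r] = _mi_of(ens, k, timepoints)
            if "gene_noiseless" in stages:
                gene = simulate_expression_ensemble(ens, gene_ref, noisy=False)
                mis["gene_noiseless"][i, r] = _mi_of(gene, k, timepoints)
            if "gene_noisy" in stages:
                gene = simulate_expression_ensemble(ens, gene_ref, cv=cv, noisy=True, rng=rng)
                mis["gene_noisy"][i, r] = _mi_of(gene, k, timepoints)
    out = {}
    for s in stages:
        out[s] = SweepResult(
            axis_name="cv",
            axis_values=cv_grid,
            mi_mean=mis[s].mean(axis=1),
            mi_sd=mis[s].std(axis=1, ddof=1) if reps > 1 else np.zeros(len(cv_grid)),
            n_reps=reps,
            stage=s,
        )
    return out


def mi_distribution_over_geneparams(
    nfkb: TrajectoryEnsemble,
    ranges: GeneParamRanges = DEFAULT_RANGES,
    n_samples: int = 1000,
    noisy: bool = False,
    cv: float = 0.25,
    rng: np.random.Generator | int | None = None,
    k: int = DEFAULT_K,
    timepoints=DEFAULT_TIMEPOINTS,
) -> pd.DataFrame:
    """Distribution of MI over random gene-parameter reference sets.

    Each sample draws a reference uniformly within the biological ranges,
    simulates expression (noise-free, or with log-normal cell-to-cell
    noise at ``cv`` around that reference), and records the MI.  Paired
    noise: the same frozen realization is reused across references.
    """
    if not nfkb.normalized:
        raise ValueError("requires a normalized NFkB ensemble")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    # split a sub-stream for the noise so the reference draws are identical
    # between noisy and noiseless modes at the same seed (paired comparison)
    z_rng = np.random.default_rng(int(rng.integers(2**31)))
    frozen_z = z_rng.standard_normal((nfkb.n_cells, 6)) if noisy else None
    records = []
    for s in range(n_samples):
        ref = draw_guess_params(ranges, rng)
        gene = simulate_expression_ensemble(
            nfkb, ref, cv=cv, noisy=noisy, rng=rng, noise_z=frozen_z
        )
        records.append({"sample": s, **ref.as_dict(), "mi_bits": _mi_of(gene, k, timepoints)})
    return pd.DataFrame.from_records(records)


def parameter_combination_analysis(
    nfkb: TrajectoryEnsemble,
    nominal: GeneParams,
    optimized: GeneParams,
    focus=("kd", "n", "tau"),
    cv: float = 0.25,
    rng: np.random.Generator | int | None = None,
    k: int = DEFAULT_K,
    timepoints=DEFAULT_TIMEPOINTS,
) -> pd.DataFrame:
    """MI for every nominal/optimized assignment of the focus parameters.

    All 2^len(focus) mixtures (non-focus parameters at nominal) plus the
    all-nominal and all-optimized references, evaluated with the noisy
    gene model under one shared noise realization (paired comparison).
    """
    for name in focus:
        if name not in GENE_PARAM_NAMES:
            raise ValueError(f"unknown gene parameter {name!r}")
    if not nfkb.normalized:
        raise ValueError("requires a normalized NFkB ensemble")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    frozen_z = rng.standard_normal((nfkb.n_cells, 6))

    def evaluate(params: GeneParams) -> float:
        gene = simulate_expression_ensemble(
            nfkb, params, cv=cv, noisy=True, rng=rng, noise_z=frozen_z
        )
        return _mi_of(gene, k, timepoints)

    records = []
    for flags in product((False, True), repeat=len(focus)):
        d = nominal.as_dict()
        for name, use_opt in zip(focus, flags):
            if use_opt:
                d[name] = getattr(optimized, name)
        label = ",".join(
            f"{name}={'opt' if use_opt else 'nom'}" for name, use_opt in zip(focus, flags)
        )
        records.append(
            {"combination": label, **{f"use_opt_{n}": f for n, f in zip(focus, flags)},
             "mi_bits": evaluate(GeneParams(**d))}
        )
    records.append({"combination": "all_nominal", "mi_bits": evaluate(nominal)})
    records.append({"combination": "all_optimized", "mi_bits": evaluate(optimized)})
    return pd.DataFrame.from_records(records)


def single_param_variability_sweep(
    param_name: str,
    cv_grid,
    nfkb: TrajectoryEnsemble | None = None,
    gene_ref: GeneParams | None = None,
    encoding_cv: float = 0.25,
    n_cells: int = 1000,
    rng: np.random.Generator | int | None = None,
    panel: StimulusPanel | None = None,
    k: int = DEFAULT_K,
    timepoints=DEFAULT_TIMEPOINTS,
) -> SweepResult:
    """MI as a function of the CV of a single gene parameter.

    The chosen parameter gets log-normal cell-to-cell noise at each CV of
    the grid while every other gene parameter stays at its reference with
    zero noise.  One NFkB ensemble (generated at ``encoding_cv`` unless
    supplied) and one standard-normal draw are shared across the grid, so
    the sweep is smooth in CV.
    """
    if param_name not in GENE_PARAM_NAMES:
        raise ValueError(
            f"unknown gene parameter {param_name!r}; expected one of {GENE_PARAM_NAMES}"
        )
    cv_grid = np.asarray(cv_grid, dtype=float)
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    if nfkb is None:
        panel = StimulusPanel() if panel is None else panel
        nfkb = normalize_ensemble(generate_ensemble(panel, n_cells, encoding_cv, rng=rng))
    gene_ref = nominal_params() if gene_ref is None else gene_ref
    j = GENE_PARAM_NAMES.index(param_name)
    z = rng.standard_normal((nfkb.n_cells, 6))
    z_single = np.zeros_like(z)
    z_single[:, j] = z[:, j]

    mis = np.empty(len(cv_grid))
    for i, cv in enumerate(cv_grid):
        if cv == 0:
            gene = simulate_expression_ensemble(nfkb, gene_ref, noisy=False)
        else:
            gene = simulate_expression_ensemble(
                nfkb, gene_ref, cv=cv, noisy=True, rng=rng, noise_z=z_single
            )
        mis[i] = _mi_of(gene, k, timepoints)
    return SweepResult(
        axis_name=f"cv_{param_name}",
        axis_values=cv_grid,
        mi_mean=mis,
        mi_sd=np.zeros(len(cv_grid)),
        n_reps=1,
        stage=f"gene_noisy_{param_name}",
    )


def expression_variability_metric(ens: TrajectoryEnsemble) -> dict[str, float]:
    """Time-averaged across-cell coefficient of variation, per ligand and pooled.

    For each ligand the across-cell sd/mean ratio (sample sd, ddof=1) is
    averaged over the time points where the mean exceeds 1e-9; the pooled
    value is the average over ligands.  Scale-invariant by construction.
    """
    out: dict[str, float] = {}
    for ligand in ens.ligands:
        vals = ens.class_values(ligand)
        if len(vals) < 2:
            raise ValueError(f"ligand {ligand!r} has fewer than 2 cells")
        mean = vals.mean(axis=0)
        sd = vals.std(axis=0, ddof=1)
        mask = mean > 1e-9
        if not mask.any():
            raise ValueError(f"ligand {ligand!r}: mean response is zero everywhere")
        out[ligand] = float((sd[mask] / mean[mask]).mean())
    out["pooled"] = float(np.mean([out[l] for l in ens.ligands]))
    return out


def ligand_specificity(
    ens: TrajectoryEnsemble,
    condition: str = "",
    squared: bool = False,
) -> SpecificityResult:
    """Separation of each ligand's mean response from the grand mean.

    Per-ligand and grand mean trajectories are scaled by the summed grand
    mean (over time points); the reported quantity is the Euclidean
    distance (or its square with ``squared=True``) between each scaled
    ligand mean and the scaled grand mean.
    """
    ligands = ens.ligands
    for ligand in ligands:
        if len(ens.class_values(ligand)) < 1:
            raise ValueError(f"ligand {ligand!r} has no cells")
    grand = ens.values.mean(axis=0)
    scale = float(grand.sum())
    if scale <= 0:
        raise ValueError("grand mean response sums to zero; cannot scale")
    grand_scaled = grand / scale
    per = {}
    for ligand in ligands:
        mean_scaled = ens.class_values(ligand).mean(axis=0) / scale
        dist = float(np.linalg.norm(mean_scaled - grand_scaled))
        per[ligand] = dist * dist if squared else dist
    vals = np.array(list(per.values()))
    return SpecificityResult(
        per_ligand=per,
        mean=float(vals.mean()),
        sd=float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
        condition=condition,
    )
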