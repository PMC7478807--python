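"""Delayed Hill-function gene-expression model driven by NFkB trajectories.

A single non-dimensionalized ODE maps a normalized nuclear-NFkB time course
x(t) into an mRNA abundance G(t):

    dG/dt = k0 + ks * hill(x(t - tau), kb, n) - kd * G
    hill(x, kb, n) = x^n / (kb^n + x^n)
    G(t_start) = k0 / kd        (pre-stimulus steady state)

All six parameters are dimensionless except the transcriptional delay tau
(minutes).  Before the grid start the input is held at its first value
(basal pre-history).  Integration is fixed-step classical Runge-Kutta on
the trajectory grid with the input linearly interpolated; the input is
measured data, not a state variable, so no delay-differential machinery is
required.  Extrinsic noise enters as per-cell log-normal sampling of the
six parameters at a common CV, sharing the sampler used for the NFkB
waveforms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields

import numpy as np

from .synthetic_nfkb import TrajectoryEnsemble, lognormal_sigma, sample_lognormal

__all__ = [
    "GeneParams",
    "GeneParamRanges",
    "DEFAULT_RANGES",
    "nominal_params",
    "hill",
    "delayed_input",
    "simulate_gene",
    "sample_gene_params",
    "simulate_expression_ensemble",
    "draw_guess_params",
    "GENE_PARAM_NAMES",
]

GENE_PARAM_NAMES = ("k0", "ks", "kd", "kb", "n", "tau")


@dataclass(frozen=True)
class GeneParams:
    """Six-parameter gene-expression model.

    k0 : basal production rate (dimensionless, >= 0)
    ks : NFkB-driven maximal production rate (dimensionless, >= 0)
    kd : mRNA degradation rate (dimensionless, > 0)
    kb : half-saturation constant of promoter activation (dimensionless, > 0)
    n  : Hill coefficient / binding cooperativity (>= 1)
    tau: delay between nuclear NFkB and transcriptional response (minutes, >= 0)
    """

    k0: float
    ks: float
    kd: float
    kb: float
    n: float
    tau: float

    def __post_init__(self) -> None:
        vals = self.as_array()
        if not np.all(np.isfinite(vals)):
            raise ValueError("all gene parameters must be finite")
        if self.kd <= 0 or self.kb <= 0:
            raise ValueError("kd and kb must be positive")
        if self.n < 1:
            raise ValueError("Hill coefficient n must be >= 1")
        if self.k0 < 0 or self.ks < 0 or self.tau < 0:
            raise ValueError("k0, ks, tau must be non-negative")

    def as_array(self) -> np.ndarray:
        return np.array([self.k0, self.ks, self.kd, self.kb, self.n, self.tau])

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in GENE_PARAM_NAMES}

    @classmethod
    def from_array(cls, arr) -> "GeneParams":
        return cls(*(float(v) for v in arr))

    def is_valid(self) -> bool:
        try:
            GeneParams(**self.as_dict())
        except ValueError:
            return False
        return True


@dataclass(frozen=True)
class GeneParamRanges:
    """Per-parameter (low, high) bounds for uniform guess draws."""

    k0: tuple[float, float]
    ks: tuple[float, float]
    kd: tuple[float, float]
    kb: tuple[float, float]
    n: tuple[float, float]
    tau: tuple[float, float]

    def __post_init__(self) -> None:
        for f in fields(self):
            low, high = getattr(self, f.name)
            if not low < high:
                raise ValueError(f"{f.name}: require low < high, got ({low}, {high})")
            if low <= 0 and f.name != "tau":
                raise ValueError(f"{f.name}: low bound must be positive")

    def as_dict(self) -> dict[str, tuple[float, float]]:
        return {name: getattr(self, name) for name in GENE_PARAM_NAMES}


# Biologically motivated bounds for the six parameters.
DEFAULT_RANGES = GeneParamRanges(
    k0=(27e-4, 0.7),
    ks=(6e-2, 1.72),
    kd=(5e-4, 23e-3),
    kb=(4e-2, 2.46),
    n=(2.0, 6.0),
    tau=(24.0, 120.0),
)


def nominal_params(ranges: GeneParamRanges = DEFAULT_RANGES) -> GeneParams:
    """Default reference parameter set: geometric mid-range for the
    multiplicative rates (k0, ks, kd, kb), arithmetic mid-range for the
    Hill coefficient and the delay."""
    d = ranges.as_dict()
    geo = {k: math.sqrt(d[k][0] * d[k][1]) for k in ("k0", "ks", "kd", "kb")}
    return GeneParams(
        **geo,
        n=0.5 * (d["n"][0] + d["n"][1]),
        tau=0.5 * (d["tau"][0] + d["tau"][1]),
    )


def hill(x, kb: float, n: float):
    """Sigmoidal promoter activation x^n / (kb^n + x^n), in [0, 1)."""
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("hill input must be non-negative")
    xn = x**n
    out = xn / (kb**n + xn)
    return float(out) if out.ndim == 0 else out


def delayed_input(traj: np.ndarray, times: np.ndarray, tau: float, t) -> np.ndarray:
    """Trajectory value at t - tau by linear interpolation.

    Times before the grid start return the first grid value (basal hold);
    times past the end hold the last value.
    """
    return np.interp(np.asarray(t, dtype=float) - tau, times, traj)


def _integrate_ensemble(
    values: np.ndarray,
    times: np.ndarray,
    params: np.ndarray,
) -> np.ndarray:
    """Vectorized RK4 of the gene ODE for many cells at once.

    values : (n_cells, n_times) normalized NFkB inputs
    params : (n_cells, 6) columns ordered (k0, ks, kd, kb, n, tau)
    """
    n_cells, n_times = values.shape
    k0, ks, kd, kb, n, tau = (params[:, j] for j in range(6))

    def inputs_at(t: float) -> np.ndarray:
        # per-cell delayed lookup on the shared grid, clamped at both ends
        tq = np.clip(t - tau, times[0], times[-1])
        idx = np.clip(np.searchsorted(times, tq, side="right") - 1, 0, n_times - 2)
        t0_, t1_ = times[idx], times[idx + 1]
        w = (tq - t0_) / (t1_ - t0_)
        rows = np.arange(n_cells)
        return (1.0 - w) * values[rows, idx] + w * values[rows, idx + 1]

    def production(x: np.ndarray) -> np.ndarray:
        xn = np.where(x > 0, x, 0.0) ** n
        return k0 + ks * xn / (kb**n + xn)

    G = np.empty((n_cells, n_times))
    G[:, 0] = k0 / kd
    for i in range(n_times - 1):
        t, h = times[i], times[i + 1] - times[i]
        p1 = production(inputs_at(t))
        p_mid = production(inputs_at(t + 0.5 * h))
        p2 = production(inputs_at(t + h))
        g = G[:, i]
        d1 = p1 - kd * g
        d2 = p_mid - kd * (g + 0.5 * h * d1)
        d3 = p_mid - kd * (g + 0.5 * h * d2)
        d4 = p2 - kd * (g + h * d3)
        G[:, i + 1] = g + (h / 6.0) * (d1 + 2.0 * d2 + 2.0 * d3 + d4)
    return G


def simulate_gene(
    traj: np.ndarray,
    p: GeneParams,
    times: np.ndarray,
) -> np.ndarray:
    """Integrate the gene ODE for one normalized NFkB trajectory.

    Returns G on the same grid, starting from the pre-stimulus steady
    state G = k0/kd.
    """
    traj = np.asarray(traj, dtype=float)
    times = np.asarray(times, dtype=float)
    if traj.shape != times.shape:
        raise ValueError("trajectory and time grid must have equal length")
    return _integrate_ensemble(traj[None, :], times, p.as_array()[None, :])[0]


def sample_gene_params(
    ref: GeneParams,
    cv: float,
    n_cells: int,
    rng: np.random.Generator,
    centering: str = "median",
    noise_z: np.ndarray | None = None,
) -> np.ndarray:
    """Per-cell gene parameters, each log-normal around the reference.

    Passing ``noise_z`` (an (n_cells, 6) standard-normal matrix) fixes the
    noise realization so that different references can be compared under
    common random numbers.  The Hill coefficient is clipped at 1 to keep
    every sampled cell a valid model.
    """
    sigma = lognormal_sigma(cv)
    ref_arr = ref.as_array()
    if sigma == 0.0:
        out = np.tile(ref_arr, (n_cells, 1))
    else:
        if noise_z is None:
            noise_z = rng.standard_normal((n_cells, 6))
        factor = np.exp(sigma * noise_z)
        if centering == "mean":
            factor *= np.exp(-0.5 * sigma * sigma)
        elif centering != "median":
            raise ValueError(f"unknown centering {centering!r}")
        out = ref_arr[None, :] * factor
    out[:, 4] = np.maximum(out[:, 4], 1.0)  # n >= 1
    return out


def simulate_expression_ensemble(
    nfkb: TrajectoryEnsemble,
    ref: GeneParams,
    cv: float = 0.0,
    noisy: bool = False,
    rng: np.random.Generator | int | None = None,
    centering: str = "median",
    noise_z: np.ndarray | None = None,
) -> TrajectoryEnsemble:
    """Drive the gene model with every cell of a normalized NFkB ensemble.

    noisy=False: all cells share the reference parameters exactly.
    noisy=True: each cell draws its own parameters log-normally at ``cv``
    (optionally from a frozen ``noise_z`` realization).  Labels carry over.
    """
    if not nfkb.normalized:
        raise ValueError("gene model requires a normalized NFkB ensemble")
    n_cells = nfkb.n_cells
    if noisy:
        rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
        params = sample_gene_params(ref, cv, n_cells, rng, centering, noise_z)
    else:
        params = np.tile(ref.as_array(), (n_cells, 1))
    G = _integrate_ensemble(nfkb.values, nfkb.times, params)
    return TrajectoryEnsemble(nfkb.times.copy(), G, nfkb.labels.copy(), normalized=False)


def draw_guess_params(
    ranges: GeneParamRanges,
    rng: np.random.Generator | int | None = None,
) -> GeneParams:
    """Independent uniform draw of each parameter within its bounds."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    d = ranges.as_dict()
    return GeneParams(
        **{name: float(rng.uniform(*d[name])) for name in GENE_PARAM_NAMES}
    )
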