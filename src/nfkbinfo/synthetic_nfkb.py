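"""Surrogate single-cell NFkB nuclear-activity trajectories.

Five innate-immune ligands (TNF, LPS, PolyIC, CpG, Pam3CSK) drive
qualitatively distinct nuclear NFkB waveforms: damped oscillations,
sustained plateaus, fast transients, or delayed slow responses.  This
module generates such trajectories from a small parametric waveform
family with cell-to-cell (extrinsic) variability introduced by
log-normal sampling of the waveform parameters at a common coefficient
of variation, and provides loading/saving of externally simulated
trajectories in a long-format CSV so that output of a mechanistic
encoding model can be plugged in instead.

The waveform for one cell is

    N(t) = B + A * env(t') * osc(t'),    t' = max(0, t - t_lag)
    env(t') = (1 - exp(-t'/t_r)) * exp(-max(0, t' - t_0)/t_f)
    osc(t') = 1 + w * cos(2*pi*t'/T_osc)

which is non-negative for B, A >= 0 and 0 <= w < 1.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "DEFAULT_LIGANDS",
    "DEFAULT_DOSES",
    "StimulusPanel",
    "WaveformParams",
    "TrajectoryEnsemble",
    "FormatError",
    "default_time_grid",
    "make_reference_panel",
    "evaluate_waveform",
    "lognormal_sigma",
    "sample_lognormal",
    "sample_cell_waveforms",
    "generate_ensemble",
    "normalize_ensemble",
    "save_trajectories",
    "load_trajectories",
]

# Stimulus panel used throughout: one dose per ligand, chosen near the
# corresponding receptor Kd.  Doses are metadata only; the surrogate
# waveforms carry no dose-response behaviour.
DEFAULT_LIGANDS = ("TNF", "LPS", "PolyIC", "CpG", "Pam3CSK")
DEFAULT_DOSES = {
    "TNF": "10 ng/ml",
    "LPS": "10 ng/ml",
    "PolyIC": "30 ug/ml",
    "CpG": "1 uM",
    "Pam3CSK": "300 ng/ml",
}

_T_MIN, _T_MAX = 1.0, 480.0


class FormatError(ValueError):
    """A trajectory file violates the long-format CSV contract."""


def default_time_grid() -> np.ndarray:
    """1-minute resolution grid over [1, 480] minutes (480 points)."""
    return np.arange(_T_MIN, _T_MAX + 1.0)


@dataclass(frozen=True)
class StimulusPanel:
    """Ordered ligand panel; order fixes the integer encoding of the input label."""

    ligands: tuple[str, ...] = DEFAULT_LIGANDS
    doses: dict[str, str] = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_DOSES)
    )

    def __post_init__(self) -> None:
        if len(self.ligands) < 2:
            raise ValueError("a stimulus panel needs at least 2 ligands")
        if len(set(self.ligands)) != len(self.ligands):
            raise ValueError("ligand identifiers must be distinct")

    @property
    def n_ligands(self) -> int:
        return len(self.ligands)


@dataclass(frozen=True)
class WaveformParams:
    """Parametric description of one nuclear-NFkB waveform.

    All amplitudes are dimensionless; times are minutes.

    B : basal level (>= 0)
    A : pulse amplitude (>= 0)
    t_lag : onset delay
    t_r : rise timescale (> 0)
    t_0 : plateau end (decay onset)
    t_f : fall timescale (> 0)
    w : oscillation weight in [0, 1)
    T_osc : oscillation period (> 0)
    """

    B: float
    A: float
    t_lag: float
    t_r: float
    t_0: float
    t_f: float
    w: float
    T_osc: float

    def __post_init__(self) -> None:
        if self.t_r <= 0 or self.t_f <= 0 or self.T_osc <= 0:
            raise ValueError("timescales t_r, t_f, T_osc must be positive")
        if self.B < 0 or self.A < 0 or self.t_lag < 0 or self.t_0 < 0:
            raise ValueError("B, A, t_lag, t_0 must be non-negative")
        if not 0 <= self.w < 1:
            raise ValueError("oscillation weight w must lie in [0, 1)")

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.B, self.A, self.t_lag, self.t_r, self.t_0, self.t_f, self.w, self.T_osc]
        )


_WAVEFORM_FIELDS = ("B", "A", "t_lag", "t_r", "t_0", "t_f", "w", "T_osc")


@dataclass
class TrajectoryEnsemble:
    """A cells x timepoints response matrix with per-cell ligand labels.

    The universal currency between pipeline stages: NFkB output, gene
    expression output, and anything loaded from file all use this shape.
    """

    times: np.ndarray
    values: np.ndarray
    labels: np.ndarray
    normalized: bool = False

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        self.labels = np.asarray(self.labels)
        if self.times.ndim != 1 or np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be a strictly increasing 1-D grid")
        if self.values.shape != (len(self.labels), len(self.times)):
            raise ValueError(
                f"values shape {self.values.shape} inconsistent with "
                f"{len(self.labels)} labels x {len(self.times)} times"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("trajectory values must be finite")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def ligands(self) -> list[str]:
        """Distinct labels in first-appearance order."""
        seen: dict[str, None] = {}
        for lab in self.labels:
            seen.setdefault(str(lab), None)
        return list(seen)

    def class_values(self, ligand: str) -> np.ndarray:
        return self.values[self.labels == ligand]


# ---------------------------------------------------------------------------
# Reference waveforms


def make_reference_panel(
    config_path: str | Path | None = None,
    panel: StimulusPanel | None = None,
) -> dict[str, WaveformParams]:
    """Load the per-ligand reference waveforms from a JSON/YAML config.

    Defaults to the package's bundled reference panel, which encodes the
    qualitative per-ligand dynamics: TNF damped-oscillatory, LPS sustained
    biphasic, PolyIC delayed slow, CpG sustained non-oscillatory, Pam3CSK
    fast transient.
    """
    if config_path is None:
        config_path = Path(__file__).parent / "data" / "reference_waveforms.json"
    with open(config_path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise FormatError("waveform config must map ligand -> parameter block")
    out: dict[str, WaveformParams] = {}
    for ligand, block in raw.items():
        unknown = set(block) - set(_WAVEFORM_FIELDS)
        if unknown:
            raise FormatError(f"unknown waveform fields for {ligand}: {sorted(unknown)}")
        missing = set(_WAVEFORM_FIELDS) - set(block)
        if missing:
            raise FormatError(f"missing waveform fields for {ligand}: {sorted(missing)}")
        out[ligand] = WaveformParams(**{k: float(block[k]) for k in _WAVEFORM_FIELDS})
    if panel is not None:
        missing_ligs = set(panel.ligands) - set(out)
        if missing_ligs:
            raise FormatError(f"config lacks waveforms for ligands: {sorted(missing_ligs)}")
        out = {lig: out[lig] for lig in panel.ligands}
    return out


def evaluate_waveform(p: WaveformParams, times: np.ndarray) -> np.ndarray:
    """Evaluate one waveform on a time grid (minutes). Result is >= 0."""
    t = np.asarray(times, dtype=float)
    tp = np.maximum(0.0, t - p.t_lag)
    env = (1.0 - np.exp(-tp / p.t_r)) * np.exp(-np.maximum(0.0, tp - p.t_0) / p.t_f)
    osc = 1.0 + p.w * np.cos(2.0 * np.pi * tp / p.T_osc)
    return p.B + p.A * env * osc


# ---------------------------------------------------------------------------
# Extrinsic noise: log-normal parameter sampling


def lognormal_sigma(cv: float) -> float:
    """Log-space standard deviation giving a log-normal the requested CV."""
    if cv < 0:
        raise ValueError("cv must be non-negative")
    return float(np.sqrt(np.log1p(cv * cv)))


def sample_lognormal(
    reference: float,
    cv: float,
    size,
    rng: np.random.Generator,
    centering: str = "median",
) -> np.ndarray:
    """Draw log-normal values around a non-negative reference.

    centering="median" puts the reference at the distribution median
    (mu = ln ref); "mean" rescales so the distribution mean equals the
    reference.  A zero reference is returned unchanged (the multiplicative
    noise model cannot move it).
    """
    sigma = lognormal_sigma(cv)
    if centering not in ("median", "mean"):
        raise ValueError(f"unknown centering {centering!r}")
    if sigma == 0.0:
        return np.full(size, float(reference))
    z = rng.standard_normal(size)
    factor = np.exp(sigma * z)
    if centering == "mean":
        factor *= np.exp(-0.5 * sigma * sigma)
    return reference * factor


def sample_cell_waveforms(
    ref: WaveformParams,
    cv: float,
    n_cells: int,
    rng: np.random.Generator | int,
    centering: str = "median",
) -> list[WaveformParams]:
    """Per-cell waveform parameters: each field drawn independently log-normal.

    The oscillation weight w is sampled like the others and then clipped to
    [0, 0.95] to preserve non-negativity of the waveform.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    ref_arr = ref.as_array()
    draws = np.empty((n_cells, len(ref_arr)))
    for j, val in enumerate(ref_arr):
        draws[:, j] = sample_lognormal(val, cv, n_cells, rng, centering)
    draws[:, 6] = np.clip(draws[:, 6], 0.0, 0.95)  # w
    return [WaveformParams(*row) for row in draws]


def generate_ensemble(
    panel: StimulusPanel,
    n_cells_per_ligand: int,
    cv: float,
    times: np.ndarray | None = None,
    rng: np.random.Generator | int | None = None,
    reference: dict[str, WaveformParams] | None = None,
    centering: str = "median",
) -> TrajectoryEnsemble:
    """Simulate an unnormalized ensemble: n_ligands x n_cells_per_ligand rows."""
    if n_cells_per_ligand < 1:
        raise ValueError("n_cells_per_ligand must be >= 1")
    times = default_time_grid() if times is None else np.asarray(times, dtype=float)
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    reference = make_reference_panel(panel=panel) if reference is None else reference

    rows, labels = [], []
    for ligand in panel.ligands:
        for cell in sample_cell_waveforms(reference[ligand], cv, n_cells_per_ligand, rng, centering):
            rows.append(evaluate_waveform(cell, times))
            labels.append(ligand)
    return TrajectoryEnsemble(times, np.vstack(rows), np.array(labels), normalized=False)


def normalize_ensemble(ens: TrajectoryEnsemble) -> TrajectoryEnsemble:
    """Divide every value by the single global maximum of the ensemble.

    The maximum is taken over all cells, times, and ligands of this
    realization, making the downstream gene-expression ODE dimensionless.
    """
    global_max = float(ens.values.max())
    if global_max <= 0:
        raise ValueError("cannot normalize: ensemble maximum is not positive")
    return TrajectoryEnsemble(
        ens.times.copy(), ens.values / global_max, ens.labels.copy(), normalized=True
    )


# ---------------------------------------------------------------------------
# Long-format CSV interchange (plugin point for external encoding models)


def save_trajectories(ens: TrajectoryEnsemble, path: str | Path) -> None:
    """Write an ensemble as long-format CSV: ligand,cell_id,time_min,value."""
    n_cells, n_times = ens.values.shape
    df = pd.DataFrame(
        {
            "ligand": np.repeat(ens.labels, n_times),
            "cell_id": np.repeat(np.arange(n_cells), n_times),
            "time_min": np.tile(ens.times, n_cells),
            "value": ens.values.ravel(),
        }
    )
    df.to_csv(path, index=False, float_format="%.17g")


def load_trajectories(path: str | Path) -> TrajectoryEnsemble:
    """Load a long-format trajectory CSV written by :func:`save_trajectories`.

    Every cell must share one time grid; violations raise :class:`FormatError`
    naming the offending cell.
    """
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except (ValueError, pd.errors.ParserError) as exc:
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    required = ["ligand", "cell_id", "time_min", "value"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    for col in ("time_min", "value"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any() or df[col].isna().any():
            row = int((coerced.isna()).idxmax())
            raise FormatError(f"{path}: non-numeric {col} at row {row}")
        df[col] = coerced

    # preserve file order of cells and of times within the first cell
    cell_keys = df[["ligand", "cell_id"]].drop_duplicates().itertuples(index=False)
    groups = df.groupby(["ligand", "cell_id"], sort=False)
    times: np.ndarray | None = None
    rows, labels = [], []
    for key in cell_keys:
        g = groups.get_group(tuple(key))
        t = g["time_min"].to_numpy()
        if times is None:
            times = t
        elif len(t) != len(times) or not np.array_equal(t, times):
            raise FormatError(
                f"{path}: cell {key.cell_id} (ligand {key.ligand}) has an "
                "inconsistent time grid"
            )
        rows.append(g["value"].to_numpy())
        labels.append(key.ligand)
    if times is None:
        raise FormatError(f"{path}: file contains no trajectories")
    return TrajectoryEnsemble(times, np.vstack(rows), np.array(labels), normalized=False)
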