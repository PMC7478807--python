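"""Run configuration, seeding discipline, and results-directory bookkeeping.

A single master seed spawns named child seeds per pipeline stage
(waveform sampling, gene noise, subsampling, SA runs), so stages can be
re-run independently yet reproducibly.  All randomness flows through
injected numpy Generators; no global random state is touched.  Every CLI
run writes a results directory with a manifest listing each output file
and its SHA-256 hash — re-running with the same config and seed
reproduces identical hashes.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .gene_expression import GENE_PARAM_NAMES, GeneParamRanges, GeneParams, nominal_params
from .optimizer import SAConfig

__all__ = [
    "RunConfig",
    "ConfigError",
    "load_config",
    "write_config",
    "child_seed",
    "child_rng",
    "write_results",
]


class ConfigError(ValueError):
    """A run-config file violates the schema."""


def _default_gene() -> dict[str, float]:
    return nominal_params().as_dict()


def _default_ranges() -> dict[str, list[float]]:
    from .gene_expression import DEFAULT_RANGES

    return {k: list(v) for k, v in DEFAULT_RANGES.as_dict().items()}


def _default_sa() -> dict:
    return {f.name: getattr(SAConfig(), f.name) for f in dataclasses.fields(SAConfig)}


@dataclass
class RunConfig:
    """Validated settings for every CLI subcommand (all fields defaulted)."""

    seed: int = 0
    waveform_config: str | None = None
    ligands: list[str] | None = None
    n_cells_per_ligand: int = 1000
    cv: float = 0.25
    centering: str = "median"
    gene: dict[str, float] = field(default_factory=_default_gene)
    gene_ranges: dict[str, list[float]] = field(default_factory=_default_ranges)
    k: int = 10
    timepoints: list[float] = field(default_factory=lambda: [50.0, 100.0, 150.0, 300.0, 450.0])
    v_max: int = 8
    fractions: list[float] = field(default_factory=lambda: [0.2, 0.4, 0.6, 0.8, 1.0])
    bias_reps: int = 5
    cv_grid: list[float] = field(default_factory=lambda: [0.10, 0.15, 0.20, 0.25, 0.30, 0.35])
    sweep_reps: int = 3
    sa: dict = field(default_factory=_default_sa)
    outdir: str = "results"

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ConfigError(f"k must be >= 1 (N > k required), got {self.k}")
        if self.n_cells_per_ligand < 1:
            raise ConfigError("n_cells_per_ligand must be >= 1")
        if self.cv < 0:
            raise ConfigError("cv must be non-negative")
        if self.centering not in ("median", "mean"):
            raise ConfigError(f"centering must be 'median' or 'mean', got {self.centering!r}")
        unknown = set(self.gene) - set(GENE_PARAM_NAMES)
        if unknown:
            raise ConfigError(f"unknown gene parameter keys: {sorted(unknown)}")
        unknown = set(self.gene_ranges) - set(GENE_PARAM_NAMES)
        if unknown:
            raise ConfigError(f"unknown gene_ranges keys: {sorted(unknown)}")
        self.gene_params()  # validate
        self.ranges()
        self.sa_config()

    def gene_params(self) -> GeneParams:
        base = _default_gene()
        base.update(self.gene)
        return GeneParams(**base)

    def ranges(self) -> GeneParamRanges:
        base = _default_ranges()
        base.update(self.gene_ranges)
        return GeneParamRanges(**{k: tuple(v) for k, v in base.items()})

    def sa_config(self) -> SAConfig:
        base = _default_sa()
        unknown = set(self.sa) - set(base)
        if unknown:
            raise ConfigError(f"unknown sa keys: {sorted(unknown)}")
        base.update(self.sa)
        return SAConfig(**base)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def load_config(path: str | Path | None) -> RunConfig:
    """Parse a JSON/YAML config; unknown keys raise :class:`ConfigError`."""
    if path is None:
        return RunConfig()
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if raw is None:
        return RunConfig()
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: config root must be a mapping")
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"{path}: unknown config keys: {sorted(unknown)}")
    try:
        return RunConfig(**raw)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"{path}: {exc}") from exc


def write_config(cfg: RunConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(cfg.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")


def child_seed(master: int, name: str) -> int:
    """Deterministic named sub-seed below 2^31 derived from the master seed."""
    digest = hashlib.sha256(f"{master}:{name}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def child_rng(master: int, name: str) -> np.random.Generator:
    return np.random.default_rng(child_seed(master, name))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_results(outdir: str | Path, files: list[str | Path]) -> Path:
    """Write manifest.json listing every output file with its SHA-256 hash."""
    outdir = Path(outdir)
    manifest = {
        "files": {
            str(Path(f).relative_to(outdir)): _sha256(Path(f)) for f in sorted(map(str, files))
        }
    }
    path = outdir / "manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return path
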