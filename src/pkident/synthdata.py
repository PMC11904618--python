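"""Synthetic observation generation, unit conversion and data/config I/O.

Synthetic datasets follow the protocol used throughout the shipped studies:
solve the model at true (nominal) parameter values over the observation grid
(default 0-1000 h, 1001 points) and add i.i.d. Gaussian noise whose scale is
a stated fraction of the maximum response.  Two readings of "noise at x% of
the maximum" are supported: the default takes the standard deviation as
fraction*max (unit-robust); the literal variance reading (sigma^2 =
fraction*max) is retained as an option, noting that it is unit-dependent and
at molar magnitudes produces noise exceeding the signal.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import yaml

from .models import (
    ModelSpec,
    ParameterInfo,
    TimeGrid,
    fixture_onecomp,
    fixture_twocomp,
    parse_unit,
    scaffold_mpbpk,
    solve_model,
)

__all__ = [
    "SyntheticDataset",
    "ConfigError",
    "RunConfig",
    "generate_synthetic",
    "convert_units",
    "read_dataset",
    "write_dataset",
    "read_config",
]

NOISE_MODES = ("sd-of-max", "variance-of-max")


class ConfigError(ValueError):
    """Raised for invalid or incomplete run configurations."""


@dataclass
class SyntheticDataset:
    """A simulated dataset: times, noisy values and generation metadata."""

    times: np.ndarray
    values: np.ndarray
    noise_fraction: Optional[float] = None
    noise_mode: Optional[str] = None
    seed: Optional[int] = None
    true_params: Optional[np.ndarray] = None
    sigma: Optional[float] = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have equal length")

    @property
    def n(self) -> int:
        return self.times.size


def generate_synthetic(
    model: ModelSpec,
    params: Optional[np.ndarray] = None,
    grid: Optional[TimeGrid] = None,
    noise_fraction: float = 0.02,
    mode: str = "sd-of-max",
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
    **solve_kwargs,
) -> SyntheticDataset:
    """Simulate noisy observations of the model response.

    ``mode`` selects how ``noise_fraction`` scales the noise: ``"sd-of-max"``
    (default) sets sigma = fraction * max|response|; ``"variance-of-max"``
    sets sigma^2 = fraction * max|response|.
    """
    if noise_fraction < 0:
        raise ValueError("noise_fraction must be nonnegative")
    if mode not in NOISE_MODES:
        raise ValueError(f"unknown noise mode {mode!r}; expected one of {NOISE_MODES}")
    grid = grid or TimeGrid()
    theta = model.nominal if params is None else np.asarray(params, dtype=float)
    response = solve_model(model, theta, grid, **solve_kwargs).response
    peak = float(np.max(np.abs(response)))
    if mode == "sd-of-max":
        sigma = noise_fraction * peak
    else:
        sigma = float(np.sqrt(noise_fraction * peak))
    rng = rng if rng is not None else np.random.default_rng(seed)
    values = response + (rng.normal(0.0, sigma, grid.n) if sigma > 0 else 0.0)
    return SyntheticDataset(
        times=grid.times,
        values=values,
        noise_fraction=noise_fraction,
        noise_mode=mode,
        seed=seed,
        true_params=theta,
        sigma=sigma,
    )


def convert_units(data, scale: float):
    """Multiply response values by ``scale`` (e.g. 1e9 for M -> nM).

    Accepts a :class:`SyntheticDataset` (noise bookkeeping is updated: the
    noise sd scales by ``scale``, hence the variance by ``scale**2``) or a
    plain array.
    """
    if scale <= 0:
        raise ValueError("unit scale must be positive")
    if isinstance(data, SyntheticDataset):
        return dataclasses.replace(
            data,
            values=data.values * scale,
            sigma=None if data.sigma is None else data.sigma * scale,
        )
    return np.asarray(data, dtype=float) * scale


def write_dataset(dataset: SyntheticDataset, path) -> None:
    """Write a dataset as CSV ``time,value`` at full precision (lossless
    round-trip through :func:`read_dataset`)."""
    arr = np.column_stack([dataset.times, dataset.values])
    np.savetxt(path, arr, delimiter=",", header="time,value", comments="",
               fmt="%.17g")


def read_dataset(path) -> SyntheticDataset:
    """Read a CSV dataset with header ``time,value``."""
    import pandas as pd

    df = pd.read_csv(path, float_precision="round_trip")
    missing = {"time", "value"} - set(df.columns)
    if missing:
        raise ValueError(f"dataset {path} is missing columns: {sorted(missing)}")
    for col in ("time", "value"):
        if not np.issubdtype(df[col].dtype, np.number):
            raise ValueError(f"dataset column {col!r} contains non-numeric cells")
    return SyntheticDataset(times=df["time"].to_numpy(),
                            values=df["value"].to_numpy())


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

_KNOWN_TOP_KEYS = {
    "model", "grid", "noise", "mcmc", "pss", "subset", "seed", "data",
    "response_unit_scale",
}
_KNOWN_MODEL_KEYS = {"name", "parameters"}
_KNOWN_PARAM_KEYS = {"name", "unit", "nominal", "prior"}
_KNOWN_NOISE_KEYS = {"fraction", "mode"}
_KNOWN_MCMC_KEYS = {"draws", "burn_in_frac", "gamma", "adapt_interval",
                    "ess_threshold", "c1_threshold", "c2_delta", "max_reruns"}
_KNOWN_GRID_KEYS = {"start", "end", "n"}
_KNOWN_PSS_KEYS = {"thresholds", "method", "step"}

_FIXTURES = {"onecomp": fixture_onecomp, "twocomp": fixture_twocomp}


@dataclass
class RunConfig:
    """A validated run specification: model, grid, noise, subsets, MCMC."""

    model: ModelSpec
    grid: TimeGrid
    noise_fraction: float
    noise_mode: str
    seed: Optional[int]
    subset: Optional[list[str]]
    thresholds: Optional[list[float]]
    mcmc: dict
    data_path: Optional[str]
    sensitivity: dict


def _check_keys(section: dict, known: set, where: str) -> None:
    unknown = set(section) - known
    if unknown:
        raise ConfigError(f"unknown config key(s) in {where}: {sorted(unknown)}")


def _parse_parameters(blocks: Sequence[dict]) -> list[ParameterInfo]:
    out = []
    for blk in blocks:
        if not isinstance(blk, dict):
            raise ConfigError("each parameter block must be a mapping")
        _check_keys(blk, _KNOWN_PARAM_KEYS, f"parameter block {blk.get('name')!r}")
        for key in ("name", "nominal"):
            if key not in blk:
                raise ConfigError(f"parameter block missing {key!r}: {blk}")
        prior = blk.get("prior")
        if prior is None or len(prior) != 2:
            raise ConfigError(
                f"parameter {blk['name']!r} needs prior bounds [low, high]"
            )
        out.append(
            ParameterInfo(
                name=str(blk["name"]),
                dimension=parse_unit(str(blk.get("unit", "-"))),
                nominal=float(blk["nominal"]),
                prior_low=float(prior[0]),
                prior_high=float(prior[1]),
            )
        )
    return out


def read_config(path) -> RunConfig:
    """Read and validate a YAML run configuration.

    Recognized sections: ``model`` (name + optional per-parameter blocks with
    name/unit/nominal/prior), ``grid`` (start/end/n), ``noise``
    (fraction/mode), ``subset``, ``pss`` (thresholds), ``mcmc`` settings,
    ``seed``, ``data`` (path to a CSV dataset) and ``response_unit_scale``.
    Unknown keys raise :class:`ConfigError` naming the offender.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    _check_keys(raw, _KNOWN_TOP_KEYS, "config root")

    model_section = raw.get("model", {"name": "onecomp"})
    if isinstance(model_section, str):
        model_section = {"name": model_section}
    _check_keys(model_section, _KNOWN_MODEL_KEYS, "model section")
    name = model_section.get("name")
    params = _parse_parameters(model_section.get("parameters", []))
    if name in _FIXTURES:
        model = _FIXTURES[name]()
    elif name == "mpbpk_scaffold":
        model = scaffold_mpbpk()
    else:
        raise ConfigError(
            f"unknown model {name!r}; expected one of "
            f"{sorted(_FIXTURES) + ['mpbpk_scaffold']}"
        )
    if params:
        # parameter blocks override registered parameters by name and append
        # new ones (e.g. the remaining scaffold parameters)
        override = {p.name: p for p in params}
        merged = [override.pop(p.name, p) for p in model.parameters]
        merged.extend(override.values())
        model.parameters = merged
    scale = raw.get("response_unit_scale")
    if scale is not None:
        model = model.with_scale(float(scale))

    grid_section = raw.get("grid", {})
    _check_keys(grid_section, _KNOWN_GRID_KEYS, "grid section")
    grid = TimeGrid(
        start=float(grid_section.get("start", 0.0)),
        end=float(grid_section.get("end", 1000.0)),
        n=int(grid_section.get("n", 1001)),
    )

    noise_section = raw.get("noise", {})
    _check_keys(noise_section, _KNOWN_NOISE_KEYS, "noise section")
    noise_mode = noise_section.get("mode", "sd-of-max")
    if noise_mode not in NOISE_MODES:
        raise ConfigError(f"unknown noise mode {noise_mode!r}")

    subset = raw.get("subset")
    if subset is not None:
        known = set(model.parameter_names)
        for s in subset:
            if s not in known:
                raise ConfigError(f"subset parameter {s!r} is not in the model")

    pss_section = raw.get("pss", {})
    _check_keys(pss_section, _KNOWN_PSS_KEYS, "pss section")
    thresholds = pss_section.get("thresholds")

    mcmc = raw.get("mcmc", {})
    _check_keys(mcmc, _KNOWN_MCMC_KEYS, "mcmc section")

    return RunConfig(
        model=model,
        grid=grid,
        noise_fraction=float(noise_section.get("fraction", 0.02)),
        noise_mode=noise_mode,
        seed=raw.get("seed"),
        subset=subset,
        thresholds=thresholds,
        mcmc=dict(mcmc),
        data_path=raw.get("data"),
        sensitivity={k: pss_section[k] for k in ("method", "step")
                     if k in pss_section},
    )
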