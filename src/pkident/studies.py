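"""Reusable simulation studies on the fixture models.

These drive the same machinery a user would: generate synthetic data, run the
calibration, and measure recovery, mixing and predictive coverage.  Problem
sizes default to the study conditions used throughout the package
documentation (0-1000 h grid with 1001 points, 2% noise, 5e4 draws for
recovery, 200 replicates at 2e4 draws for coverage).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .models import ModelSpec, TimeGrid, fixture_onecomp
from .sampling import BayesianCalibration, CalibrationResults
from .synthdata import generate_synthetic

__all__ = ["RecoveryResult", "parameter_recovery", "prediction_coverage"]


@dataclass
class RecoveryResult:
    """Posterior recovery of known true parameters from one synthetic fit."""

    names: list[str]
    truth: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    ess: np.ndarray
    results: CalibrationResults

    @property
    def z_scores(self) -> np.ndarray:
        """|posterior mean - truth| in units of the posterior sd."""
        return np.abs(self.mean - self.truth) / self.sd


def parameter_recovery(
    model: Optional[ModelSpec] = None,
    sample_names: Sequence[str] = ("F", "CL"),
    draws: int = 50_000,
    noise_fraction: float = 0.02,
    seed: Optional[int] = 0,
    grid: Optional[TimeGrid] = None,
    **fit_options,
) -> RecoveryResult:
    """Fit a fixture model to one synthetic dataset generated at the nominal
    (true) parameter values and summarize recovery."""
    model = model or fixture_onecomp()
    grid = grid or TimeGrid()
    ss = np.random.SeedSequence(seed)
    data_seed, fit_seed = (int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(2))
    ds = generate_synthetic(model, grid=grid, noise_fraction=noise_fraction,
                            seed=data_seed)
    calib = BayesianCalibration(ds.values, ds.times, model, list(sample_names),
                                grid=grid)
    res = calib.fit(draws=draws, seed=fit_seed, **fit_options)
    truth = np.array([model.parameter(n).nominal for n in sample_names])
    return RecoveryResult(
        names=list(sample_names),
        truth=truth,
        mean=res.params,
        sd=res.sd,
        ess=res.ess,
        results=res,
    )


def prediction_coverage(
    model: Optional[ModelSpec] = None,
    sample_names: Sequence[str] = ("F", "CL"),
    n_replicates: int = 200,
    draws: int = 20_000,
    noise_fraction: float = 0.02,
    level: float = 0.95,
    seed: Optional[int] = 0,
    grid: Optional[TimeGrid] = None,
    n_band_draws: int = 400,
) -> float:
    """Empirical pointwise coverage of the prediction band.

    For each replicate: simulate a dataset at the true parameters, fit the
    posterior, build the ``level`` prediction band, and score the fraction of
    a *fresh* noise realization of the data falling inside the band.  Returns
    the coverage fraction pooled over replicates and grid points.
    """
    model = model or fixture_onecomp()
    grid = grid or TimeGrid()
    root = np.random.SeedSequence(seed)
    covered = 0
    total = 0
    for rep_ss in root.spawn(n_replicates):
        s_data, s_fit, s_band, s_fresh = (
            int(s.generate_state(1)[0] % 2**31) for s in rep_ss.spawn(4)
        )
        ds = generate_synthetic(model, grid=grid, noise_fraction=noise_fraction,
                                seed=s_data)
        calib = BayesianCalibration(ds.values, ds.times, model,
                                    list(sample_names), grid=grid)
        res = calib.fit(draws=draws, seed=s_fit)
        bands = res.posterior_predictive(level=level, n_draws=n_band_draws,
                                         seed=s_band)
        fresh = generate_synthetic(model, grid=grid,
                                   noise_fraction=noise_fraction, seed=s_fresh)
        inside = (fresh.values >= bands.prediction_lower) & (
            fresh.values <= bands.prediction_upper
        )
        covered += int(inside.sum())
        total += inside.size
    return covered / total
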