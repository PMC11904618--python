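"""Shared fixtures: fixture models, grids, and the expensive session-scoped
calibration runs reused across diagnostic and acceptance tests."""

import numpy as np
import pytest

import pkident as pk
from pkident.dimensional import Quantity, quantities_from_model
from pkident.pss import SubsetLadder, eliminate_order
from pkident.refine import run_refinement
from pkident.studies import parameter_recovery
from pkident.synthdata import generate_synthetic


@pytest.fixture(scope="session")
def onecomp():
    return pk.fixture_onecomp()


@pytest.fixture(scope="session")
def twocomp():
    return pk.fixture_twocomp()


@pytest.fixture(scope="session")
def grid():
    return pk.TimeGrid()


@pytest.fixture(scope="session")
def onecomp_sensitivity(onecomp, grid):
    return pk.sensitivity_matrix(onecomp, grid)


@pytest.fixture(scope="session")
def onecomp_reduction(onecomp):
    """Dimensional reduction of the one-compartment concentration relation:
    C = F(D, V, CL, F, t)."""
    qs = quantities_from_model(
        onecomp, extra=[Quantity("D", (1, 0, 0)), Quantity("t", (0, 0, 1))]
    )
    return pk.reduce(Quantity("C", (1, -1, 0)), qs)


@pytest.fixture(scope="session")
def recovery_run():
    """One-compartment {F, CL} calibration (V fixed at nominal): 2% noise,
    5e4 draws.  Shared by the recovery, diagnostics and band tests."""
    return parameter_recovery(draws=50_000, seed=0)


@pytest.fixture(scope="session")
def refinement_report(onecomp, grid, onecomp_sensitivity, onecomp_reduction):
    """End-to-end refinement over the ladder {F,CL} ⊂ {F,CL,V} on one 2%-noise
    synthetic dataset, 5e4 draws per run."""
    ds = generate_synthetic(onecomp, grid=grid, noise_fraction=0.02, seed=11)
    trace = eliminate_order(onecomp_sensitivity)
    ladder = SubsetLadder(
        thresholds=[1e-2, 1e-9], subsets=[["F", "CL"], ["F", "CL", "V"]]
    )
    return run_refinement(
        onecomp, ds.times, ds.values, ladder,
        draws=50_000, seed=5, trace=trace, reduction=onecomp_reduction,
        grid=grid, keep_results=True,
    )
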