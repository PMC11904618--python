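"""SVD-based parameter subset selection (PSS).

Starting from the full n x p log-sensitivity matrix, parameters are
eliminated greedily: at each step the singular value decomposition of the
current matrix is computed and, if the squared ratio of the smallest to the
largest singular value, (sigma_min/sigma_max)^2, is below a threshold eta,
the column with the largest-magnitude component in the right singular vector
of sigma_min — the least identifiable parameter — is removed and the SVD is
recomputed on the reduced matrix.  The elimination order does not depend on
eta, so a single trace serves a whole ladder of thresholds, producing nested
candidate subsets A_1 ⊂ A_2 ⊂ ... (larger eta is stricter and keeps fewer
parameters).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import least_squares

from .models import ModelSpec, TimeGrid, solve_model
from .sensitivity import SensitivityMatrix

__all__ = [
    "EliminationTrace",
    "SubsetLadder",
    "eliminate_order",
    "subsets_for_thresholds",
    "relative_error_norm",
]


@dataclass
class EliminationTrace:
    """Record of one greedy PSS elimination run.

    ``order`` lists (eliminated parameter, squared singular-value ratio of the
    matrix it was eliminated from), from the full matrix (p columns) down to
    two columns; the single surviving column has ratio 1 by convention.
    """

    parameter_names: list[str]
    order: list[tuple[str, float]]

    def __post_init__(self) -> None:
        eliminated = [name for name, _ in self.order]
        if len(set(eliminated)) != len(eliminated):
            raise ValueError("eliminated parameters must be distinct")
        for _, r in self.order:
            if not 0.0 <= r <= 1.0 + 1e-12:
                raise ValueError(f"squared singular-value ratio {r} outside [0, 1]")

    @property
    def ratios_at_elimination(self) -> list[float]:
        """(sigma_min/sigma_max)^2 of the matrix *before* each elimination,
        i.e. at sizes p, p-1, ..., 2."""
        return [r for _, r in self.order]

    @property
    def ratios_after(self) -> list[float]:
        """Squared ratio after each elimination (the next matrix's ratio; the
        final single-column matrix has ratio 1)."""
        return self.ratios_at_elimination[1:] + [1.0]

    def eliminated_before(self, name: str) -> int:
        """Elimination position of ``name`` (0 = first eliminated); parameters
        never eliminated sort last."""
        for k, (n, _) in enumerate(self.order):
            if n == name:
                return k
        return len(self.order) + self.parameter_names.index(name)

    def survivors(self, n_eliminated: int) -> list[str]:
        gone = {name for name, _ in self.order[:n_eliminated]}
        return [n for n in self.parameter_names if n not in gone]


@dataclass
class SubsetLadder:
    """Nested candidate subsets A_1 ⊂ ... ⊂ A_k for decreasing thresholds."""

    thresholds: list[float]
    subsets: list[list[str]]
    rbar: Optional[list[float]] = None

    def __post_init__(self) -> None:
        for a, b in zip(self.subsets, self.subsets[1:]):
            if not set(a) <= set(b):
                raise ValueError("subset ladder is not nested")

    def rows(self):
        for i, (eta, subset) in enumerate(zip(self.thresholds, self.subsets)):
            yield eta, subset, (self.rbar[i] if self.rbar else None)

    def to_dict(self) -> dict:
        return {
            "thresholds": self.thresholds,
            "subsets": self.subsets,
            "rbar": self.rbar,
        }


def _tie_break_argmax(weights: np.ndarray, col_indices: np.ndarray,
                      rel_tol: float = 1e-9) -> int:
    """Index (into the current columns) of the largest |component|; near-ties
    resolve to the highest original column index for determinism."""
    m = np.abs(weights)
    top = m.max()
    tied = np.flatnonzero(m >= top * (1.0 - rel_tol))
    # among tied positions pick the one with the highest original column index
    return int(tied[np.argmax(col_indices[tied])])


def eliminate_order(S: SensitivityMatrix | np.ndarray,
                    parameter_names: Optional[Sequence[str]] = None) -> EliminationTrace:
    """Greedy PSS elimination trace of a sensitivity matrix.

    At each step the SVD of the current column set is recomputed; the recorded
    ratio is (sigma_min/sigma_max)^2 of that matrix and the removed column is
    the one dominating the right singular vector of sigma_min.
    """
    if isinstance(S, SensitivityMatrix):
        A = np.asarray(S.values, dtype=float)
        names = list(S.parameter_names)
    else:
        A = np.asarray(S, dtype=float)
        if parameter_names is None:
            names = [f"p{j}" for j in range(A.shape[1])]
        else:
            names = list(parameter_names)
    if A.ndim != 2:
        raise ValueError("sensitivity matrix must be 2-D")
    n, p = A.shape
    if p < 1 or n < p:
        raise ValueError(f"need n >= p >= 1 columns, got shape {A.shape}")
    if not np.all(np.isfinite(A)):
        raise ValueError("sensitivity matrix contains non-finite entries")
    if not np.any(A):
        raise ValueError("all-zero sensitivity matrix: no identifiable parameters")

    active = np.arange(p)
    order: list[tuple[str, float]] = []
    while active.size > 1:
        sub = A[:, active]
        _, s, Vt = np.linalg.svd(sub, full_matrices=False)
        if s[0] == 0.0:
            raise ValueError("all-zero sensitivity matrix: no identifiable parameters")
        ratio = float((s[-1] / s[0]) ** 2)
        v_min = Vt[-1]
        kill = _tie_break_argmax(v_min, active)
        order.append((names[active[kill]], ratio))
        active = np.delete(active, kill)
    return EliminationTrace(parameter_names=names, order=order)


def subsets_for_thresholds(trace: EliminationTrace,
                           thresholds: Sequence[float]) -> SubsetLadder:
    """Candidate subsets for a strictly decreasing ladder of thresholds.

    For each eta the subset is the column set surviving when the squared
    ratio (sigma_min/sigma_max)^2 first reaches >= eta during elimination;
    the single-column endpoint (ratio 1) guarantees termination.  Nesting
    across thresholds is automatic because the greedy order never consults
    eta.
    """
    thr = list(thresholds)
    if not thr:
        raise ValueError("threshold list is empty")
    for eta in thr:
        if not 0.0 < eta < 1.0:
            raise ValueError(f"threshold {eta} outside (0, 1)")
    if any(a <= b for a, b in zip(thr, thr[1:])):
        raise ValueError("thresholds must be strictly decreasing")

    # ratios of the matrices of sizes p, p-1, ..., 2, then 1 (ratio 1)
    ratios = trace.ratios_at_elimination + [1.0]
    subsets = []
    for eta in thr:
        stop = next(i for i, r in enumerate(ratios) if r >= eta)
        subsets.append(trace.survivors(stop))
    return SubsetLadder(thresholds=thr, subsets=subsets)


def relative_error_norm(
    model: ModelSpec,
    grid: TimeGrid,
    subset: Sequence[str],
    perturbation: float = 0.2,
    **solve_kwargs,
) -> float:
    """Average relative error norm R̄ of a candidate subset.

    Verification protocol: every parameter *outside* the subset is perturbed
    by ``perturbation`` (default +20%) of its nominal value; the subset
    parameters are re-estimated by least squares against the nominal-parameter
    response; R̄ is the grid average of |fit - nominal| / max|nominal|.  A
    small R̄ means the subset can compensate for misspecification of the
    parameters held fixed, i.e. it captures the directions the response
    actually depends on.
    """
    subset = list(subset)
    if not subset:
        raise ValueError("subset must be nonempty")
    for name in subset:
        model.parameter(name)
    others = [n for n in model.parameter_names if n not in subset]
    target = solve_model(model, model.nominal, grid, **solve_kwargs).response
    scale = np.max(np.abs(target))
    if not others:
        return 0.0

    theta_pert = model.nominal
    for name in others:
        j = model.index(name)
        theta_pert[j] = theta_pert[j] * (1.0 + perturbation)
    idx = [model.index(n) for n in subset]

    def residual(x):
        theta = theta_pert.copy()
        theta[idx] = x
        return (solve_model(model, theta, grid, **solve_kwargs).response - target) / scale

    x0 = model.nominal[idx]
    lo = np.array([max(model.parameter(n).prior_low, 1e-12) for n in subset])
    hi = np.array([model.parameter(n).prior_high for n in subset])
    fit = least_squares(residual, x0, bounds=(lo, hi), xtol=1e-12, ftol=1e-12)
    if not fit.success:
        raise RuntimeError(
            f"least-squares refit failed for subset {subset}: {fit.message}"
        )
    return float(np.mean(np.abs(fit.fun)))
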