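"""Local sensitivity of the observed response to log-transformed parameters.

The (i, j) entry of the sensitivity matrix is d response(t_i) / d log(theta_j)
evaluated at the nominal parameter vector.  The log transform puts parameters
of very different magnitudes on a common scale, and the response is taken
after unit conversion (``response_unit_scale``) so matrix entries are
well-scaled.  Derivatives are computed by central finite differences in
log-parameter space (default) or by the complex-step method where the model
supplies an analytic solution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .models import ModelSpec, TimeGrid, solve_model

__all__ = ["SensitivityMatrix", "sensitivity_matrix"]


@dataclass
class SensitivityMatrix:
    """n x p matrix of response sensitivities with respect to log parameters."""

    values: np.ndarray
    times: np.ndarray
    parameter_names: list[str]
    method: str

    def __post_init__(self) -> None:
        if self.values.shape != (len(self.times), len(self.parameter_names)):
            raise ValueError("sensitivity matrix shape mismatch")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("sensitivity matrix contains non-finite entries")

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.parameter_names.index(name)]

    def to_dataframe(self):
        import pandas as pd

        df = pd.DataFrame(self.values, columns=self.parameter_names)
        df.insert(0, "time", self.times)
        return df

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def sensitivity_matrix(
    model: ModelSpec,
    grid: TimeGrid | None = None,
    subset: list[str] | None = None,
    method: str = "central",
    step: float = 1e-4,
    **solve_kwargs,
) -> SensitivityMatrix:
    """Sensitivities of the observed response at the nominal parameter values.

    Parameters
    ----------
    subset
        Parameter names to differentiate with respect to, in the requested
        column order; defaults to all model parameters.
    method
        ``"central"`` (central differences in log space, step in log units) or
        ``"complex"`` (complex-step; requires an analytic ``model.solution``).
    step
        Absolute step in log-parameter units.
    """
    grid = grid or TimeGrid()
    names = subset if subset is not None else model.parameter_names
    unknown = set(names) - set(model.parameter_names)
    if unknown:
        raise KeyError(f"unknown parameters in subset: {sorted(unknown)}")
    if step < 1e-12:
        raise ValueError(f"finite-difference step {step} underflows")
    theta0 = model.nominal
    for name in names:
        if theta0[model.index(name)] <= 0:
            raise ValueError(
                f"parameter {name!r} has non-positive nominal value; "
                "log-parameter sensitivities are undefined"
            )

    cols = np.empty((grid.n, len(names)))
    if method == "central":
        for k, name in enumerate(names):
            j = model.index(name)
            up, dn = theta0.copy(), theta0.copy()
            up[j] = theta0[j] * np.exp(step)
            dn[j] = theta0[j] * np.exp(-step)
            r_up = solve_model(model, up, grid, **solve_kwargs).response
            r_dn = solve_model(model, dn, grid, **solve_kwargs).response
            cols[:, k] = (r_up - r_dn) / (2.0 * step)
    elif method == "complex":
        if model.solution is None:
            raise ValueError(
                "complex-step sensitivities require a model with an analytic "
                "solution; use method='central'"
            )
        observe = model.observe or (lambda tr: tr[:, 0])
        for k, name in enumerate(names):
            j = model.index(name)
            theta_c = theta0.astype(complex)
            theta_c[j] = theta0[j] * np.exp(1j * step)
            states = np.asarray(model.solution(grid.times, theta_c))
            resp = observe(states) * model.response_unit_scale
            cols[:, k] = resp.imag / step
    else:
        raise ValueError(f"unknown sensitivity method {method!r}")

    return SensitivityMatrix(
        values=cols, times=grid.times, parameter_names=list(names), method=method
    )
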