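"""Declarative ODE model descriptions and fixture pharmacokinetic models.

A model is a system dx/dt = g(t, x, theta) with parameter-dependent initial
condition x(t0) = x0(theta) and a scalar observed response obtained by mapping
the state trajectory (typically a plasma concentration).  Parameters carry
physical dimensions over the three base dimensions used throughout this
package: (amount, volume, time).

Two fully specified compartment fixtures are shipped (a one-compartment model
with first-order elimination and a two-compartment distribution model), plus a
configuration scaffold for a 16-state minimal physiologically based
pharmacokinetic (mPBPK) model of antibody disposition in the brain, whose rate
equations must be supplied by the user.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "BASE_DIMENSIONS",
    "ParameterInfo",
    "TimeGrid",
    "ModelSpec",
    "SolveResult",
    "ModelEquationsRequired",
    "SolverError",
    "parse_unit",
    "format_dimension",
    "solve_model",
    "fixture_onecomp",
    "fixture_twocomp",
    "scaffold_mpbpk",
    "MPBPK_STATE_NAMES",
    "MPBPK_CANDIDATE_PARAMETERS",
]

#: Base physical dimensions, in order: amount of substance, volume, time.
BASE_DIMENSIONS = ("amount", "volume", "time")

#: Unit tokens understood by :func:`parse_unit`, as exponent vectors over
#: ``BASE_DIMENSIONS``.
_UNIT_TOKENS = {
    "l": (0, 1, 0),
    "L": (0, 1, 0),
    "h": (0, 0, 1),
    "hr": (0, 0, 1),
    "mol": (1, 0, 0),
    "M": (1, -1, 0),   # molar = mol per litre
    "nM": (1, -1, 0),  # same dimensions as M; scale handled separately
    "1": (0, 0, 0),
}


class ModelEquationsRequired(RuntimeError):
    """Raised when a scaffold model is solved without user-supplied dynamics."""


class SolverError(RuntimeError):
    """Raised when the ODE integrator fails or produces non-finite states."""


def parse_unit(unit: str) -> tuple[int, int, int]:
    """Parse a unit string like ``"L"``, ``"l/h"``, ``"1/h"``, ``"-"`` into an
    integer exponent vector over (amount, volume, time).

    Only products and a single quotient of the tokens litre, hour, mole and
    molar are supported; this is deliberately not a general units engine.
    """
    s = unit.strip()
    if s in ("", "-", "—", "1"):
        return (0, 0, 0)
    if s.count("/") > 1:
        raise ValueError(f"cannot parse unit {unit!r}: at most one '/'")
    num, _, den = s.partition("/")

    def side(expr: str, sign: int, out: list[int]) -> None:
        expr = expr.strip()
        if not expr:
            return
        for tok in expr.replace("·", "*").split("*"):
            tok = tok.strip()
            if tok not in _UNIT_TOKENS:
                raise ValueError(f"cannot parse unit {unit!r}: unknown token {tok!r}")
            for i, e in enumerate(_UNIT_TOKENS[tok]):
                out[i] += sign * e

    vec = [0, 0, 0]
    side(num, +1, vec)
    side(den, -1, vec)
    return tuple(vec)  # type: ignore[return-value]


def format_dimension(dim: Sequence[int]) -> str:
    """Human-readable rendering of a dimension vector, e.g. ``amount·volume⁻¹``."""
    if not any(dim):
        return "1"
    parts = []
    for name, e in zip(BASE_DIMENSIONS, dim):
        if e == 0:
            continue
        parts.append(name if e == 1 else f"{name}^{e}")
    return "·".join(parts)


@dataclass(frozen=True)
class ParameterInfo:
    """A model parameter: name, physical dimension, nominal value and the
    bounds of its uniform prior.

    The nominal value is the physiologically accepted reference value at which
    sensitivities are evaluated and at which non-identifiable parameters are
    fixed.
    """

    name: str
    dimension: tuple[int, int, int]
    nominal: float
    prior_low: float
    prior_high: float

    def __post_init__(self) -> None:
        if len(self.dimension) != len(BASE_DIMENSIONS):
            raise ValueError(
                f"parameter {self.name!r}: dimension vector must have length "
                f"{len(BASE_DIMENSIONS)}"
            )
        if not self.prior_low < self.prior_high:
            raise ValueError(
                f"parameter {self.name!r}: prior_low must be < prior_high"
            )
        if not (self.prior_low <= self.nominal <= self.prior_high):
            raise ValueError(
                f"parameter {self.name!r}: nominal {self.nominal} outside prior "
                f"bounds ({self.prior_low}, {self.prior_high})"
            )

    @property
    def is_dimensioned(self) -> bool:
        return any(self.dimension)


@dataclass(frozen=True)
class TimeGrid:
    """Uniform observation grid in hours.  Defaults cover 0-1000 h on 1001
    points, the grid used for all shipped studies."""

    start: float = 0.0
    end: float = 1000.0
    n: int = 1001

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("grid needs at least two points")
        if not self.end > self.start:
            raise ValueError("grid end must exceed start")

    @property
    def times(self) -> np.ndarray:
        return np.linspace(self.start, self.end, self.n)


@dataclass
class ModelSpec:
    """Declarative description of an ODE model with an observed response.

    Parameters
    ----------
    state_names
        Names of the state variables, in the order used by ``dynamics``.
    parameters
        :class:`ParameterInfo` records; the order defines the parameter vector.
    dynamics
        ``g(t, x, theta) -> dx/dt`` or None for a scaffold awaiting equations.
    initial_condition
        ``x0(theta) -> ndarray`` of length ``len(state_names)``.
    observe
        Maps the (n, m) state trajectory to the scalar response series (n,).
    response_unit_scale
        Multiplier applied to the observed response (e.g. 1e9 to report a
        molar concentration in nanomolar).  Strictly positive.
    solution
        Optional exact solution ``(times, theta) -> (n, m) states``; used by
        :func:`solve_model` unless ``force_numeric`` is requested.  Fixture
        models provide closed forms, which keeps large sampling studies cheap
        and gives the numeric integrator an oracle to be tested against.
    """

    state_names: list[str]
    parameters: list[ParameterInfo]
    dynamics: Optional[Callable] = None
    initial_condition: Optional[Callable] = None
    observe: Optional[Callable] = None
    response_unit_scale: float = 1.0
    solution: Optional[Callable] = None
    name: str = "model"

    def __post_init__(self) -> None:
        if self.response_unit_scale <= 0:
            raise ValueError("response_unit_scale must be positive")
        names = [p.name for p in self.parameters]
        if len(set(names)) != len(names):
            raise ValueError("duplicate parameter names")

    # -- parameter bookkeeping -------------------------------------------------
    @property
    def parameter_names(self) -> list[str]:
        return [p.name for p in self.parameters]

    @property
    def nominal(self) -> np.ndarray:
        return np.array([p.nominal for p in self.parameters], dtype=float)

    def parameter(self, name: str) -> ParameterInfo:
        for p in self.parameters:
            if p.name == name:
                return p
        raise KeyError(f"unknown parameter {name!r}")

    def index(self, name: str) -> int:
        return self.parameter_names.index(name)

    def with_scale(self, response_unit_scale: float) -> "ModelSpec":
        """Copy of this model reporting the response on another unit scale."""
        return dataclasses.replace(self, response_unit_scale=response_unit_scale)


@dataclass
class SolveResult:
    """Solution of a model on a grid: response series and full trajectory."""

    times: np.ndarray
    response: np.ndarray
    states: np.ndarray

    def to_dataframe(self, state_names: Optional[Sequence[str]] = None):
        import pandas as pd

        data = {"time": self.times, "response": self.response}
        if state_names is not None:
            for j, s in enumerate(state_names):
                data[s] = self.states[:, j]
        return pd.DataFrame(data)


def solve_model(
    model: ModelSpec,
    params: Optional[np.ndarray] = None,
    grid: Optional[TimeGrid] = None,
    *,
    rtol: float = 1e-8,
    atol: Optional[float] = None,
    force_numeric: bool = False,
    method: str = "LSODA",
) -> SolveResult:
    """Solve ``model`` at a parameter vector over ``grid``.

    Uses the model's exact solution when available (fixtures), otherwise a
    stiff-capable integrator.  The absolute tolerance defaults to
    ``1e-12 / response_unit_scale`` so that raw responses of order
    ``1/response_unit_scale`` are resolved well below the noise floor.
    """
    grid = grid or TimeGrid()
    theta = model.nominal if params is None else np.asarray(params, dtype=float)
    if theta.shape != (len(model.parameters),):
        raise ValueError(
            f"expected {len(model.parameters)} parameters, got shape {theta.shape}"
        )
    for p, v in zip(model.parameters, theta):
        if p.is_dimensioned and not v >= 0:
            raise ValueError(
                f"dimensioned parameter {p.name!r} must be nonnegative, got {v}"
            )

    times = grid.times
    if model.solution is not None and not force_numeric:
        states = np.asarray(model.solution(times, theta))
    else:
        if model.dynamics is None:
            raise ModelEquationsRequired(
                f"model equations required: {model.name!r} has no dynamics; "
                "supply right-hand sides via the scaffold configuration"
            )
        if model.initial_condition is None:
            raise ModelEquationsRequired(
                f"model equations required: {model.name!r} has no initial condition"
            )
        x0 = np.atleast_1d(np.asarray(model.initial_condition(theta), dtype=float))
        if x0.shape != (len(model.state_names),):
            raise ValueError(
                f"initial condition has {x0.size} entries for "
                f"{len(model.state_names)} states"
            )
        if atol is None:
            atol = 1e-12 / model.response_unit_scale
        sol = solve_ivp(
            lambda t, x: model.dynamics(t, x, theta),
            (times[0], times[-1]),
            x0,
            method=method,
            t_eval=times,
            rtol=rtol,
            atol=atol,
        )
        if not sol.success:
            raise SolverError(
                f"ODE solver failed for {model.name!r} at theta={theta.tolist()}: "
                f"{sol.message}"
            )
        states = sol.y.T
    if states.shape[0] != times.size:
        raise SolverError("trajectory length does not match grid")
    if not np.all(np.isfinite(states)):
        raise SolverError(
            f"non-finite state encountered for {model.name!r} at "
            f"theta={theta.tolist()}"
        )
    observe = model.observe or (lambda tr: tr[:, 0])
    response = np.asarray(observe(states), dtype=float) * model.response_unit_scale
    if response.shape != times.shape:
        raise SolverError("observation map must return one value per grid time")
    return SolveResult(times=times, response=response, states=states)


# ---------------------------------------------------------------------------
# Fixture models
# ---------------------------------------------------------------------------

#: Fixed dose (amount) used by both fixtures.
FIXTURE_DOSE = 1.0


def fixture_onecomp() -> ModelSpec:
    """One-compartment model with first-order elimination and bioavailability.

    V dC/dt = -CL C,  C(0) = F D / V  with fixed dose D = 1, so that
    C(t) = (F D / V) exp(-(CL/V) t).

    Deliberately rank-deficient from plasma data alone: the response depends on
    the three parameters (F, V, CL) only through the two combinations F/V and
    CL/V, which makes this the canonical test bed for the non-identifiability
    machinery (sensitivity rank deficiency, posterior ridges, refinement).
    """
    params = [
        ParameterInfo("F", (0, 0, 0), 0.7, 0.0, 1.0),
        ParameterInfo("V", (0, 1, 0), 3.0, 0.5, 10.0),
        ParameterInfo("CL", (0, 1, -1), 0.2, 0.01, 2.0),
    ]

    def dynamics(t, x, theta):
        F, V, CL = theta
        return np.array([-(CL / V) * x[0]])

    def init(theta):
        F, V, CL = theta
        return np.array([F * FIXTURE_DOSE / V])

    def solution(times, theta):
        F, V, CL = theta
        c0 = F * FIXTURE_DOSE / V
        return (c0 * np.exp(-(CL / V) * np.asarray(times)))[:, None]

    return ModelSpec(
        state_names=["C"],
        parameters=params,
        dynamics=dynamics,
        initial_condition=init,
        observe=lambda tr: tr[:, 0],
        solution=solution,
        name="onecomp",
    )


def fixture_twocomp() -> ModelSpec:
    """Two-compartment distribution model with central elimination.

    V1 dC1/dt = -(CL + Q) C1 + Q C2
    V2 dC2/dt = Q C1 - Q C2
    C1(0) = D/V1, C2(0) = 0, fixed dose D = 1.

    All four parameters (V1, V2, CL, Q) are generically identifiable from the
    biexponential plasma profile C1(t).
    """
    params = [
        ParameterInfo("V1", (0, 1, 0), 3.0, 0.5, 10.0),
        ParameterInfo("V2", (0, 1, 0), 11.0, 1.0, 30.0),
        ParameterInfo("CL", (0, 1, -1), 0.25, 0.01, 2.0),
        ParameterInfo("Q", (0, 1, -1), 0.5, 0.01, 5.0),
    ]

    def _matrix(theta):
        V1, V2, CL, Q = theta
        return np.array(
            [[-(CL + Q) / V1, Q / V1], [Q / V2, -Q / V2]]
        )

    def dynamics(t, x, theta):
        return _matrix(theta) @ x

    def init(theta):
        V1 = theta[0]
        return np.array([FIXTURE_DOSE / V1, 0.0])

    def solution(times, theta):
        # eigen-decomposition of the 2x2 rate matrix; distinct real
        # eigenvalues except on a measure-zero parameter set, where we fall
        # back to the numeric integrator
        A = _matrix(theta)
        lam, P = np.linalg.eig(A)
        if np.iscomplexobj(lam) and np.max(np.abs(lam.imag)) > 1e-12:
            raise np.linalg.LinAlgError("complex eigenvalues")
        lam = lam.real
        P = P.real
        x0 = init(theta)
        c = np.linalg.solve(P, x0)
        t = np.asarray(times)[:, None]
        return np.exp(t * lam[None, :]) * c[None, :] @ P.T

    def safe_solution(times, theta):
        try:
            return solution(times, theta)
        except np.linalg.LinAlgError:
            spec_num = dataclasses.replace(model, solution=None)
            return solve_model(
                spec_num, theta, TimeGrid(times[0], times[-1], len(times))
            ).states

    model = ModelSpec(
        state_names=["C1", "C2"],
        parameters=params,
        dynamics=dynamics,
        initial_condition=init,
        observe=lambda tr: tr[:, 0],
        name="twocomp",
    )
    model.solution = safe_solution
    return model


# ---------------------------------------------------------------------------
# mPBPK brain model scaffold
# ---------------------------------------------------------------------------

#: The 16 compartments of the minimal PBPK brain model for antibody
#: therapeutics: antibody concentrations in plasma, peripheral tissue,
#: endosomal and interstitial spaces, the brain vascular/barrier/CSF spaces,
#: lymph, and the free neonatal Fc receptor (FcRn) pools.
MPBPK_STATE_NAMES = [
    "plasma",
    "tissue_vascular",
    "tissue_endosome_unbound",
    "tissue_endosome_fcrn_bound",
    "tissue_interstitium",
    "brain_vascular",
    "bbb_endosome_unbound",
    "bbb_endosome_fcrn_bound",
    "brain_interstitium",
    "bcsfb_endosome_unbound",
    "bcsfb_endosome_fcrn_bound",
    "brain_csf",
    "lymph",
    "fcrn_tissue_endosome",
    "fcrn_bbb_endosome",
    "fcrn_bcsfb_endosome",
]

#: The ten candidate parameters screened for plasma-concentration
#: identifiability, with literature nominal values and uniform priors:
#: plasma volume VP, vascular reflection coefficients (sigma_TV, sigma_BCSFB,
#: sigma_BBB, switch-like fractions in [0,1]), endosomal degradation rate
#: kdeg, endosomal/interstitial/vascular tissue volumes (VTE, VTI, VTV),
#: FcRn recycling fraction FR and lymph flow LT.
MPBPK_CANDIDATE_PARAMETERS = [
    ParameterInfo("VP", parse_unit("l"), 3.12, 0.0, 100.0),
    ParameterInfo("sigma_TV", parse_unit("-"), 0.92, 0.0, 1.0),
    ParameterInfo("kdeg", parse_unit("1/h"), 26.60, 0.0, 100.0),
    ParameterInfo("VTE", parse_unit("l"), 0.33, 0.0, 100.0),
    ParameterInfo("VTI", parse_unit("l"), 11.09, 0.0, 100.0),
    ParameterInfo("FR", parse_unit("-"), 0.71, 0.0, 100.0),
    ParameterInfo("sigma_BCSFB", parse_unit("-"), 0.99, 0.0, 1.0),
    ParameterInfo("LT", parse_unit("l/h"), 0.32, 0.289, 0.353),
    ParameterInfo("sigma_BBB", parse_unit("-"), 1.0, 0.0, 1.0),
    ParameterInfo("VTV", parse_unit("l"), 1.68, 0.0, 100.0),
]


def scaffold_mpbpk(
    dynamics: Optional[Callable] = None,
    initial_condition: Optional[Callable] = None,
    extra_parameters: Sequence[ParameterInfo] = (),
    observe: Optional[Callable] = None,
    response_unit_scale: float = 1.0,
) -> ModelSpec:
    """Scaffold for the 16-state, 31-parameter mPBPK brain model.

    The compartment structure and the ten candidate parameters (units,
    nominal values, priors) are pre-registered; the rate equations, initial
    conditions and the remaining parameters are model-specific and must be
    supplied by the user (``dynamics``, ``initial_condition``,
    ``extra_parameters``).  Solving a scaffold without dynamics raises
    :class:`ModelEquationsRequired`.

    The default observation is the plasma compartment; set
    ``response_unit_scale=1e9`` to report molar concentrations in nM.
    """
    params = list(MPBPK_CANDIDATE_PARAMETERS) + list(extra_parameters)
    return ModelSpec(
        state_names=list(MPBPK_STATE_NAMES),
        parameters=params,
        dynamics=dynamics,
        initial_condition=initial_condition,
        observe=observe or (lambda tr: tr[:, 0]),
        response_unit_scale=response_unit_scale,
        name="mpbpk_scaffold",
    )
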