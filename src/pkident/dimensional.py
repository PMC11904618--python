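"""Exact dimensional analysis (Buckingham-Pi construction).

Writing the response as a monomial in the dimensioned quantities times an
unknown function of dimensionless products imposes one linear equation per
base dimension on the monomial exponents.  Solving that system exactly over
the rationals yields a particular exponent assignment matching the response's
dimension, and the null space of the dimension matrix enumerates the
independent dimensionless products.  Ratios of products can expose algebraic
dependencies between parameter pairs — combinations that the response can
constrain while the individual parameters remain free.

All linear algebra here is exact (sympy rationals): floating-point null
spaces produce spurious small exponents.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Optional, Sequence

import numpy as np
import sympy

from .models import BASE_DIMENSIONS, ModelSpec

__all__ = [
    "Quantity",
    "Monomial",
    "DimensionalReduction",
    "AlgebraicRelation",
    "dimension_matrix",
    "reduce",
    "algebraic_relation",
    "quantities_from_model",
]


@dataclass(frozen=True)
class Quantity:
    """A named quantity with an integer dimension vector over
    (amount, volume, time); the zero vector means unitless."""

    name: str
    dimension: tuple[int, int, int]

    def __post_init__(self) -> None:
        if len(self.dimension) != len(BASE_DIMENSIONS):
            raise ValueError(f"quantity {self.name!r}: bad dimension vector length")

    @property
    def is_unitless(self) -> bool:
        return not any(self.dimension)


@dataclass(frozen=True)
class Monomial:
    """A monomial over named quantities, stored as a name -> exponent map
    with exact rational exponents (canonical form uses coprime integers)."""

    exponents: tuple[tuple[str, Fraction], ...]

    @classmethod
    def from_dict(cls, d: dict) -> "Monomial":
        items = tuple(
            (k, Fraction(v)) for k, v in d.items() if Fraction(v) != 0
        )
        return cls(exponents=items)

    def as_dict(self) -> dict[str, Fraction]:
        return dict(self.exponents)

    def exponent(self, name: str) -> Fraction:
        return dict(self.exponents).get(name, Fraction(0))

    @property
    def names(self) -> list[str]:
        return [k for k, _ in self.exponents]

    def __str__(self) -> str:
        if not self.exponents:
            return "1"
        num, den = [], []
        for name, e in self.exponents:
            txt = name if abs(e) == 1 else f"{name}^{abs(e)}"
            (num if e > 0 else den).append(txt)
        s = "·".join(num) or "1"
        if den:
            s += " / (" + "·".join(den) + ")" if len(den) > 1 else " / " + den[0]
        return s


def dimension_matrix(quantities: Sequence[Quantity]) -> np.ndarray:
    """Integer dimension matrix with one row per base dimension and one
    column per quantity, in input order."""
    mat = np.zeros((len(BASE_DIMENSIONS), len(quantities)), dtype=int)
    for j, q in enumerate(quantities):
        mat[:, j] = q.dimension
    return mat


def _canonical_integer(vec: sympy.Matrix) -> list[Fraction]:
    """Scale a rational vector to coprime integers with positive leading
    (first nonzero) entry."""
    fracs = [sympy.nsimplify(v) for v in vec]
    denoms = [sympy.fraction(f)[1] for f in fracs]
    scale = sympy.lcm([d for d in denoms] or [1])
    ints = [sympy.Integer(f * scale) for f in fracs]
    g = sympy.gcd([i for i in ints if i != 0] or [1])
    ints = [i / g for i in ints]
    lead = next((i for i in ints if i != 0), sympy.Integer(1))
    if lead < 0:
        ints = [-i for i in ints]
    return [Fraction(int(i)) for i in ints]


@dataclass
class DimensionalReduction:
    """Result of reducing a response relation to dimensionless form.

    ``particular`` is the exponent assignment on the dimensioned quantities
    whose monomial has exactly the response's dimension (free exponents set
    to zero); ``new_products`` is the canonical integer basis of dimensionless
    products from the null space of the dimension matrix;
    ``already_unitless`` lists quantities that are dimensionless as given and
    therefore pass through as their own products.
    """

    response: Quantity
    quantities: list[Quantity]
    particular: Monomial
    new_products: list[Monomial]
    already_unitless: list[str]

    @property
    def products(self) -> list[Monomial]:
        """All dimensionless products: the new ones plus each already
        unitless quantity as its own monomial."""
        return self.new_products + [
            Monomial.from_dict({n: 1}) for n in self.already_unitless
        ]

    def to_dict(self) -> dict:
        return {
            "response": self.response.name,
            "particular": {k: str(v) for k, v in self.particular.as_dict().items()},
            "new_products": [str(m) for m in self.new_products],
            "already_unitless": self.already_unitless,
        }


def reduce(response: Quantity, quantities: Sequence[Quantity]) -> DimensionalReduction:
    """Dimensional reduction of ``response = F(quantities)``.

    Solves, exactly over the rationals, for exponents of the dimensioned
    quantities matching the response's dimension, and enumerates the
    null-space basis of dimensionless products in a canonical form (reduced
    echelon over the free variables in input order, scaled to coprime integer
    exponents with positive leading entry).
    """
    quantities = list(quantities)
    names = [q.name for q in quantities]
    if len(set(names)) != len(names):
        raise ValueError("duplicate quantity names")
    dimensioned = [q for q in quantities if not q.is_unitless]
    unitless = [q.name for q in quantities if q.is_unitless]

    r = sympy.Matrix([sympy.Integer(e) for e in response.dimension])
    if not dimensioned:
        if any(response.dimension):
            raise ValueError(
                "dimensionally inconsistent relation: response is dimensioned "
                "but every quantity is unitless"
            )
        return DimensionalReduction(
            response=response,
            quantities=quantities,
            particular=Monomial.from_dict({}),
            new_products=[],
            already_unitless=unitless,
        )

    D = sympy.Matrix(
        [[sympy.Integer(q.dimension[i]) for q in dimensioned]
         for i in range(len(BASE_DIMENSIONS))]
    )

    # particular solution: rref of [D | r] with free variables set to zero
    aug = D.row_join(r)
    rref, pivots = aug.rref()
    ncols = D.shape[1]
    if ncols in pivots:
        raise ValueError(
            f"dimensionally inconsistent relation: response dimension "
            f"{response.dimension} is not reachable from the given quantities"
        )
    part = [sympy.Integer(0)] * ncols
    for row, col in enumerate(pivots):
        part[col] = rref[row, ncols]
    particular = Monomial.from_dict(
        {q.name: Fraction(int(sympy.fraction(p)[0]), int(sympy.fraction(p)[1]))
         for q, p in zip(dimensioned, part)}
    )

    # null-space basis, canonicalized
    basis = []
    for vec in D.nullspace():
        ints = _canonical_integer(vec)
        basis.append(
            Monomial.from_dict({q.name: e for q, e in zip(dimensioned, ints)})
        )
    expected = len(dimensioned) - D.rank()
    assert len(basis) == expected, "null-space dimension mismatch"

    return DimensionalReduction(
        response=response,
        quantities=quantities,
        particular=particular,
        new_products=basis,
        already_unitless=unitless,
    )


@dataclass(frozen=True)
class AlgebraicRelation:
    """A dimensionless monomial tying two parameters together.

    ``kind`` is "inverse" when the pair members enter with same-sign
    exponents (their product is pinned, so one scales as the reciprocal of
    the other along the unidentifiable direction) and "proportional" when
    the exponents have opposite signs (their ratio is pinned).
    """

    pair: tuple[str, str]
    monomial: Monomial
    kind: str
    combination: tuple[int, ...]

    def to_dict(self) -> dict:
        return {
            "pair": list(self.pair),
            "monomial": str(self.monomial),
            "kind": self.kind,
            "combination": list(self.combination),
        }


def algebraic_relation(
    reduction: DimensionalReduction,
    pair: tuple[str, str],
    max_exponent: int = 3,
) -> Optional[AlgebraicRelation]:
    """Search integer combinations of the dimensionless-product basis for a
    monomial containing both members of ``pair``.

    Exponents of the basis products are bounded by ``max_exponent`` in
    absolute value; among hits, the simplest monomial wins (fewest distinct
    quantities, then smallest total degree, preferring a positive exponent on
    the first pair member).  Returns None when no bounded combination
    involves both parameters.
    """
    a, b = pair
    known = {q.name for q in reduction.quantities}
    for name in pair:
        if name not in known:
            raise KeyError(f"unknown quantity {name!r}")
    # only products mentioning a pair member can contribute; others would
    # merely add quantities and worsen the simplicity score
    basis = [m for m in reduction.products if a in m.names or b in m.names]
    if not basis:
        return None

    best = None
    rng = range(-max_exponent, max_exponent + 1)
    for combo in itertools.product(rng, repeat=len(basis)):
        if not any(combo):
            continue
        merged: dict[str, Fraction] = {}
        for c, mono in zip(combo, basis):
            if c == 0:
                continue
            for name, e in mono.exponents:
                merged[name] = merged.get(name, Fraction(0)) + c * e
        merged = {k: v for k, v in merged.items() if v != 0}
        ea, eb = merged.get(a), merged.get(b)
        if not ea or not eb:
            continue
        score = (
            len(merged),
            sum(abs(v) for v in merged.values()),
            0 if ea > 0 else 1,
            combo,
        )
        if best is None or score < best[0]:
            best = (score, merged, combo)
    if best is None:
        return None
    _, merged, combo = best
    ea, eb = merged[a], merged[b]
    kind = "inverse" if (ea > 0) == (eb > 0) else "proportional"
    return AlgebraicRelation(
        pair=(a, b),
        monomial=Monomial.from_dict(merged),
        kind=kind,
        combination=tuple(combo),
    )


def quantities_from_model(
    model: ModelSpec,
    extra: Sequence[Quantity] = (),
) -> list[Quantity]:
    """Quantities for a reduction: the model parameters plus any extra
    quantities (e.g. the initial concentration and time)."""
    qs = [Quantity(p.name, p.dimension) for p in model.parameters]
    return qs + list(extra)
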