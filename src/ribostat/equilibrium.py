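"""Equilibrium analysis and inverse design of the inhibition network.

Two nested models are covered.

*Simple model* (agent A + inhibitor X only, cY = 0).  The equilibrium free
agent concentration x = eA solves the quadratic

    x**2 + (cX - cA + K) x - K cA = 0,

which has exactly one root in (0, cA).  The *system capacity*

    beta = 1 / (dx/dcA) = (x**2 + K cA) / (x**2 + K x)

measures how strongly the equilibrium is buffered against additions or
removals of total agent: after a perturbation d(cA) the equilibrium free
concentration shifts by only d(cA)/beta.  It satisfies 1 < beta < cA/x,
so pushing x far below cA (by adding inhibitor) buys arbitrarily large
capacity.

*Full model* (anti-inhibitor Y included).  The equilibrium x is the unique
root in (0, cA) of the cubic

    L(x) = a x**3 + b x**2 + c x + d,

    a = k - K
    b = (k - K)(cX + K - cA) + K (cA + cY)
    c = K cA (2K - k - cA + cX - cY)
    d = -K**2 cA**2,

with L(0) = -K^2 cA^2 < 0 and L(cA) = k cX cA^2 > 0 guaranteeing a
bracketed sign change.  Differentiating L(x(cA)) = 0 with respect to cA
gives the capacity in closed form,

    beta = (3a x**2 + 2b x + c) / (e x**2 + f x + g),

    e = k - 2K,  f = -K (2K - k - 2 cA + cX - cY),  g = 2 K**2 cA,

bounded by 0 < beta < cA/x.

*Inverse design*: for a desired equilibrium x, admissible totals lie on the
line S cX - T cY = U with S, T > 0, so fixing either total determines the
other.  This is how an experimenter (or evolution) would choose inhibitor
and anti-inhibitor amounts to pin the free agent level.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.optimize import brentq

from .errors import InfeasibleStateError, InvalidParameterError
from .kinetics import MixtureState, RateConstants, Totals

__all__ = [
    "SimpleEquilibrium",
    "CubicCoefficients",
    "FullEquilibrium",
    "DesignCoefficients",
    "simple_equilibrium",
    "simple_capacity",
    "simple_required_cX",
    "cubic_coefficients",
    "full_equilibrium",
    "full_capacity",
    "design_coefficients",
    "design_concentrations",
]

#: Absolute root tolerance, relative to cA (the bracket width).
ROOT_XTOL_FACTOR = 1e-12


@dataclass(frozen=True)
class SimpleEquilibrium:
    """Equilibrium of the model without anti-inhibitors (cY = 0)."""

    x: float          # equilibrium free agent concentration eA
    eX: float         # equilibrium free inhibitor
    eAX: float        # equilibrium complex
    beta: float       # system capacity
    discriminant: float


@dataclass(frozen=True)
class CubicCoefficients:
    """Coefficients of the full-model equilibrium cubic L and its cA-derivative.

    a..d define L(x); e, f, g arise from differentiating the equilibrium
    condition with respect to cA and enter the capacity formula.
    """

    a: float
    b: float
    c: float
    d: float
    e: float
    f: float
    g: float

    def L(self, x: float) -> float:
        """Evaluate the equilibrium cubic (Horner form)."""
        return ((self.a * x + self.b) * x + self.c) * x + self.d

    def dL(self, x: float) -> float:
        """Derivative of L with respect to x."""
        return (3.0 * self.a * x + 2.0 * self.b) * x + self.c


@dataclass(frozen=True)
class FullEquilibrium:
    """Equilibrium of the full model, with capacity."""

    x: float
    state: MixtureState
    beta: float
    totals: Totals
    rates: RateConstants


@dataclass(frozen=True)
class DesignCoefficients:
    """Coefficients of the linear design relation S*cX - T*cY = U."""

    S: float
    T: float
    U: float


def simple_equilibrium(cA: float, cX: float, K: float) -> SimpleEquilibrium:
    """Solve the simple-model equilibrium quadratic for the free agent level.

    Returns the larger quadratic root, which is the unique root in (0, cA)
    for cX > 0; for cX = 0 the quadratic factors as (x - cA)(x + K) and
    x = cA exactly (no inhibitor, nothing is complexed).
    """
    if not (cA > 0.0) or not (K > 0.0):
        raise InvalidParameterError(f"cA and K must be positive, got {cA!r}, {K!r}")
    if cX < 0.0:
        raise InvalidParameterError(f"cX must be nonnegative, got {cX!r}")
    p = cX - cA + K
    disc = p * p + 4.0 * K * cA
    if cX == 0.0:
        x = cA
    elif p > 0.0:
        # larger root via the product-of-roots form, avoiding cancellation
        x = 2.0 * K * cA / (p + math.sqrt(disc))
    else:
        x = 0.5 * (-p + math.sqrt(disc))
    eAX = cA - x
    eX = cX - eAX
    beta = (x * x + K * cA) / (x * x + K * x)
    return SimpleEquilibrium(x=x, eX=max(eX, 0.0), eAX=max(eAX, 0.0),
                             beta=beta, discriminant=disc)


def simple_capacity(x: float, cA: float, K: float) -> float:
    """Simple-model capacity beta = (x^2 + K cA)/(x^2 + K x) at equilibrium x.

    Valid for 0 < x < cA; the value lies strictly in (1, cA/x).
    """
    if not (K > 0.0) or not (cA > 0.0):
        raise InvalidParameterError(f"cA and K must be positive, got {cA!r}, {K!r}")
    if not (0.0 < x < cA):
        raise InvalidParameterError(f"x must lie in (0, cA)=(0, {cA!r}), got {x!r}")
    return (x * x + K * cA) / (x * x + K * x)


def simple_required_cX(target_x: float, cA: float, K: float) -> float:
    """Total inhibitor needed to hold the simple-model equilibrium at target_x.

    Closed form cX = (cA - x)(x + K)/x, the algebraic inverse of the
    equilibrium quadratic; always positive for 0 < x < cA.
    """
    if not (K > 0.0) or not (cA > 0.0):
        raise InvalidParameterError(f"cA and K must be positive, got {cA!r}, {K!r}")
    if not (0.0 < target_x < cA):
        raise InvalidParameterError(
            f"target_x must lie in (0, cA)=(0, {cA!r}), got {target_x!r}"
        )
    return (cA - target_x) * (target_x + K) / target_x


def cubic_coefficients(
    K: float, k: float, cA: float, cX: float, cY: float
) -> CubicCoefficients:
    """Coefficients of the equilibrium cubic and of the capacity denominator."""
    if not (K > 0.0) or not (k > 0.0):
        raise InvalidParameterError(f"K and k must be positive, got {K!r}, {k!r}")
    Totals(cA=cA, cX=cX, cY=cY)  # domain check
    a = k - K
    b = (k - K) * (cX + K - cA) + K * (cA + cY)
    c = K * cA * (2.0 * K - k - cA + cX - cY)
    d = -(K * K) * (cA * cA)
    e = k - 2.0 * K
    f = -K * (2.0 * K - k - 2.0 * cA + cX - cY)
    g = 2.0 * (K * K) * cA
    return CubicCoefficients(a=a, b=b, c=c, d=d, e=e, f=f, g=g)


def _solve_cubic_root(coef: CubicCoefficients, cA: float) -> float:
    """Unique root of L in (0, cA).

    L(0) < 0 and L(cA) > 0 guarantee a bracketed sign change, so bracketed
    iteration is robust; closed-form cubic formulas are avoided.  When
    a = 0 (equal dissociation constants, as in the worked scenarios) L is
    a quadratic and is solved by the numerically stable quadratic formula.
    """
    a, b, c, d = coef.a, coef.b, coef.c, coef.d
    if a == 0.0:
        # b = K (cA + cY) > 0, d < 0: one positive and one negative root.
        disc = c * c - 4.0 * b * d
        q = -0.5 * (c + math.copysign(math.sqrt(disc), c))
        for root in (q / b, d / q if q != 0.0 else math.nan):
            if 0.0 < root <= cA * (1.0 + 1e-12):
                return min(root, cA)
        raise InvalidParameterError("quadratic equilibrium has no root in (0, cA]")
    xtol = ROOT_XTOL_FACTOR * cA
    return brentq(coef.L, 0.0, cA, xtol=xtol, rtol=8.8817841970012523e-16)


def _state_at_root(x: float, rates: RateConstants, totals: Totals) -> MixtureState:
    """Reconstruct the equilibrium state from the root of the cubic."""
    K = rates.K
    cA, cX, cY = totals.cA, totals.cX, totals.cY
    X = K * (cA - x) / x
    AX = cA - x
    Y = X + cA - x - cX + cY
    XY = cY - Y
    # Rounding at the root tolerance can leave tiny negatives.
    vals = [x, X, Y, AX, XY]
    scale = max(1.0, cA, cX, cY)
    for i, v in enumerate(vals):
        if v < 0.0:
            if v > -1e-9 * scale:
                vals[i] = 0.0
            else:
                raise InfeasibleStateError(
                    f"equilibrium reconstruction produced negative concentration {v!r}"
                )
    return MixtureState(A=vals[0], X=vals[1], Y=vals[2], AX=vals[3], XY=vals[4])


def full_equilibrium(rates: RateConstants, totals: Totals) -> FullEquilibrium:
    """Equilibrium of the full model by bracketed root finding on (0, cA).

    Degenerate cases: with cX = 0 there is no inhibitor, so x = cA and all
    complexes vanish; with cY = 0 the root coincides with the simple model.
    """
    cA, cX, cY = totals.cA, totals.cX, totals.cY
    if cX == 0.0:
        state = MixtureState(A=cA, X=0.0, Y=cY, AX=0.0, XY=0.0)
        return FullEquilibrium(x=cA, state=state, beta=1.0, totals=totals, rates=rates)
    coef = cubic_coefficients(rates.K, rates.k, cA, cX, cY)
    x = _solve_cubic_root(coef, cA)
    state = _state_at_root(x, rates, totals)
    beta = coef.dL(x) / ((coef.e * x + coef.f) * x + coef.g)
    return FullEquilibrium(x=x, state=state, beta=beta, totals=totals, rates=rates)


def full_capacity(rates: RateConstants, totals: Totals) -> float:
    """Full-model system capacity beta = 1/(dx/dcA) at the equilibrium.

    Evaluated in closed form as (3a x^2 + 2b x + c)/(e x^2 + f x + g) at the
    cubic's root; the value lies in (0, cA/x).
    """
    return full_equilibrium(rates, totals).beta


def design_coefficients(
    rates: RateConstants, cA: float, target_x: float
) -> DesignCoefficients:
    """Coefficients of the design line S*cX - T*cY = U for a desired x.

    S = x [k x + K (cA - x)] and T = K x (cA - x) are both positive for
    0 < x < cA, so either total can be solved for in terms of the other.
    """
    if not (cA > 0.0):
        raise InvalidParameterError(f"cA must be positive, got {cA!r}")
    if not (0.0 < target_x < cA):
        raise InvalidParameterError(
            f"target_x must lie in (0, cA)=(0, {cA!r}), got {target_x!r}"
        )
    K, k = rates.K, rates.k
    x = target_x
    S = x * (k * x + K * (cA - x))
    T = K * x * (cA - x)
    U = (
        (K - k) * x ** 3
        + ((K - k) * (K - cA) - K * cA) * x ** 2
        - K * cA * (2.0 * K - k - cA) * x
        + (K * K) * (cA * cA)
    )
    return DesignCoefficients(S=S, T=T, U=U)


def design_concentrations(
    rates: RateConstants,
    cA: float,
    target_x: float,
    *,
    cX: float | None = None,
    cY: float | None = None,
) -> Totals:
    """Choose inhibitor/anti-inhibitor totals that pin the equilibrium at target_x.

    Exactly one of ``cX`` or ``cY`` must be given; the other is solved from
    the design line.  Raises :class:`InfeasibleStateError` when the fixed
    value forces the other total to be negative (the fixed value is too
    small or too large for the requested target).
    """
    if (cX is None) == (cY is None):
        raise InvalidParameterError("fix exactly one of cX or cY")
    coef = design_coefficients(rates, cA, target_x)
    if cY is None:
        if cX < 0.0:
            raise InvalidParameterError(f"cX must be nonnegative, got {cX!r}")
        other = (coef.S * cX - coef.U) / coef.T
        if other < -1e-12 * max(1.0, abs(cX)):
            raise InfeasibleStateError(
                f"cX={cX!r} is too small to reach target_x={target_x!r}: "
                f"required cY={other!r} is negative"
            )
        return Totals(cA=cA, cX=cX, cY=max(other, 0.0))
    if cY < 0.0:
        raise InvalidParameterError(f"cY must be nonnegative, got {cY!r}")
    other = (coef.U + coef.T * cY) / coef.S
    if other < -1e-12 * max(1.0, abs(cY)):
        raise InfeasibleStateError(
            f"cY={cY!r} is infeasible for target_x={target_x!r}: "
            f"required cX={other!r} is negative"
        )
    return Totals(cA=cA, cX=max(other, 0.0), cY=cY)
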