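"""Mass-action chemistry of the agent / inhibitor / anti-inhibitor mixture.

The model tracks three RNA species and their complexes in a well-mixed
solution.  The *agent* A is the active molecule (for instance a replicase
ribozyme) whose free concentration is being regulated.  The *inhibitor* X
binds A reversibly into an inactive duplex AX; the *anti-inhibitor* Y binds
X into the duplex XY, releasing A from control:

    A + X  <=>  AX        (rates k1 forward, k2 back)
    X + Y  <=>  XY        (rates k3 forward, k4 back)

All reactions follow the law of mass action.  Concentrations are treated as
dimensionless reals; no unit system is enforced.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

from .errors import InfeasibleStateError, InvalidParameterError

__all__ = [
    "RateConstants",
    "Totals",
    "MixtureState",
    "Derivatives",
    "mass_action_rhs",
    "totals_of",
    "state_from_free",
]

#: Magnitude below which a negative concentration is treated as rounding
#: noise and clipped to zero.  Anything more negative signals a real bug
#: (the continuous dynamics provably keep concentrations nonnegative).
NEGATIVE_TOL = 1e-12


@dataclass(frozen=True)
class RateConstants:
    """The four mass-action rate constants.

    k1/k2 govern agent-inhibitor binding, k3/k4 inhibitor-anti-inhibitor
    binding.  The dissociation constants ``K = k2/k1`` and ``k = k4/k3``
    are derived properties, never stored separately.
    """

    k1: float
    k2: float
    k3: float
    k4: float

    def __post_init__(self) -> None:
        for name in ("k1", "k2", "k3", "k4"):
            v = getattr(self, name)
            if not (v > 0.0) or not math.isfinite(v):
                raise InvalidParameterError(
                    f"rate constant {name} must be strictly positive, got {v!r}"
                )

    @property
    def K(self) -> float:
        """Dissociation constant of the AX duplex (k2/k1)."""
        return self.k2 / self.k1

    @property
    def k(self) -> float:
        """Dissociation constant of the XY duplex (k4/k3)."""
        return self.k4 / self.k3

    @classmethod
    def all_equal(cls, value: float = 1.0) -> "RateConstants":
        """Convenience constructor with every rate set to ``value``."""
        return cls(value, value, value, value)


@dataclass(frozen=True)
class Totals:
    """Conserved total concentrations (free plus complexed).

    cA = [A] + [AX];  cX = [X] + [AX] + [XY];  cY = [Y] + [XY].
    cX = 0 and/or cY = 0 select the reduced models without inhibitor or
    without anti-inhibitor.
    """

    cA: float
    cX: float
    cY: float = 0.0

    def __post_init__(self) -> None:
        if not (self.cA > 0.0):
            raise InvalidParameterError(f"cA must be positive, got {self.cA!r}")
        if self.cX < 0.0 or self.cY < 0.0:
            raise InvalidParameterError(
                f"cX and cY must be nonnegative, got cX={self.cX!r}, cY={self.cY!r}"
            )


@dataclass(frozen=True)
class MixtureState:
    """Concentrations of the five species at one instant.

    All fields must be nonnegative; the constructor clips values within
    ``NEGATIVE_TOL`` of zero and rejects anything more negative.
    """

    A: float
    X: float
    Y: float
    AX: float
    XY: float

    def __post_init__(self) -> None:
        for name in ("A", "X", "Y", "AX", "XY"):
            v = getattr(self, name)
            if v < 0.0:
                if v > -NEGATIVE_TOL:
                    object.__setattr__(self, name, 0.0)
                else:
                    raise InfeasibleStateError(
                        f"concentration {name} is negative: {v!r}"
                    )

    def as_tuple(self) -> tuple[float, float, float, float, float]:
        return (self.A, self.X, self.Y, self.AX, self.XY)


class Derivatives(NamedTuple):
    """Time derivatives of the five concentrations (conc/time)."""

    A: float
    X: float
    Y: float
    AX: float
    XY: float


def mass_action_rhs(state: MixtureState, rates: RateConstants) -> Derivatives:
    """Right-hand side of the kinetic ODE system.

    d[A]/dt  =  k2 [AX] - k1 [A][X]
    d[AX]/dt = -d[A]/dt
    d[Y]/dt  =  k4 [XY] - k3 [X][Y]
    d[XY]/dt = -d[Y]/dt
    d[X]/dt  =  d[A]/dt + d[Y]/dt

    The pairwise identities above hold exactly at the level of floating
    point (each flux is computed once and reused), so the conserved totals
    have exactly zero time derivative.
    """
    r1 = rates.k2 * state.AX - rates.k1 * state.A * state.X
    r2 = rates.k4 * state.XY - rates.k3 * state.X * state.Y
    return Derivatives(A=r1, X=r1 + r2, Y=r2, AX=-r1, XY=-r2)


def totals_of(state: MixtureState) -> Totals:
    """Conserved totals implied by a state.

    Raises :class:`InvalidParameterError` when the implied cA is not
    positive (e.g. the all-zero state), since such totals cannot describe
    a valid mixture.
    """
    return Totals(
        cA=state.A + state.AX,
        cX=state.X + state.AX + state.XY,
        cY=state.Y + state.XY,
    )


def state_from_free(
    A_free: float, Y_free: float, totals: Totals, *, tol: float = 1e-9
) -> MixtureState:
    """Reconstruct the full five-species state from the two free concentrations.

    The conservation relations leave only two degrees of freedom, so
    [A] and [Y] determine everything:

        [AX] = cA - [A];   [XY] = cY - [Y];
        [X]  = cX - cA + [A] - cY + [Y].

    Raises :class:`InfeasibleStateError` when any derived concentration
    would be negative by more than ``tol``.
    """
    AX = totals.cA - A_free
    XY = totals.cY - Y_free
    X = totals.cX - AX - XY
    values = {"A": A_free, "Y": Y_free, "AX": AX, "XY": XY, "X": X}
    for name, v in values.items():
        if v < -tol:
            raise InfeasibleStateError(
                f"free concentrations ({A_free!r}, {Y_free!r}) imply "
                f"negative {name} = {v!r} for totals {totals}"
            )
        values[name] = max(v, 0.0)
    return MixtureState(
        A=values["A"], X=values["X"], Y=values["Y"], AX=values["AX"], XY=values["XY"]
    )
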