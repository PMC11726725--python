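"""Deterministic time integration of the kinetic equations with scenario forcings.

The reference integrator is explicit forward Euler at a fixed step, which
mirrors how the original spreadsheet/C++ studies discretised the equations
(state += rhs * dt).  Three forcings perturb the agent balance:

* ``jump_noise`` — with a small per-step probability, a uniform random
  amount is added to the free agent concentration (sudden injection or
  removal of A; the total cA jumps by the same amount).
* ``ramp_noise`` — a constant signed rate s is added to d[A]/dt, a steady
  drift that the inhibition network has to fight continuously.
* ``replication`` — the agent self-replicates: d[A]/dt gains
  kRR [A]^2 - dR [A] (autocatalytic copying 2A -> 3A at rate kRR, decay at
  rate dR).  Without inhibitors this diverges in finite time; with them the
  blow-up is postponed but not prevented.

A Lyapunov function certifies global convergence of the unforced system:
with x = [A] - x0 and y = [Y] - y0 (deviations from equilibrium),

    V(x, y) = k3 y0 x^2 + k1 x0 y^2

is positive definite and strictly decreasing along trajectories, with

    dV/dt = -2 k2 k3 y0 x^2 - 2 k1 k4 x0 y^2
            - 2 k1 k3 x0 y0 (x + y)^2 - 2 k1 k3 (y0 x^2 + x0 y^2) [X]  <=  0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .equilibrium import FullEquilibrium
from .errors import DivergenceError, InvalidParameterError
from .kinetics import NEGATIVE_TOL, MixtureState, RateConstants

__all__ = [
    "Forcing",
    "Trajectory",
    "integrate",
    "jump_noise_step",
    "lyapunov_value",
    "lyapunov_derivative",
]

#: A run is declared exploded when [A] exceeds this multiple of the initial cA.
EXPLOSION_FACTOR = 1e3


@dataclass(frozen=True)
class Forcing:
    """Scenario-specific perturbation of the agent balance."""

    kind: str = "none"  # none | jump_noise | ramp_noise | replication
    p_event: float = 0.0      # jump_noise: per-step event probability
    lo: float = 0.0           # jump_noise: lower end of the jump interval
    hi: float = 0.0           # jump_noise: upper end of the jump interval
    s: float = 0.0            # ramp_noise: signed drift rate (conc/time)
    kRR: float = 0.0          # replication: autocatalytic rate constant
    dR: float = 0.0           # replication: first-order decay rate

    def __post_init__(self) -> None:
        if self.kind not in ("none", "jump_noise", "ramp_noise", "replication"):
            raise InvalidParameterError(f"unknown forcing kind {self.kind!r}")
        if not (0.0 <= self.p_event <= 1.0):
            raise InvalidParameterError(f"p_event must be in [0,1], got {self.p_event!r}")
        if self.lo > self.hi:
            raise InvalidParameterError(f"jump interval is empty: [{self.lo}, {self.hi}]")
        if self.kRR < 0.0 or self.dR < 0.0:
            raise InvalidParameterError("kRR and dR must be nonnegative")

    @classmethod
    def none(cls) -> "Forcing":
        return cls()

    @classmethod
    def jump_noise(cls, p_event: float, lo: float, hi: float) -> "Forcing":
        return cls(kind="jump_noise", p_event=p_event, lo=lo, hi=hi)

    @classmethod
    def ramp_noise(cls, s: float) -> "Forcing":
        return cls(kind="ramp_noise", s=s)

    @classmethod
    def replication(cls, kRR: float, dR: float) -> "Forcing":
        return cls(kind="replication", kRR=kRR, dR=dR)


@dataclass
class Trajectory:
    """Recorded Euler trajectory (possibly strided) plus run metadata.

    ``exploded`` marks replication runs whose [A] left the physical range
    (> EXPLOSION_FACTOR * initial cA) or became non-finite; the run stops
    cleanly at ``explosion_step`` rather than raising.
    """

    t: np.ndarray
    step: np.ndarray
    A: np.ndarray
    X: np.ndarray
    Y: np.ndarray
    AX: np.ndarray
    XY: np.ndarray
    cA: np.ndarray
    cX: np.ndarray
    cY: np.ndarray
    V: Optional[np.ndarray]
    dt: float
    seed: Optional[int]
    record_every: int = 1
    exploded: bool = False
    explosion_step: Optional[int] = None
    n_jumps: int = 0
    metadata: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.t)

    def final_state(self) -> MixtureState:
        return MixtureState(
            A=float(self.A[-1]), X=float(self.X[-1]), Y=float(self.Y[-1]),
            AX=float(self.AX[-1]), XY=float(self.XY[-1]),
        )

    def to_frame(self) -> pd.DataFrame:
        cols = {
            "step": self.step, "t": self.t, "A": self.A, "X": self.X,
            "Y": self.Y, "AX": self.AX, "XY": self.XY,
            "cA": self.cA, "cX": self.cX, "cY": self.cY,
        }
        if self.V is not None:
            cols["V"] = self.V
        return pd.DataFrame(cols)


def jump_noise_step(
    state: MixtureState,
    rng: np.random.Generator,
    p_event: float,
    lo: float,
    hi: float,
) -> MixtureState:
    """Apply one step of jump noise to the free agent concentration.

    With probability ``p_event`` a draw from U(lo, hi) is added to [A]
    (and therefore to the total cA).  A draw that would push [A] below
    zero is clipped at zero — concentrations cannot be negative and a
    removal can take away at most what is present.
    """
    if rng.random() < p_event:
        delta = rng.uniform(lo, hi) if lo < hi else lo
        return MixtureState(
            A=max(state.A + delta, 0.0), X=state.X, Y=state.Y,
            AX=state.AX, XY=state.XY,
        )
    return state


def _check_nonnegative(value: float, name: str, step: int) -> float:
    if value < 0.0:
        if value > -NEGATIVE_TOL:
            return 0.0
        raise DivergenceError(
            f"concentration {name} became negative ({value!r}) at step {step}; "
            "the continuous dynamics are provably nonnegative, so this "
            "indicates a step size too large for the rates involved"
        )
    return value


def integrate(
    initial: MixtureState,
    rates: RateConstants,
    forcing: Forcing = Forcing(),
    *,
    dt: float = 0.001,
    n_steps: int = 5000,
    seed: Optional[int] = None,
    equilibrium_ref: Optional[FullEquilibrium] = None,
    record_every: int = 1,
) -> Trajectory:
    """Forward-Euler integration of the five-species kinetics with forcing.

    Every ``record_every``-th state (plus the initial and final ones) is
    recorded.  When ``equilibrium_ref`` is supplied the Lyapunov value V is
    recorded alongside.  Runs are reproducible: the jump-noise RNG is
    seeded with ``seed`` and the seed is stored on the trajectory.

    Replication runs that blow up are reported via ``Trajectory.exploded``
    rather than raising; a concentration that turns negative beyond
    rounding tolerance raises :class:`DivergenceError`.
    """
    if dt <= 0.0:
        raise InvalidParameterError(f"dt must be positive, got {dt!r}")
    if n_steps < 0:
        raise InvalidParameterError(f"n_steps must be nonnegative, got {n_steps!r}")
    if record_every < 1:
        raise InvalidParameterError("record_every must be >= 1")

    k1, k2, k3, k4 = rates.k1, rates.k2, rates.k3, rates.k4
    A, X, Y, AX, XY = initial.as_tuple()
    cA0 = A + AX
    explosion_limit = EXPLOSION_FACTOR * max(cA0, 1e-300)

    jumping = forcing.kind == "jump_noise"
    ramping = forcing.kind == "ramp_noise"
    replicating = forcing.kind == "replication"
    rng = np.random.default_rng(seed) if jumping else None

    if equilibrium_ref is not None:
        x0 = equilibrium_ref.x
        y0 = equilibrium_ref.state.Y

    n_rec_max = n_steps // record_every + 3
    rec = np.empty((n_rec_max, 10), dtype=float)
    rec_V = np.empty(n_rec_max, dtype=float) if equilibrium_ref is not None else None

    n_rec = 0
    n_jumps = 0
    exploded = False
    explosion_step: Optional[int] = None

    def record(i: int) -> None:
        nonlocal n_rec
        rec[n_rec] = (i, i * dt, A, X, Y, AX, XY, A + AX, X + AX + XY, Y + XY)
        if rec_V is not None:
            dx = A - x0
            dy = Y - y0
            rec_V[n_rec] = k3 * y0 * dx * dx + k1 * x0 * dy * dy
        n_rec += 1

    record(0)
    for i in range(1, n_steps + 1):
        if jumping and rng.random() < forcing.p_event:
            delta = rng.uniform(forcing.lo, forcing.hi) if forcing.lo < forcing.hi else forcing.lo
            A = max(A + delta, 0.0)
            n_jumps += 1
        r1 = k2 * AX - k1 * A * X
        r2 = k4 * XY - k3 * X * Y
        dA = r1
        if replicating:
            dA += forcing.kRR * A * A - forcing.dR * A
        elif ramping:
            dA += forcing.s
        A += dA * dt
        X += (r1 + r2) * dt
        Y += r2 * dt
        AX += -r1 * dt
        XY += -r2 * dt
        if ramping and A < 0.0:
            A = 0.0  # drift removal exhausts the free agent; clip at empty
        A = _check_nonnegative(A, "A", i)
        X = _check_nonnegative(X, "X", i)
        Y = _check_nonnegative(Y, "Y", i)
        AX = _check_nonnegative(AX, "AX", i)
        XY = _check_nonnegative(XY, "XY", i)
        if not math.isfinite(A) or A > explosion_limit:
            exploded = True
            explosion_step = i
            record(i)
            break
        if i % record_every == 0 or i == n_steps:
            record(i)

    rec = rec[:n_rec]
    return Trajectory(
        step=rec[:, 0].astype(int), t=rec[:, 1],
        A=rec[:, 2], X=rec[:, 3], Y=rec[:, 4], AX=rec[:, 5], XY=rec[:, 6],
        cA=rec[:, 7], cX=rec[:, 8], cY=rec[:, 9],
        V=None if rec_V is None else rec_V[:n_rec],
        dt=dt, seed=seed, record_every=record_every,
        exploded=exploded, explosion_step=explosion_step, n_jumps=n_jumps,
    )


def _check_reference(state: MixtureState, equilibrium_ref: FullEquilibrium,
                     tol: float = 1e-6) -> None:
    """The Lyapunov argument only applies when state and reference share totals."""
    ref = equilibrium_ref.totals
    scale = max(1.0, ref.cA, ref.cX, ref.cY)
    if (
        abs(state.A + state.AX - ref.cA) > tol * scale
        or abs(state.X + state.AX + state.XY - ref.cX) > tol * scale
        or abs(state.Y + state.XY - ref.cY) > tol * scale
    ):
        raise InvalidParameterError(
            "state totals do not match the equilibrium reference; "
            "the Lyapunov function is defined per conservation class"
        )


def lyapunov_value(
    state: MixtureState, equilibrium_ref: FullEquilibrium, rates: RateConstants
) -> float:
    """V(x, y) = k3 y0 x^2 + k1 x0 y^2 with x, y the deviations of [A], [Y].

    Zero exactly at the equilibrium, positive elsewhere, and strictly
    decreasing along unforced trajectories.
    """
    _check_reference(state, equilibrium_ref)
    x = state.A - equilibrium_ref.x
    y = state.Y - equilibrium_ref.state.Y
    x0 = equilibrium_ref.x
    y0 = equilibrium_ref.state.Y
    return rates.k3 * y0 * x * x + rates.k1 * x0 * y * y


def lyapunov_derivative(
    state: MixtureState, equilibrium_ref: FullEquilibrium, rates: RateConstants
) -> float:
    """Total time derivative of V along the unforced dynamics; <= 0 everywhere.

    Vanishes only at the equilibrium.  Depends on the instantaneous free
    inhibitor concentration [X] of the state.
    """
    _check_reference(state, equilibrium_ref)
    k1, k2, k3, k4 = rates.k1, rates.k2, rates.k3, rates.k4
    x0 = equilibrium_ref.x
    y0 = equilibrium_ref.state.Y
    x = state.A - x0
    y = state.Y - y0
    return (
        -2.0 * k2 * k3 * y0 * x * x
        - 2.0 * k1 * k4 * x0 * y * y
        - 2.0 * k1 * k3 * x0 * y0 * (x + y) ** 2
        - 2.0 * k1 * k3 * (y0 * x * x + x0 * y * y) * state.X
    )
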