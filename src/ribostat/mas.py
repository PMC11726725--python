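"""Stochastic spatial multi-agent simulation of replicases, parasites and inhibitors.

A 2D arena (toroidal, so no edge artefacts) holds individual RNA molecules:

* **replicases** (R) — copy nearby templates, including each other;
* **parasites** (P) — are copied by replicases but copy nothing themselves;
  a parasite toggles reversibly between an unfolded shape (replicable,
  bindable, degradable) and a folded compact shape (protected from decay
  but neither copied nor bound) — the classic template-versus-stability
  trade-off, which makes parasites fitter than the replicases that must
  stay active;
* **inhibitors** (X) and **anti-inhibitors** (Y) — the concentration-control
  pair.  Depending on the scenario the inhibitors bind either parasites
  (``only_P``) or replicases (``only_R``); they also bind anti-inhibitors.
  Inhibitors and anti-inhibitors never decay, so their total counts
  (free + complexed) are exactly conserved.

Binding/unbinding events fire with the Poisson-process probability
``p_i = 1 - exp(-k_i * dt)`` per step.  Replication requires a free
replicase within the interaction radius of the template, succeeds with the
species' affinity (aR or aP, scaled by the global replication constant),
is suppressed when the template is crowded (>= Nmax RNA neighbours), and a
replicase offspring mutates into a parasite with probability delta.
Replicase extinction is irreversible (parasites cannot replicate anything),
so runs may stop at the extinction step.

Per step the event order is fixed for reproducibility: diffusion -> decay
-> replication -> folding -> inhibition (target binding, target-complex
dissociation, anti-inhibitor binding, XY dissociation).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .errors import InvalidParameterError

__all__ = [
    "MASParams",
    "World",
    "PopulationSeries",
    "reaction_probability",
    "initial_world",
    "step",
    "run",
]


def reaction_probability(k: float, dt: float) -> float:
    """Per-step event probability of a Poisson process with rate ``k``.

    p = 1 - exp(-k dt); in [0, 1), monotone increasing in both arguments.
    """
    if k < 0.0:
        raise InvalidParameterError(f"rate must be nonnegative, got {k!r}")
    if dt <= 0.0:
        raise InvalidParameterError(f"dt must be positive, got {dt!r}")
    return -math.expm1(-k * dt)


@dataclass(frozen=True)
class MASParams:
    """Parameters of the spatial simulation (defaults: the reference study set)."""

    sizeX: float = 1050.0       # arena width
    sizeY: float = 675.0        # arena height
    init_R: int = 2250          # initial replicases
    init_P: int = 112           # initial parasites
    agent_size: float = 3.0     # agent radius; interaction radius is 2x this
    Nmax: int = 4               # crowding cap: max RNA neighbours of a template
    d: float = 0.1              # per-step decay probability rate for R and P
    aR: float = 0.8             # replicase-template replication affinity
    aP: float = 0.8             # parasite-template replication affinity
    lP: float = 0.2             # per-step parasite folding probability rate
    D: float = 400.0            # diffusion constant, simple agents
    Dprime: float = 400.0       # diffusion constant, complexes
    delta: float = 0.1          # replicase offspring -> parasite mutation prob
    dt: float = 1.0             # time step
    K_repl: float = 1.0         # global replication probability multiplier
    k1: float = 10.0            # inhibitor-target association rate
    k2: float = 5.0             # inhibitor-target dissociation rate
    k3: float = 10.0            # inhibitor-anti-inhibitor association rate
    k4: float = 5.0             # XY dissociation rate
    n_inhibitors: int = 0
    n_anti_inhibitors: int = 0
    target_mode: str = "only_P"  # which species inhibitors bind

    def __post_init__(self) -> None:
        if self.sizeX <= 0 or self.sizeY <= 0:
            raise InvalidParameterError("arena dimensions must be positive")
        if self.agent_size <= 0:
            raise InvalidParameterError("agent_size must be positive")
        for name in ("aR", "aP", "lP", "d", "delta"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise InvalidParameterError(f"{name} must be in [0,1], got {v!r}")
        for name in ("init_R", "init_P", "n_inhibitors", "n_anti_inhibitors", "Nmax"):
            if getattr(self, name) < 0:
                raise InvalidParameterError(f"{name} must be nonnegative")
        for name in ("k1", "k2", "k3", "k4", "D", "Dprime", "K_repl"):
            if getattr(self, name) < 0:
                raise InvalidParameterError(f"{name} must be nonnegative")
        if self.dt <= 0:
            raise InvalidParameterError("dt must be positive")
        if self.target_mode not in ("only_P", "only_R"):
            raise InvalidParameterError(
                f"target_mode must be 'only_P' or 'only_R', got {self.target_mode!r}"
            )

    @property
    def interaction_radius(self) -> float:
        """Two agents can react when their centres are within two radii."""
        return 2.0 * self.agent_size

    def scaled(self, area_factor: float) -> "MASParams":
        """Shrink (or grow) the arena and all populations at fixed density.

        Linear dimensions scale with sqrt(area_factor), counts with
        area_factor; local densities, interaction ranges and per-step
        probabilities are untouched, so the local dynamics are unchanged
        and only demographic noise grows as the system shrinks.
        """
        if area_factor <= 0:
            raise InvalidParameterError("area_factor must be positive")
        lin = math.sqrt(area_factor)
        return replace(
            self,
            sizeX=self.sizeX * lin,
            sizeY=self.sizeY * lin,
            init_R=int(round(self.init_R * area_factor)),
            init_P=int(round(self.init_P * area_factor)),
            n_inhibitors=int(round(self.n_inhibitors * area_factor)),
            n_anti_inhibitors=int(round(self.n_anti_inhibitors * area_factor)),
        )


def _empty_pos() -> np.ndarray:
    return np.empty((0, 2), dtype=float)


@dataclass
class World:
    """Positions of every agent, one array per compartment.

    ``XT`` holds inhibitor-target complexes; the bound target species is
    fixed by ``params.target_mode`` (parasites in only_P, replicases in
    only_R).  Bound targets neither replicate nor copy, but they still
    decay (releasing their inhibitor); bound parasites are unfolded by
    construction.
    """

    R: np.ndarray = field(default_factory=_empty_pos)    # free replicases
    Pu: np.ndarray = field(default_factory=_empty_pos)   # free unfolded parasites
    Pf: np.ndarray = field(default_factory=_empty_pos)   # folded parasites
    X: np.ndarray = field(default_factory=_empty_pos)    # free inhibitors
    Y: np.ndarray = field(default_factory=_empty_pos)    # free anti-inhibitors
    XY: np.ndarray = field(default_factory=_empty_pos)   # inhibitor-anti-inhibitor
    XT: np.ndarray = field(default_factory=_empty_pos)   # inhibitor-target

    def n_replicases(self, params: MASParams) -> int:
        """Replicases alive, free or bound in a complex."""
        bound = len(self.XT) if params.target_mode == "only_R" else 0
        return len(self.R) + bound

    def n_parasites(self, params: MASParams) -> int:
        """Parasites alive (unfolded + folded + bound), for the census."""
        bound = len(self.XT) if params.target_mode == "only_P" else 0
        return len(self.Pu) + len(self.Pf) + bound

    def n_inhibitors_total(self) -> int:
        return len(self.X) + len(self.XY) + len(self.XT)

    def n_anti_inhibitors_total(self) -> int:
        return len(self.Y) + len(self.XY)


def initial_world(params: MASParams, rng: np.random.Generator) -> World:
    """All agents placed uniformly at random; inhibitor pairs start free."""

    def uniform(n: int) -> np.ndarray:
        pos = np.empty((n, 2), dtype=float)
        pos[:, 0] = rng.uniform(0.0, params.sizeX, n)
        pos[:, 1] = rng.uniform(0.0, params.sizeY, n)
        return pos

    return World(
        R=uniform(params.init_R),
        Pu=uniform(params.init_P),
        X=uniform(params.n_inhibitors),
        Y=uniform(params.n_anti_inhibitors),
    )


@dataclass
class PopulationSeries:
    """Per-step census of every compartment plus run metadata."""

    step: np.ndarray
    R: np.ndarray          # replicases alive (free + bound)
    P: np.ndarray          # unfolded parasites alive (free + bound)
    P_folded: np.ndarray
    X_free: np.ndarray
    Y_free: np.ndarray
    XY: np.ndarray
    XT: np.ndarray
    seed: Optional[int]
    extinction_step: Optional[int] = None
    metadata: dict = field(default_factory=dict)

    @property
    def survived(self) -> bool:
        """True when replicases were still alive at the end of the run."""
        return self.extinction_step is None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "step": self.step, "R": self.R, "P": self.P,
                "P_folded": self.P_folded, "X_free": self.X_free,
                "Y_free": self.Y_free, "XY": self.XY, "XT": self.XT,
            }
        )


def _wrap(pos: np.ndarray, params: MASParams) -> np.ndarray:
    """Toroidal wrap into [0, size); the modulo of a tiny negative can round
    up to exactly ``size``, which the periodic KD-tree rejects."""
    pos[:, 0] %= params.sizeX
    pos[:, 1] %= params.sizeY
    pos[:, 0][pos[:, 0] >= params.sizeX] = 0.0
    pos[:, 1][pos[:, 1] >= params.sizeY] = 0.0
    return pos


def _diffuse(pos: np.ndarray, D: float, params: MASParams,
             rng: np.random.Generator) -> np.ndarray:
    """Free Brownian displacement: per-axis Gaussian with variance 2 D dt."""
    if len(pos) == 0 or D == 0.0:
        return pos
    pos = pos + rng.normal(0.0, math.sqrt(2.0 * D * params.dt), size=pos.shape)
    return _wrap(pos, params)


def _survive(pos: np.ndarray, p_decay: float, rng: np.random.Generator) -> np.ndarray:
    if len(pos) == 0 or p_decay <= 0.0:
        return pos
    return pos[rng.random(len(pos)) >= p_decay]


def _greedy_bind(
    a_pos: np.ndarray,
    b_pos: np.ndarray,
    radius: float,
    p: float,
    rng: np.random.Generator,
    boxsize: tuple[float, float],
) -> tuple[np.ndarray, np.ndarray]:
    """One-to-one stochastic matching of ``a`` agents to ``b`` agents in range.

    Agents of ``a`` are visited in random order; each picks a uniformly
    random unbound partner from ``b`` within ``radius`` and binds with
    probability ``p``.  Returns index arrays (into a and b) of the pairs.
    """
    if len(a_pos) == 0 or len(b_pos) == 0 or p <= 0.0:
        return np.empty(0, dtype=int), np.empty(0, dtype=int)
    tree = cKDTree(b_pos, boxsize=boxsize)
    neigh = tree.query_ball_point(a_pos, radius)
    used_b = np.zeros(len(b_pos), dtype=bool)
    pairs_a: list[int] = []
    pairs_b: list[int] = []
    for i in rng.permutation(len(a_pos)):
        cand = [j for j in neigh[i] if not used_b[j]]
        if not cand:
            continue
        j = cand[rng.integers(len(cand))] if len(cand) > 1 else cand[0]
        if rng.random() < p:
            used_b[j] = True
            pairs_a.append(i)
            pairs_b.append(j)
    return np.asarray(pairs_a, dtype=int), np.asarray(pairs_b, dtype=int)


def _replicate(world: World, params: MASParams, rng: np.random.Generator) -> None:
    """Replication with crowding cap, copier matching and mutation.

    Templates are all free replicases and unfolded free parasites; copiers
    are free replicases.  Per step each template is copied at most once and
    each copier copies at most once, but a replicase may serve as template
    and copier simultaneously (copying proceeds in parallel).  Offspring
    appear uniformly within the interaction radius of the template.
    """
    nR = len(world.R)
    if nR == 0:
        return
    radius = params.interaction_radius
    boxsize = (params.sizeX, params.sizeY)
    tmpl_pos = np.vstack([world.R, world.Pu]) if len(world.Pu) else world.R
    rna_pos = np.vstack([p for p in (world.R, world.Pu, world.Pf) if len(p)])
    crowd_tree = cKDTree(rna_pos, boxsize=boxsize)
    # counts include the template itself; the cap applies to its neighbours
    ncrowd = crowd_tree.query_ball_point(tmpl_pos, radius, return_length=True)
    cop_tree = cKDTree(world.R, boxsize=boxsize)
    neigh = cop_tree.query_ball_point(tmpl_pos, radius)
    used = np.zeros(nR, dtype=bool)
    pR = min(params.aR * params.K_repl, 1.0)
    pP = min(params.aP * params.K_repl, 1.0)
    new_R: list[np.ndarray] = []
    new_P: list[np.ndarray] = []
    for t in rng.permutation(len(tmpl_pos)):
        is_repl = t < nR
        if ncrowd[t] - 1 >= params.Nmax:
            continue
        if is_repl:
            cand = [j for j in neigh[t] if not used[j] and j != t]
        else:
            cand = [j for j in neigh[t] if not used[j]]
        if not cand:
            continue
        j = cand[rng.integers(len(cand))] if len(cand) > 1 else cand[0]
        if rng.random() >= (pR if is_repl else pP):
            continue
        used[j] = True
        rr = radius * math.sqrt(rng.random())
        th = rng.uniform(0.0, 2.0 * math.pi)
        px = (tmpl_pos[t, 0] + rr * math.cos(th)) % params.sizeX
        py = (tmpl_pos[t, 1] + rr * math.sin(th)) % params.sizeY
        pos = np.array(
            [px if px < params.sizeX else 0.0, py if py < params.sizeY else 0.0]
        )
        if is_repl and rng.random() >= params.delta:
            new_R.append(pos)
        else:
            new_P.append(pos)
    if new_R:
        world.R = np.vstack([world.R, new_R])
    if new_P:
        world.Pu = np.vstack([world.Pu, new_P]) if len(world.Pu) else np.array(new_P)


def step(world: World, params: MASParams, rng: np.random.Generator) -> World:
    """Advance the world by one time step (in place; also returned)."""
    boxsize = (params.sizeX, params.sizeY)
    radius = params.interaction_radius

    # 1. diffusion
    world.R = _diffuse(world.R, params.D, params, rng)
    world.Pu = _diffuse(world.Pu, params.D, params, rng)
    world.Pf = _diffuse(world.Pf, params.D, params, rng)
    world.X = _diffuse(world.X, params.D, params, rng)
    world.Y = _diffuse(world.Y, params.D, params, rng)
    world.XY = _diffuse(world.XY, params.Dprime, params, rng)
    world.XT = _diffuse(world.XT, params.Dprime, params, rng)

    # 2. decay of replicases and unfolded parasites; folded parasites are
    # protected (compact shape), bound targets keep decaying and free
    # their inhibitor when they go
    p_decay = min(params.d * params.dt, 1.0)
    world.R = _survive(world.R, p_decay, rng)
    world.Pu = _survive(world.Pu, p_decay, rng)
    if len(world.XT) and p_decay > 0.0:
        died = rng.random(len(world.XT)) < p_decay
        if died.any():
            freed = world.XT[died]
            world.XT = world.XT[~died]
            world.X = np.vstack([world.X, freed]) if len(world.X) else freed.copy()

    # 3. replication
    _replicate(world, params, rng)

    # 4. parasite folding: a reversible conformational toggle
    p_fold = min(params.lP * params.dt, 1.0)
    if len(world.Pu) or len(world.Pf):
        fold = rng.random(len(world.Pu)) < p_fold if len(world.Pu) else np.zeros(0, bool)
        unfold = rng.random(len(world.Pf)) < p_fold if len(world.Pf) else np.zeros(0, bool)
        folding = world.Pu[fold] if fold.any() else _empty_pos()
        unfolding = world.Pf[unfold] if unfold.any() else _empty_pos()
        if len(folding) or len(unfolding):
            world.Pu = np.vstack([world.Pu[~fold], unfolding])
            world.Pf = np.vstack([world.Pf[~unfold], folding])

    # 5. inhibition chemistry.  Dissociations run before associations so a
    # complex formed in one step exists for at least one full step (and its
    # bound target spends a whole replication/decay phase sequestered);
    # freed inhibitors may rebind within the same step.
    p1 = reaction_probability(params.k1, params.dt)
    p2 = reaction_probability(params.k2, params.dt)
    p3 = reaction_probability(params.k3, params.dt)
    p4 = reaction_probability(params.k4, params.dt)

    # 5a. inhibitor-target complexes dissociate
    if len(world.XT) and p2 > 0.0:
        diss = rng.random(len(world.XT)) < p2
        if diss.any():
            released = world.XT[diss]
            world.XT = world.XT[~diss]
            world.X = np.vstack([world.X, released]) if len(world.X) else released.copy()
            if params.target_mode == "only_P":
                world.Pu = (
                    np.vstack([world.Pu, released]) if len(world.Pu) else released.copy()
                )
            else:
                world.R = (
                    np.vstack([world.R, released]) if len(world.R) else released.copy()
                )

    # 5b. inhibitor-anti-inhibitor complexes dissociate
    if len(world.XY) and p4 > 0.0:
        diss = rng.random(len(world.XY)) < p4
        if diss.any():
            released = world.XY[diss]
            world.XY = world.XY[~diss]
            world.X = np.vstack([world.X, released]) if len(world.X) else released.copy()
            world.Y = np.vstack([world.Y, released]) if len(world.Y) else released.copy()

    # 5c. inhibitor binds its target (parasite or replicase, by scenario)
    targets = world.Pu if params.target_mode == "only_P" else world.R
    ti, xi = _greedy_bind(targets, world.X, radius, p1, rng, boxsize)
    if len(ti):
        new_XT = targets[ti]
        keep_t = np.ones(len(targets), dtype=bool)
        keep_t[ti] = False
        keep_x = np.ones(len(world.X), dtype=bool)
        keep_x[xi] = False
        if params.target_mode == "only_P":
            world.Pu = world.Pu[keep_t]
        else:
            world.R = world.R[keep_t]
        world.X = world.X[keep_x]
        world.XT = np.vstack([world.XT, new_XT]) if len(world.XT) else new_XT

    # 5d. inhibitor binds anti-inhibitor
    xi, yi = _greedy_bind(world.X, world.Y, radius, p3, rng, boxsize)
    if len(xi):
        new_XY = world.X[xi]
        keep_x = np.ones(len(world.X), dtype=bool)
        keep_x[xi] = False
        keep_y = np.ones(len(world.Y), dtype=bool)
        keep_y[yi] = False
        world.X = world.X[keep_x]
        world.Y = world.Y[keep_y]
        world.XY = np.vstack([world.XY, new_XY]) if len(world.XY) else new_XY

    return world


def run(
    params: MASParams,
    n_steps: int,
    seed: Optional[int] = None,
    *,
    stop_at_extinction: bool = True,
) -> PopulationSeries:
    """Simulate ``n_steps`` steps from a fresh random world; full census per step.

    Extinction (no replicase alive, free or bound) is terminal: parasites
    have no replication source left, so by default the run stops there and
    the series ends at the extinction step.
    """
    rng = np.random.default_rng(seed)
    world = initial_world(params, rng)
    cols = {name: [] for name in
            ("step", "R", "P", "P_folded", "X_free", "Y_free", "XY", "XT")}
    extinction_step: Optional[int] = None

    def census(i: int) -> int:
        nR = world.n_replicases(params)
        bound_P = len(world.XT) if params.target_mode == "only_P" else 0
        cols["step"].append(i)
        cols["R"].append(nR)
        cols["P"].append(len(world.Pu) + bound_P)
        cols["P_folded"].append(len(world.Pf))
        cols["X_free"].append(len(world.X))
        cols["Y_free"].append(len(world.Y))
        cols["XY"].append(len(world.XY))
        cols["XT"].append(len(world.XT))
        return nR

    census(0)
    for i in range(1, n_steps + 1):
        step(world, params, rng)
        nR = census(i)
        if nR == 0 and extinction_step is None:
            extinction_step = i
            if stop_at_extinction:
                break
    return PopulationSeries(
        **{k: np.asarray(v) for k, v in cols.items()},
        seed=seed,
        extinction_step=extinction_step,
        metadata={"params": params, "n_steps": n_steps},
    )
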