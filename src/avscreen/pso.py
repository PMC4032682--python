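"""Particle swarm optimization with time-varying acceleration coefficients.

A scalar swarm tunes the recognition coefficient xi of the CRA classifier by
minimising the leave-one-out mean squared error function (MSEF).  The update
rules are the classic inertial PSO,

    dxi[g] <- w * dxi[g] + c1 * rand1 * (pbest[g] - xi[g])
                          + c2 * rand2 * (gbest   - xi[g])
    xi[g]  <- xi[g] + dxi[g]

with time-varying acceleration coefficients (TVAC): the cognitive weight c1
decays linearly from a1 to b1 (default 2.5 -> 0.5) while the social weight c2
grows from a2 to b2 (default 0.5 -> 2.5) over the allowed iterations, shifting
the swarm from exploration to consensus.  The inertia weight w is not pinned
down by the TVAC scheme; the default is the standard linear decay 0.9 -> 0.4.

Iteration stops at the first of: global best fitness <= epsilon (default
0.05, the training convergence condition) or p == p_max (default 100).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Union

import numpy as np
import pandas as pd

from .exceptions import ConfigError, DomainError, OptimizerError
from .cra import CRAModel, TrainingSet, loo_msef_function

__all__ = [
    "SwarmConfig",
    "SwarmState",
    "OptimizeResult",
    "tvac_coefficients",
    "inertia_weight",
    "init_swarm",
    "swarm_step",
    "optimize",
    "optimize_recognition_coefficient",
    "fit_cra",
]


@dataclass(frozen=True)
class SwarmConfig:
    """Swarm hyperparameters.

    population_g : particles in the swarm (>= 2).
    p_max : maximum iterations.
    a1, b1 / a2, b2 : TVAC endpoints of the cognitive / social coefficients.
    inertia : either a constant float or a (start, end) pair decayed linearly.
    xi_bounds : closed search interval for xi; grades underflow for large xi,
        flattening the fitness, so the default upper bound is 50.
    epsilon : convergence threshold on the best MSEF.
    velocity_clamp_frac : velocity magnitude cap as a fraction of the bound
        range.
    seed : RNG seed for reproducible runs.
    """

    population_g: int = 20
    p_max: int = 100
    a1: float = 2.5
    b1: float = 0.5
    a2: float = 0.5
    b2: float = 2.5
    inertia: Union[float, tuple] = (0.9, 0.4)
    xi_bounds: tuple = (1e-3, 50.0)
    epsilon: float = 0.05
    velocity_clamp_frac: float = 0.2
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.population_g < 2:
            raise ConfigError("population_g must be >= 2")
        if self.p_max < 1:
            raise ConfigError("p_max must be >= 1")
        lo, hi = self.xi_bounds
        if not 0 < lo < hi:
            raise ConfigError(f"xi_bounds must satisfy 0 < lower < upper, got {self.xi_bounds}")
        if self.epsilon <= 0:
            raise ConfigError("epsilon must be positive")
        if self.velocity_clamp_frac <= 0:
            raise ConfigError("velocity_clamp_frac must be positive")


@dataclass
class SwarmState:
    """Positions, velocities and bests of the swarm at one iteration."""

    positions: np.ndarray
    velocities: np.ndarray
    personal_best_pos: np.ndarray
    personal_best_fit: np.ndarray
    global_best_pos: float
    global_best_fit: float
    iteration: int
    c1: float
    c2: float


@dataclass(frozen=True)
class OptimizeResult:
    xi_best: float
    msef_best: float
    converged: bool
    n_iterations: int
    trace: pd.DataFrame  # columns: iteration, c1, c2, best_xi, best_msef


def tvac_coefficients(p: int, cfg: SwarmConfig) -> tuple[float, float]:
    """Linear TVAC schedules c1: a1 -> b1 and c2: a2 -> b2 over p in [0, p_max]."""
    if not 0 <= p <= cfg.p_max:
        raise DomainError(f"iteration p must lie in [0, {cfg.p_max}], got {p}")
    frac = p / cfg.p_max
    c1 = (cfg.b1 - cfg.a1) * frac + cfg.a1
    c2 = (cfg.b2 - cfg.a2) * frac + cfg.a2
    return c1, c2


def inertia_weight(p: int, cfg: SwarmConfig) -> float:
    """Inertia weight at iteration p: constant, or linear decay for a pair."""
    if isinstance(cfg.inertia, (int, float)):
        return float(cfg.inertia)
    w0, w1 = cfg.inertia
    return w0 + (w1 - w0) * p / cfg.p_max


def _evaluate(fitness: Callable[[float], float], positions: np.ndarray) -> np.ndarray:
    vals = np.array([float(fitness(float(x))) for x in positions])
    if not np.all(np.isfinite(vals)):
        bad = positions[~np.isfinite(vals)]
        raise OptimizerError(f"fitness returned non-finite value(s) at xi={bad}")
    return vals


def init_swarm(
    fitness: Callable[[float], float], cfg: SwarmConfig, rng: np.random.Generator
) -> SwarmState:
    """Uniform positions in the bounds, zero velocities, bests from evaluation."""
    lo, hi = cfg.xi_bounds
    pos = rng.uniform(lo, hi, cfg.population_g)
    fit = _evaluate(fitness, pos)
    best = int(np.argmin(fit))
    c1, c2 = tvac_coefficients(0, cfg)
    return SwarmState(
        positions=pos,
        velocities=np.zeros_like(pos),
        personal_best_pos=pos.copy(),
        personal_best_fit=fit.copy(),
        global_best_pos=float(pos[best]),
        global_best_fit=float(fit[best]),
        iteration=0,
        c1=c1,
        c2=c2,
    )


def swarm_step(
    state: SwarmState,
    fitness: Callable[[float], float],
    cfg: SwarmConfig,
    rng: np.random.Generator,
) -> SwarmState:
    """One velocity/position update with fresh uniform rand1, rand2 per particle.

    Positions are clipped to the bounds; personal and global bests update only
    on strict improvement, so the best-fitness sequence is non-increasing.
    """
    lo, hi = cfg.xi_bounds
    c1, c2 = tvac_coefficients(state.iteration, cfg)
    w = inertia_weight(state.iteration, cfg)
    r1 = rng.random(cfg.population_g)
    r2 = rng.random(cfg.population_g)
    vel = (
        w * state.velocities
        + c1 * r1 * (state.personal_best_pos - state.positions)
        + c2 * r2 * (state.global_best_pos - state.positions)
    )
    vmax = cfg.velocity_clamp_frac * (hi - lo)
    vel = np.clip(vel, -vmax, vmax)
    pos = np.clip(state.positions + vel, lo, hi)
    fit = _evaluate(fitness, pos)

    improved = fit < state.personal_best_fit
    pbest_pos = np.where(improved, pos, state.personal_best_pos)
    pbest_fit = np.where(improved, fit, state.personal_best_fit)
    gbest_pos, gbest_fit = state.global_best_pos, state.global_best_fit
    best = int(np.argmin(pbest_fit))
    if pbest_fit[best] < gbest_fit:
        gbest_fit = float(pbest_fit[best])
        gbest_pos = float(pbest_pos[best])
    return SwarmState(
        positions=pos,
        velocities=vel,
        personal_best_pos=pbest_pos,
        personal_best_fit=pbest_fit,
        global_best_pos=gbest_pos,
        global_best_fit=gbest_fit,
        iteration=state.iteration + 1,
        c1=c1,
        c2=c2,
    )


def optimize(fitness: Callable[[float], float], cfg: SwarmConfig) -> OptimizeResult:
    """Run the swarm on an arbitrary scalar fitness over cfg.xi_bounds."""
    rng = np.random.default_rng(cfg.seed)
    state = init_swarm(fitness, cfg, rng)
    rows = [
        dict(
            iteration=0,
            c1=state.c1,
            c2=state.c2,
            best_xi=state.global_best_pos,
            best_msef=state.global_best_fit,
        )
    ]
    converged = state.global_best_fit <= cfg.epsilon
    while not converged and state.iteration < cfg.p_max:
        state = swarm_step(state, fitness, cfg, rng)
        rows.append(
            dict(
                iteration=state.iteration,
                c1=state.c1,
                c2=state.c2,
                best_xi=state.global_best_pos,
                best_msef=state.global_best_fit,
            )
        )
        converged = state.global_best_fit <= cfg.epsilon
    return OptimizeResult(
        xi_best=state.global_best_pos,
        msef_best=state.global_best_fit,
        converged=converged,
        n_iterations=state.iteration,
        trace=pd.DataFrame(rows),
    )


def optimize_recognition_coefficient(
    training: TrainingSet,
    cfg: SwarmConfig = SwarmConfig(),
    convention: str = "class_centered",
    error_mode: str = "wrapped",
    intensity_rescale: bool = False,
) -> OptimizeResult:
    """Tune xi by minimising the leave-one-out MSEF of the CRA classifier."""
    fitness = loo_msef_function(training, convention, error_mode, intensity_rescale)
    return optimize(fitness, cfg)


def fit_cra(
    training: TrainingSet,
    cfg: SwarmConfig = SwarmConfig(),
    convention: str = "class_centered",
    error_mode: str = "wrapped",
    intensity_rescale: bool = False,
) -> tuple[CRAModel, OptimizeResult]:
    """Convenience: optimize xi and return the trained model with the trace."""
    result = optimize_recognition_coefficient(
        training, cfg, convention, error_mode, intensity_rescale
    )
    model = CRAModel(
        training=training,
        xi=result.xi_best,
        hue_branch_convention=convention,
        error_mode=error_mode,
        intensity_rescale=intensity_rescale,
    )
    return model, result
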