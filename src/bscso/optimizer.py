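"""Binary sand cat swarm optimizer (bSCSO).

Agents carry bit vectors (1 = feature selected) and no continuous state.
Each iteration, every agent computes a continuous candidate position from
the SCSO mechanics applied to the binary positions (exploration or
exploitation, chosen per agent by the phase-control value ``R``), and that
candidate is passed directly through a V-shaped transfer function to obtain
a per-dimension flip probability: the bit is complemented when a uniform
draw falls below it, and kept otherwise.  A zero candidate never flips a
bit; because every update term is a product of position values, a dimension
that is 0 in both the global best and an agent yields a zero candidate, so
the search concentrates on (and gradually shrinks within) the support of
the incumbent best — a strong bias toward small subsets that suits feature
selection; see the methods note for the resulting limitations.

The swarm minimizes an arbitrary fitness over {0,1}^d.  The global best is
elitist: it is replaced only on strict improvement and never lost, which
makes the best-fitness convergence history non-increasing by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

from .mechanics import (
    Phase,
    ScheduleState,
    agent_sensitivity,
    exploitation_candidate,
    exploration_candidate,
    phase_control,
    sample_angle,
    select_phase,
)
from .transfer import TransferFunction

__all__ = [
    "EvaluationError",
    "BinaryAgent",
    "OptimizerConfig",
    "OptimizationResult",
    "initialize_population",
    "repair_empty",
    "flip_update",
    "step",
    "optimize",
]

FitnessFn = Callable[[np.ndarray], float]


class EvaluationError(RuntimeError):
    """Raised when a fitness function returns a non-finite value."""


@dataclass
class BinaryAgent:
    """One search agent: a bit vector and its current fitness."""

    bits: np.ndarray
    fitness: float = np.nan

    def copy(self) -> "BinaryAgent":
        return BinaryAgent(self.bits.copy(), self.fitness)


@dataclass(frozen=True)
class OptimizerConfig:
    """Swarm-level settings with the standard experimental defaults."""

    n_agents: int = 30
    max_iter: int = 100
    transfer: TransferFunction = TransferFunction.V4
    s_M: float = 2.0
    seed: Optional[int] = None
    repair_empty: bool = True

    def __post_init__(self) -> None:
        if self.n_agents < 2:
            raise ValueError("n_agents must be >= 2")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        object.__setattr__(
            self, "transfer", TransferFunction.from_name(self.transfer)
        )


@dataclass
class OptimizationResult:
    """Best bit vector found, its fitness, and the convergence history."""

    best_bits: np.ndarray
    best_fitness: float
    history: np.ndarray
    evaluations: int

    @property
    def n_selected(self) -> int:
        return int(self.best_bits.sum())


def initialize_population(
    n_agents: int,
    d: int,
    rng: np.random.Generator,
    repair: bool = True,
) -> list[BinaryAgent]:
    """Draw ``n_agents`` agents of ``d`` independent equiprobable bits."""
    if d < 1:
        raise ValueError("dimension d must be >= 1")
    if n_agents < 2:
        raise ValueError("n_agents must be >= 2")
    agents = []
    for _ in range(n_agents):
        bits = rng.integers(0, 2, size=d).astype(np.int8)
        if repair:
            bits = repair_empty(bits, rng)
        agents.append(BinaryAgent(bits=bits))
    return agents


def repair_empty(bits: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Set one uniformly chosen bit of an all-zero vector; otherwise no-op."""
    if bits.any():
        return bits
    out = bits.copy()
    out[int(rng.integers(0, out.size))] = 1
    return out


def flip_update(
    bit: int,
    candidate: float,
    u: float,
    kind: TransferFunction = TransferFunction.V4,
) -> int:
    """Flip rule: complement the bit when ``u < V(candidate)``, else keep it."""
    if not np.isfinite(candidate):
        raise ValueError("candidate must be finite")
    if u < kind(candidate):
        return 1 - bit
    return bit


def step(
    swarm: Sequence[BinaryAgent],
    best: BinaryAgent,
    schedule: ScheduleState,
    fitness_fn: FitnessFn,
    rng: np.random.Generator,
    transfer: Callable = TransferFunction.V4,
    repair: bool = True,
) -> tuple[list[BinaryAgent], BinaryAgent]:
    """One swarm iteration: update, re-evaluate, and advance the global best.

    Per agent the phase-control value ``R`` and sensitivity ``r`` are drawn
    once; the continuous candidate uses the global best as attractor (with a
    fresh roulette-wheel angle per agent in exploitation) and is binarized
    through ``transfer``.  The best is updated only on strict fitness
    improvement.
    """
    r_G = schedule.r_G
    d = best.bits.size
    swarm = list(swarm)
    for i, agent in enumerate(swarm):
        R = phase_control(r_G, rng.uniform())
        r = agent_sensitivity(r_G, rng.uniform())
        u = rng.uniform(size=d)
        cur = agent.bits.astype(float)
        if select_phase(R) is Phase.EXPLOITATION:
            angle = sample_angle(rng)
            cand = exploitation_candidate(best.bits, cur, r, u, angle)
        else:
            cand = exploration_candidate(best.bits, cur, r, u)
        prob = transfer(cand)
        flips = rng.uniform(size=d) < prob
        bits = np.where(flips, 1 - agent.bits, agent.bits).astype(np.int8)
        if repair:
            bits = repair_empty(bits, rng)
        value = float(fitness_fn(bits))
        if not np.isfinite(value):
            raise EvaluationError(f"non-finite fitness for agent {i}")
        agent.bits = bits
        agent.fitness = value
        if value < best.fitness:
            best = BinaryAgent(bits.copy(), value)
    return swarm, best


def optimize(
    fitness_fn: FitnessFn,
    d: int,
    config: OptimizerConfig = OptimizerConfig(),
) -> OptimizationResult:
    """Run the full binary optimization loop.

    Returns the minimizing bit vector observed, its fitness, the
    per-iteration best-fitness history (length ``max_iter``) and the number
    of fitness evaluations (``n_agents * (max_iter + 1)``: every agent is
    evaluated at initialization and re-evaluated each iteration).
    """
    if d < 1:
        raise ValueError("dimension d must be >= 1")
    rng = np.random.default_rng(config.seed)
    swarm = initialize_population(config.n_agents, d, rng, repair=config.repair_empty)
    evaluations = 0
    for i, agent in enumerate(swarm):
        value = float(fitness_fn(agent.bits))
        if not np.isfinite(value):
            raise EvaluationError(f"non-finite fitness for agent {i}")
        agent.fitness = value
        evaluations += 1
    best = min(swarm, key=lambda a: a.fitness).copy()
    history = np.empty(config.max_iter, dtype=float)
    for it in range(config.max_iter):
        schedule = ScheduleState(iter_c=it, iter_max=config.max_iter, s_M=config.s_M)
        swarm, best = step(
            swarm,
            best,
            schedule,
            fitness_fn,
            rng,
            transfer=config.transfer,
            repair=config.repair_empty,
        )
        evaluations += len(swarm)
        history[it] = best.fitness
    return OptimizationResult(
        best_bits=best.bits.copy(),
        best_fitness=best.fitness,
        history=history,
        evaluations=evaluations,
    )
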