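"""Continuous sand cat swarm mechanics.

Sand cat swarm optimization (SCSO) steers a population of agents with three
per-iteration scalars: the general sensitivity range ``r_G`` (modelling the
cat's low-frequency hearing limit) decays linearly from ``s_M`` (default 2)
to 0 over the run; the phase-control value ``R`` is drawn uniformly from
``[-r_G, r_G]`` and switches each agent between exploration (search for
prey) and exploitation (attack); and the per-agent sensitivity ``r`` is a
uniform fraction of ``r_G`` scaling the step.  Exploitation moves around the
best position along a direction set by a random angle drawn by roulette
wheel over the full circle, so the cosine factor spans [-1, 1].

All functions here are pure given explicit random draws; the binary
optimizer owns the random stream.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

__all__ = [
    "Phase",
    "AngleSample",
    "ScheduleState",
    "general_sensitivity",
    "phase_control",
    "agent_sensitivity",
    "exploration_candidate",
    "exploitation_candidate",
    "select_phase",
    "sample_angle",
]


class Phase(enum.Enum):
    EXPLORATION = "exploration"
    EXPLOITATION = "exploitation"


@dataclass(frozen=True)
class AngleSample:
    """A random direction angle in degrees and its cosine."""

    theta: float
    cos_theta: float


@dataclass(frozen=True)
class ScheduleState:
    """Per-iteration schedule: current/total iteration and hearing constant."""

    iter_c: int
    iter_max: int
    s_M: float = 2.0

    def __post_init__(self) -> None:
        if self.iter_max < 1:
            raise ValueError("iter_max must be >= 1")
        if not 0 <= self.iter_c <= self.iter_max:
            raise ValueError("iter_c must satisfy 0 <= iter_c <= iter_max")
        if self.s_M <= 0:
            raise ValueError("s_M must be positive")

    @property
    def r_G(self) -> float:
        return general_sensitivity(self.iter_c, self.iter_max, self.s_M)


def general_sensitivity(iter_c: int, iter_max: int, s_M: float = 2.0) -> float:
    """General sensitivity range: linear decay from ``s_M`` to 0.

    ``r_G = s_M - s_M * iter_c / iter_max``.
    """
    if iter_max < 1:
        raise ValueError("iter_max must be >= 1")
    if not 0 <= iter_c <= iter_max:
        raise ValueError("iter_c must satisfy 0 <= iter_c <= iter_max")
    if s_M <= 0:
        raise ValueError("s_M must be positive")
    return s_M - s_M * iter_c / iter_max


def phase_control(r_G: float, u: float) -> float:
    """Phase-control value ``R = 2 * r_G * u - r_G``, uniform on [-r_G, r_G]."""
    if r_G < 0:
        raise ValueError("r_G must be non-negative")
    return 2.0 * r_G * u - r_G


def agent_sensitivity(r_G: float, u: float) -> float:
    """Per-agent sensitivity ``r = r_G * u`` in [0, r_G]."""
    if r_G < 0:
        raise ValueError("r_G must be non-negative")
    return r_G * u


def exploration_candidate(pos_bc, pos_c, r: float, u):
    """Search-for-prey update: ``r * (pos_bc - u * pos_c)`` per dimension.

    ``pos_bc`` is the best-candidate position, ``pos_c`` the agent's current
    position, ``u`` a uniform draw per dimension.
    """
    if r < 0:
        raise ValueError("r must be non-negative")
    pos_bc = np.asarray(pos_bc, dtype=float)
    pos_c = np.asarray(pos_c, dtype=float)
    return r * (pos_bc - np.asarray(u, dtype=float) * pos_c)


def exploitation_candidate(pos_b, pos_c, r: float, u, angle: AngleSample):
    """Attack-prey update around the best position.

    The random distance ``pos_rnd = |u * pos_b - pos_c|`` is taken with the
    absolute value (a distance cannot be negative); the candidate is
    ``pos_b - r * pos_rnd * cos(theta)``.
    """
    if r < 0:
        raise ValueError("r must be non-negative")
    pos_b = np.asarray(pos_b, dtype=float)
    pos_c = np.asarray(pos_c, dtype=float)
    pos_rnd = np.abs(np.asarray(u, dtype=float) * pos_b - pos_c)
    return pos_b - r * pos_rnd * angle.cos_theta


def select_phase(R: float) -> Phase:
    """Exploitation when ``|R| <= 1``, exploration otherwise.

    ``R`` is symmetric around 0, so the switch uses its magnitude; early in
    the run (large ``r_G``) exploration dominates, and once ``r_G`` falls
    below 1 every agent exploits.
    """
    if not np.isfinite(R):
        raise ValueError("R must be finite")
    return Phase.EXPLOITATION if abs(R) <= 1.0 else Phase.EXPLORATION


# Equal weights over 360 integer-degree bins: the roulette wheel reduces to
# discrete-uniform selection but keeps the weighted machinery explicit.
_ANGLE_CUMWEIGHTS = np.cumsum(np.ones(360))


def sample_angle(rng: np.random.Generator) -> AngleSample:
    """Draw a direction angle in [0, 360] degrees by roulette wheel."""
    u = rng.uniform(0.0, _ANGLE_CUMWEIGHTS[-1])
    idx = int(np.searchsorted(_ANGLE_CUMWEIGHTS, u, side="right"))
    theta = float(idx + 1)  # degrees 1..360
    return AngleSample(theta=theta, cos_theta=float(np.cos(np.radians(theta))))
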