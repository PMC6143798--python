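"""Continuous reward evaluation and working-memory relative reward.

The agent's reward at each moment combines a per-state-category basic
reward with a continuous, geometry-dependent evaluation term:

    r_t = R_b(s_t) + alpha * Eva(s_t)

so two observations assigned to the same discrete state still receive
different rewards when their geometry differs.  The learning signal is
not r_t itself but the working-memory *relative* reward

    r_end = r_{t+1} - r_t,

the change in evaluation across the executed action — a prediction-
error-like quantity whose sign gates the dopamine response.

Window task categories (14 states):
    C1 = {s13}            window lost          R_b = -1000, Eva = 0
    C2 = {s2..s9}         far, fully visible   R_b =  -600, Eva = (win_w+win_h)/(I_w+I_h)
    C3 = {s1,s10,s11,s12} near, one step off   R_b =  -300, Eva = -(|G_u-G_d|+|G_l-G_r|)/(I_w+I_h)
    C4 = {s0}             centred (goal)       R_b =  1000, Eva = 1000

Obstacle task (2 states): R_b = -500 for both, Eva = max(width - x, x)
where x is the obstacle's horizontal image coordinate — centred obstacles
are worst, obstacles pushed toward either border are safer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .environments import Observation

C1, C2, C3, C4 = "C1", "C2", "C3", "C4"

#: Default evaluation scale factors.  The window task uses alpha = 100 so
#: the continuous term is commensurate with the 300-400 point gaps
#: between basic rewards; the obstacle evaluation is already in pixels,
#: so alpha = 1.
DEFAULT_ALPHA_WINDOW = 100.0
DEFAULT_ALPHA_OBSTACLE = 1.0


def _window_categories() -> dict[int, str]:
    cats = {0: C4, 13: C1}
    for s in (1, 10, 11, 12):
        cats[s] = C3
    for s in range(2, 10):
        cats[s] = C2
    return cats


@dataclass(frozen=True)
class RewardConfig:
    """Basic rewards, evaluation scale and the state->category map."""

    basic_rewards: dict[str, float]
    alpha: float
    categories: dict[int, str]
    task: str = "window"

    @classmethod
    def window_defaults(cls, alpha: float = DEFAULT_ALPHA_WINDOW) -> "RewardConfig":
        return cls(
            basic_rewards={C1: -1000.0, C2: -600.0, C3: -300.0, C4: 1000.0},
            alpha=alpha,
            categories=_window_categories(),
            task="window",
        )

    @classmethod
    def obstacle_defaults(cls, alpha: float = DEFAULT_ALPHA_OBSTACLE) -> "RewardConfig":
        return cls(
            basic_rewards={"obstacle": -500.0},
            alpha=alpha,
            categories={0: "obstacle", 1: "obstacle"},
            task="obstacle",
        )


@dataclass
class WorkingMemory:
    """Holds the previous evaluation r_t so r_end can be formed.

    Empty before the first evaluation of an episode; the first call to
    :func:`actual_reward` in priming mode only stores r_t.
    """

    last_reward: float | None = field(default=None)

    @property
    def empty(self) -> bool:
        return self.last_reward is None

    def clear(self) -> None:
        self.last_reward = None


def eva_window(obs: "Observation", category: str | None = None) -> float:
    """Continuous evaluation of a window-task observation.

    C2 (far, fully visible): apparent window size (win_w+win_h)/(I_w+I_h),
    growing as the agent approaches — in (0, 1].
    C3 (near): negative border-gap imbalance, 0 when perfectly balanced —
    in [-1, 0].
    C1 (lost): 0.   C4 (goal): 1000.

    If ``category`` is not given it is derived by classifying the
    observation.
    """
    if category is None:
        from .environments import classify_state  # local import to avoid cycle

        state = classify_state(obs, task="window")
        category = _window_categories()[state]
    cat = category
    if cat not in (C1, C2, C3, C4):
        raise ValueError(f"unknown window category {cat!r}")
    if obs.image_w <= 0 or obs.image_h <= 0:
        raise ValueError("image dimensions must be positive")
    denom = obs.image_w + obs.image_h
    if cat == C2:
        if obs.win_w is None or obs.win_h is None:
            raise ValueError("C2 observation requires window dimensions")
        if obs.win_w > obs.image_w or obs.win_h > obs.image_h:
            raise ValueError("window larger than the frame in a C2 observation")
        return (obs.win_w + obs.win_h) / denom
    if cat == C3:
        gaps = (obs.g_u, obs.g_d, obs.g_l, obs.g_r)
        if any(g is None for g in gaps):
            raise ValueError("C3 observation requires all four border gaps")
        if any(g < 0 for g in gaps):
            raise ValueError("border gaps must be non-negative")
        return -(abs(obs.g_u - obs.g_d) + abs(obs.g_l - obs.g_r)) / denom
    if cat == C1:
        return 0.0
    return 1000.0  # C4


def eva_obstacle(width: float, x: float) -> float:
    """Obstacle-task evaluation max(width - x, x): distance of the
    obstacle from the farther image border.  Minimal (worst) when the
    obstacle is dead centre."""
    if not 0 <= x <= width:
        raise ValueError(f"obstacle x={x} outside [0, {width}]")
    return max(width - x, x)


def state_reward(state: int, obs: "Observation", cfg: RewardConfig) -> float:
    """r_t = R_b(category of state) + alpha * Eva(observation)."""
    if state not in cfg.categories:
        raise KeyError(f"state {state} not in the reward configuration")
    cat = cfg.categories[state]
    if cfg.task == "window":
        eva = eva_window(obs, category=cat)
    else:
        if obs.obstacle_x is None:
            raise ValueError("obstacle observation requires obstacle_x")
        eva = eva_obstacle(obs.image_w, obs.obstacle_x)
    return cfg.basic_rewards[cat] + cfg.alpha * eva


def actual_reward(mem: WorkingMemory, r_next: float) -> tuple[float, WorkingMemory]:
    """Working-memory relative reward r_end = r_{t+1} - r_t.

    The memory must hold the previous evaluation; it is updated to
    ``r_next`` in place.  Use :meth:`WorkingMemory.clear` plus a direct
    assignment (or the decision loop's priming step) before the first
    comparison of an episode.
    """
    if mem.empty:
        raise ValueError(
            "working memory is empty; prime it with the first evaluation "
            "before computing an actual reward"
        )
    if not np.isfinite(r_next):
        raise ValueError("r_next must be finite")
    r_end = r_next - mem.last_reward
    mem.last_reward = r_next
    return r_end, mem
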