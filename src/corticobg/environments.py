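"""Synthetic decision tasks emitting window/obstacle visual geometry.

These worlds stand in for an aerial vehicle's camera-based tasks.  They
emit the same geometric quantities the reward evaluators consume (frame
size, apparent window size, border gaps, obstacle x-coordinate) and a
deterministic observation->state classifier replaces the vision
pipeline's state-recognition step.

Window world
------------
The agent occupies a cell of a bounded lattice of misalignments
(dx, dy) relative to the window centre, dx positive when the agent is
right of centre and dy positive when above.  The apparent window size
shrinks with Euclidean distance from the centre and the window is
displaced within the frame opposite to the agent's misalignment, so the
border gaps encode (dx, dy) linearly.  States:

* s0   — centred, (0,0): the goal (category C4).
* s1, s10, s11, s12 — one step off centre along an axis (E, N, W, S):
  the near band, category C3, scored by gap imbalance.
* s2..s9 — farther cells grouped by the sign pattern of (dx, dy) into
  eight compass sectors (E, NE, N, NW, W, SW, S, SE): category C2,
  scored by apparent window size.  Grouping by sign pattern (rather
  than angle) makes the set of improving actions identical for every
  cell of a sector, so a policy learned once per state is correct
  everywhere in that state.
* s13  — window lost (Chebyshev distance >= 4), category C1.  Entering
  it yields the C1 penalty through the relative reward and the agent
  then recovers to its previous cell; inside the lost region every
  reward is the constant C1 floor, so no policy is definable there and
  recovery mirrors an operator pulling the vehicle back.

Obstacle world
--------------
The obstacle sits at horizontal image coordinate x; the agent's lateral
step moves it the opposite way in the frame (step 40 px).  Two states:
obstacle in the left (s0) or right (s1) half.  The episode ends when the
obstacle leaves the central danger band (x <= 40 or x >= 280 on the
default 320 px frame).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

# Window-task actions.
LEFT, UP, RIGHT, DOWN = 0, 1, 2, 3
WINDOW_ACTIONS = {LEFT: (-1, 0), UP: (0, 1), RIGHT: (1, 0), DOWN: (0, -1)}
WINDOW_ACTION_NAMES = {LEFT: "left", UP: "up", RIGHT: "right", DOWN: "down"}

# Obstacle-task actions.
OB_LEFT, OB_RIGHT = 0, 1

N_WINDOW_STATES = 14
N_OBSTACLE_STATES = 2

# Sign-pattern -> compass C2 state. Axis patterns are the four cardinal
# sectors, quadrant patterns the four diagonal sectors.
_SECTOR_STATE = {
    (1, 0): 2,    # E
    (1, 1): 3,    # NE
    (0, 1): 4,    # N
    (-1, 1): 5,   # NW
    (-1, 0): 6,   # W
    (-1, -1): 7,  # SW
    (0, -1): 8,   # S
    (1, -1): 9,   # SE
}
_NEAR_STATE = {(1, 0): 1, (0, 1): 10, (-1, 0): 11, (0, -1): 12}


@dataclass(frozen=True)
class WindowGeometry:
    """Fixed camera/window geometry of the synthetic window world."""

    image_w: float = 320.0
    image_h: float = 240.0
    base_win_w: float = 160.0   # apparent window width when centred
    base_win_h: float = 120.0
    px_per_dx: float = 30.0     # horizontal frame shift per lattice step
    px_per_dy: float = 25.0
    lost_chebyshev: int = 4     # window leaves the frame at this ring
    lattice_bound: int = 4


DEFAULT_GEOMETRY = WindowGeometry()


@dataclass(frozen=True)
class Observation:
    """Geometric observation emitted by either world.

    Window world: when ``visible``, the gap/size fields satisfy
    g_l + win_w + g_r = image_w and g_u + win_h + g_d = image_h.
    Obstacle world: only ``obstacle_x`` is set, in [0, image_w].
    """

    image_w: float
    image_h: float
    visible: bool = True
    win_w: float | None = None
    win_h: float | None = None
    g_u: float | None = None
    g_d: float | None = None
    g_l: float | None = None
    g_r: float | None = None
    obstacle_x: float | None = None


def cell_to_state(dx: int, dy: int, geom: WindowGeometry = DEFAULT_GEOMETRY) -> int:
    """Map a lattice misalignment to one of the 14 window states."""
    cheb = max(abs(dx), abs(dy))
    if cheb == 0:
        return 0
    if cheb >= geom.lost_chebyshev:
        return 13
    if cheb == 1 and (dx == 0 or dy == 0):
        return _NEAR_STATE[(int(np.sign(dx)), int(np.sign(dy)))]
    return _SECTOR_STATE[(int(np.sign(dx)), int(np.sign(dy)))]


def state_category(state: int) -> str:
    if state == 0:
        return "C4"
    if state == 13:
        return "C1"
    if state in (1, 10, 11, 12):
        return "C3"
    return "C2"


def observe_cell(
    dx: int,
    dy: int,
    geom: WindowGeometry = DEFAULT_GEOMETRY,
    jitter: float = 0.0,
    rng: np.random.Generator | None = None,
) -> Observation:
    """Canonical observation for a lattice cell.

    Optional zero-mean uniform jitter (px) perturbs the border gaps; the
    size/gap sum invariants are maintained by construction.
    """
    cheb = max(abs(dx), abs(dy))
    if cheb >= geom.lost_chebyshev:
        return Observation(image_w=geom.image_w, image_h=geom.image_h, visible=False)
    dist = float(np.hypot(dx, dy))
    win_w = geom.base_win_w / (1.0 + dist)
    win_h = geom.base_win_h / (1.0 + dist)
    off_x = geom.px_per_dx * dx
    off_y = geom.px_per_dy * dy
    if jitter > 0:
        if rng is None:
            rng = np.random.default_rng()
        off_x += rng.uniform(-jitter, jitter)
        off_y += rng.uniform(-jitter, jitter)
    # agent right of centre -> window displaced left in the frame
    g_l = (geom.image_w - win_w) / 2.0 - off_x
    g_r = (geom.image_w - win_w) / 2.0 + off_x
    # agent above centre -> window displaced down -> top gap grows
    g_u = (geom.image_h - win_h) / 2.0 + off_y
    g_d = (geom.image_h - win_h) / 2.0 - off_y
    return Observation(
        image_w=geom.image_w,
        image_h=geom.image_h,
        visible=True,
        win_w=win_w,
        win_h=win_h,
        g_u=g_u,
        g_d=g_d,
        g_l=g_l,
        g_r=g_r,
    )


def classify_state(
    obs: Observation,
    task: str = "window",
    geom: WindowGeometry = DEFAULT_GEOMETRY,
) -> int:
    """Deterministic observation -> discrete state classifier.

    Window task: inverts the border-gap displacement to the nearest
    lattice cell and applies the cell->state map; an invisible window is
    s13.  Obstacle task: left/right half-plane rule.
    """
    if task == "obstacle":
        if obs.obstacle_x is None:
            raise ValueError("obstacle observation requires obstacle_x")
        if not 0 <= obs.obstacle_x <= obs.image_w:
            raise ValueError("obstacle_x outside the frame")
        return 0 if obs.obstacle_x < obs.image_w / 2.0 else 1
    if task != "window":
        raise ValueError(f"unknown task {task!r}")
    if not obs.visible:
        return 13
    fields = (obs.win_w, obs.win_h, obs.g_u, obs.g_d, obs.g_l, obs.g_r)
    if any(f is None for f in fields):
        raise ValueError("visible window observation is missing geometry fields")
    dx = (obs.g_r - obs.g_l) / (2.0 * geom.px_per_dx)
    dy = (obs.g_u - obs.g_d) / (2.0 * geom.px_per_dy)
    bound = geom.lattice_bound
    dxi = int(np.clip(round(dx), -bound, bound))
    dyi = int(np.clip(round(dy), -bound, bound))
    return cell_to_state(dxi, dyi, geom)


CORNER_CELLS = {
    "upper_left": (-3, 3),
    "upper_right": (3, 3),
    "lower_left": (-3, -3),
    "lower_right": (3, -3),
}


class EpisodeDone(RuntimeError):
    """Raised when stepping a finished episode."""


@dataclass
class WindowWorld:
    """Lattice window-centering world; see the module docstring."""

    geometry: WindowGeometry = field(default_factory=WindowGeometry)
    jitter: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self._rng = np.random.default_rng(self.seed)
        self.dx: int = 0
        self.dy: int = 0
        self.done: bool = True

    @property
    def n_states(self) -> int:
        return N_WINDOW_STATES

    @property
    def n_actions(self) -> int:
        return len(WINDOW_ACTIONS)

    def reset(self, corner: str) -> tuple[int, Observation]:
        """Place the agent at a named corner of the window's neighbourhood."""
        if corner not in CORNER_CELLS:
            raise ValueError(
                f"unknown corner {corner!r}; expected one of {sorted(CORNER_CELLS)}"
            )
        self.dx, self.dy = CORNER_CELLS[corner]
        self.done = False
        return self.current()

    def current(self) -> tuple[int, Observation]:
        obs = self.observe()
        return classify_state(obs, "window", self.geometry), obs

    def observe(self) -> Observation:
        return observe_cell(self.dx, self.dy, self.geometry, self.jitter, self._rng)

    def step(self, action: int) -> tuple[int, Observation, bool]:
        """Move one lattice cell; returns (state, observation, done).

        Entering the lost region returns the s13 observation (whose C1
        reward delivers the penalty) and recovers the agent to its
        previous cell; the episode ends only at the centred goal.
        """
        if self.done:
            raise EpisodeDone("window episode is finished; reset before stepping")
        if action not in WINDOW_ACTIONS:
            raise ValueError(f"unknown window action {action}")
        mx, my = WINDOW_ACTIONS[action]
        bound = self.geometry.lattice_bound
        nx = int(np.clip(self.dx + mx, -bound, bound))
        ny = int(np.clip(self.dy + my, -bound, bound))
        state = cell_to_state(nx, ny, self.geometry)
        if state == 13:
            obs = observe_cell(nx, ny, self.geometry)
            # recovery: position reverts, episode continues
            return state, obs, False
        self.dx, self.dy = nx, ny
        obs = self.observe()
        if state == 0:
            self.done = True
        return state, obs, self.done

    # -- oracles used by metrics and tests ---------------------------------
    def reward_at(self, dx: int, dy: int, alpha: float = 100.0) -> float:
        """r_t the reward system would assign at a cell (jitter-free)."""
        from .rewards import RewardConfig, state_reward

        cfg = RewardConfig.window_defaults(alpha=alpha)
        state = cell_to_state(dx, dy, self.geometry)
        return state_reward(state, observe_cell(dx, dy, self.geometry), cfg)

    def correct_actions(self, dx: int | None = None, dy: int | None = None) -> set[int]:
        """Actions that strictly increase the reward from a cell.

        By construction of the sector layout this set depends only on
        the cell's state, not on the particular cell within the state.
        """
        if dx is None:
            dx, dy = self.dx, self.dy
        here = self.reward_at(dx, dy)
        bound = self.geometry.lattice_bound
        good = set()
        for a, (mx, my) in WINDOW_ACTIONS.items():
            nx = int(np.clip(dx + mx, -bound, bound))
            ny = int(np.clip(dy + my, -bound, bound))
            if self.reward_at(nx, ny) > here:
                good.add(a)
        return good


@dataclass
class ObstacleWorld:
    """Two-state lateral obstacle-avoidance world."""

    image_w: float = 320.0
    image_h: float = 240.0
    step_px: float = 40.0
    danger_margin: float = 40.0   # done once x <= margin or x >= image_w - margin
    start_offset: float = 40.0    # initial |x - centre|
    seed: int = 0

    def __post_init__(self) -> None:
        self._rng = np.random.default_rng(self.seed)
        self.x: float = self.image_w / 2.0
        self.done: bool = True

    @property
    def n_states(self) -> int:
        return N_OBSTACLE_STATES

    @property
    def n_actions(self) -> int:
        return 2

    def reset(self, side: str | None = None) -> tuple[int, Observation]:
        """Start with the obstacle slightly off-centre; side seeded if not given."""
        if side is None:
            side = "right" if self._rng.random() < 0.5 else "left"
        if side not in ("left", "right"):
            raise ValueError(f"unknown side {side!r}")
        sign = 1.0 if side == "right" else -1.0
        self.x = self.image_w / 2.0 + sign * self.start_offset
        self.done = False
        return self.current()

    def current(self) -> tuple[int, Observation]:
        obs = self.observe()
        return classify_state(obs, "obstacle"), obs

    def observe(self) -> Observation:
        return Observation(
            image_w=self.image_w, image_h=self.image_h, visible=True, obstacle_x=self.x
        )

    def step(self, action: int) -> tuple[int, Observation, bool]:
        """Shift laterally; the obstacle moves the opposite way in frame."""
        if self.done:
            raise EpisodeDone("obstacle episode is finished; reset before stepping")
        if action not in (OB_LEFT, OB_RIGHT):
            raise ValueError(f"unknown obstacle action {action}")
        shift = self.step_px if action == OB_LEFT else -self.step_px
        self.x = float(np.clip(self.x + shift, 0.0, self.image_w))
        if self.x <= self.danger_margin or self.x >= self.image_w - self.danger_margin:
            self.done = True
        state, obs = classify_state(self.observe(), "obstacle"), self.observe()
        return state, obs, self.done

    def correct_actions(self) -> set[int]:
        """The action pushing the obstacle away from the frame centre."""
        return {OB_LEFT} if self.x >= self.image_w / 2.0 else {OB_RIGHT}


def window_reset(corner: str, seed: int = 0, **kwargs) -> tuple[WindowWorld, int, Observation]:
    """Build a window world at a named corner; returns (world, state, obs)."""
    world = WindowWorld(seed=seed, **kwargs)
    state, obs = world.reset(corner)
    return world, state, obs


def window_step(world: WindowWorld, action: int) -> tuple[int, Observation, bool]:
    return world.step(action)


def obstacle_step(world: ObstacleWorld, action: int) -> tuple[int, Observation, bool]:
    return world.step(action)


def canonical_cells() -> dict[int, tuple[int, int]]:
    """One representative lattice cell per window state."""
    return {
        0: (0, 0), 1: (1, 0), 10: (0, 1), 11: (-1, 0), 12: (0, -1),
        2: (2, 0), 3: (2, 2), 4: (0, 2), 5: (-2, 2), 6: (-2, 0),
        7: (-2, -2), 8: (0, -2), 9: (2, -2), 13: (4, 0),
    }


def canonical_observation(state: int, task: str = "window") -> Observation:
    """A representative observation classifying to ``state``."""
    if task == "obstacle":
        if state not in (0, 1):
            raise ValueError("obstacle task has states 0 and 1")
        x = 80.0 if state == 0 else 240.0
        return Observation(image_w=320.0, image_h=240.0, visible=True, obstacle_x=x)
    cells = canonical_cells()
    if state not in cells:
        raise ValueError(f"unknown window state {state}")
    return observe_cell(*cells[state])
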