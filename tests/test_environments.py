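import numpy as np
import pytest

from corticobg.environments import (
    CORNER_CELLS,
    EpisodeDone,
    Observation,
    ObstacleWorld,
    WindowWorld,
    canonical_cells,
    canonical_observation,
    cell_to_state,
    classify_state,
    observe_cell,
    state_category,
)
from corticobg.rewards import RewardConfig, state_reward


@pytest.mark.parametrize("state", list(range(14)))
def test_window_classifier_inverts_the_canonical_observation(state):
    assert classify_state(canonical_observation(state, "window")) == state


@pytest.mark.parametrize("state", [0, 1])
def test_obstacle_classifier_half_plane_rule(state):
    assert classify_state(canonical_observation(state, "obstacle"), "obstacle") == state
    near_left = Observation(image_w=320.0, image_h=240.0, obstacle_x=10.0)
    assert classify_state(near_left, "obstacle") == 0


def test_classifier_rejects_malformed_observations():
    with pytest.raises(ValueError):
        classify_state(Observation(image_w=320.0, image_h=240.0, visible=True))
    with pytest.raises(ValueError):
        classify_state(Observation(image_w=320.0, image_h=240.0), "obstacle")


def test_observation_geometry_invariants():
    for dx in range(-3, 4):
        for dy in range(-3, 4):
            o = observe_cell(dx, dy)
            assert o.g_l + o.win_w + o.g_r == pytest.approx(o.image_w)
            assert o.g_u + o.win_h + o.g_d == pytest.approx(o.image_h)
            assert min(o.g_l, o.g_r, o.g_u, o.g_d) >= 0


def test_corner_starts_are_distinct_deterministic_and_off_goal():
    states = {}
    for corner in CORNER_CELLS:
        w1 = WindowWorld(seed=7)
        s1, o1 = w1.reset(corner)
        w2 = WindowWorld(seed=7)
        s2, o2 = w2.reset(corner)
        assert (s1, o1) == (s2, o2)
        assert s1 != 0
        assert state_category(s1) in ("C2", "C3")
        states[corner] = s1
    assert len(set(states.values())) == 4
    with pytest.raises(ValueError):
        WindowWorld().reset("middle")


def test_moving_toward_centre_raises_reward_and_balances_gaps():
    w = WindowWorld(seed=0)
    w.reset("upper_right")  # east-north quadrant: dx>0, so 'left' improves
    cfg = RewardConfig.window_defaults()
    s0, o0 = w.current()
    r0 = state_reward(s0, o0, cfg)
    s1, o1, done = w.step(0)  # left
    r1 = state_reward(s1, o1, cfg)
    assert r1 > r0
    assert abs(o1.g_l - o1.g_r) < abs(o0.g_l - o0.g_r)


def test_goal_absorption_from_adjacent_cell():
    w = WindowWorld(seed=0)
    w.reset("upper_left")
    w.dx, w.dy = 1, 0  # one step east of centre (a near C3 state)
    s, obs, done = w.step(0)  # left -> centred
    assert done and s == 0
    with pytest.raises(EpisodeDone):
        w.step(0)


def test_losing_the_window_penalises_then_recovers():
    w = WindowWorld(seed=0)
    w.reset("upper_right")
    w.dx, w.dy = 3, 3
    cfg = RewardConfig.window_defaults()
    r_before = state_reward(*w.current(), cfg)
    s, obs, done = w.step(2)  # right: off the visible region
    assert s == 13 and not done and not obs.visible
    assert state_reward(13, obs, cfg) == -1000.0 < r_before
    # the agent recovered to its previous cell
    assert (w.dx, w.dy) == (3, 3)


def test_reward_gradient_consistent_across_the_lattice():
    """Any improving move strictly raises r_t; the improving set depends
    only on the state, never on the particular cell within it."""
    w = WindowWorld()
    per_state = {}
    for dx in range(-4, 5):
        for dy in range(-4, 5):
            st = cell_to_state(dx, dy)
            if st in (0, 13):
                continue
            acts = frozenset(w.correct_actions(dx, dy))
            assert acts, f"cell ({dx},{dy}) has no improving action"
            per_state.setdefault(st, set()).add(acts)
    assert all(len(v) == 1 for v in per_state.values())


def test_correct_policy_reaches_goal_within_lattice_diameter():
    w = WindowWorld(seed=3)
    for corner in CORNER_CELLS:
        w.reset(corner)
        for _ in range(8):  # lattice diameter
            if w.done:
                break
            action = min(w.correct_actions())
            w.step(action)
        assert w.done


def test_obstacle_frame_shift_arithmetic():
    w = ObstacleWorld(seed=0)
    w.reset("right")  # obstacle at 200, right of centre
    x0 = w.x
    s, obs, done = w.step(1)  # moving right shifts the obstacle left in frame
    assert obs.obstacle_x == x0 - w.step_px
    s, obs, done = w.step(0)  # moving left shifts it right again
    assert obs.obstacle_x == x0


def test_obstacle_mirror_symmetry():
    wr = ObstacleWorld(seed=0)
    wr.reset("right")
    wl = ObstacleWorld(seed=0)
    wl.reset("left")
    for a_r, a_l in [(0, 1), (0, 1)]:
        sr, orr, dr = wr.step(a_r)
        sl, ol, dl = wl.step(a_l)
        assert orr.obstacle_x == pytest.approx(wr.image_w - ol.obstacle_x)
        assert dr == dl
    assert dr  # both escaped the danger band after two correct moves


def test_obstacle_episode_end_and_errors():
    w = ObstacleWorld(seed=1)
    w.reset("left")
    done = False
    for _ in range(10):
        if done:
            break
        _, _, done = w.step(1)
    assert done
    with pytest.raises(EpisodeDone):
        w.step(0)
    with pytest.raises(ValueError):
        ObstacleWorld().reset("up")
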