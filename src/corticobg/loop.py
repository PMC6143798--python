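"""The perceive -> evaluate -> decide -> act -> feedback -> learn cycle.

One *decision* is a full pass through the cycle: the current state's
reward r_t is evaluated and primes working memory, the network selects
an action (first premotor spike), the environment transitions, the new
observation is evaluated (r_{t+1}), the relative reward
r_end = r_{t+1} - r_t is formed and fed back to the network as phasic
dopamine plus an STDP window.  An *episode* iterates decisions until
the environment reports completion, and an *experiment* aggregates
independent runs into steps-to-goal, trials-to-correct and latency
metrics.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .circuit import CircuitConfig, DecisionRecord, NetworkState, build_network
from .environments import ObstacleWorld, WindowWorld, CORNER_CELLS
from .rewards import RewardConfig, WorkingMemory, actual_reward, state_reward


@dataclass
class DecisionEvent:
    """One record of an episode trace."""

    index: int
    state: int
    r_t: float
    action: int
    latency: int
    timed_out: bool
    r_next: float
    r_end: float
    da_d1: float
    da_d2: float
    next_state: int
    done: bool
    correct: bool  # did the action strictly improve the reward?
    decision_counts: dict = field(default_factory=dict)
    feedback_counts: dict = field(default_factory=dict)
    ofc_weight_sums: dict = field(default_factory=dict)


@dataclass
class EpisodeTrace:
    """Ordered decision records of one episode plus provenance."""

    task: str
    seed: int
    start: str | None
    events: list[DecisionEvent] = field(default_factory=list)
    reached_goal: bool = False
    config_digest: str | None = None

    @property
    def n_decisions(self) -> int:
        return len(self.events)

    @property
    def latencies(self) -> list[int]:
        return [e.latency for e in self.events]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for e in self.events:
            d = asdict(e)
            d.pop("decision_counts")
            d.pop("feedback_counts")
            d.pop("ofc_weight_sums")
            rows.append(d)
        return pd.DataFrame(rows)

    def to_json_lines(self) -> str:
        return "\n".join(json.dumps(asdict(e)) for e in self.events)


def run_episode(
    env: WindowWorld | ObstacleWorld,
    net: NetworkState,
    reward_cfg: RewardConfig,
    max_decisions: int = 200,
    learn: bool = True,
) -> EpisodeTrace:
    """Run one episode of the decision cycle on a freshly reset environment.

    Working memory is local to the episode; nothing persists into the
    next one except the network's weights.
    """
    if env.n_states != net.n_states or env.n_actions != net.n_actions:
        raise ValueError(
            f"environment ({env.n_states}x{env.n_actions}) does not match "
            f"network ({net.n_states}x{net.n_actions})"
        )
    trace = EpisodeTrace(task=reward_cfg.task, seed=net.seed, start=None)
    mem = WorkingMemory()
    for k in range(max_decisions):
        if env.done:
            break
        state, obs = env.current()
        r_t = state_reward(state, obs, reward_cfg)
        mem.last_reward = r_t  # prime/update working memory at s_t
        rec: DecisionRecord = net.decide(state)
        correct_set = env.correct_actions()
        next_state, next_obs, done = env.step(rec.action)
        r_next = state_reward(next_state, next_obs, reward_cfg)
        r_end, mem = actual_reward(mem, r_next)
        if learn:
            net.deliver_feedback(r_end, rec)
        trace.events.append(
            DecisionEvent(
                index=k,
                state=state,
                r_t=r_t,
                action=rec.action,
                latency=rec.latency,
                timed_out=rec.timed_out,
                r_next=r_next,
                r_end=r_end,
                da_d1=rec.da_d1 if learn else float("nan"),
                da_d2=rec.da_d2 if learn else float("nan"),
                next_state=next_state,
                done=done,
                correct=rec.action in correct_set,
                decision_counts=rec.decision_counts,
                feedback_counts=rec.feedback_counts or {},
                ofc_weight_sums=rec.ofc_weight_sums or {},
            )
        )
        if done:
            trace.reached_goal = True
    return trace


def trials_to_correct(traces: list[EpisodeTrace]) -> dict[int, int]:
    """Number of failed trials per state before its terminal correct streak.

    A trial is one decision taken at a state.  A state counts as learned
    once every later visit (within the run) chooses a reward-improving
    action; the metric is the number of incorrect trials before that
    point.  States never visited are absent.
    """
    visits: dict[int, list[bool]] = {}
    for tr in traces:
        for e in tr.events:
            visits.setdefault(e.state, []).append(e.correct)
    out = {}
    for s, hist in visits.items():
        wrong = 0
        for k, ok in enumerate(hist):
            if not ok:
                wrong = sum(1 for x in hist[: k + 1] if not x)
        out[s] = wrong
    return out


@dataclass
class RunMetrics:
    task: str
    variant: str
    seed: int
    steps_to_goal: dict[str, int]
    trials: dict[int, int]
    latencies: list[int]
    traces: list[EpisodeTrace] = field(default_factory=list)


def run_window_session(
    seed: int,
    config: CircuitConfig | None = None,
    variant: str = "full",
    n_cycles: int = 4,
    corners: tuple[str, ...] = ("upper_left", "upper_right", "lower_left", "lower_right"),
    reward_cfg: RewardConfig | None = None,
    max_decisions: int = 200,
    keep_traces: bool = True,
) -> RunMetrics:
    """One continuously learning run over repeated corner episodes.

    A single network learns across ``n_cycles`` passes over the four
    corner starts (weights persist within the run); used for latency
    statistics and the trained-network analyses.
    """
    net = _make_net(14, 4, config, seed, variant)
    reward_cfg = reward_cfg or RewardConfig.window_defaults()
    env = WindowWorld(seed=seed)
    traces = []
    steps: dict[str, int] = {}
    for cycle in range(n_cycles):
        for corner in corners:
            env.reset(corner)
            tr = run_episode(env, net, reward_cfg, max_decisions=max_decisions)
            tr.start = corner
            traces.append(tr)
            if cycle == 0:
                steps[corner] = tr.n_decisions
    lat = [l for tr in traces for l in tr.latencies]
    return RunMetrics(
        task="window",
        variant=variant,
        seed=seed,
        steps_to_goal=steps,
        trials=trials_to_correct(traces),
        latencies=lat,
        traces=traces if keep_traces else [],
    )


def run_experiment(
    task: str = "window",
    variants: tuple[str, ...] = ("full",),
    n_runs: int = 15,
    seeds: list[int] | None = None,
    config: CircuitConfig | None = None,
    corners: tuple[str, ...] = ("upper_left", "upper_right", "lower_left", "lower_right"),
    reset_per_run: bool = True,
) -> pd.DataFrame:
    """Aggregate independent runs into a metrics table.

    For the window task each run is one episode per corner with a fresh
    network per run (``reset_per_run``) or one continuously learning
    network; rows report steps-to-goal per start, worst trials-to-correct
    and mean decision latency per variant.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    if seeds is None:
        seeds = list(range(n_runs))
    if len(set(seeds)) != len(seeds):
        raise ValueError("seeds must be distinct")
    for v in variants:
        if v not in ("full", "no_ofc"):
            raise ValueError(f"unknown variant {v!r}")
    rows = []
    for variant in variants:
        for seed in seeds[:n_runs]:
            if task == "window":
                if reset_per_run:
                    # fresh network per corner episode (independent experiments)
                    for corner in corners:
                        net = _make_net(14, 4, config, seed, variant)
                        env = WindowWorld(seed=seed)
                        env.reset(corner)
                        tr = run_episode(env, net, RewardConfig.window_defaults())
                        tr.start = corner
                        trials = trials_to_correct([tr])
                        rows.append(
                            {
                                "task": task,
                                "variant": variant,
                                "seed": seed,
                                "start": corner,
                                "steps_to_goal": tr.n_decisions,
                                "reached_goal": tr.reached_goal,
                                "max_trials_to_correct": max(trials.values()),
                                "mean_latency": float(np.mean(tr.latencies)),
                            }
                        )
                else:
                    m = run_window_session(seed, config, variant, corners=corners,
                                           keep_traces=False)
                    for corner, st in m.steps_to_goal.items():
                        rows.append(
                            {
                                "task": task,
                                "variant": variant,
                                "seed": seed,
                                "start": corner,
                                "steps_to_goal": st,
                                "reached_goal": True,
                                "max_trials_to_correct": max(m.trials.values()),
                                "mean_latency": float(np.mean(m.latencies)),
                            }
                        )
            elif task == "obstacle":
                net = _make_net(2, 2, config, seed, variant)
                env = ObstacleWorld(seed=seed)
                env.reset()
                tr = run_episode(env, net, RewardConfig.obstacle_defaults(), max_decisions=50)
                trials = trials_to_correct([tr])
                rows.append(
                    {
                        "task": task,
                        "variant": variant,
                        "seed": seed,
                        "start": None,
                        "steps_to_goal": tr.n_decisions,
                        "reached_goal": tr.reached_goal,
                        "max_trials_to_correct": max(trials.values()),
                        "mean_latency": float(np.mean(tr.latencies)),
                    }
                )
            else:
                raise ValueError(f"unknown task {task!r}")
    return pd.DataFrame(rows)


def _make_net(
    n_states: int, n_actions: int, config: CircuitConfig | None, seed: int, variant: str
) -> NetworkState:
    ablate = ("no_ofc",) if variant == "no_ofc" else ()
    return build_network(n_states, n_actions, config or CircuitConfig(), seed=seed, ablate=ablate)
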