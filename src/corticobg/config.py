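"""Run configuration: YAML loading, validation, digests, test fixtures.

A run configuration names the task (which fixes the state/action space),
the circuit's numerical and learning parameters, the reward constants
and the seeds.  Every loaded configuration carries a content digest so
any output can be traced back to the exact parameter set that produced
it.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from .circuit import CircuitConfig, DEFAULT_GAINS, build_network, save_hdf5
from .environments import (
    N_OBSTACLE_STATES,
    N_WINDOW_STATES,
    canonical_observation,
    classify_state,
)
from .plasticity import STDPParams
from .rewards import DEFAULT_ALPHA_OBSTACLE, DEFAULT_ALPHA_WINDOW, RewardConfig

TASKS = {
    "window": dict(n_states=N_WINDOW_STATES, n_actions=4, alpha=DEFAULT_ALPHA_WINDOW),
    "obstacle": dict(n_states=N_OBSTACLE_STATES, n_actions=2, alpha=DEFAULT_ALPHA_OBSTACLE),
}

KNOWN_VARIANTS = ("full", "no_ofc", "no_stn", "no_dlpfc_thalamus")


class ConfigError(ValueError):
    """A run configuration failed validation."""


@dataclass(frozen=True)
class RunConfig:
    """Validated parameters of one experiment run."""

    task: str = "window"
    n_states: int = N_WINDOW_STATES
    n_actions: int = 4
    alpha: float = DEFAULT_ALPHA_WINDOW
    circuit: CircuitConfig = field(default_factory=CircuitConfig)
    seeds: tuple[int, ...] = (0,)
    variant: str = "full"
    n_cycles: int = 3
    max_decisions: int = 200
    output_dir: str = "results"

    def reward_config(self) -> RewardConfig:
        if self.task == "window":
            return RewardConfig.window_defaults(alpha=self.alpha)
        return RewardConfig.obstacle_defaults(alpha=self.alpha)

    def build(self, seed: int | None = None):
        ablate = () if self.variant == "full" else (self.variant,)
        return build_network(
            self.n_states,
            self.n_actions,
            self.circuit,
            seed=self.seeds[0] if seed is None else seed,
            ablate=ablate,
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    def digest(self) -> str:
        """Stable content hash of the full parameter set."""
        blob = json.dumps(self.to_dict(), sort_keys=True, default=float)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _validate(cfg: RunConfig) -> RunConfig:
    errors = []
    if cfg.task not in TASKS:
        errors.append(f"task: unknown task {cfg.task!r}; expected one of {sorted(TASKS)}")
    else:
        preset = TASKS[cfg.task]
        if cfg.n_states != preset["n_states"]:
            errors.append(
                f"n_states: task {cfg.task!r} has {preset['n_states']} states, got {cfg.n_states}"
            )
        if cfg.n_actions != preset["n_actions"]:
            errors.append(
                f"n_actions: task {cfg.task!r} has {preset['n_actions']} actions, got {cfg.n_actions}"
            )
    if cfg.n_actions < 2:
        errors.append("n_actions: winner-take-all selection needs at least 2 actions")
    if cfg.variant not in KNOWN_VARIANTS:
        errors.append(f"variant: unknown variant {cfg.variant!r}")
    if not cfg.seeds:
        errors.append("seeds: at least one seed is required")
    if len(set(cfg.seeds)) != len(cfg.seeds):
        errors.append("seeds: seeds must be distinct")
    if cfg.circuit.dt <= 0:
        errors.append("circuit.dt: must be positive")
    if cfg.circuit.w_min < 0 or cfg.circuit.w_max <= cfg.circuit.w_min:
        errors.append("circuit.w_min/w_max: need 0 <= w_min < w_max")
    unknown_gains = set(cfg.circuit.gains) - set(DEFAULT_GAINS)
    if unknown_gains:
        errors.append(f"circuit.gains: unknown connections {sorted(unknown_gains)}")
    if cfg.alpha < 0:
        errors.append("alpha: evaluation scale must be non-negative")
    if errors:
        raise ConfigError("invalid run configuration:\n  " + "\n  ".join(errors))
    return cfg


def default_config(task: str = "window", **overrides) -> RunConfig:
    """A fully validated configuration with task presets filled in."""
    if task not in TASKS:
        raise ConfigError(f"unknown task {task!r}")
    preset = TASKS[task]
    cfg = RunConfig(
        task=task,
        n_states=preset["n_states"],
        n_actions=preset["n_actions"],
        alpha=preset["alpha"],
    )
    if overrides:
        cfg = replace(cfg, **overrides)
    return _validate(cfg)


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration.

    Unspecified fields take the task preset defaults; the circuit block
    accepts the fields of :class:`CircuitConfig` with a nested ``gains``
    mapping and an optional ``stdp`` block (A_plus, A_minus, tau_plus,
    tau_minus).
    """
    path = Path(path)
    raw = yaml.safe_load(path.read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    task = raw.pop("task", "window")
    if task not in TASKS:
        raise ConfigError(f"task: unknown task {task!r}")
    preset = TASKS[task]

    circ_raw = raw.pop("circuit", {}) or {}
    gains = dict(DEFAULT_GAINS)
    gains.update(circ_raw.pop("gains", {}) or {})
    stdp_raw = circ_raw.pop("stdp", {}) or {}
    circ_fields = {f.name for f in dataclasses.fields(CircuitConfig)}
    unknown = set(circ_raw) - circ_fields
    if unknown:
        raise ConfigError(f"circuit: unknown fields {sorted(unknown)}")
    circuit = CircuitConfig(gains=gains, stdp=STDPParams(**stdp_raw), **circ_raw)

    known = {f.name for f in dataclasses.fields(RunConfig)} - {"circuit"}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown fields {sorted(unknown)}")
    if "seeds" in raw:
        raw["seeds"] = tuple(int(s) for s in raw["seeds"])
    cfg = RunConfig(
        task=task,
        n_states=raw.pop("n_states", preset["n_states"]),
        n_actions=raw.pop("n_actions", preset["n_actions"]),
        alpha=raw.pop("alpha", preset["alpha"]),
        circuit=circuit,
        **raw,
    )
    return _validate(cfg)


def dump_config(cfg: RunConfig, path: str | Path) -> None:
    """Write a configuration back to YAML (round-trips through load_config)."""
    d = cfg.to_dict()
    d["seeds"] = list(cfg.seeds)
    d["circuit"]["stdp"] = asdict(cfg.circuit.stdp)
    d["circuit"].pop("neuron", None)  # RS preset is not configurable here
    Path(path).write_text(yaml.safe_dump(d, sort_keys=True))


def spawn_seeds(master_seed: int, n: int) -> list[int]:
    """Expand one master seed into independent per-run seeds (< 2**31)."""
    ss = np.random.SeedSequence(master_seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


def generate_fixtures(out_dir: str | Path, seed: int = 0) -> dict:
    """Write a small, byte-stable fixture bundle for tests.

    Contents: one canonical observation per window/obstacle state
    (JSON), a three-decision toy episode trace (JSON lines) and a tiny
    pre-built obstacle-network weight snapshot (HDF5).
    """
    from .loop import run_episode
    from .environments import ObstacleWorld

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    obs_bundle = {}
    for s in range(N_WINDOW_STATES):
        o = canonical_observation(s, "window")
        assert classify_state(o, "window") == s
        obs_bundle[f"window_s{s}"] = asdict(o)
    for s in range(N_OBSTACLE_STATES):
        o = canonical_observation(s, "obstacle")
        assert classify_state(o, "obstacle") == s
        obs_bundle[f"obstacle_s{s}"] = asdict(o)
    (out / "observations.json").write_text(json.dumps(obs_bundle, indent=1, sort_keys=True))

    cfg = default_config("obstacle", seeds=(seed,))
    net = cfg.build()
    # start at the frame centre so the toy episode is exactly 3 decisions
    env = ObstacleWorld(seed=seed, start_offset=0.0)
    env.reset("right")
    trace = run_episode(env, net, cfg.reward_config(), max_decisions=3)
    (out / "toy_trace.jsonl").write_text(trace.to_json_lines())
    save_hdf5(net, out / "network.h5")

    digest = hashlib.sha256(
        (out / "observations.json").read_bytes() + (out / "toy_trace.jsonl").read_bytes()
    ).hexdigest()[:16]
    (out / "MANIFEST.json").write_text(
        json.dumps({"seed": seed, "digest": digest, "config_digest": cfg.digest()})
    )
    return {"digest": digest, "files": sorted(p.name for p in out.iterdir())}
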