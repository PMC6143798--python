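import numpy as np
import pytest

from corticobg import analysis
from corticobg.circuit import CircuitConfig, build_network
from corticobg.environments import ObstacleWorld, canonical_cells, WindowWorld
from corticobg.loop import run_episode, _make_net
from corticobg.rewards import RewardConfig


@pytest.fixture(scope="module")
def single_synapse_runs():
    return {
        cond: analysis.single_synapse_experiment(cond, duration=800.0, reward_time=300.0, seed=0)
        for cond in analysis.SINGLE_SYNAPSE_CONDITIONS
    }


def test_dopamine_burst_and_dip_bracket_plain_stdp(single_synapse_runs):
    """Final weight and post-reward spike density order as
    burst+STDP > STDP alone > dip+STDP."""
    r = single_synapse_runs
    final = {c: r[c].weight_trajectory[-1] for c in r}
    assert final["da_d1_stdp"] > final["stdp_only"] > final["da_d2_stdp"]
    density = {c: (r[c].post_spikes >= 300.0).sum() for c in r}
    assert density["da_d1_stdp"] > density["stdp_only"] > density["da_d2_stdp"]


def test_conditions_are_identical_before_the_reward(single_synapse_runs):
    r = single_synapse_runs
    for cond in ("da_d1_stdp", "da_d2_stdp"):
        pre_a = r["stdp_only"].post_spikes
        pre_b = r[cond].post_spikes
        np.testing.assert_array_equal(pre_a[pre_a < 300.0], pre_b[pre_b < 300.0])
        reward_tick = int(300.0 / r[cond].dt)
        np.testing.assert_array_equal(
            r["stdp_only"].weight_trajectory[:reward_tick],
            r[cond].weight_trajectory[:reward_tick],
        )


def test_single_synapse_rejects_bad_arguments():
    with pytest.raises(ValueError):
        analysis.single_synapse_experiment("da_d3_stdp")
    with pytest.raises(ValueError):
        analysis.single_synapse_experiment("stdp_only", duration=100.0, reward_time=200.0)


def test_weight_map_shapes_and_initial_range():
    net = build_network(14, 4, seed=0)
    for conn in ("DLPFC->StrD1", "DLPFC->StrD2", "DLPFC->PM"):
        grid = analysis.weight_map(net, conn)
        assert grid.shape == (14, 4)
        assert np.all(grid >= 0.8) and np.all(grid <= 1.2)
    with pytest.raises(ValueError):
        analysis.weight_map(net, "DLPFC->GPi")


def test_trained_weight_maps_point_at_the_correct_action(trained_window):
    """After training, the direct-pathway and premotor rows peak at a
    reward-improving action while the indirect-pathway rows peak at a
    punished one."""
    net, traces = trained_window
    oracle = WindowWorld()
    visits = {}
    for tr in traces:
        for e in tr.events:
            rec = visits.setdefault(e.state, {"correct": 0, "wrong": 0})
            rec["correct" if e.correct else "wrong"] += 1
    d1 = analysis.weight_map(net, "DLPFC->StrD1")
    d2 = analysis.weight_map(net, "DLPFC->StrD2")
    pm = analysis.weight_map(net, "DLPFC->PM")
    for state, rec in visits.items():
        dx, dy = canonical_cells()[state]
        correct = oracle.correct_actions(dx, dy)
        if rec["correct"] >= 4:
            assert int(np.argmax(d1[state])) in correct, state
            assert int(np.argmax(pm[state])) in correct, state
        if rec["wrong"] >= 1 and rec["correct"] >= 4:
            assert int(np.argmax(d2[state])) not in correct, state


def test_rate_computation_conserves_spike_counts():
    env = ObstacleWorld(seed=0)
    env.reset()
    net = build_network(2, 2, seed=0)
    tr = run_episode(env, net, RewardConfig.obstacle_defaults(), max_decisions=5)
    rates = analysis.firing_rates(tr, "StrD1", baseline=0.0)
    counts = np.array([e.decision_counts["StrD1"] for e in tr.events])
    ticks = np.array([max(e.latency, 1) for e in tr.events])
    np.testing.assert_allclose(rates * ticks, counts)
    # default baseline is the first decision's rate
    assert analysis.firing_rates(tr, "StrD1")[0] == 0.0


def test_striatal_rates_track_the_last_feedback_valence():
    """After a punished decision the direct pathway quiets and the
    indirect pathway rises on the next same-state decision; a rewarded
    decision does the reverse (aggregate over seeds)."""
    agree = total = 0
    for seed in range(10):
        env = ObstacleWorld(seed=seed)
        env.reset()
        net = _make_net(2, 2, CircuitConfig(), seed, "full")
        tr = run_episode(env, net, RewardConfig.obstacle_defaults(), max_decisions=50)
        for e0, e1 in zip(tr.events, tr.events[1:]):
            if e0.state != e1.state:
                continue
            d1_0 = e0.decision_counts["StrD1"] / max(e0.latency, 1)
            d1_1 = e1.decision_counts["StrD1"] / max(e1.latency, 1)
            d2_0 = e0.decision_counts["StrD2"] / max(e0.latency, 1)
            d2_1 = e1.decision_counts["StrD2"] / max(e1.latency, 1)
            if e0.r_end <= 0:
                ok = d1_1 <= d1_0 and d2_1 >= d2_0
            else:
                ok = d1_1 >= d1_0 and d2_1 <= d2_0
            agree += ok
            total += 1
    assert total >= 8
    assert agree / total >= 0.8


def test_latency_statistics():
    env = ObstacleWorld(seed=2)
    env.reset()
    net = build_network(2, 2, seed=2)
    tr = run_episode(env, net, RewardConfig.obstacle_defaults(), max_decisions=4)
    with pytest.warns(UserWarning):
        mean = analysis.latency_stats(tr, n_decisions=100)
    assert mean == pytest.approx(np.mean(tr.latencies))
    assert analysis.latency_stats(tr, n_decisions=1) == tr.events[0].latency
    with pytest.raises(ValueError):
        analysis.latency_stats([], n_decisions=10)


def test_valence_channels_specialise_onto_their_pathways(trained_window):
    """Training strengthens LOFC->StrD2 over LOFC->StrD1 and
    MOFC->StrD1 over MOFC->StrD2."""
    net, traces = trained_window
    traj = analysis.ofc_weight_trajectories(traces)
    last = traj.iloc[-1]
    assert last["lofc_strd2"] > last["lofc_strd1"]
    assert last["mofc_strd1"] > last["mofc_strd2"]


def test_ofc_trajectories_require_learning_snapshots():
    env = ObstacleWorld(seed=0)
    env.reset()
    net = build_network(2, 2, seed=0)
    tr = run_episode(env, net, RewardConfig.obstacle_defaults(), max_decisions=2, learn=False)
    with pytest.raises(ValueError):
        analysis.ofc_weight_trajectories(tr)


def test_valence_channels_raise_striatal_feedback_activity():
    """With the orbitofrontal channels active, striatal populations fire
    more during the feedback window than in the ablated variant on
    matched seeds."""
    totals = {}
    for variant in ("full", "no_ofc"):
        tot = 0
        for seed in range(5):
            env = ObstacleWorld(seed=seed)
            env.reset()
            net = _make_net(2, 2, CircuitConfig(), seed, variant)
            tr = run_episode(env, net, RewardConfig.obstacle_defaults(), max_decisions=20)
            for e in tr.events:
                tot += e.feedback_counts["StrD1"] + e.feedback_counts["StrD2"]
        totals[variant] = tot
    assert totals["full"] > totals["no_ofc"]
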