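import numpy as np
import pytest
from scipy import stats

from corticobg.circuit import (
    CircuitConfig,
    EXCITATORY,
    INHIBITORY,
    NetworkState,
    build_network,
    connection_mask,
    connection_table,
    load_weights_hdf5,
    population_sizes,
    run_decision,
    save_hdf5,
)

INHIBITORY_CONNECTIONS = {
    "strd1_gpi", "strd2_gpe", "gpe_gpi", "gpe_stn", "gpi_thal", "pm_pm",
}


@pytest.mark.parametrize(
    "ns, na, strd, others",
    [(14, 4, 56, 4), (2, 2, 4, 2), (1, 2, 2, 2)],
)
def test_population_sizes_follow_the_state_action_space(ns, na, strd, others):
    sizes = population_sizes(ns, na)
    assert sizes["DLPFC"] == ns
    assert sizes["StrD1"] == sizes["StrD2"] == strd
    for pop in ("PM", "Thalamus", "GPi", "GPe"):
        assert sizes[pop] == others
    assert sizes["STN"] == sizes["VTA"] == 2
    assert sizes["MOFC"] == sizes["LOFC"] == 1
    net = build_network(ns, na, seed=0)
    assert net.n_total == sum(sizes.values())


def test_degenerate_sizes_are_rejected():
    with pytest.raises(ValueError):
        build_network(0, 4)
    with pytest.raises(ValueError):
        build_network(14, 1)
    with pytest.raises(ValueError):
        build_network(14, 4, CircuitConfig().with_gains(nonexistent=1.0))
    with pytest.raises(ValueError):
        build_network(14, 4, ablate=("no_cerebellum",))


def test_connection_signs_match_the_anatomy():
    for spec in connection_table():
        expected = INHIBITORY if spec.name in INHIBITORY_CONNECTIONS else EXCITATORY
        assert spec.sign == expected, spec.name


def test_specific_patterns_route_pairs_correctly():
    ns, na = 3, 2
    sizes = population_sizes(ns, na)
    specs = {c.name: c for c in connection_table()}
    m = connection_mask(specs["dlpfc_strd1"], sizes, ns, na)
    for s in range(ns):
        assert set(np.flatnonzero(m[s])) == {s * na, s * na + 1}
    m = connection_mask(specs["pm_strd1"], sizes, ns, na)
    for a in range(na):
        assert set(np.flatnonzero(m[a])) == {s * na + a for s in range(ns)}
    m = connection_mask(specs["strd1_gpi"], sizes, ns, na)
    for s in range(ns):
        for a in range(na):
            assert set(np.flatnonzero(m[s * na + a])) == {a}
    m = connection_mask(specs["pm_pm"], sizes, ns, na)
    assert np.all(np.diag(m) == 0) and np.all(m + np.eye(na) == 1)


def test_assembled_matrix_respects_signs(trained_window):
    """Excitatory blocks never acquire negative entries through learning
    and inhibitory blocks never positive ones."""
    net, _ = trained_window
    for name, spec in net.specs.items():
        w = net.weights[name]
        assert np.all(w >= 0), name  # stored magnitudes
        so = net.offsets[spec.source]
        to = net.offsets[spec.target]
        block = net._G[so:so + w.shape[0], to:to + w.shape[1]]
        if spec.sign == EXCITATORY:
            assert np.all(block >= 0), name
        else:
            assert np.all(block <= 0), name


def test_learning_never_creates_new_synapses(trained_window):
    net, _ = trained_window
    for name in net.weights:
        outside = net.weights[name][net.masks[name] == 0]
        assert np.all(outside == 0), name


def test_first_spike_selection_follows_the_strong_channel():
    net = build_network(14, 4, seed=2)
    s, na = 5, 4
    net.weights["dlpfc_strd1"][s, s * na:(s + 1) * na] = [1, 1, 8, 1]
    net._assemble()
    action, latency, rec = run_decision(net, s)
    assert action == 2 and not rec.timed_out
    # a strongly favoured direct cortico-premotor row also wins
    net = build_network(14, 4, seed=2)
    net.weights["dlpfc_pm"][s] = [0.8, 0.8, 0.8, 10.0]
    net._assemble()
    action, latency, rec = run_decision(net, s)
    assert action == 3


def test_selection_is_deterministic_given_the_seed():
    a1, l1, _ = run_decision(build_network(14, 4, seed=11), 3)
    a2, l2, _ = run_decision(build_network(14, 4, seed=11), 3)
    assert (a1, l1) == (a2, l2)


def test_silent_network_falls_back_to_a_seeded_draw():
    net = build_network(14, 4, seed=4)
    for name in net.weights:
        net.weights[name][:] = 0.0
    net._assemble()
    action, latency, rec = run_decision(net, 0, max_ticks=200)
    assert rec.timed_out
    assert 0 <= action < 4
    assert latency == 200


def test_invalid_state_is_rejected():
    net = build_network(2, 2, seed=0)
    with pytest.raises(ValueError):
        net.decide(5)
    with pytest.raises(ValueError):
        net.deliver_feedback(1.0, None)


def test_reward_feedback_shifts_the_pathway_balance():
    """Repeated reward strengthens the executed pair's direct-pathway
    weight and weakens its indirect-pathway weight; punishment mirrors."""
    net = build_network(14, 4, seed=1)
    s = 3
    rec = net.decide(s)
    pair = s * 4 + rec.action
    w1 = [net.weights["dlpfc_strd1"][s, pair]]
    w2 = [net.weights["dlpfc_strd2"][s, pair]]
    mofc_before = net.weights["mofc_strd1"].sum()
    for _ in range(3):
        net.deliver_feedback(+100.0, rec)
        w1.append(net.weights["dlpfc_strd1"][s, pair])
        w2.append(net.weights["dlpfc_strd2"][s, pair])
        rec = net.decide(s)
        rec.action = pair % 4  # keep reinforcing the same pair
    assert all(b > a for a, b in zip(w1, w1[1:]))
    assert all(b < a for a, b in zip(w2, w2[1:]))
    # reward feedback also strengthens the positive-valence channel
    assert net.weights["mofc_strd1"].sum() >= mofc_before

    net = build_network(14, 4, seed=1)
    rec = net.decide(s)
    pair = s * 4 + rec.action
    d1_0 = net.weights["dlpfc_strd1"][s, pair]
    d2_0 = net.weights["dlpfc_strd2"][s, pair]
    net.deliver_feedback(-100.0, rec)
    assert net.weights["dlpfc_strd1"][s, pair] < d1_0
    assert net.weights["dlpfc_strd2"][s, pair] > d2_0


def test_previous_reward_raises_repeat_probability():
    """Across seeds, an action is far more likely to be repeated after a
    reward than after a punishment (one-sided Fisher test)."""
    repeats = {"reward": 0, "punish": 0}
    n = 20
    for seed in range(n):
        for valence, key in ((+500.0, "reward"), (-500.0, "punish")):
            net = build_network(14, 4, seed=seed)
            first = net.decide(3)
            net.deliver_feedback(valence, first)
            second = net.decide(3)
            repeats[key] += second.action == first.action
    table = [
        [repeats["reward"], n - repeats["reward"]],
        [repeats["punish"], n - repeats["punish"]],
    ]
    _, p = stats.fisher_exact(table, alternative="greater")
    assert p < 0.05


@pytest.mark.parametrize(
    "ablation, silent_pops",
    [("no_stn", ("GPe", "GPi")), ("no_dlpfc_thalamus", ("Thalamus",))],
)
def test_removing_the_sole_excitatory_input_silences_the_target(ablation, silent_pops):
    net = build_network(14, 4, seed=1, ablate=(ablation,))
    net.decide(3)
    raster = net.spike_raster()
    for pop in silent_pops:
        assert raster[:, net.pop_slice(pop)].sum() == 0


def test_weight_snapshot_round_trips_through_hdf5(tmp_path):
    net = build_network(2, 2, seed=5)
    net.decide(0)
    path = tmp_path / "net.h5"
    save_hdf5(net, path, spikes=net.spike_raster())
    other = build_network(2, 2, seed=99)
    load_weights_hdf5(other, path)
    for name in net.weights:
        np.testing.assert_array_equal(net.weights[name], other.weights[name])
    with pytest.raises(ValueError):
        load_weights_hdf5(build_network(14, 4, seed=0), path)
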