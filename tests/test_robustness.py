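import numpy as np
import pandas as pd
import pytest

from ccinet.niche import niche_table
from ccinet.robustness import (
    correlate_T_with_niche,
    removal_order,
    robustness_T,
    robustness_suite,
    simulate_extinctions,
)
from ccinet.synthetic import generate_nested_multilayer
from conftest import make_net


def test_degree_order_with_identifier_tie_break():
    layer = np.zeros((4, 6), dtype=int)
    layer[0, :5] = 1  # a: 5
    layer[1, :3] = 1  # b: 3
    layer[2, :3] = 1  # c: 3
    layer[3, :1] = 1  # d: 1
    order = removal_order(layer, ["a", "b", "c", "d"], "degree")
    assert order == ["a", "b", "c", "d"]


def test_module_first_order():
    layer = np.zeros((4, 6), dtype=int)
    layer[0, :4] = 1  # a
    layer[1, :3] = 1  # b
    layer[2, :2] = 1  # c
    layer[3, :1] = 1  # d
    labels = [1, 2, 1, 2]  # modules {a,c} and {b,d}
    order = removal_order(layer, ["a", "b", "c", "d"], "module_first_A", group_labels=labels)
    assert order == ["a", "c", "b", "d"]
    order_b = removal_order(layer, ["a", "b", "c", "d"], "module_first_B", group_labels=labels)
    assert order_b == ["b", "d", "a", "c"]


def test_modular_scenario_requires_labels():
    layer = np.ones((2, 2), dtype=int)
    with pytest.raises(ValueError, match="group labels"):
        removal_order(layer, ["a", "b"], "module_first_A")


def test_random_order_reproducible():
    layer = np.ones((5, 3), dtype=int)
    ids = list("abcde")
    o1 = removal_order(layer, ids, "random", seed=3)
    o2 = removal_order(layer, ids, "random", seed=3)
    assert o1 == o2
    assert sorted(o1) == ids


def test_extinction_curve_hand_example():
    """chap1-{c1,c2,c3}, chap2-{c1}: removing chap1 leaves 1/3 of clients."""
    layer = np.array([[1, 1, 1], [1, 0, 0]])
    curve = simulate_extinctions(layer, ["chap1", "chap2"], ["chap1", "chap2"])
    np.testing.assert_allclose(curve.x, [0, 0.5, 1.0])
    np.testing.assert_allclose(curve.y, [1.0, 1 / 3, 0.0])
    assert robustness_T(curve) == pytest.approx(5 / 12)


def test_complete_bipartite_robustness_closed_form():
    for N in (2, 15):
        layer = np.ones((N, 10), dtype=int)
        ids = [f"c{i}" for i in range(N)]
        T = robustness_T(simulate_extinctions(layer, ids, ids))
        assert T == pytest.approx((2 * N - 1) / (2 * N))


def test_immediate_collapse_T():
    """y drops to 0 after the first of two removals: T = 0.25."""
    layer = np.array([[1, 1], [0, 0]])
    # chap2 has no links: removing chap1 first kills every client
    with pytest.raises(ValueError):
        simulate_extinctions(np.zeros((2, 2), int), ["a", "b"], ["a", "b"])
    curve = simulate_extinctions(layer, ["a", "b"], ["a", "b"])
    np.testing.assert_allclose(curve.y, [1.0, 0.0, 0.0])
    assert robustness_T(curve) == pytest.approx(0.25)


def test_exclusive_clients_partition_the_decline():
    layer = np.zeros((3, 6), dtype=int)
    layer[0, :3] = 1
    layer[1, 3:5] = 1
    layer[2, 5] = 1
    ids = ["a", "b", "c"]
    curve = simulate_extinctions(layer, ids, ids)
    np.testing.assert_allclose(curve.y, [1.0, 0.5, 1 / 6, 0.0])


def test_survival_is_monotone_non_increasing():
    rng = np.random.default_rng(0)
    layer = (rng.random((8, 50)) < 0.2).astype(int)
    layer[0, 0] = 1  # ensure non-empty
    ids = [f"c{i}" for i in range(8)]
    order = removal_order(layer, ids, "random", seed=1)
    curve = simulate_extinctions(layer, ids, order)
    assert np.all(np.diff(curve.y) <= 1e-12)
    assert curve.y[-1] == 0.0


def test_T_invariant_to_client_relabeling():
    rng = np.random.default_rng(2)
    layer = (rng.random((5, 30)) < 0.3).astype(int)
    ids = list("abcde")
    order = removal_order(layer, ids, "degree")
    T1 = robustness_T(simulate_extinctions(layer, ids, order))
    T2 = robustness_T(simulate_extinctions(layer[:, rng.permutation(30)], ids, order))
    assert T1 == pytest.approx(T2)


def test_redundant_duplicate_row_never_decreases_random_T():
    rng = np.random.default_rng(3)
    layer = (rng.random((5, 40)) < 0.25).astype(int)
    layer[0, 0] = 1
    aug = np.vstack([layer, layer[0]])  # duplicate the first chaperone
    ids = list("abcde")
    ids_aug = ids + ["f"]

    def mean_random_T(lay, names, reps=40):
        out = []
        for s in range(reps):
            order = removal_order(lay, names, "random", seed=s)
            out.append(robustness_T(simulate_extinctions(lay, names, order)))
        return np.mean(out)

    assert mean_random_T(aug, ids_aug) >= mean_random_T(layer, ids) - 0.01


def test_attack_vs_tolerance_ordering():
    """Most-to-least-connected removal collapses faster than least-to-most."""
    net = generate_nested_multilayer(10, 150, 3, seed=4)
    for a in range(3):
        layer = net.incidence[:, :, a]
        attack = removal_order(layer, net.chaperone_ids, "degree")
        T_attack = robustness_T(simulate_extinctions(layer, net.chaperone_ids, attack))
        T_tolerant = robustness_T(
            simulate_extinctions(layer, net.chaperone_ids, attack[::-1])
        )
        assert T_attack <= T_tolerant + 1e-12


def test_suite_shape_and_degree_below_random():
    """4 scenarios per layer; degree-targeted removal is never more robust than
    random removal on heterogeneous layers (attack-sensitivity)."""
    net = generate_nested_multilayer(12, 200, 4, seed=5)
    labels = np.array([0] * 6 + [1] * 6)
    table = robustness_suite(net, labels, n_random_reps=30, seed=6)
    assert len(table) == 4 * net.n_layers
    for lid, sub in table.groupby("layer"):
        t = sub.set_index("scenario")["T"]
        assert t["degree"] <= t["random"] + 1e-9


def test_identical_layers_give_identical_T_rows(small_random_net):
    inc = np.repeat(small_random_net.incidence[:, :, :1], 3, axis=2)
    net = make_net(inc)
    labels = np.array([0, 0, 0, 1, 1, 1])
    table = robustness_suite(net, labels, n_random_reps=5, seed=7)
    fixed = table[table.scenario != "random"]
    pivot = fixed.pivot(index="scenario", columns="layer", values="T")
    assert (pivot.nunique(axis=1) == 1).all()


def test_correlate_T_with_niche_density_gradient():
    """Denser layers are more robust under random removal: positive rho."""
    rng = np.random.default_rng(8)
    densities = [0.05, 0.1, 0.2, 0.35, 0.5]
    inc = np.stack(
        [(rng.random((10, 100)) < d).astype(np.int8) for d in densities], axis=2
    )
    net = make_net(inc)
    labels = np.array([0] * 5 + [1] * 5)
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        table = robustness_suite(net, labels, n_random_reps=20, seed=9)
        tab = niche_table(net)
        corr = correlate_T_with_niche(table, tab)
    rho_random = corr.set_index("scenario").loc["random", "rho"]
    assert rho_random > 0


def test_correlate_requires_three_layers(small_random_net):
    net = make_net(small_random_net.incidence[:, :, :2])
    tab = niche_table(net)
    T = pd.DataFrame({"layer": ["L0", "L1"], "scenario": ["degree"] * 2, "T": [0.5, 0.6]})
    with pytest.raises(ValueError):
        correlate_T_with_niche(T, tab)
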