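import numpy as np
import pytest

from ccinet.sbm import (
    MembershipModel,
    coassignment_agreement,
    expected_edges,
    fit_multitensor,
    hard_assignments,
    select_K,
)
from ccinet.synthetic import generate_sbm_multilayer
from conftest import make_net


def _model(u, v, w, K):
    return MembershipModel(
        u=np.asarray(u, float), v=np.asarray(v, float), w=np.asarray(w, float),
        K=K, log_likelihood=0.0, BIC=0.0, n_restarts=0, converged=True,
    )


def test_expected_edges_scalar_reduction():
    m = _model(np.ones((3, 1)), np.ones((4, 1)), np.full((1, 1, 2), 0.3), K=1)
    np.testing.assert_allclose(expected_edges(m), 0.3)


def test_expected_edges_zero_membership_row():
    u = np.array([[1.0, 0.0], [0.0, 0.0]])
    v = np.ones((3, 2))
    w = np.ones((2, 2, 1))
    m = _model(u, v, w, K=2)
    M = expected_edges(m)
    assert np.all(M[1] == 0)


def test_expected_edges_hand_expansion():
    """u=(1,0), v=(0,1), w=[[a,b],[c,d]] selects entry b."""
    u = np.array([[1.0, 0.0]])
    v = np.array([[0.0, 1.0]])
    w = np.array([[[0.1], [0.7]], [[0.3], [0.9]]])  # w[k,l,0]; b = w[0,1] = 0.7
    m = _model(u, v, w, K=2)
    assert expected_edges(m)[0, 0, 0] == pytest.approx(0.7)


@pytest.mark.parametrize("seed", range(20))
def test_em_loglikelihood_never_decreases(seed):
    """EM ascent on 20 random instances, likelihood checked every iteration."""
    rng = np.random.default_rng(seed)
    inc = (rng.random((6, 25, 2)) < 0.3).astype(np.int8)
    if not inc.any():
        inc[0, 0, 0] = 1
    net = make_net(inc)
    with np.errstate(all="ignore"):
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = fit_multitensor(
                net, K=3, n_restarts=1, seed=seed, check_every=1, max_iter=60
            )
    diffs = np.diff(model.loglik_trace)
    assert np.all(diffs >= -1e-10)


def test_k1_fit_approximates_layer_densities():
    rng = np.random.default_rng(5)
    dens = [0.1, 0.4]
    inc = np.stack(
        [(rng.random((10, 200)) < d).astype(np.int8) for d in dens], axis=2
    )
    net = make_net(inc)
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = fit_multitensor(net, K=1, n_restarts=2, seed=0)
    M = expected_edges(model)
    for a, d in enumerate(dens):
        assert M[:, :, a].mean() == pytest.approx(inc[:, :, a].mean(), rel=0.05)


def test_planted_two_group_recovery(planted_net):
    """High-contrast planted groups recovered with co-assignment agreement >= 0.9.

    Nodes whose true membership is genuinely mixed (argmax weight < 0.75)
    have no well-defined hard label, so agreement is scored on the near-hard
    nodes only.
    """
    net, truth = planted_net
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = fit_multitensor(net, K=2, n_restarts=3, seed=0)
    hard_u = truth.true_memberships_u.max(axis=1) >= 0.75
    hard_v = truth.true_memberships_v.max(axis=1) >= 0.75
    agree_u = coassignment_agreement(
        hard_assignments(model, "chaperones")[hard_u], truth.hard_labels_u[hard_u]
    )
    agree_v = coassignment_agreement(
        hard_assignments(model, "clients")[hard_v], truth.hard_labels_v[hard_v]
    )
    assert agree_u >= 0.9
    assert agree_v >= 0.9


def test_duplicating_a_layer_keeps_assignments():
    net, truth = generate_sbm_multilayer(10, 150, 2, K=2, affinity_contrast=10, seed=21)
    dup_inc = np.concatenate([net.incidence, net.incidence[:, :, -1:]], axis=2)
    dup = make_net(dup_inc)
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        m1 = fit_multitensor(net, K=2, n_restarts=3, seed=1)
        m2 = fit_multitensor(dup, K=2, n_restarts=3, seed=1)
    assert (
        coassignment_agreement(hard_assignments(m1), hard_assignments(m2)) == 1.0
    )


def test_bic_formula_and_trace(planted_net):
    net, _ = planted_net
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        best, trace = select_K(net, 2, 4, n_restarts=1, max_iter=100, seed=3)
    assert len(trace) == 3
    for K, bic, ll in trace:
        p = K * (net.n_chaperones + net.n_clients) + K * K * net.n_layers
        n = net.n_chaperones * net.n_clients * net.n_layers
        assert bic == pytest.approx(-2 * ll + p * np.log(n))
    assert best.BIC == min(b for _, b, _ in trace)


def test_hard_assignment_tie_breaks_to_lowest_index():
    m = _model(np.array([[0.5, 0.5], [0.1, 0.9]]), np.ones((2, 2)), np.ones((2, 2, 1)), K=2)
    labels = hard_assignments(m)
    assert labels.tolist() == [0, 1]


def test_hard_assignment_zero_row_unassigned():
    m = _model(np.array([[0.0, 0.0], [1.0, 0.0]]), np.ones((2, 2)), np.ones((2, 2, 1)), K=2)
    with pytest.warns(UserWarning, match="unassigned"):
        labels = hard_assignments(m)
    assert labels[0] == -1


def test_coassignment_agreement_label_permutation_invariant():
    a = np.array([0, 0, 1, 1])
    b = np.array([1, 1, 0, 0])
    assert coassignment_agreement(a, b) == 1.0
    c = np.array([0, 1, 0, 1])
    assert coassignment_agreement(a, c) < 1.0


def test_empty_network_rejected():
    net = make_net(np.zeros((2, 3, 1), dtype=np.int8))
    with pytest.raises(ValueError, match="empty"):
        fit_multitensor(net, K=1)


def test_model_json_round_trip(planted_net):
    net, _ = planted_net
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        m = fit_multitensor(net, K=2, n_restarts=1, max_iter=50, seed=0)
    back = MembershipModel.from_dict(m.to_dict())
    np.testing.assert_allclose(back.u, m.u)
    np.testing.assert_allclose(back.w, m.w)
    assert back.K == m.K
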