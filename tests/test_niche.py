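import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from ccinet.niche import (
    expression_summary,
    layer_similarity,
    niche_table,
    partner_fidelity,
    spearman_with_bonferroni,
    within_layer_overlap,
)
from conftest import make_net


def test_niche_table_formula_example():
    """L=3 links in one layer out of P_c=10 potential clients gives R=0.3."""
    inc = np.zeros((1, 10, 2), dtype=np.int8)
    inc[0, :3, 0] = 1
    inc[0, :10, 1] = 1
    tab = niche_table(make_net(inc))
    assert tab.per_chaperone.loc[0, "P_c"] == 10
    assert tab.per_chaperone.loc[0, "S_c"] == pytest.approx(1.0)
    row = tab.per_layer.query("layer == 'L0'").iloc[0]
    assert row["L_ca"] == 3
    assert row["R_ca"] == pytest.approx(0.3)


def test_single_layer_realized_niche_is_one():
    rng = np.random.default_rng(0)
    inc = (rng.random((5, 30, 1)) < 0.4).astype(np.int8)
    tab = niche_table(make_net(inc))
    connected = tab.per_layer.dropna(subset=["R_ca"])
    assert np.allclose(connected["R_ca"], 1.0)


def test_isolated_chaperone_flagged_with_nan_ratios():
    inc = np.zeros((2, 5, 2), dtype=np.int8)
    inc[0, 0, 0] = 1
    with pytest.warns(UserWarning, match="no links"):
        tab = niche_table(make_net(inc))
    assert tab.isolated == ["h1"]
    assert np.isnan(tab.per_layer.query("chaperone == 'h1'")["R_ca"]).all()


def test_union_invariant_and_layer_bound(small_random_net):
    tab = niche_table(small_random_net)
    for c in small_random_net.chaperone_ids:
        p_c = int(tab.per_chaperone.set_index("chaperone").loc[c, "P_c"])
        max_l = tab.per_layer.query("chaperone == @c")["L_ca"].max()
        assert max_l <= p_c


def test_partner_fidelity_counts_at_study_scale():
    rng = np.random.default_rng(1)
    inc = (rng.random((15, 40, 12)) < 0.3).astype(np.int8)
    sim = partner_fidelity(make_net(inc))
    assert sim.between_layers.groupby("chaperone").size().eq(66).all()
    assert len(sim.between_layers) == 990


def test_partner_fidelity_jaccard_formula():
    """Sets {A,B,C} vs {B,C,D} give J = 2/4."""
    inc = np.zeros((1, 4, 2), dtype=np.int8)
    inc[0, [0, 1, 2], 0] = 1
    inc[0, [1, 2, 3], 1] = 1
    sim = partner_fidelity(make_net(inc))
    assert sim.between_layers["J_c_ab"].iloc[0] == pytest.approx(0.5)


def test_identical_layers_give_unit_fidelity(small_random_net):
    inc = np.repeat(small_random_net.incidence[:, :, :1], 3, axis=2)
    sim = partner_fidelity(make_net(inc))
    linked = sim.fidelity.dropna(subset=["J_c"])
    assert np.allclose(linked["J_c"], 1.0)


def test_empty_empty_layer_pairs_are_excluded_from_median():
    inc = np.zeros((1, 3, 3), dtype=np.int8)
    inc[0, 0, 0] = 1  # layers 1, 2 empty for this chaperone
    sim = partner_fidelity(make_net(inc))
    # pairs (0,1) and (0,2): J = 0; pair (1,2): undefined
    assert sim.between_layers["J_c_ab"].isna().sum() == 1
    assert sim.fidelity["J_c"].iloc[0] == pytest.approx(0.0)


def test_within_layer_overlap_counts_and_self_exclusion():
    rng = np.random.default_rng(2)
    inc = (rng.random((15, 40, 12)) < 0.3).astype(np.int8)
    sim = within_layer_overlap(make_net(inc))
    assert len(sim.within_layer) == 1260
    per_layer = sim.within_layer.groupby("layer").size()
    assert per_layer.eq(105).all()
    assert not (sim.within_layer["chaperone_x"] == sim.within_layer["chaperone_y"]).any()


def test_within_layer_disjoint_sets_give_zero():
    inc = np.zeros((2, 4, 1), dtype=np.int8)
    inc[0, :2, 0] = 1
    inc[1, 2:, 0] = 1
    sim = within_layer_overlap(make_net(inc))
    assert sim.within_layer["J_xy_a"].iloc[0] == pytest.approx(0.0)


@settings(max_examples=25, deadline=None)
@given(
    arrays(np.int8, (4, 12, 3), elements=st.integers(min_value=0, max_value=1))
)
def test_jaccard_symmetry_under_row_swap(inc):
    """J(x, y) = J(y, x): swapping two chaperones permutes but preserves values."""
    net = make_net(inc)
    swapped = inc.copy()
    swapped[[0, 1]] = swapped[[1, 0]]
    a = within_layer_overlap(net).within_layer
    b = within_layer_overlap(make_net(swapped)).within_layer
    pair_a = a.query("chaperone_x == 'h0' and chaperone_y == 'h1'")["J_xy_a"].to_numpy()
    pair_b = b.query("chaperone_x == 'h0' and chaperone_y == 'h1'")["J_xy_a"].to_numpy()
    np.testing.assert_array_equal(pair_a, pair_b)


def test_layer_similarity_examples():
    inc = np.zeros((2, 3, 3), dtype=np.int8)
    inc[0, 0, 0] = inc[0, 1, 0] = 1  # layer 0: {e1, e2}
    inc[0, 1, 1] = inc[1, 2, 1] = 1  # layer 1: {e2, e3}
    inc[:, :, 2] = inc[:, :, 0]  # layer 2 duplicates layer 0
    sim = layer_similarity(make_net(inc))
    assert sim.iloc[0, 1] == pytest.approx(1 / 3)
    assert sim.iloc[0, 2] == pytest.approx(1.0)
    assert np.allclose(np.diag(sim), 1.0)
    np.testing.assert_allclose(sim.to_numpy(), sim.to_numpy().T)


def test_spearman_bonferroni_arithmetic():
    x = np.arange(6, dtype=float)
    rho, p_raw, p_corr = spearman_with_bonferroni(x, x**3, n_tests=15)
    assert rho == pytest.approx(1.0)
    assert p_corr == pytest.approx(min(1.0, p_raw * 15))
    # cap at 1
    rng = np.random.default_rng(3)
    _, p_raw2, p_corr2 = spearman_with_bonferroni(rng.random(10), rng.random(10), n_tests=1000)
    assert p_corr2 == 1.0


def test_spearman_constant_vector_flagged():
    with pytest.warns(UserWarning, match="constant"):
        rho, p, pc = spearman_with_bonferroni(np.ones(5), np.arange(5.0))
    assert np.isnan(rho)


def test_expression_summary_log10_of_median():
    from ccinet.core import ExpressionMatrix

    expr = ExpressionMatrix(
        gene_ids=["c1", "c2", "c3"],
        sample_ids=["s1", "s2", "s3"],
        values=np.array([[100.0, 100, 100], [1.0, 10, 100], [0.0, 0, 0]]),
        layer_id="L",
    )
    with pytest.warns(UserWarning, match="zero median"):
        df = expression_summary([expr], ["c1", "c2", "c3"])
    vals = df.set_index("chaperone")["log10_median"]
    assert vals["c1"] == pytest.approx(2.0)
    assert vals["c2"] == pytest.approx(1.0)
    assert np.isnan(vals["c3"])


def test_fidelity_correlates_with_realized_niche_on_shared_structure(planted_net):
    """With affinities shared across layers, median fidelity and median realized
    niche correlate positively across chaperones (sign property)."""
    net, _ = planted_net
    fid = partner_fidelity(net).fidelity.set_index("chaperone")["J_c"]
    tab = niche_table(net)
    med_R = tab.per_layer.groupby("chaperone", sort=False)["R_ca"].median()
    rho, _, _ = spearman_with_bonferroni(
        fid.reindex(med_R.index).to_numpy(), med_R.to_numpy(), n_tests=1
    )
    assert rho > 0
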