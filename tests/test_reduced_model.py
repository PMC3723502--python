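"""The mixture-of-Delta-rules model: transitions, equivalences, dynamics."""

import dataclasses

import numpy as np
import pytest
from helpers import delta_rule, two_node_reference

from deltamix import (
    Bernoulli,
    FullModel,
    GaussianMean,
    HazardSpec,
    NodeSet,
    ReducedModel,
    ReducedModelState,
    build_transition_prior,
    effective_learning_rate,
    log_spaced_nodes,
    sample_dataset,
)


def nodes(*l, chi0=0.0, nu0=1.0):
    return NodeSet(np.array(l, dtype=float), chi0, nu0)


class TestTransitionPrior:
    def test_adjacent_integer_nodes(self):
        tp = build_transition_prior(nodes(1.0, 2.0), h=0.1)
        np.testing.assert_allclose(tp.matrix, [[0.1, 0.9], [0.1, 0.9]])

    def test_spacing_two_advances_half_the_time(self):
        tp = build_transition_prior(nodes(1.0, 3.0), h=0.0)
        np.testing.assert_allclose(tp.matrix[0], [0.5, 0.5])
        # expected no-change increase in run-length is exactly 1
        assert tp.advance[0] * (3.0 - 1.0) == pytest.approx(1.0)

    def test_single_node_self_loops(self):
        tp = build_transition_prior(nodes(4.0), h=0.3)
        np.testing.assert_allclose(tp.matrix, [[1.0]])

    @pytest.mark.parametrize("l", [(1, 2, 5, 30), (2.5, 4.0, 10.0), (1, 7, 8)])
    def test_unit_expected_increase_for_wide_spacing(self, l):
        """Interior nodes with spacing >= 1 grow by exactly 1 in expectation."""
        tp = build_transition_prior(nodes(*l), h=0.17)
        spacing = np.diff(np.asarray(l, dtype=float))
        for i, s in enumerate(spacing):
            assert s >= 1
            assert tp.advance[i] * s == pytest.approx(1.0, abs=1e-15)

    def test_sub_unit_spacing_caps_advance(self):
        tp = build_transition_prior(nodes(1.0, 1.5), h=0.0)
        assert tp.advance[0] == 1.0  # expected increase 0.5 < 1, under-matched

    def test_rows_are_distributions(self):
        tp = build_transition_prior(nodes(1.0, 2.7, 9.0), h=0.25)
        np.testing.assert_allclose(tp.matrix.sum(axis=1), 1.0, atol=1e-15)
        assert (tp.matrix >= 0).all()

    def test_unordered_nodes_rejected(self):
        with pytest.raises(ValueError):
            nodes(3.0, 2.0)
        with pytest.raises(ValueError):
            nodes(-1.0, 2.0)


class TestStep:
    def test_one_node_is_plain_delta_rule(self, rng):
        """A single node reduces exactly to a Delta rule with rate 1/(l+nu0)."""
        fam = GaussianMean(sigma=1.0)
        x = rng.normal(0, 2, 300)
        for l1, nu0 in [(4.0, 1e-12), (2.0, 0.5)]:
            m = ReducedModel(fam, nodes(l1, chi0=0.0, nu0=nu0), h=0.3)
            preds, _ = m.run(x)
            ref = delta_rule(x, 1.0 / (l1 + nu0), 0.0)
            np.testing.assert_allclose(preds, ref, atol=1e-14)

    def test_two_node_matches_handcoded_recursion(self, rng):
        fam = GaussianMean(sigma=0.7)
        x = rng.normal(1, 2, 1000)
        l1, l2, h = 2.0, 12.0, 0.08
        m = ReducedModel(fam, nodes(l1, l2, chi0=0.5, nu0=0.5), h=h)
        preds, _ = m.run(x)
        ref = two_node_reference(x, fam, 0.5, 0.5, l1, l2, h)
        np.testing.assert_allclose(preds, ref, atol=1e-12)

    def test_delta_update_arithmetic(self):
        fam = GaussianMean(sigma=1.0)
        m = ReducedModel(fam, nodes(1.0, chi0=0.0, nu0=1.0), h=0.0)  # alpha = 0.5
        state = m.init_state()
        new = m.step(state, 10.0)
        assert new.mu[0] == pytest.approx(5.0)

    def test_learning_rate_capped_at_one(self):
        ns = nodes(0.3, 2.0, chi0=0.0, nu0=0.1)
        assert ns.learning_rates[0] == 1.0

    def test_normalization_every_step(self, rng):
        fam = Bernoulli()
        m = ReducedModel(fam, nodes(1, 5, 25, chi0=1.0, nu0=2.0), h=0.1)
        state = m.init_state()
        for x in (rng.random(200) < 0.3).astype(float):
            state = m.step(state, x)
            assert abs(state.w.sum() - 1.0) < 1e-12

    def test_state_is_memoryless(self):
        """The state carries only node means and weights; equal states step equally."""
        assert {f.name for f in dataclasses.fields(ReducedModelState)} == {"mu", "w"}
        fam = GaussianMean(sigma=1.0)
        m = ReducedModel(fam, nodes(1, 8, chi0=0.0, nu0=1.0), h=0.1)
        s1 = ReducedModelState(mu=np.array([1.0, 2.0]), w=np.array([0.3, 0.7]))
        s2 = ReducedModelState(mu=np.array([1.0, 2.0]), w=np.array([0.3, 0.7]))
        a, b = m.step(s1, 0.5), m.step(s2, 0.5)
        np.testing.assert_array_equal(a.mu, b.mu)
        np.testing.assert_array_equal(a.w, b.w)

    def test_per_step_cost_linear_in_nodes(self, monkeypatch):
        fam = GaussianMean(sigma=1.0)
        counter = {"n": 0}
        orig = fam.log_predictive

        def counting(chi, nu, x):
            out = orig(chi, nu, x)
            counter["n"] += np.size(out)
            return out

        monkeypatch.setattr(fam, "log_predictive", counting)
        T, N = 50, 6
        m = ReducedModel(fam, nodes(*np.arange(1, N + 1), chi0=0.0, nu0=1.0), h=0.1)
        m.run(np.zeros(T))
        assert counter["n"] <= 2 * T * N


class TestPredict:
    def test_degenerate_weight_selects_node(self):
        fam = GaussianMean(sigma=1.0)
        m = ReducedModel(fam, nodes(1, 8, chi0=0.0, nu0=1.0), h=0.1)
        state = ReducedModelState(mu=np.array([3.0, 7.0]), w=np.array([1.0, 0.0]))
        assert m.predict_mean(state) == pytest.approx(3.0)

    def test_identical_means_are_weight_invariant(self):
        fam = GaussianMean(sigma=1.0)
        m = ReducedModel(fam, nodes(1, 8, chi0=0.0, nu0=1.0), h=0.1)
        for w in ([0.5, 0.5], [0.9, 0.1]):
            state = ReducedModelState(mu=np.array([4.2, 4.2]), w=np.array(w))
            assert m.predict_mean(state) == pytest.approx(4.2)

    def test_weight_shifts_to_fast_node_after_change(self):
        """Weight jumps to the short run-length at a change, then returns."""
        fam = GaussianMean(sigma=0.5)
        rng = np.random.default_rng(41)
        theta = np.where(np.arange(120) < 60, 0.0, 5.0)
        x = rng.normal(theta, 0.5)
        m = ReducedModel(fam, nodes(1.0, 10.0, chi0=0.0, nu0=1.0), h=0.05)
        _, _, w = m.run(x, return_weights=True)
        w_fast = w[:, 0]
        assert w_fast[61] > w_fast[58] + 0.3     # abrupt shift at the change
        assert w_fast[110] < w_fast[61] - 0.3    # returns once stabilized


class TestEffectiveLearningRate:
    def test_recovers_constant_delta_rule_rate(self, rng):
        x = rng.normal(0, 1, 100)
        preds = delta_rule(x, 0.2, 0.0)
        al = effective_learning_rate(preds, x)
        np.testing.assert_allclose(al, 0.2, atol=1e-12)

    def test_full_jump_is_rate_one(self):
        preds = np.array([0.0, 10.0])
        x = np.array([10.0, 11.0])
        assert effective_learning_rate(preds, x)[0] == pytest.approx(1.0)

    def test_tiny_errors_flagged(self):
        preds = np.array([1.0, 1.0])
        x = np.array([1.0, 2.0])
        assert np.isnan(effective_learning_rate(preds, x)[0])

    def test_rate_spikes_after_change(self):
        fam = GaussianMean(sigma=0.5)
        rng = np.random.default_rng(42)
        theta = np.where(np.arange(120) < 60, 0.0, 5.0)
        x = rng.normal(theta, 0.5)
        m = ReducedModel(fam, nodes(1.0, 10.0, chi0=0.0, nu0=1.0), h=0.05)
        preds, _ = m.run(x)
        al = effective_learning_rate(preds, x)
        post_change = np.nanmean(al[60:64])
        stable = np.nanmean(al[40:58])
        assert post_change > stable + 0.2


def test_node_mean_is_exponential_kernel(rng):
    """Each node mean is an exponentially decaying average of past inputs."""
    fam = GaussianMean(sigma=1.0)
    x = rng.normal(0, 1, 60)
    m = ReducedModel(fam, nodes(5.0, chi0=0.0, nu0=1.0), h=0.2)
    state = m.init_state()
    for xt in x:
        state = m.step(state, xt)
    a = m.alpha[0]
    T = len(x)
    kernel = a * (1 - a) ** np.arange(T)[::-1]
    expected = float(kernel @ x)  # initial mean is 0
    assert state.mu[0] == pytest.approx(expected, abs=1e-12)


def test_dense_nodes_approach_full_model():
    """Integer nodes 1..R track the exact filter closely (corr > 0.95)."""
    fam = GaussianMean(sigma=5.0)
    chi0, nu0 = 0.0, 25.0 / 400.0  # mean prior N(0, 20^2)
    ds = sample_dataset(fam, (chi0, nu0), HazardSpec(0.025), 400, seed=43)
    full, _ = FullModel(fam, chi0, nu0, h=0.025, r_max=60).run(ds.x)
    red, _ = ReducedModel(
        fam, NodeSet(np.arange(1.0, 61.0), chi0, nu0), h=0.025
    ).run(ds.x)
    r = np.corrcoef(full[1:], red[1:])[0, 1]
    assert r > 0.95


def test_log_spaced_nodes_span():
    l = log_spaced_nodes(18, 1.0, 100.0)
    assert len(l) == 18
    assert l[0] == pytest.approx(1.0) and l[-1] == pytest.approx(100.0)
    assert np.all(np.diff(np.log(l)) > 0)
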