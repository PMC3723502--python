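"""Independent oracles used across the test suite."""

from itertools import product

import numpy as np

from deltamix.families import ConjugateState


def enumerate_posterior(family, chi0, nu0, h, x):
    """Exact run-length posterior and predictive mean by brute force.

    Enumerates every change-point configuration over the T-1 intervals of the
    sequence (2^(T-1) of them), weights each by its Bernoulli prior times the
    conjugate marginal likelihood of the induced epochs, and reads off the
    distribution of the run length after the final observation (a change in
    the upcoming interval, probability h, resets it to 0) together with the
    predictive point estimate for the next observation.
    """
    T = len(x)
    assert 0.0 < h < 1.0
    post = np.zeros(T + 1)
    pred = 0.0
    log_joint = []
    finals = []
    for cfg in product([0, 1], repeat=T - 1):
        c = (1,) + cfg  # the first observation always starts an epoch
        lp = 0.0
        state = ConjugateState(chi0, nu0)
        last_start = 0
        for t in range(T):
            if c[t] == 1:
                state = ConjugateState(chi0, nu0)
                last_start = t
            lp += float(family.log_predictive(state.chi, state.nu, x[t]))
            state = ConjugateState(
                state.chi + float(family.sufficient_stat(x[t])), state.nu + 1.0
            )
        n_changes = sum(cfg)
        lp += n_changes * np.log(h) + (T - 1 - n_changes) * np.log1p(-h)
        log_joint.append(lp)
        finals.append((last_start, state))
    log_joint = np.asarray(log_joint)
    w = np.exp(log_joint - log_joint.max())
    w /= w.sum()
    prior_est = family.param_estimate(chi0 / nu0)
    for wi, (s, state) in zip(w, finals):
        post[T - s] += wi * (1.0 - h)
        post[0] += wi * h
        pred += wi * ((1.0 - h) * family.mean(state) + h * prior_est)
    return post, pred


def delta_rule(x, alpha, mu0):
    """Plain Delta rule; returns predictions aligned before each observation."""
    mu = mu0
    preds = np.empty(len(x))
    for t, xt in enumerate(x):
        preds[t] = mu
        mu = mu + alpha * (xt - mu)
    return preds


def two_node_reference(x, family, chi0, nu0, l1, l2, h):
    """Hand-coded two-node mixture-of-Delta-rules recursion.

    Scalar transcription of the two-node weight and mean updates: independent
    Delta rules on each node plus explicit increase/self/change messages.
    Written without the library's transition-matrix machinery so it can serve
    as an independent check of ReducedModel.step.
    """
    a1 = min(1.0 / (l1 + nu0), 1.0)
    a2 = min(1.0 / (l2 + nu0), 1.0)
    s = l2 - l1
    p_adv = min(1.0 / s, 1.0)
    mu1 = mu2 = chi0 / nu0
    w1, w2 = 1.0, 0.0
    preds = np.empty(len(x))
    for t, xt in enumerate(x):
        preds[t] = w1 * float(family.param_estimate(mu1)) + w2 * float(
            family.param_estimate(mu2)
        )
        f1 = float(np.exp(family.log_predictive(mu1 * (l1 + nu0), l1 + nu0, xt)))
        f2 = float(np.exp(family.log_predictive(mu2 * (l2 + nu0), l2 + nu0, xt)))
        # change messages from both nodes land on node 1; node 1's no-change
        # mass splits between advancing to node 2 and staying; node 2 stays.
        n1 = h * (w1 * f1 + w2 * f2) + (1.0 - h) * (1.0 - p_adv) * w1 * f1
        n2 = (1.0 - h) * (p_adv * w1 * f1 + w2 * f2)
        z = n1 + n2
        w1, w2 = n1 / z, n2 / z
        u = float(family.sufficient_stat(xt))
        mu1 = mu1 + a1 * (u - mu1)
        mu2 = mu2 + a2 * (u - mu2)
    return preds
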