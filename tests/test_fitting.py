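"""Subject simulation, likelihoods, MLE fitting and group model selection."""

import numpy as np
import pytest
from scipy import stats

from deltamix import (
    GaussianMean,
    NodeSet,
    ReducedModel,
    SubjectData,
    TaskConfig,
    fit,
    generate_task,
    group_bms,
    loglik,
    model_predictions,
    simulate_subject,
)
from deltamix.fitting import (
    TASK_PRIOR_MEAN,
    TASK_PRIOR_SD,
    _profiled_nll,
    _reduced_gauss_block,
    n_free_params,
)


@pytest.fixture(scope="module")
def task():
    return generate_task(TaskConfig(), n_blocks=2, seed=50)


@pytest.fixture(scope="module")
def subject_r2(task):
    params = {"h": 0.2, "alphas": np.array([0.9, 0.45])}
    return simulate_subject("reduced-2", params, task, sigma_n=6.0, seed=51)


def test_fast_block_matches_reduced_model(rng):
    """The tight scalar loop equals the reference ReducedModel trajectory."""
    x = rng.normal(150, 40, 300)
    sigma = 5.0
    fam, chi0, nu0 = GaussianMean.from_mean_prior(sigma, TASK_PRIOR_MEAN, TASK_PRIOR_SD)
    alphas = np.array([0.95, 0.5, 0.2])
    l = np.sort(1.0 / alphas - nu0)
    ref, _ = ReducedModel(fam, NodeSet(l, chi0, nu0), 0.15).run(x)
    fast = _reduced_gauss_block(x, sigma, 0.15, alphas, chi0, nu0)
    np.testing.assert_allclose(fast, ref, atol=1e-10)


class TestSimulateSubject:
    def test_zero_noise_reports_model_predictions(self, task):
        params = {"alphas": np.array([0.5])}
        subj = simulate_subject("reduced-1", params, task, sigma_n=0.0, seed=52)
        preds = model_predictions("reduced-1", params, task.x, task.noise_sd)
        np.testing.assert_allclose(subj.predictions, np.clip(preds, 0, 300))

    def test_noise_scale_increases_report_spread(self, task):
        params = {"alphas": np.array([0.5])}
        preds = model_predictions("reduced-1", params, task.x, task.noise_sd)
        devs = []
        for sn in (2.0, 10.0):
            subj = simulate_subject("reduced-1", params, task, sigma_n=sn, seed=53)
            devs.append(np.mean(np.abs(subj.predictions - preds)))
        assert devs[1] > devs[0]

    def test_residuals_look_gaussian(self, task):
        params = {"alphas": np.array([0.5])}
        subj = simulate_subject("reduced-1", params, task, sigma_n=5.0, seed=54)
        preds = model_predictions("reduced-1", params, task.x, task.noise_sd)
        resid = subj.predictions - preds
        # clipping at [0, 300] almost never binds for these settings
        _, p = stats.normaltest(resid)
        assert p > 1e-3

    def test_reports_outside_bounds_rejected(self):
        with pytest.raises(ValueError):
            SubjectData(
                x=np.array([10.0, 20.0]),
                predictions=np.array([10.0, 400.0]),
                noise_sd=np.array([5.0, 5.0]),
            )


class TestLoglik:
    def test_zero_residuals_closed_form(self, task):
        params = {"alphas": np.array([0.5])}
        subj = simulate_subject("reduced-1", params, task, sigma_n=0.0, seed=55)
        sn = 2.0
        ll = loglik("reduced-1", {**params, "sigma_n": sn}, subj)
        n = len(subj)
        assert ll == pytest.approx(-n * np.log(sn * np.sqrt(2 * np.pi)))

    def test_profiled_sigma_is_residual_rms(self, subject_r2):
        theta = np.array([0.2, 0.9, 0.45])
        nll, sigma = _profiled_nll("reduced-2", theta, subject_r2, 120)
        params = {"h": 0.2, "alphas": np.array([0.9, 0.45])}
        for factor in (0.8, 1.25):
            worse = loglik("reduced-2", {**params, "sigma_n": sigma * factor}, subject_r2)
            assert -nll >= worse

    def test_profiled_surface_consistent_with_loglik(self, subject_r2):
        """The profiled objective equals loglik evaluated at the profiled sigma."""
        for alpha in (0.3, 0.6, 0.9):
            nll, sigma = _profiled_nll("reduced-1", np.array([alpha]), subject_r2, 120)
            ll = loglik(
                "reduced-1", {"alphas": np.array([alpha]), "sigma_n": sigma}, subject_r2
            )
            assert ll == pytest.approx(-nll, rel=1e-12)

    def test_invalid_params_rejected(self, subject_r2):
        with pytest.raises(ValueError):
            loglik("reduced-1", {"alphas": np.array([0.5]), "sigma_n": -1.0}, subject_r2)
        with pytest.raises(ValueError):
            loglik("reduced-2", {"h": 1.4, "alphas": np.array([0.9, 0.4]), "sigma_n": 5.0}, subject_r2)


class TestFit:
    def test_one_node_rate_recovery(self, task):
        truth = 0.55
        subj = simulate_subject(
            "reduced-1", {"alphas": np.array([truth])}, task, sigma_n=5.0, seed=56
        )
        res = fit("reduced-1", subj)
        assert res.params["alphas"][0] == pytest.approx(truth, abs=0.05)
        assert res.params["sigma_n"] == pytest.approx(5.0, abs=1.0)
        assert res.bic == pytest.approx(-2 * res.log_lik + res.k * np.log(res.n_obs))
        assert res.k == n_free_params("reduced-1") == 2

    def test_needless_parameters_worsen_bic(self, task):
        """Fitting a larger nested model to 1-node data pays the BIC penalty."""
        subj = simulate_subject(
            "reduced-1", {"alphas": np.array([0.5])}, task, sigma_n=5.0, seed=57
        )
        r1 = fit("reduced-1", subj, seed=0)
        r2 = fit("reduced-2", subj, n_starts=4, seed=0)
        assert r2.log_lik >= r1.log_lik - 0.5  # nesting: fit cannot get much worse
        assert r2.bic > r1.bic

    def test_short_subject_rejected(self):
        subj = SubjectData(
            x=np.full(15, 150.0),
            predictions=np.full(15, 150.0),
            noise_sd=np.full(15, 5.0),
        )
        with pytest.raises(ValueError):
            fit("reduced-1", subj)


class TestGroupBMS:
    def test_identical_evidence_is_symmetric(self):
        L = np.tile([-100.0, -100.0], (6, 1))
        res = group_bms(L, seed=1)
        np.testing.assert_allclose(res.model_probability, [0.5, 0.5], atol=1e-6)
        np.testing.assert_allclose(res.exceedance_probability, [0.5, 0.5], atol=0.02)

    def test_dominant_model_exceeds(self):
        rng = np.random.default_rng(2)
        L = rng.normal(-100, 1, size=(10, 3))
        L[:, 1] += 10.0  # model 2 better by >= 10 log units for every subject
        res = group_bms(L, seed=2)
        assert res.exceedance_probability[1] > 0.99
        assert np.argmax(res.model_probability) == 1

    def test_probabilities_normalize(self):
        rng = np.random.default_rng(3)
        L = rng.normal(-50, 3, size=(5, 4))
        res = group_bms(L, seed=3)
        assert res.model_probability.sum() == pytest.approx(1.0)
        assert res.exceedance_probability.sum() == pytest.approx(1.0)
        np.testing.assert_allclose(res.subject_posteriors.sum(axis=1), 1.0)

    def test_degenerate_shapes_rejected(self):
        with pytest.raises(ValueError):
            group_bms(np.zeros((1, 3)))


def test_predictions_ignore_subject_reports(subject_r2):
    """Model predictions depend only on observed outcomes, never on reports."""
    params = {"h": 0.2, "alphas": np.array([0.9, 0.45])}
    p1 = model_predictions("reduced-2", params, subject_r2.x, subject_r2.noise_sd)
    altered = SubjectData(
        x=subject_r2.x,
        predictions=np.clip(subject_r2.predictions + 20.0, 0, 300),
        noise_sd=subject_r2.noise_sd,
    )
    p2 = model_predictions("reduced-2", params, altered.x, altered.noise_sd)
    np.testing.assert_array_equal(p1, p2)
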