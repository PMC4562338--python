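"""Estimator correctness: boundary theorem, score, oracles, decomposition."""

import json
import math

import numpy as np
import pytest
from scipy.optimize import brentq

from lambertw import (
    TailParams,
    delta_only_loglik,
    delta_only_score,
    delta_taylor,
    gaussian_mle,
    igmm,
    loglik_decomposed,
    lr_test,
    max_finite_moment,
    mle_delta_only,
    mle_double_tail,
    mle_joint,
    penalty_term,
    sample_kurtosis,
    taylor_fit,
    tukey_h,
    uniform_input,
)
from lambertw.distributions import LambertWDistribution, gaussian_input


def draw_z(delta, n, seed):
    return np.asarray(tukey_h(0.0, 1.0, delta).sample(n, seed=seed))


# ---------------------------------------------------------------------------
# moment statistics


def test_sample_kurtosis_hand_values(rng):
    assert sample_kurtosis([1.0, -1.0, 1.0, -1.0]) == pytest.approx(1.0)
    y = rng.standard_normal(200_000)
    assert sample_kurtosis(y) == pytest.approx(3.0, abs=0.05)
    # brute-force moment ratio on an arbitrary fixture
    v = np.array([0.3, -1.2, 2.5, 0.0, -0.7, 1.1])
    d = v - v.mean()
    assert sample_kurtosis(v) == pytest.approx(np.mean(d**4) / np.mean(d**2) ** 2)
    with pytest.raises(ValueError):
        sample_kurtosis([2.0, 2.0, 2.0, 2.0])


def test_delta_taylor_rule():
    # kurtosis exactly 3 or below clips to zero
    assert delta_taylor([1.0, -1.0, 1.0, -1.0]) == 0.0
    g = np.array([-1.7317, -0.1, 0.1, 1.7317])  # platykurtic
    assert delta_taylor(g) == 0.0
    # a sample engineered to kurtosis 3.765 must invert to exactly 0.05:
    # zeros plus +-1 plus +-a, kurtosis = n (1 + a^4) / (2 (1 + a^2)^2)
    target = 3.765
    n = 8

    def kurt_gap(a):
        return n * (1 + a**4) / (2 * (1 + a**2) ** 2) - target

    a = brentq(kurt_gap, 0.01, 0.9, xtol=1e-15)
    y = np.array([0.0] * (n - 4) + [1.0, -1.0, a, -a])
    assert sample_kurtosis(y) == pytest.approx(target, abs=1e-12)
    assert delta_taylor(y) == pytest.approx(0.05, abs=1e-12)


# ---------------------------------------------------------------------------
# delta-only MLE and the boundary theorem


def test_boundary_alternating_sample():
    z = np.array([1.0, -1.0] * 5)
    fit = mle_delta_only(z)
    assert fit.estimates["delta"] == 0.0
    assert fit.at_boundary
    assert fit.penalty == 0.0


def test_boundary_condition_equivalence(rng):
    """delta_hat = 0 exactly when sum(z^4)/sum(z^2) <= 3, over many samples."""
    agree = 0
    for _ in range(200):
        n = int(rng.integers(8, 60))
        if rng.random() < 0.5:
            z = rng.standard_normal(n)
        else:
            z = draw_z(float(rng.uniform(0, 1)), n, rng)
        at_zero = mle_delta_only(z).estimates["delta"] == 0.0
        cond = np.sum(z**4) / np.sum(z**2) <= 3.0
        agree += at_zero == cond
    assert agree == 200


def test_score_zero_at_interior_optimum(rng):
    for delta in (0.1, 1 / 3, 1.0):
        z = draw_z(delta, 500, rng)
        fit = mle_delta_only(z)
        if not fit.at_boundary:
            assert abs(delta_only_score(fit.estimates["delta"], z)) < 1e-6 * z.size


def test_score_matches_numerical_derivative(rng):
    z = draw_z(0.5, 200, rng)
    for d in (0.05, 0.3, 1.2):
        h = 1e-6 * max(d, 1.0)
        num = (delta_only_loglik(d + h, z) - delta_only_loglik(d - h, z)) / (2 * h)
        assert delta_only_score(d, z) == pytest.approx(num, rel=1e-5, abs=1e-6)


def test_interior_mle_matches_grid_search(rng):
    """Dense-grid oracle (coarse scan + 1e-4 refinement; likelihood is unimodal)."""
    for _ in range(20):
        delta = float(rng.uniform(0.05, 3.0))
        z = draw_z(delta, 50, rng)
        fit = mle_delta_only(z)
        coarse = np.arange(0.0, 10.0 + 1e-9, 0.01)
        ll = np.array([delta_only_loglik(d, z) for d in coarse])
        d0 = coarse[np.argmax(ll)]
        fine = np.arange(max(d0 - 0.02, 0.0), d0 + 0.02 + 1e-9, 1e-4)
        llf = np.array([delta_only_loglik(d, z) for d in fine])
        d_grid = fine[np.argmax(llf)]
        assert abs(fit.estimates["delta"] - d_grid) < 1e-3


def test_delta_only_recovery(heavy_sample):
    fit = mle_delta_only(heavy_sample)
    assert fit.estimates["delta"] == pytest.approx(1 / 3, abs=0.1)
    assert fit.converged
    with pytest.raises(ValueError):
        mle_delta_only(np.array([1.0, np.inf, 0.0, 2.0]))


# ---------------------------------------------------------------------------
# penalty and decomposition


def test_penalty_sign_and_zero_cases(heavy_sample):
    tau0 = TailParams.symmetric_tau(0.0, 1.0, 0.0)
    assert penalty_term(heavy_sample, tau0) == 0.0
    for delta in (0.01, 0.3, 2.0):
        tau = TailParams.symmetric_tau(0.0, 1.0, delta)
        assert penalty_term(heavy_sample, tau) < 0.0
    # observations at the center carry no penalty
    tau = TailParams.symmetric_tau(0.0, 1.0, 5.0)
    assert penalty_term(np.zeros(10), tau) == 0.0
    # monotone decreasing in delta for fixed data away from the center
    y = np.array([1.0, -2.0, 0.5])
    vals = [penalty_term(y, TailParams.symmetric_tau(0.0, 1.0, d))
            for d in np.linspace(0.0, 3.0, 30)]
    assert np.all(np.diff(vals) < 0)


@pytest.mark.parametrize("delta", [0.0, 0.2, 0.7])
def test_decomposition_identity_and_pdf_consistency(rng, delta):
    y = draw_z(0.4, 300, rng) * 1.4 + 0.3
    tau = TailParams.symmetric_tau(0.3, 1.4, delta)
    total, input_part, pen = loglik_decomposed(y, tau)
    assert total == pytest.approx(input_part + pen, abs=1e-8)
    assert pen <= 0.0
    if delta == 0.0:
        assert pen == 0.0
    dist = LambertWDistribution(
        input=gaussian_input(0.3, 1.4), tau=tau
    )
    assert total == pytest.approx(float(np.sum(np.log(dist.pdf(y)))), abs=1e-8)


def test_decomposition_non_gaussian_input(rng):
    inp = uniform_input(0.0, 1.0)
    tau = TailParams.symmetric_tau(inp.mean, inp.sd, 0.3)
    dist = LambertWDistribution(input=inp, tau=tau)
    y = dist.sample(200, seed=rng)
    total, input_part, pen = loglik_decomposed(y, tau, inp)
    assert total == pytest.approx(float(np.sum(np.log(dist.pdf(y)))), abs=1e-8)
    # zero input density outside the support -> -inf with no crash
    bad_total, _, _ = loglik_decomposed(np.array([5.0]), tau, inp)
    assert bad_total == -math.inf


# ---------------------------------------------------------------------------
# joint and double-tail MLE


def test_joint_mle_gaussian_data(gaussian_sample):
    fit = mle_joint(gaussian_sample)
    ref = gaussian_mle(gaussian_sample)
    assert fit.estimates["delta"] < 0.02
    assert fit.estimates["mu_x"] == pytest.approx(np.mean(gaussian_sample), abs=0.02)
    assert fit.loglik_total >= ref.loglik_total - 1e-8
    assert fit.converged


def test_joint_mle_recovery_and_optimality(rng):
    y = np.asarray(tukey_h(0.5, 2.0, 1 / 3).sample(1000, rng))
    fit = mle_joint(y)
    assert fit.estimates["delta"] == pytest.approx(1 / 3, abs=0.12)
    assert fit.estimates["mu_x"] == pytest.approx(0.5, abs=0.25)
    assert fit.estimates["sigma_x"] == pytest.approx(2.0, rel=0.15)
    # attained likelihood at least that of the true parameters
    truth = TailParams.symmetric_tau(0.5, 2.0, 1 / 3)
    ll_truth, _, _ = loglik_decomposed(y, truth)
    assert fit.loglik_total >= ll_truth - 1e-6
    assert fit.loglik_total == pytest.approx(fit.loglik_input + fit.penalty, abs=1e-8)
    assert fit.std_errors is not None and fit.std_errors["delta"] > 0


def test_double_tail_mle(rng):
    y = np.asarray(tukey_h(0.0, 1.0, 0.3).sample(800, rng))
    sym = mle_joint(y)
    hh = mle_double_tail(y)
    assert hh.loglik_total >= sym.loglik_total - 1e-8
    assert hh.estimates["delta_l"] == pytest.approx(hh.estimates["delta_r"], abs=0.15)
    stat, p = lr_test(sym, hh, df=1)
    assert stat >= 0.0
    # asymmetric truth is detected
    y2 = np.asarray(tukey_h(0.0, 1.0, 0.0, delta_r=0.6).sample(2000, rng))
    hh2 = mle_double_tail(y2)
    assert hh2.estimates["delta_r"] > hh2.estimates["delta_l"] + 0.2


# ---------------------------------------------------------------------------
# IGMM


def test_igmm_gaussian_data(gaussian_sample):
    fit = igmm(gaussian_sample)
    assert fit.converged
    assert fit.estimates["delta"] < 0.02
    assert fit.estimates["mu_x"] == pytest.approx(np.mean(gaussian_sample), abs=0.02)


def test_igmm_recovery_and_exit_kurtosis(rng):
    y = np.asarray(tukey_h(1.0, 0.5, 0.4).sample(2000, rng))
    fit = igmm(y)
    assert fit.converged
    assert fit.estimates["delta"] == pytest.approx(0.4, abs=0.12)
    assert fit.estimates["mu_x"] == pytest.approx(1.0, abs=0.1)
    # by construction the back-transformed sample has kurtosis 3 at the exit
    assert fit.config["achieved_kurtosis"] == pytest.approx(3.0, abs=1.22e-4 * 10)


# ---------------------------------------------------------------------------
# LR test and tail index


def test_lr_test_worked_example():
    stat, p = lr_test(-3606.56, -3606.0, df=1)
    assert stat == pytest.approx(1.12, abs=1e-9)
    assert round(p, 2) == 0.29


def test_lr_test_edges():
    assert lr_test(-10.0, -10.0, df=1) == (0.0, 1.0)
    stat, p_plain = lr_test(-11.0, -10.0, df=1)
    _, p_mix = lr_test(-11.0, -10.0, df=1, boundary_mixture=True)
    assert p_mix == pytest.approx(0.5 * p_plain)
    assert p_mix <= p_plain
    with pytest.raises(ValueError):
        lr_test(-10.0, -11.0, df=1)


def test_max_finite_moment():
    assert round(max_finite_moment(0.172), 2) == 5.81
    assert max_finite_moment(1.0) == 1.0
    assert max_finite_moment(0.25) == 4.0
    # consistency: kurtosis (4th moment) diverges exactly where 1/delta <= 4
    from lambertw import kurtosis_gamma2

    assert kurtosis_gamma2(0.25) == math.inf
    assert math.isfinite(kurtosis_gamma2(0.24))
    with pytest.raises(ValueError):
        max_finite_moment(0.0)


# ---------------------------------------------------------------------------
# FitResult plumbing


def test_fit_result_serialization(heavy_sample):
    fit = mle_delta_only(heavy_sample, config={"seed": 1})
    data = json.loads(fit.to_json())
    assert set(data) == {"method", "n", "estimates", "std_errors", "loglik",
                         "converged", "iterations", "at_boundary", "config"}
    assert data["loglik"]["total"] == pytest.approx(
        data["loglik"]["input"] + data["loglik"]["penalty"]
    )
    assert data["config"]["seed"] == 1


def test_taylor_fit(rng):
    y = np.asarray(tukey_h(0.0, 1.0, 0.2).sample(5000, rng))
    fit = taylor_fit(y)
    assert fit.method == "taylor"
    assert fit.estimates["delta"] == pytest.approx(0.2, abs=0.15)
    assert fit.loglik_total == pytest.approx(fit.loglik_input + fit.penalty, abs=1e-8)
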