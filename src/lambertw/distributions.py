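"""Probability law of heavy-tail Lambert W x F_X random variables.

A latent "nice" variable X from a location-scale family F_X (Gaussian by
default, giving Tukey's h) is pushed through the bijective tail-inflating
transform of :mod:`lambertw.transforms`:

    U = (X - mu_X) / sigma_X,    Y = H_delta(U) * sigma_X + mu_X.

Because the transform is monotone with an explicit Lambert-W inverse, the
output law has closed-form cdf, pdf and quantile function:

    G_Y(y) = F_X( W_delta(z) sigma_X + mu_X ),          z = (y - mu_X)/sigma_X,
    g_Y(y) = f_X( W_delta(z) sigma_X + mu_X )
             * W_delta(z)/z * 1 / (1 + W(delta z^2)),
    y_p    = H_delta(u_p) sigma_X + mu_X,               u_p the input quantile.

The module also carries the closed-form moments of the Gaussian-input
(Tukey's h) case: the n-th moment of Z = H_delta(U) exists only for
n < 1/delta (tail index 1/delta), the variance map is
sigma_Y = sigma_X (1-2 delta)^(-3/4) wherever finite, and the kurtosis map
gamma_2(delta) = 3 (1-2 delta)^3 / (1-4 delta)^(5/2) links delta to the
fourth standardized moment (the basis of the moment estimators in
:mod:`lambertw.estimation`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np
from scipy import optimize, stats

from .transforms import TailParams, denormalize, normalize, w_delta

__all__ = [
    "InputDistribution",
    "gaussian_input",
    "uniform_input",
    "LambertWDistribution",
    "tukey_h",
    "tukeyh_moment",
    "kurtosis_gamma2",
    "sigma_y",
    "t_moment_match",
]


@dataclass(frozen=True)
class InputDistribution:
    """Contract for the latent input law F_X (a location-scale family).

    ``mean`` and ``sd`` must be the true mean and standard deviation of the
    law described by ``pdf``/``cdf``/``quantile``; they define the
    standardization U = (X - mean)/sd used by the heavy-tail transform.
    """

    name: str
    params: tuple
    pdf: Callable[[np.ndarray], np.ndarray]
    cdf: Callable[[np.ndarray], np.ndarray]
    quantile: Callable[[np.ndarray], np.ndarray]
    sampler: Callable[[int, np.random.Generator], np.ndarray]
    mean: float
    sd: float

    def sample(self, n: int, seed=None) -> np.ndarray:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        return self.sampler(n, rng)


def gaussian_input(mu: float = 0.0, sigma: float = 1.0) -> InputDistribution:
    """Gaussian latent law N(mu, sigma^2); yields Tukey's h as output."""
    frozen = stats.norm(loc=mu, scale=sigma)
    return InputDistribution(
        name="gaussian",
        params=(mu, sigma),
        pdf=frozen.pdf,
        cdf=frozen.cdf,
        quantile=frozen.ppf,
        sampler=lambda n, rng: rng.normal(mu, sigma, size=n),
        mean=mu,
        sd=sigma,
    )


def uniform_input(a: float = 0.0, b: float = 1.0) -> InputDistribution:
    """Uniform latent law on [a, b]."""
    frozen = stats.uniform(loc=a, scale=b - a)
    return InputDistribution(
        name="uniform",
        params=(a, b),
        pdf=frozen.pdf,
        cdf=frozen.cdf,
        quantile=frozen.ppf,
        sampler=lambda n, rng: rng.uniform(a, b, size=n),
        mean=0.5 * (a + b),
        sd=(b - a) / math.sqrt(12.0),
    )


def _jacobian_factor(z: np.ndarray, delta: float) -> np.ndarray:
    """dX/dY factor  W_delta(z)/z * 1/(1 + W(delta z^2)), with limit 1 at z=0.

    Note 1 + W(delta z^2) = 1 + delta W_delta(z)^2, so this equals the
    per-observation likelihood-penalty factor R_i.
    """
    z = np.asarray(z, dtype=float)
    if delta == 0.0:
        return np.ones_like(z)
    u = np.asarray(w_delta(z, delta))
    ratio = np.ones_like(z)
    nz = z != 0
    # u/z = exp(-delta u^2 / 2), numerically stable even for huge z
    ratio[nz] = np.exp(-0.5 * delta * u[nz] ** 2)
    return ratio / (1.0 + delta * u**2)


@dataclass(frozen=True)
class LambertWDistribution:
    """Output law Y ~ heavy-tail Lambert W x F_X for a given tau.

    Supports asymmetric (double-tail) ``tau``: each half-line uses its own
    tail parameter; the factors are continuous at the center since both
    tend to 1.
    """

    input: InputDistribution
    tau: TailParams

    def __post_init__(self) -> None:
        if (self.tau.mu_x, self.tau.sigma_x) != (self.input.mean, self.input.sd):
            raise ValueError(
                "tau location/scale must equal the input law's mean/sd: "
                f"tau=({self.tau.mu_x}, {self.tau.sigma_x}) vs input "
                f"({self.input.mean}, {self.input.sd})"
            )

    def pdf(self, y) -> np.ndarray:
        y = np.asarray(y, dtype=float)
        tau = self.tau
        z = (y - tau.mu_x) / tau.sigma_x
        x = np.asarray(normalize(y, tau))
        jac = np.where(
            z > 0,
            _jacobian_factor(z, tau.delta_r),
            _jacobian_factor(z, tau.delta_l),
        )
        g = self.input.pdf(x) * jac
        return g if g.ndim else float(g)

    def cdf(self, y) -> np.ndarray:
        y = np.asarray(y, dtype=float)
        g = self.input.cdf(np.asarray(normalize(y, self.tau)))
        g = np.asarray(g)
        return g if g.ndim else float(g)

    def quantile(self, p) -> np.ndarray:
        p = np.asarray(p, dtype=float)
        if np.any((p <= 0) | (p >= 1)):
            raise ValueError("quantile probabilities must lie strictly in (0, 1)")
        x_p = np.asarray(self.input.quantile(p), dtype=float)
        y = np.asarray(denormalize(x_p, self.tau))
        return y if y.ndim else float(y)

    def sample(self, n: int, seed=None) -> np.ndarray:
        """Generative draw: sample X from the input law, push forward."""
        if n < 1:
            raise ValueError("n must be >= 1")
        x = self.input.sample(n, seed)
        return np.asarray(denormalize(x, self.tau))


def tukey_h(
    mu: float = 0.0,
    sigma: float = 1.0,
    delta: float = 0.0,
    delta_r: Optional[float] = None,
) -> LambertWDistribution:
    """Tukey's h (or hh) distribution: Gaussian input with tail parameter(s)."""
    if delta_r is None:
        tau = TailParams.symmetric_tau(mu_x=mu, sigma_x=sigma, delta=delta)
    else:
        tau = TailParams(mu_x=mu, sigma_x=sigma, delta_l=delta, delta_r=delta_r)
    return LambertWDistribution(input=gaussian_input(mu, sigma), tau=tau)


def tukeyh_moment(n: int, delta: float) -> float:
    """n-th raw moment of Z = U exp(delta U^2 / 2), U standard normal.

    Exists only below the tail index 1/delta:

    * odd n < 1/delta  -> 0 (symmetry),
    * even n < 1/delta -> n! (1 - n delta)^(-(n+1)/2) / (2^(n/2) (n/2)!),
    * odd n >= 1/delta  -> NaN (does not exist),
    * even n >= 1/delta -> +inf.

    The boundary n = 1/delta is grouped with the divergent regime.
    """
    if not (isinstance(n, (int, np.integer)) and n >= 1):
        raise ValueError(f"moment order must be a positive integer, got {n}")
    if delta < 0:
        raise ValueError("delta must be nonnegative")
    exists = delta == 0.0 or n < 1.0 / delta
    if n % 2 == 1:
        return 0.0 if exists else math.nan
    if not exists:
        return math.inf
    k = n // 2
    return math.factorial(n) / (2**k * math.factorial(k)) * (1.0 - n * delta) ** (-(n + 1) / 2.0)


def kurtosis_gamma2(delta: float) -> float:
    """Kurtosis map of the Gaussian-input output law.

    gamma_2(delta) = 3 (1 - 2 delta)^3 / (1 - 4 delta)^(5/2) for
    delta < 1/4, +inf otherwise; equals 3 at delta = 0 and is strictly
    increasing on [0, 1/4).
    """
    if delta < 0:
        raise ValueError("delta must be nonnegative")
    if delta >= 0.25:
        return math.inf
    return 3.0 * (1.0 - 2.0 * delta) ** 3 / (1.0 - 4.0 * delta) ** 2.5


def sigma_y(tau: TailParams) -> float:
    """Standard deviation of Y: sigma_X (1 - 2 delta)^(-3/4), +inf for delta >= 1/2."""
    delta = tau.delta  # symmetric only
    if delta >= 0.5:
        return math.inf
    return tau.sigma_x * (1.0 - 2.0 * delta) ** -0.75


def t_moment_match(c: float, s: float, nu: float) -> TailParams:
    """Gaussian-input tau matching the first four moments of a location-scale t.

    A t distribution with location ``c``, scale ``s`` and ``nu > 4`` degrees
    of freedom has mean c, variance s^2 nu/(nu-2) and kurtosis
    3 (nu-2)/(nu-4).  Matching kurtosis determines delta (monotone 1-D
    root-find on [0, 1/4)), and matching the variance then fixes sigma_X.
    """
    if not nu > 4:
        raise ValueError(
            f"moment matching needs nu > 4 (got nu={nu}): the kurtosis of a "
            "t distribution does not exist otherwise"
        )
    target = 3.0 * (nu - 2.0) / (nu - 4.0)

    def gap(d: float) -> float:
        return kurtosis_gamma2(d) - target

    hi = 0.25 - 1e-12
    while not np.isfinite(gap(hi)) or gap(hi) < 0:
        hi = 0.25 - (0.25 - hi) * 10  # unreachable for nu > 4; defensive
    delta = optimize.brentq(gap, 0.0, hi, xtol=1e-14)
    sd_t = s * math.sqrt(nu / (nu - 2.0))
    sigma_x = sd_t * (1.0 - 2.0 * delta) ** 0.75
    return TailParams.symmetric_tau(mu_x=c, sigma_x=sigma_x, delta=delta)
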