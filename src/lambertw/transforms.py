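"""Heavy-tail transform H and its exact Lambert-W inverse.

The forward map inflates the tails of a standardized variable ``u``:

    H_delta(u) = u * exp((delta / 2) * (u^2)^alpha),      delta >= 0,

with ``alpha = 1`` giving Tukey's h transform.  Its inverse is expressed
through the principal branch of the Lambert W function (the inverse of
``w * exp(w)``):

    W_delta(z) = sgn(z) * ( W(alpha * delta * z^(2*alpha)) / (alpha * delta) )^(1 / (2*alpha)).

Both maps are odd, strictly increasing and mutually inverse for every
``delta >= 0``; ``delta = 0`` is the identity.  Negative ``delta`` would make
the transform non-bijective and is rejected everywhere.

A two-parameter ("double-tail" / hh) variant applies a separate tail
parameter on each side of the origin: ``delta_l`` for ``u <= 0`` and
``delta_r`` for ``u > 0``.  Since sgn is preserved by the transform, the
branch on inversion is chosen by the sign of ``z``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import lambertw as _scipy_lambertw

__all__ = [
    "TailParams",
    "h_transform",
    "w_delta",
    "h_double_tail",
    "w_double_tail",
    "normalize",
    "denormalize",
]

logger = logging.getLogger("lambertw")

# below this, W(delta * z^2)/delta is evaluated by its delta -> 0 limit (= z^2)
_SMALL_ARG = 1e-14
# above this, lambertw's argument would overflow; switch to log-domain asymptotics
_BIG_ARG = 1e300


@dataclass(frozen=True)
class TailParams:
    """Transformation vector tau = (mu_x, sigma_x, delta_l, delta_r, alpha).

    ``mu_x`` and ``sigma_x`` are the mean and standard deviation of the
    latent input X; ``delta_l``/``delta_r`` are the left/right tail
    parameters (equal in the symmetric case, where the common value is
    exposed as ``delta``); ``alpha`` generalizes the exponent of the inner
    ``u^2`` term and defaults to 1 (Tukey's h).
    """

    mu_x: float = 0.0
    sigma_x: float = 1.0
    delta_l: float = 0.0
    delta_r: float = field(default=None)  # type: ignore[assignment]
    alpha: float = 1.0

    def __post_init__(self) -> None:
        if self.delta_r is None:
            object.__setattr__(self, "delta_r", self.delta_l)
        if not self.sigma_x > 0:
            raise ValueError(f"sigma_x must be positive, got {self.sigma_x}")
        if self.delta_l < 0 or self.delta_r < 0:
            raise ValueError(
                f"tail parameters must be nonnegative, got delta_l={self.delta_l}, "
                f"delta_r={self.delta_r} (the delta < 0 regime is non-bijective)"
            )
        if not self.alpha > 0:
            raise ValueError(f"alpha must be positive, got {self.alpha}")

    @classmethod
    def symmetric_tau(
        cls, mu_x: float, sigma_x: float, delta: float, alpha: float = 1.0
    ) -> "TailParams":
        return cls(mu_x=mu_x, sigma_x=sigma_x, delta_l=delta, delta_r=delta, alpha=alpha)

    def symmetric(self) -> bool:
        return self.delta_l == self.delta_r

    @property
    def delta(self) -> float:
        """Common tail parameter; only defined in the symmetric case."""
        if not self.symmetric():
            raise ValueError("delta is undefined for asymmetric tails; use delta_l/delta_r")
        return self.delta_l


def _check_delta(delta: float) -> float:
    delta = float(delta)
    if delta < 0 or np.isnan(delta):
        raise ValueError(
            f"delta must be nonnegative, got {delta}: the transform is not "
            "bijective for delta < 0"
        )
    return delta


def _check_alpha(alpha: float) -> float:
    alpha = float(alpha)
    if not alpha > 0:
        raise ValueError(f"alpha must be positive, got {alpha}")
    return alpha


def _warn_nonfinite(arr: np.ndarray, what: str) -> None:
    n_bad = int(np.size(arr) - np.sum(np.isfinite(arr)))
    if n_bad:
        logger.warning("%s produced %d non-finite value(s)", what, n_bad)


def h_transform(u, delta: float, alpha: float = 1.0):
    """Forward heavy-tail transform ``u -> u * exp((delta/2) * (u^2)^alpha)``.

    Odd and strictly increasing in ``u`` for every ``delta >= 0``; the
    identity at ``delta = 0``.  Overflow of the exponential yields
    ``+/-inf`` with a warning rather than NaN.
    """
    delta = _check_delta(delta)
    alpha = _check_alpha(alpha)
    u = np.asarray(u, dtype=float)
    if np.any(np.isnan(u)):
        logger.warning("h_transform: %d NaN input(s) propagated", int(np.isnan(u).sum()))
    with np.errstate(over="ignore"):
        z = u * np.exp(0.5 * delta * (u * u) ** alpha)
    if np.any(np.isinf(z) & np.isfinite(u)):
        warnings.warn("h_transform overflowed to infinity", RuntimeWarning, stacklevel=2)
    return z if z.ndim else float(z)


def w_delta(z, delta: float, alpha: float = 1.0):
    """Inverse heavy-tail transform via the principal Lambert W branch.

    ``W_delta(z) = sgn(z) * (W(alpha*delta*z^(2*alpha)) / (alpha*delta))^(1/(2*alpha))``,
    the exact inverse of :func:`h_transform`.  The limit ``delta -> 0`` is
    the identity and is used directly for tiny ``delta * z^2`` where the
    exact ratio is numerically 0/0.
    """
    delta = _check_delta(delta)
    alpha = _check_alpha(alpha)
    z = np.asarray(z, dtype=float)
    if delta == 0.0:
        return z if z.ndim else float(z)
    ad = alpha * delta
    with np.errstate(over="ignore"):
        arg = ad * np.abs(z) ** (2.0 * alpha)
    small = arg < _SMALL_ARG
    u = np.empty_like(z)
    # limit W(x)/x -> 1 as x -> 0, so (W(ad z^2a)/ad)^(1/2a) -> |z|
    u[small] = z[small]
    if np.any(~small):
        a = arg[~small]
        big = a > _BIG_ARG
        ratio = np.empty_like(a)
        ratio[~big] = np.real(_scipy_lambertw(a[~big])) / ad
        if np.any(big):
            # log-domain evaluation: ratio = exp(log W(a) - log ad)
            logger.warning(
                "w_delta: %d argument(s) in the asymptotic Lambert W regime", int(big.sum())
            )
            la = 2.0 * alpha * np.log(np.abs(z[~small][big])) + np.log(ad)
            w = la - np.log(la)
            for _ in range(3):
                w = w + w * np.expm1(la - w - np.log(w)) / (1 + w)
            ratio[big] = np.exp(np.log(w) - np.log(ad))
        u[~small] = np.sign(z[~small]) * ratio ** (0.5 / alpha)
    _warn_nonfinite(u[np.isfinite(z)], "w_delta")
    return u if u.ndim else float(u)


def h_double_tail(u, tau: TailParams):
    """Piecewise forward transform: delta_l on u <= 0, delta_r on u > 0."""
    u = np.asarray(u, dtype=float)
    z = np.where(
        u > 0,
        h_transform(u, tau.delta_r, tau.alpha),
        h_transform(u, tau.delta_l, tau.alpha),
    )
    return z if z.ndim else float(z)


def w_double_tail(z, tau: TailParams):
    """Piecewise inverse transform, branch chosen by sgn(z) (sign-preserving)."""
    z = np.asarray(z, dtype=float)
    u = np.where(
        z > 0,
        w_delta(z, tau.delta_r, tau.alpha),
        w_delta(z, tau.delta_l, tau.alpha),
    )
    return u if u.ndim else float(u)


def normalize(y, tau: TailParams):
    """Back-transform observed data to the latent input scale.

    ``x_i = W_delta((y_i - mu_x)/sigma_x) * sigma_x + mu_x`` — removes the
    heavy tails encoded by ``tau``; bijective for nonnegative tail
    parameters.  Handles symmetric and double-tail ``tau``.
    """
    y = np.asarray(y, dtype=float)
    z = (y - tau.mu_x) / tau.sigma_x
    u = w_double_tail(z, tau)
    x = np.asarray(u) * tau.sigma_x + tau.mu_x
    return x if x.ndim else float(x)


def denormalize(x, tau: TailParams):
    """Forward transform latent input to the heavy-tailed scale (inverse of
    :func:`normalize`)."""
    x = np.asarray(x, dtype=float)
    u = (x - tau.mu_x) / tau.sigma_x
    z = h_double_tail(u, tau)
    y = np.asarray(z) * tau.sigma_x + tau.mu_x
    return y if y.ndim else float(y)
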