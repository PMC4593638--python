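"""Spine-size distributions and their threshold-exceedance probabilities.

Dendritic spine volumes ``u`` (in um^3) are modelled by one of six
distribution families, three short-tailed (exponential, gamma of fixed
order n=1 or n=2, Rayleigh) and two heavy-tailed (log-logistic,
log-normal).  Each family is parametrized by its *mean* spine volume
``ubar`` so that the conditional probability of spine formation,

    P(ubar; theta) = integral_theta^inf H(u) du,

i.e. the probability that a potential spine exceeds the volume threshold
``theta``, becomes a closed-form function of ``ubar`` alone (plus the
family's shape parameter).  ``P`` and its derivative ``dP/dubar`` are the
quantities the tissue-composition optimization needs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy import special, stats

__all__ = [
    "FAMILIES",
    "SHAPE_FAMILIES",
    "SpineSizeDistribution",
    "calibrate_from_mean",
    "exceedance_functions",
]

FAMILIES = (
    "exponential",
    "gamma_n1",
    "gamma_n2",
    "rayleigh",
    "loglogistic",
    "lognormal",
)

#: families whose single shape parameter must be supplied by the caller
SHAPE_FAMILIES = {"loglogistic": "beta", "lognormal": "sigma"}

_GAMMA_ORDER = {"gamma_n1": 1, "gamma_n2": 2}


def _validate_family(family: str, shape: float | None) -> None:
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}; expected one of {FAMILIES}")
    if family in SHAPE_FAMILIES:
        if shape is None:
            raise ValueError(
                f"{family} requires shape parameter {SHAPE_FAMILIES[family]!r}"
            )
        if family == "loglogistic" and not shape > 1:
            raise ValueError(
                "log-logistic shape beta must be > 1 (the mean diverges otherwise)"
            )
        if family == "lognormal" and not shape > 0:
            raise ValueError("log-normal shape sigma must be > 0")
    elif shape is not None:
        raise ValueError(f"{family} takes no shape parameter")


def exceedance_functions(
    family: str, shape: float | None = None
) -> tuple[Callable, Callable]:
    """Closed-form ``P(ubar, theta)`` and ``dP/dubar(ubar, theta)``.

    Returns a pair of vectorized callables for the given family, suitable
    for the optimizer's inner loop.  Both accept positive ``ubar`` and
    nonnegative ``theta``.
    """
    _validate_family(family, shape)

    if family == "exponential":

        def P(ub, th):
            return np.exp(-th / ub)

        def dP(ub, th):
            return np.exp(-th / ub) * th / ub**2

    elif family in _GAMMA_ORDER:
        n = _GAMMA_ORDER[family]
        fact = math.factorial(n)

        def P(ub, th):
            z = (n + 1) * th / ub
            poly = 1.0 + z if n == 1 else 1.0 + z + 0.5 * z * z
            return poly * np.exp(-z)

        def dP(ub, th):
            z = (n + 1) * th / ub
            # d/dz of the polynomial-times-exponential collapses to
            # -z^n/n! e^{-z}; the chain rule brings (n+1) theta / ub^2
            return (z**n / fact) * np.exp(-z) * (n + 1) * th / ub**2

    elif family == "rayleigh":

        def P(ub, th):
            return np.exp(-(math.pi / 4.0) * (th / ub) ** 2)

        def dP(ub, th):
            return P(ub, th) * (math.pi / 2.0) * th**2 / ub**3

    elif family == "loglogistic":
        b = shape
        # renormalized threshold theta_tilde = theta * (pi/b)/sin(pi/b)
        tfac = (math.pi / b) / math.sin(math.pi / b)

        def P(ub, th):
            tt = th * tfac
            return ub**b / (ub**b + tt**b)

        def dP(ub, th):
            tt = th * tfac
            return b * ub ** (b - 1) * tt**b / (ub**b + tt**b) ** 2

    else:  # lognormal
        sg = shape

        def P(ub, th):
            # erfc keeps the deep lower tail (P ~ 1e-300) from
            # underflowing, unlike the equivalent (1 - erf)/2 form
            with np.errstate(divide="ignore"):
                w = (np.log(th / ub) + 0.5 * sg * sg) / (math.sqrt(2) * sg)
            return 0.5 * special.erfc(w)

        def dP(ub, th):
            with np.errstate(divide="ignore"):
                w = (np.log(th / ub) + 0.5 * sg * sg) / (math.sqrt(2) * sg)
            return np.exp(-w * w) / (math.sqrt(2.0 * math.pi) * sg * ub)

    return P, dP


@dataclass(frozen=True)
class SpineSizeDistribution:
    """A spine-volume distribution calibrated to a target mean volume.

    Parameters
    ----------
    family : str
        One of :data:`FAMILIES`.
    mean_volume : float
        Mean spine volume ``ubar`` in um^3 (> 0).
    shape : float, optional
        ``beta`` (> 1) for the log-logistic family, ``sigma`` (> 0) for the
        log-normal family.  Must be omitted for the other families, whose
        gamma order n is fixed by the family name.

    Notes
    -----
    The internal scale parameter is derived from the mean:

    ========================  =======================================
    family                    scale from mean
    ========================  =======================================
    exponential               alpha = 1/ubar
    gamma (order n)           alpha = (n+1)/ubar
    rayleigh                  sigma_R = ubar * sqrt(2/pi)
    log-logistic              alpha = ubar * beta * sin(pi/beta) / pi
    log-normal                mu = ln(ubar) - sigma^2/2
    ========================  =======================================
    """

    family: str
    mean_volume: float
    shape: float | None = None
    scale: float = field(init=False)

    def __post_init__(self):
        _validate_family(self.family, self.shape)
        if not self.mean_volume > 0:
            raise ValueError("mean spine volume ubar must be > 0")
        object.__setattr__(self, "scale", self._derive_scale())

    # -- parametrization ------------------------------------------------

    def _derive_scale(self) -> float:
        ub = self.mean_volume
        if self.family == "exponential":
            return 1.0 / ub
        if self.family in _GAMMA_ORDER:
            return (_GAMMA_ORDER[self.family] + 1) / ub
        if self.family == "rayleigh":
            return ub * math.sqrt(2.0 / math.pi)
        if self.family == "loglogistic":
            b = self.shape
            return ub * b * math.sin(math.pi / b) / math.pi
        # lognormal: location mu of ln u
        return math.log(ub) - 0.5 * self.shape**2

    @property
    def gamma_order(self) -> int | None:
        return _GAMMA_ORDER.get(self.family)

    @property
    def renormalized_threshold_factor(self) -> float | None:
        """Log-logistic only: theta_tilde / theta = (pi/beta)/sin(pi/beta)."""
        if self.family != "loglogistic":
            return None
        return (math.pi / self.shape) / math.sin(math.pi / self.shape)

    def frozen(self):
        """The equivalent frozen :mod:`scipy.stats` distribution.

        Backs :meth:`pdf` and part of :meth:`sample`; also serves as an
        independent cross-check of the closed-form exceedance in tests.
        """
        if self.family == "exponential":
            return stats.expon(scale=1.0 / self.scale)
        if self.family in _GAMMA_ORDER:
            n = self.gamma_order
            return stats.gamma(a=n + 1, scale=1.0 / self.scale)
        if self.family == "rayleigh":
            return stats.rayleigh(scale=self.scale)
        if self.family == "loglogistic":
            return stats.fisk(c=self.shape, scale=self.scale)
        return stats.lognorm(s=self.shape, scale=math.exp(self.scale))

    # -- densities and exceedance ---------------------------------------

    def pdf(self, u):
        """Probability density H(u) of spine volume, per um^3 (u >= 0)."""
        u = np.asarray(u, dtype=float)
        if np.any(u < 0):
            raise ValueError("spine volume u must be >= 0")
        out = self.frozen().pdf(u)
        return out if out.ndim else float(out)

    def exceedance(self, theta):
        """Conditional probability of spine formation P(ubar; theta).

        Returns a value in (0, 1]; strictly increasing in ubar for
        theta > 0, identically 1 at theta = 0.
        """
        theta = np.asarray(theta, dtype=float)
        if np.any(theta < 0):
            raise ValueError("threshold theta must be >= 0")
        P, _ = exceedance_functions(self.family, self.shape)
        out = np.asarray(P(self.mean_volume, theta))
        return out if out.ndim else float(out)

    def exceedance_derivative(self, theta):
        """dP/dubar at fixed threshold; nonnegative."""
        theta = np.asarray(theta, dtype=float)
        if np.any(theta < 0):
            raise ValueError("threshold theta must be >= 0")
        _, dP = exceedance_functions(self.family, self.shape)
        out = np.asarray(dP(self.mean_volume, theta))
        return out if out.ndim else float(out)

    # -- sampling -------------------------------------------------------

    def sample(self, n: int, seed) -> np.ndarray:
        """Draw ``n`` spine volumes, reproducibly.

        ``seed`` is mandatory: an int or a :class:`numpy.random.Generator`.
        Inverse-CDF sampling is used where the quantile function is
        closed-form (exponential, Rayleigh, log-logistic); the scipy
        generators are used otherwise.
        """
        if n < 1:
            raise ValueError("sample size n must be >= 1")
        rng = np.random.default_rng(seed)
        if self.family == "exponential":
            return -np.log1p(-rng.random(n)) / self.scale
        if self.family == "rayleigh":
            return self.scale * np.sqrt(-2.0 * np.log1p(-rng.random(n)))
        if self.family == "loglogistic":
            q = rng.random(n)
            return self.scale * (q / (1.0 - q)) ** (1.0 / self.shape)
        return self.frozen().rvs(size=n, random_state=rng)


def calibrate_from_mean(
    family: str, mean_volume: float, shape: float | None = None
) -> SpineSizeDistribution:
    """Build a spine-size distribution whose mean equals ``mean_volume``."""
    return SpineSizeDistribution(family, mean_volume, shape)
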