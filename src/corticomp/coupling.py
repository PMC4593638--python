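"""Coupling laws tying the five cortical volume fractions together.

The gray matter is partitioned into axons (x), dendrites (y), dendritic
spines (s), glia/astrocytes (g) and capillaries (c), fractions of unit
volume.  Three couplings close the system:

* geometric probability of synapse formation, ``s = P x y``, where P is
  the probability that a potential spine exceeds the volume threshold;
* astrocytes as minimal spanning trees over the spines they serve,
  giving ``g = a (s/ubar)^(2/3)`` with a single physical constant
  ``a = (pi/4) b d_as^2`` (b the spanning-tree prefactor, d_as the mean
  astrocyte process diameter);
* capillaries clustering where both spines and astrocytes are dense,
  ``c = g s``.

Spine density rho_s (um^-3) relates to the spine fraction via
``s = rho_s * ubar``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = [
    "CouplingConstants",
    "CompositionFractions",
    "DEFAULT_CONSTANTS",
    "derive_constants",
    "spine_fraction",
    "glia_fraction",
    "capillary_fraction",
    "complete_composition",
]

#: spanning-tree prefactor, total tree length L = b N^(2/3) V^(1/3)
TREE_PREFACTOR = (3.0 / (4.0 * math.pi)) ** (1.0 / 3.0)


@dataclass(frozen=True)
class CouplingConstants:
    """Physical constants of the astrocyte/capillary coupling.

    d_as is the mean astrocyte process diameter in um — the single fixed
    physical parameter of the model.  ``a = (pi/4) b d_as^2`` is in um^2,
    which against the spine density rho_s^(2/3) (um^-2) makes the glia
    fraction unitless.
    """

    d_as: float = 0.85
    V_pr: float | None = None  # astrocyte process volume, um^3
    S_pr: float | None = None  # astrocyte process surface area, um^2
    b: float = field(init=False, default=TREE_PREFACTOR)

    def __post_init__(self):
        if not self.d_as > 0:
            raise ValueError("astrocyte process diameter d_as must be > 0")

    @property
    def a(self) -> float:
        """Astrocyte coupling constant (pi/4) * b * d_as^2, um^2."""
        return (math.pi / 4.0) * self.b * self.d_as**2


DEFAULT_CONSTANTS = CouplingConstants()  # d_as = 0.85 um -> a = 0.352 um^2


def derive_constants(V_pr: float, S_pr: float) -> CouplingConstants:
    """Constants from astrocyte process volume and surface area.

    Treating processes as cylinders, the mean diameter is
    ``d_as = 4 V_pr / S_pr``.  Defaults V_pr = 350 um^3, S_pr = 1650 um^2
    (cat sensorimotor cortex) give d_as ~ 0.85 um and a ~ 0.352 um^2.
    """
    if not (V_pr > 0 and S_pr > 0):
        raise ValueError("V_pr and S_pr must be > 0")
    return CouplingConstants(d_as=4.0 * V_pr / S_pr, V_pr=V_pr, S_pr=S_pr)


@dataclass(frozen=True)
class CompositionFractions:
    """The five-vector of volume fractions plus derived spine density."""

    x: float  # axons
    y: float  # dendrites
    s: float  # spines
    g: float  # glia/astrocytes
    c: float  # capillaries
    mean_spine_volume: float | None = None  # ubar, um^3

    def __post_init__(self):
        for name in ("x", "y", "s", "g", "c"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"fraction {name}={v} outside [0, 1]")

    @property
    def spine_density(self) -> float | None:
        """rho_s = s / ubar in um^-3 (None if ubar unknown)."""
        if self.mean_spine_volume is None:
            return None
        return self.s / self.mean_spine_volume

    @property
    def total(self) -> float:
        return self.x + self.y + self.s + self.g + self.c

    @property
    def residual(self) -> float:
        """Deviation of the fraction sum from unity."""
        return self.total - 1.0

    def as_array(self):
        import numpy as np

        return np.array([self.x, self.y, self.s, self.g, self.c])


def spine_fraction(x: float, y: float, P: float) -> float:
    """Spine fraction from geometric probability: s = P * x * y."""
    for name, v in (("x", x), ("y", y), ("P", P)):
        if not (0.0 <= v <= 1.0):
            raise ValueError(f"{name}={v} outside [0, 1]")
    return P * x * y


def glia_fraction(s: float, ubar: float, a: float = DEFAULT_CONSTANTS.a) -> float:
    """Glia/astrocyte fraction g = a * (s/ubar)^(2/3) = a * rho_s^(2/3)."""
    if not ubar > 0:
        raise ValueError("mean spine volume ubar must be > 0")
    if s < 0:
        raise ValueError("spine fraction s must be >= 0")
    return a * (s / ubar) ** (2.0 / 3.0)


def capillary_fraction(g: float, s: float) -> float:
    """Capillary fraction as the product law c = g * s.

    Equivalent to a * s^(5/3) / ubar^(2/3) when g came from
    :func:`glia_fraction`; implies c ~ g^(5/2), hence c/g = s << 1.
    """
    for name, v in (("g", g), ("s", s)):
        if not (0.0 <= v <= 1.0):
            raise ValueError(f"{name}={v} outside [0, 1]")
    return g * s


def complete_composition(
    x: float,
    y: float,
    ubar: float,
    dist,
    theta: float,
    a: float = DEFAULT_CONSTANTS.a,
) -> CompositionFractions:
    """Chain the couplings from the independent variables (x, y, ubar).

    ``dist`` is a :class:`~corticomp.distributions.SpineSizeDistribution`
    family handle: anything with ``family``/``shape`` attributes, or a
    family-name string.  The distribution is evaluated at mean volume
    ``ubar``.  The fraction sum is *not* forced to one; inspect
    ``result.residual``.
    """
    from .distributions import SpineSizeDistribution

    if isinstance(dist, str):
        family, shape = dist, None
    else:
        family, shape = dist.family, dist.shape
    P = SpineSizeDistribution(family, ubar, shape).exceedance(theta)
    s = spine_fraction(x, y, P)
    g = glia_fraction(s, ubar, a) if s > 0 else 0.0
    c = capillary_fraction(g, s)
    return CompositionFractions(x, y, s, g, c, mean_spine_volume=ubar)
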