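"""Synthetic-data generators for end-to-end testing without downloads.

Two generators emulate the statistical structure the analysis assumes:

* cross-species composition tables with a controllable allometric
  slope per component and Gaussian noise on log10(fraction) — exactly
  the model under which the log-log OLS regression is well-specified,
  so slopes and the normalized reference are recoverable from the
  synthetic tables;
* Monte-Carlo spine-volume populations from any of the six families,
  for validating the closed-form means and exceedance probabilities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .distributions import SpineSizeDistribution
from .empirical import COMPONENTS, SpeciesComposition

__all__ = [
    "SyntheticTableSpec",
    "synth_composition_table",
    "synth_spine_samples",
    "SpineSampleSummary",
]


@dataclass(frozen=True)
class SyntheticTableSpec:
    """Generator spec for a synthetic cross-species composition table.

    Fractions are generated per component as

        fraction = 10^(intercept + slope * log10(V) + eps),
        eps ~ N(0, noise_sd),

    in percent, where the intercept is chosen so a species of geometric
    mean volume sits at ``true_fractions``.  Defaults mimic the scale of
    the real six-species table: volumes log-uniform over [0.1, 600] cm^3
    and the powers-of-1/3-like true composition.
    """

    n_species: int = 6
    true_fractions: tuple = (0.408, 0.355, 0.100, 0.122, 0.015)  # unitless
    log10_volume_range: tuple = (-1.0, np.log10(600.0))  # cm^3
    slopes: tuple = (0.0, 0.0, 0.0, 0.0, 0.0)  # per component
    noise_sd: tuple = (0.0, 0.0, 0.0, 0.0, 0.0)  # on log10(fraction)
    seed: int = 0

    def __post_init__(self):
        if self.n_species < 2:
            raise ValueError("need at least two species")
        if len(self.true_fractions) != 5 or len(self.slopes) != 5 \
                or len(self.noise_sd) != 5:
            raise ValueError("true_fractions, slopes and noise_sd need "
                             "five entries")
        if any(sd < 0 for sd in self.noise_sd):
            raise ValueError("noise sd must be >= 0")
        if any(not f > 0 for f in self.true_fractions):
            raise ValueError("true fractions must be > 0")


def synth_composition_table(spec: SyntheticTableSpec) -> list[SpeciesComposition]:
    """Generate a reproducible synthetic composition table.

    Raises if any generated fraction leaves (0, 100)%, reporting the
    offending component — noise on log10 keeps fractions positive, so
    only the upper bound can trip.
    """
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.log10_volume_range
    logv = np.sort(rng.uniform(lo, hi, spec.n_species))
    center = logv.mean()
    out = []
    for i, lv in enumerate(logv):
        fr = {}
        for j, comp in enumerate(COMPONENTS):
            log10f = (
                np.log10(spec.true_fractions[j] * 100.0)
                + spec.slopes[j] * (lv - center)
                + (rng.normal(0.0, spec.noise_sd[j]) if spec.noise_sd[j] else 0.0)
            )
            pct = 10.0**log10f
            if not (0.0 < pct < 100.0):
                raise ValueError(
                    f"synthetic {comp} fraction {pct:.3g}% outside (0, 100); "
                    "reduce slope/noise or true fraction"
                )
            fr[comp] = pct
        out.append(
            SpeciesComposition(
                species=f"synthetic_{i}",
                fractions=fr,
                sds={c: None for c in COMPONENTS},
                gray_matter_volume=10.0**lv,
            )
        )
    return out


@dataclass(frozen=True)
class SpineSampleSummary:
    samples: np.ndarray = field(repr=False)
    empirical_mean: float
    empirical_exceedance: float
    theta: float


def synth_spine_samples(
    family: str,
    mean_volume: float,
    theta: float,
    n: int,
    seed,
    shape: float | None = None,
) -> SpineSampleSummary:
    """Monte-Carlo spine population with its empirical summary.

    Returns the samples, their mean, and the empirical fraction of
    spines above the threshold ``theta`` (the Monte-Carlo estimate of
    the conditional probability of spine formation).
    """
    dist = SpineSizeDistribution(family, mean_volume, shape)
    u = dist.sample(n, seed)
    return SpineSampleSummary(
        samples=u,
        empirical_mean=float(u.mean()),
        empirical_exceedance=float(np.mean(u > theta)),
        theta=theta,
    )
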