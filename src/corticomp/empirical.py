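"""The empirical side: cross-species composition data and its analysis.

Ships a compiled table of gray-matter volume fractions for six mammals
(mouse to human) together with gray-matter volumes, and provides

* per-component species means and the normalization of those means to
  100% (the reference composition every model is compared against),
* the "powers of 1/3" rule — axons and dendrites each ~1/3 of cortical
  volume, spines and glia each ~(1/3)^2, capillaries ~(1/3)^4,
* allometric log-log regressions of component fraction on gray-matter
  volume across species (near-zero slopes = brain-size invariance).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "COMPONENTS",
    "SpeciesComposition",
    "EmpiricalReference",
    "AllometricFit",
    "builtin_table",
    "load_table",
    "write_table",
    "species_means",
    "recomputed_normalized_means",
    "normalized_reference",
    "powers_rule",
    "allometric_fit",
]

COMPONENTS = ("axons", "dendrites", "spines", "glia", "capillaries")

# Printed species-mean and normalized-mean reference rows (percent). The
# uncertainties of these rows come from the source compilation and are not
# re-derivable from the per-species entries, so they are stored verbatim;
# the model-data distances are only meaningful with these exact values.
SPECIES_MEAN_PCT = (39.0, 34.0, 9.6, 11.7, 1.4)
SPECIES_MEAN_SD_PCT = (2.3, 5.3, 2.0, 1.1, 0.1)
NORMALIZED_MEAN_PCT = (40.8, 35.5, 10.0, 12.2, 1.5)
NORMALIZED_SD_PCT = (2.4, 5.5, 2.1, 1.2, 0.1)


@dataclass(frozen=True)
class SpeciesComposition:
    """One species' fractions (%), uncertainties (%), and volume (cm^3)."""

    species: str
    fractions: dict  # component -> % or None if not reported
    sds: dict  # component -> % or None
    gray_matter_volume: float
    notes: dict | None = None

    def __post_init__(self):
        if not self.gray_matter_volume > 0:
            raise ValueError("gray-matter volume must be > 0")
        for comp, v in self.fractions.items():
            if v is not None and not (0.0 < v < 100.0):
                raise ValueError(f"{self.species} {comp}: fraction {v}% "
                                 "outside (0, 100)")


@dataclass(frozen=True)
class EmpiricalReference:
    """Reference composition for model-data distances (unitless fractions).

    ``means`` are the species means normalized to sum to one;
    ``sds`` their stated standard deviations.
    """

    means: np.ndarray
    sds: np.ndarray

    def __post_init__(self):
        if len(self.means) != 5 or len(self.sds) != 5:
            raise ValueError("reference needs exactly five components")
        if abs(float(np.sum(self.means)) - 1.0) > 1e-3:
            raise ValueError("normalized reference means must sum to 1")
        if np.any(np.asarray(self.sds) <= 0):
            raise ValueError("reference sds must all be > 0")


@dataclass(frozen=True)
class AllometricFit:
    """OLS fit of log10(fraction %) on log10(volume cm^3)."""

    component: str
    slope: float
    intercept: float
    r_squared: float
    p_value: float  # two-sided t-test on the slope
    n: int


def _table_to_species(df: pd.DataFrame) -> list[SpeciesComposition]:
    out = []
    for sp, grp in df.groupby("species", sort=False):
        fr = {c: None for c in COMPONENTS}
        sd = {c: None for c in COMPONENTS}
        notes = {}
        for _, row in grp.iterrows():
            comp = row["component"]
            if not pd.isna(row["fraction_pct"]):
                fr[comp] = float(row["fraction_pct"])
            if "sd_pct" in row and not pd.isna(row["sd_pct"]):
                sd[comp] = float(row["sd_pct"])
            if "note" in row and isinstance(row["note"], str) and row["note"]:
                notes[comp] = row["note"]
        out.append(
            SpeciesComposition(
                species=sp,
                fractions=fr,
                sds=sd,
                gray_matter_volume=float(grp["volume_cm3"].iloc[0]),
                notes=notes or None,
            )
        )
    return out


def load_table(path) -> list[SpeciesComposition]:
    """Read a composition table (CSV: species, component, fraction_pct,
    sd_pct, volume_cm3[, note]; ``#`` lines are comments)."""
    df = pd.read_csv(path, comment="#")
    return _table_to_species(df)


def write_table(species: list[SpeciesComposition], path) -> None:
    rows = []
    for sp in species:
        for comp in COMPONENTS:
            rows.append(
                dict(
                    species=sp.species,
                    component=comp,
                    fraction_pct=sp.fractions.get(comp),
                    sd_pct=sp.sds.get(comp),
                    volume_cm3=sp.gray_matter_volume,
                    note=(sp.notes or {}).get(comp, ""),
                )
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def builtin_table() -> list[SpeciesComposition]:
    """The compiled six-species table shipped with the package."""
    ref = importlib.resources.files("corticomp") / "data/cortical_composition.csv"
    with importlib.resources.as_file(ref) as path:
        return load_table(path)


def species_means(table: list[SpeciesComposition] | None = None) -> np.ndarray:
    """Unweighted per-component means (%) over species, skipping gaps."""
    table = builtin_table() if table is None else table
    return np.array(
        [
            np.mean([sp.fractions[c] for sp in table if sp.fractions[c] is not None])
            for c in COMPONENTS
        ]
    )


def recomputed_normalized_means(
    table: list[SpeciesComposition] | None = None, decimals: int | None = 1
) -> np.ndarray:
    """Species means rescaled so the five components sum to 100%.

    The means are rounded to ``decimals`` before normalizing (the
    published reference row was produced from 1-d.p. means; pass
    ``decimals=None`` to skip rounding).  Returns percent.
    """
    m = species_means(table)
    if decimals is not None:
        m = np.round(m, decimals)
    return m / m.sum() * 100.0


def normalized_reference() -> EmpiricalReference:
    """The reference composition used by all model-data distances.

    Means and standard deviations of the normalized-mean row, converted
    from percent to unitless fractions.
    """
    return EmpiricalReference(
        means=np.asarray(NORMALIZED_MEAN_PCT) / 100.0,
        sds=np.asarray(NORMALIZED_SD_PCT) / 100.0,
    )


def powers_rule() -> np.ndarray:
    """The "powers of 1/3" prediction as percent.

    (1/3, 1/3, (1/3)^2, (1/3)^2, (1/3)^4) -> (33.3, 33.3, 11.1, 11.1, 1.2).
    Note the rule is not normalized: the five values sum to ~90%.
    """
    thirds = np.array([1, 1, 2, 2, 4], dtype=float)
    return (1.0 / 3.0) ** thirds * 100.0


def allometric_fit(
    component: str, table: list[SpeciesComposition] | None = None
) -> AllometricFit:
    """Log-log scaling of one component's fraction with gray-matter volume.

    Ordinary least squares of log10(fraction %) on log10(volume cm^3),
    dropping species without data for the component (pairwise deletion).
    A slope near zero means the fraction is brain-size invariant.
    """
    if component not in COMPONENTS:
        raise ValueError(f"unknown component {component!r}")
    table = builtin_table() if table is None else table
    pts = [
        (sp.gray_matter_volume, sp.fractions[component])
        for sp in table
        if sp.fractions[component] is not None
    ]
    if len(pts) < 3:
        raise ValueError(
            f"need >= 3 species with data for {component}, have {len(pts)}"
        )
    v, f = np.array(pts).T
    X = sm.add_constant(np.log10(v))
    fit = sm.OLS(np.log10(f), X).fit()
    r2 = float(fit.rsquared)
    p = float(fit.pvalues[1])
    return AllometricFit(
        component=component,
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        # a perfectly flat response has zero total variance; report no fit
        r_squared=r2 if np.isfinite(r2) else 0.0,
        p_value=p if np.isfinite(p) else 1.0,
        n=len(pts),
    )
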