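"""Model-data distances, parameter sweeps, and best-fit table extraction.

The similarity between a model's five-component composition and the
empirical reference is quantified by the Euclidean distance

    ED = sqrt( sum_i (x_i - x_ex,i)^2 )

and its variance-normalized counterpart, the Mahalanobis distance

    MD = sqrt( sum_i ((x_i - x_ex,i)/sd_ex,i)^2 ),

both on unitless fractions.  Sweeps solve the stationarity system on
parameter grids (asymmetry r, spine-cost exponent gamma2, distribution
shape, threshold theta, mixing ratio f) and extract the minimal-ED and
minimal-MD solutions, reproducing the best-fit tables and the profile
curves of the composition-optimization study design.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .distributions import FAMILIES
from .empirical import EmpiricalReference, normalized_reference
from .model import (
    WIRE_EXPONENTS,
    PrincipleSpec,
    SolverSettings,
    TissueCompositionModel,
)

__all__ = [
    "DistanceResult",
    "SweepResult",
    "euclidean_distance",
    "mahalanobis_distance",
    "model_data_distance",
    "sweep_minimize",
    "reproduce_table",
    "profile_curves",
    "DEFAULT_GRIDS",
]

#: default sweep grids, mirroring the resolution of the reference tables
DEFAULT_GRIDS = {
    "r": np.round(np.arange(0.50, 1.2001, 0.01), 10),
    "gamma2": np.round(np.arange(0.05, 7.0001, 0.05), 10),
    "sigma": np.round(np.arange(0.10, 1.0001, 0.05), 10),   # log-normal
    "beta": np.round(np.arange(1.5, 7.0001, 0.5), 10),      # log-logistic
    "theta": (0.100, 0.321),
    "f": (0.0, 0.1, 0.5, 0.9, 1.0),
}


def euclidean_distance(fractions, reference: EmpiricalReference) -> float:
    """ED between a five-vector of unitless fractions and the reference."""
    fractions = np.asarray(fractions, dtype=float)
    if fractions.shape != (5,):
        raise ValueError("expected exactly five fractions")
    return float(np.sqrt(np.sum((fractions - reference.means) ** 2)))


def mahalanobis_distance(fractions, reference: EmpiricalReference) -> float:
    """Variance-normalized ED; reduces to ED when all sds equal one."""
    fractions = np.asarray(fractions, dtype=float)
    if fractions.shape != (5,):
        raise ValueError("expected exactly five fractions")
    z = (fractions - reference.means) / reference.sds
    return float(np.sqrt(np.sum(z**2)))


@dataclass(frozen=True)
class DistanceResult:
    """ED and MD with per-component contributions (squared terms)."""

    ed: float
    md: float
    ed_contributions: np.ndarray
    md_contributions: np.ndarray


def model_data_distance(fractions, reference: EmpiricalReference) -> DistanceResult:
    fractions = np.asarray(fractions, dtype=float)
    d = fractions - reference.means
    return DistanceResult(
        ed=euclidean_distance(fractions, reference),
        md=mahalanobis_distance(fractions, reference),
        ed_contributions=d**2,
        md_contributions=(d / reference.sds) ** 2,
    )


# ---------------------------------------------------------------------------
# sweeps


@dataclass
class SweepResult:
    """All solved grid points of one sweep plus the argmin records."""

    base_spec: PrincipleSpec
    grids: dict
    records: pd.DataFrame = field(repr=False)
    failures: pd.DataFrame = field(repr=False)

    def _argmin(self, col: str) -> pd.Series:
        if self.records.empty:
            raise RuntimeError("sweep produced no converged solutions")
        return self.records.loc[self.records[col].idxmin()]

    @property
    def min_ed(self) -> pd.Series:
        return self._argmin("ed")

    @property
    def min_md(self) -> pd.Series:
        return self._argmin("md")


def _spec_with(base: PrincipleSpec, **overrides) -> PrincipleSpec:
    from dataclasses import replace

    return replace(base, **overrides)


def sweep_minimize(
    base_spec: PrincipleSpec,
    grids: dict,
    reference: EmpiricalReference | None = None,
    settings: SolverSettings | None = None,
    warm_start: bool = True,
) -> SweepResult:
    """Solve on the Cartesian product of parameter grids.

    ``grids`` maps PrincipleSpec field names (``r``, ``gamma2``,
    ``shape``, ``theta``, ``f``, ``gamma1``) to value sequences.  Every
    grid point is solved; non-converged points are recorded in
    ``failures`` and excluded from the argmin — never silently dropped.
    Consecutive solves along the last grid axis are warm-started, while
    the multi-start battery still guards against branch switching.
    """
    reference = reference or normalized_reference()
    names = list(grids)
    rows, fails = [], []
    prev_params = None
    for values in itertools.product(*(grids[n] for n in names)):
        overrides = dict(zip(names, values))
        spec = _spec_with(base_spec, **overrides)
        model = TissueCompositionModel(spec, reference=reference,
                                       settings=settings)
        start = prev_params if (warm_start and prev_params is not None) else None
        res = model.fit(start=start)
        if not res.converged:
            fails.append(overrides)
            prev_params = None
            continue
        if not res.divergent:
            prev_params = res.params
        fr = res.fractions
        d = model_data_distance(fr.as_array(), reference)
        rows.append(
            {
                **overrides,
                "x": fr.x, "y": fr.y, "s": fr.s, "g": fr.g, "c": fr.c,
                "ubar": res.mean_spine_volume, "P": res.P,
                "ed": d.ed, "md": d.md,
                "extremum_class": res.extremum_class,
                "objective": res.fun,
            }
        )
    return SweepResult(
        base_spec=base_spec,
        grids=grids,
        records=pd.DataFrame(rows),
        failures=pd.DataFrame(fails),
    )


def _round_half_away(v: float, nd: int = 3) -> float:
    import math

    m = 10**nd
    return math.copysign(math.floor(abs(v) * m + 0.5) / m, v)


def _best_row(sweep: SweepResult, by: str) -> dict:
    row = sweep._argmin(by)
    out = {}
    for k, v in row.items():
        if isinstance(v, (int, float, np.floating)) and k != "extremum_class":
            out[k] = _round_half_away(float(v)) if np.isfinite(v) else float(v)
        else:
            out[k] = v
    return out


def _family_grids(family: str, gamma2_grid, r_grid=None) -> dict:
    """Per-family sweep grids: shape parameter where applicable."""
    grids: dict = {}
    if family == "loglogistic":
        grids["shape"] = DEFAULT_GRIDS["beta"]
    elif family == "lognormal":
        grids["shape"] = DEFAULT_GRIDS["sigma"]
    if r_grid is not None:
        grids["r"] = r_grid
    if gamma2_grid is not None:
        grids["gamma2"] = gamma2_grid
    return grids


def reproduce_table(
    which: int,
    theta: float | tuple = (0.100, 0.321),
    families=FAMILIES,
    r_grid=None,
    gamma2_grid=None,
    reference: EmpiricalReference | None = None,
) -> pd.DataFrame:
    """Best-fit rows per distribution for the published table layouts.

    ``which``: 2 = pure wire-volume minimization (f=1, gamma1=0; sweep r
    and shape; minimal-ED and minimal-MD rows per theta); 3 = pure
    spine-economy maximization (f=0; sweep gamma2 and shape); 4/5/6 =
    the mixed meta-principle with f = 0.1/0.5/0.9, one block per
    wire-cost flavour (gamma1 = 2/3, 1/3, 0, 5/6), minimal-MD row only,
    at theta = 0.321.  Values are rounded to 3 decimals,
    half-away-from-zero.
    """
    reference = reference or normalized_reference()
    thetas = (theta,) if np.isscalar(theta) else tuple(theta)
    rows = []

    if which == 2:
        r_grid = DEFAULT_GRIDS["r"] if r_grid is None else r_grid
        for fam in families:
            for th in thetas:
                base = PrincipleSpec(family=fam, f=1.0, gamma1=0.0, theta=th,
                                     shape=_default_shape(fam), gamma2=1.0)
                sw = sweep_minimize(base, _family_grids(fam, None, r_grid),
                                    reference)
                for by in ("ed", "md"):
                    rows.append({"family": fam, "theta": th, "criterion": by,
                                 **_best_row(sw, by)})
    elif which == 3:
        gamma2_grid = (
            np.round(np.arange(0.05, 1.5001, 0.05), 10)
            if gamma2_grid is None else gamma2_grid
        )
        for fam in families:
            for th in thetas:
                base = PrincipleSpec(family=fam, f=0.0, theta=th,
                                     shape=_default_shape(fam))
                sw = sweep_minimize(base, _family_grids(fam, gamma2_grid),
                                    reference)
                for by in ("ed", "md"):
                    rows.append({"family": fam, "theta": th, "criterion": by,
                                 **_best_row(sw, by)})
    elif which in (4, 5, 6):
        f = {4: 0.1, 5: 0.5, 6: 0.9}[which]
        th = thetas[-1] if not np.isscalar(theta) else theta
        r_grid = DEFAULT_GRIDS["r"] if r_grid is None else r_grid
        gamma2_grid = DEFAULT_GRIDS["gamma2"] if gamma2_grid is None else gamma2_grid
        for flavour, g1 in WIRE_EXPONENTS.items():
            for fam in families:
                base = PrincipleSpec(family=fam, f=f, gamma1=g1, theta=th,
                                     shape=_default_shape(fam))
                sw = sweep_minimize(
                    base, _family_grids(fam, gamma2_grid, r_grid), reference
                )
                rows.append({"wire_cost": flavour, "gamma1": g1, "f": f,
                             "family": fam, "theta": th, "criterion": "md",
                             **_best_row(sw, "md")})
    else:
        raise ValueError("which must be one of 2, 3, 4, 5, 6")
    return pd.DataFrame(rows)


def _default_shape(family: str) -> float | None:
    return {"loglogistic": 3.0, "lognormal": 0.3}.get(family)


def profile_curves(
    base_spec: PrincipleSpec,
    parameter: str,
    grid,
    shape_grid=None,
    reference: EmpiricalReference | None = None,
) -> pd.DataFrame:
    """Solution profile along one parameter, for plotting.

    For each grid value the model is solved (minimizing over
    ``shape_grid`` for the heavy-tailed families when given, matching
    the published figure convention) and (fractions, ubar, P, ED, MD)
    recorded.
    """
    reference = reference or normalized_reference()
    rows = []
    for v in grid:
        if shape_grid is not None:
            sw = sweep_minimize(
                _spec_with(base_spec, **{parameter: v}),
                {"shape": shape_grid}, reference,
            )
            if sw.records.empty:
                continue
            row = sw.min_ed.to_dict()
        else:
            spec = _spec_with(base_spec, **{parameter: v})
            res = TissueCompositionModel(spec, reference=reference).fit()
            if not res.converged:
                continue
            fr = res.fractions
            d = model_data_distance(fr.as_array(), reference)
            row = {"x": fr.x, "y": fr.y, "s": fr.s, "g": fr.g, "c": fr.c,
                   "ubar": res.mean_spine_volume, "P": res.P,
                   "ed": d.ed, "md": d.md}
        row[parameter] = v
        rows.append(row)
    return pd.DataFrame(rows)
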