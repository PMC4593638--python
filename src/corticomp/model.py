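"""Constrained optimization of cortical tissue composition.

The meta fitness function combines two design principles with mixing
ratio f in [0, 1]:

    F(x, y, ubar) = f (r x + y) / ubar^gamma1  -  (1-f) s / ubar^gamma2

with the spine fraction s = P(ubar; theta) x y, the glia and capillary
fractions g = a (s/ubar)^(2/3), c = g s slaved to (x, y, ubar), and the
normalization constraint x + y + s + g + c = 1.  f = 1 is pure neural
wire minimization (gamma1 = 0 wire volume, 1/3 surface area, 2/3 length,
5/6 conduction delays; r the axon/dendrite asymmetry); f = 0 is pure
spine-economy maximization (maximize s per unit spine-size cost
ubar^gamma2).  Minimizing F covers both: the spine term enters with a
negative sign.

Stationary points satisfy the Lagrange conditions; the multiplier is
eliminated via cross products of the objective and constraint gradients,
leaving three residual equations solved by multi-start root finding.
For f*gamma1 > 0 the wire term can push ubar to infinity; the analytic
limit branch (P = 1, g = c = 0, s = x y) then applies.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .coupling import DEFAULT_CONSTANTS, CompositionFractions
from .distributions import SpineSizeDistribution, exceedance_functions

__all__ = [
    "PrincipleSpec",
    "SolverSettings",
    "TissueCompositionModel",
    "CompositionResults",
    "wire_limit_solution",
    "wire_stationarity_sides",
    "spine_stationarity_sides",
]

#: exponent gamma1 of each wire-minimization flavour
WIRE_EXPONENTS = {
    "volume": 0.0,
    "surface": 1.0 / 3.0,
    "length": 2.0 / 3.0,
    "delays": 5.0 / 6.0,
}


@dataclass(frozen=True)
class PrincipleSpec:
    """One fully specified fitness function.

    Parameters
    ----------
    f : float
        Mixing ratio in [0, 1]: 1 = pure wire minimization, 0 = pure
        spine-economy maximization.
    gamma1 : float
        Wire-cost exponent (0, 1/3, 2/3 or 5/6 for volume, surface,
        length, delays; any real >= 0 accepted).
    gamma2 : float
        Spine-size cost exponent (> 0 whenever f < 1).
    r : float
        Axon/dendrite asymmetry (> 0); may exceed 1.
    theta : float
        Spine-formation volume threshold, um^3 (>= 0).
    family, shape :
        Spine-size distribution family and its shape parameter.
    a : float
        Astrocyte coupling constant, um^2.
    """

    family: str = "exponential"
    shape: float | None = None
    f: float = 0.0
    gamma1: float = 0.0
    gamma2: float = 0.5
    r: float = 1.0
    theta: float = 0.321
    a: float = DEFAULT_CONSTANTS.a

    def __post_init__(self):
        if not (0.0 <= self.f <= 1.0):
            raise ValueError("mixing ratio f must be in [0, 1]")
        if self.gamma1 < 0:
            raise ValueError("gamma1 must be >= 0")
        if self.f < 1.0 and not self.gamma2 > 0:
            raise ValueError("gamma2 must be > 0 when the spine term is active")
        if not self.r > 0:
            raise ValueError("asymmetry r must be > 0")
        if self.theta < 0:
            raise ValueError("threshold theta must be >= 0")
        # validate family/shape eagerly
        exceedance_functions(self.family, self.shape)

    def distribution(self, ubar: float) -> SpineSizeDistribution:
        return SpineSizeDistribution(self.family, ubar, self.shape)


@dataclass(frozen=True)
class SolverSettings:
    """Numerical settings of the stationarity solver."""

    residual_tol: float = 1e-8  # max acceptable stationarity residual norm
    constraint_tol: float = 1e-9
    divergence_cap: float = 1e4  # ubar above this flags the divergent limit
    x_starts: tuple = (0.25, 0.33, 0.40, 0.46)
    ubar_starts: tuple = (0.03, 0.1, 0.3, 0.65, 1.2, 3.0, 10.0)
    dedup_decimals: int = 6
    fraction_floor: float = 1e-6  # roots with any fraction below are discarded


# ---------------------------------------------------------------------------
# analytic gradients of objective and constraint


def _pieces(spec: PrincipleSpec, x, y, ub, P, dPdu):
    """Values and partials of s, g, c and the constraint C = sum - 1."""
    a = spec.a
    s = P * x * y
    sx, sy, su = P * y, P * x, dPdu * x * y
    u23 = ub ** (2.0 / 3.0)
    if s > 0:
        g = a * s ** (2.0 / 3.0) / u23
        dg_ds = (2.0 / 3.0) * a * s ** (-1.0 / 3.0) / u23
    else:
        g, dg_ds = 0.0, 0.0
    dg_du_expl = -(2.0 / 3.0) * g / ub  # explicit ubar dependence of g
    gx, gy = dg_ds * sx, dg_ds * sy
    gu = dg_ds * su + dg_du_expl
    c = g * s
    cx, cy = gx * s + g * sx, gy * s + g * sy
    cu = gu * s + g * su
    Cx = 1.0 + sx + gx + cx
    Cy = 1.0 + sy + gy + cy
    Cu = su + gu + cu
    Cval = x + y + s + g + c - 1.0
    return s, g, c, (Cx, Cy, Cu), Cval


def _objective_grad(spec: PrincipleSpec, x, y, ub, P, dPdu):
    """F and its gradient w.r.t. (x, y, ubar)."""
    f, g1, g2, r = spec.f, spec.gamma1, spec.gamma2, spec.r
    w = ub**-g1 if f > 0 else 0.0
    v = ub**-g2 if f < 1 else 0.0
    F = f * (r * x + y) * w - (1.0 - f) * P * x * y * v
    Fx = f * r * w - (1.0 - f) * P * y * v
    Fy = f * w - (1.0 - f) * P * x * v
    Fu = -f * g1 * (r * x + y) * w / ub - (1.0 - f) * x * y * (
        dPdu * v - g2 * P * v / ub
    )
    return F, (Fx, Fy, Fu)


class TissueCompositionModel:
    """Optimal cortical composition under one design principle.

    statsmodels-style interface: build the model from a
    :class:`PrincipleSpec` (and optionally the empirical reference
    composition), call :meth:`fit` to obtain a
    :class:`CompositionResults`.

    Examples
    --------
    >>> from corticomp import PrincipleSpec, TissueCompositionModel
    >>> spec = PrincipleSpec(family="exponential", f=0.0, gamma2=0.45,
    ...                      theta=0.321)
    >>> res = TissueCompositionModel(spec).fit()
    >>> round(res.fractions.s, 3)
    0.098
    """

    def __init__(self, spec: PrincipleSpec, reference=None,
                 settings: SolverSettings | None = None):
        self.spec = spec
        self.reference = reference
        self.settings = settings or SolverSettings()
        self._P, self._dP = exceedance_functions(spec.family, spec.shape)

    # -- residuals ------------------------------------------------------

    def stationarity_residuals(self, x: float, y: float, ubar: float) -> np.ndarray:
        """Lambda-free first-order conditions at (x, y, ubar).

        Residual vector ``[Fx*Cy - Fy*Cx, Fy*Cu - Fu*Cy, C - 1]`` where F
        is the objective and C the fraction sum; all three vanish at a
        stationary point of the constrained problem.
        """
        th = self.spec.theta
        P, dPdu = self._P(ubar, th), self._dP(ubar, th)
        _, _, _, (Cx, Cy, Cu), Cval = _pieces(self.spec, x, y, ubar, P, dPdu)
        _, (Fx, Fy, Fu) = _objective_grad(self.spec, x, y, ubar, P, dPdu)
        return np.array([Fx * Cy - Fy * Cx, Fy * Cu - Fu * Cy, Cval])

    def lagrange_multiplier(self, x: float, y: float, ubar: float) -> float:
        """Multiplier of the normalization constraint, lam = -Fx/Cx."""
        th = self.spec.theta
        P, dPdu = self._P(ubar, th), self._dP(ubar, th)
        _, _, _, (Cx, _, _), _ = _pieces(self.spec, x, y, ubar, P, dPdu)
        _, (Fx, _, _) = _objective_grad(self.spec, x, y, ubar, P, dPdu)
        return -Fx / Cx

    def objective(self, x: float, y: float, ubar: float) -> float:
        """The meta fitness F at (x, y, ubar)."""
        th = self.spec.theta
        P, dPdu = self._P(ubar, th), self._dP(ubar, th)
        F, _ = _objective_grad(self.spec, x, y, ubar, P, dPdu)
        return F

    def composition(self, x: float, y: float, ubar: float) -> CompositionFractions:
        P = float(self._P(ubar, self.spec.theta))
        s = P * x * y
        g = self.spec.a * (s / ubar) ** (2.0 / 3.0) if s > 0 else 0.0
        return CompositionFractions(x, y, s, g, g * s, mean_spine_volume=ubar)

    # -- solving --------------------------------------------------------

    def _root_from(self, start) -> np.ndarray | None:
        spec = self.spec
        symmetric = spec.f == 0.0  # x = y by symmetry of the spine principle

        if symmetric:

            def fun(z):
                x, ub = z
                if x <= 0 or x >= 1 or ub <= 0:
                    return [1e6, 1e6]
                rr = self.stationarity_residuals(x, x, ub)
                return [rr[1], rr[2]]

            sol = optimize.root(fun, [start[0], start[2]], method="hybr",
                                options={"xtol": 1e-13})
            if not sol.success:
                return None
            x, ub = sol.x
            z = np.array([x, x, ub])
        else:

            def fun(z):
                x, y, ub = z
                if min(x, y) <= 0 or max(x, y) >= 1 or ub <= 0:
                    return [1e6, 1e6, 1e6]
                return self.stationarity_residuals(x, y, ub)

            sol = optimize.root(fun, list(start), method="hybr",
                                options={"xtol": 1e-13})
            if not sol.success:
                return None
            z = sol.x

        x, y, ub = z
        st = self.settings
        if not (st.fraction_floor < x < 1 - st.fraction_floor
                and st.fraction_floor < y < 1 - st.fraction_floor
                and ub > 0):
            return None
        rr = self.stationarity_residuals(x, y, ub)
        if np.linalg.norm(rr) > st.residual_tol or abs(rr[2]) > st.constraint_tol:
            return None
        return z

    def _collect_roots(self, extra_starts=()) -> list[np.ndarray]:
        st = self.settings
        roots: dict[tuple, np.ndarray] = {}
        starts = [tuple(s) for s in extra_starts]
        starts += [
            (x0, x0, u0)
            for x0, u0 in itertools.product(st.x_starts, st.ubar_starts)
        ]
        for s in starts:
            z = self._root_from(s)
            if z is None:
                continue
            key = tuple(np.round(z, st.dedup_decimals))
            roots.setdefault(key, z)
        return list(roots.values())

    def fit(self, start=None) -> "CompositionResults":
        """Solve the stationarity system and return the optimal solution.

        Multi-start root finding (optionally warm-started from ``start``
        = (x, y, ubar)); among distinct stationary points the one with
        the best objective value is selected — minimal F for f > 0,
        maximal spine economy F_s = s/ubar^gamma2 for f = 0.  If the
        wire term is active with gamma1 > 0 and the solution runs away
        in ubar, the analytic divergent-limit branch is returned.
        """
        spec = self.spec
        if spec.f == 1.0 and spec.gamma1 > 0:
            # F_w -> 0 only as ubar -> inf; no finite stationary point
            return self._limit_results()

        extra = [tuple(start)] if start is not None else []
        roots = self._collect_roots(extra_starts=extra)
        finite = [z for z in roots if z[2] <= self.settings.divergence_cap]
        runaway = len(roots) > len(finite)

        if not finite:
            if spec.f * spec.gamma1 > 0:
                return self._limit_results()
            return CompositionResults(
                model=self, params=None, converged=False,
                extremum_class="none", n_roots=len(roots),
            )

        best = self._select_root(finite)
        if spec.f * spec.gamma1 > 0 and runaway:
            # compare against the limit branch, which has objective -> 0-
            Fbest = self.objective(*best)
            if Fbest >= 0.0:
                return self._limit_results()
        return self._results_at(best, n_roots=len(roots))

    def _select_root(self, roots) -> np.ndarray:
        if self.spec.f == 0.0:
            # maximize spine economy s / ubar^gamma2  (= -F)
            key = lambda z: -self.objective(*z)
            return max(roots, key=key)
        return min(roots, key=lambda z: self.objective(*z))

    def _results_at(self, z, n_roots=1) -> "CompositionResults":
        x, y, ub = z
        return CompositionResults(
            model=self,
            params=np.asarray(z, dtype=float),
            converged=True,
            extremum_class=self.classify_extremum(x, y, ub),
            n_roots=n_roots,
        )

    def _limit_results(self) -> "CompositionResults":
        x, y = wire_limit_solution(self.spec.r)
        return CompositionResults(
            model=self,
            params=np.array([x, y, math.inf]),
            converged=True,
            extremum_class="divergent-limit",
            n_roots=0,
        )

    # -- independent grid oracle ----------------------------------------

    def grid_search(self, n_x: int = 120, n_ubar: int = 160,
                    ubar_range=(1e-3, 50.0), polish: bool = True):
        """Direct constrained optimization, independent of stationarity.

        For every (x, ubar) on a dense grid the dendrite fraction y is
        obtained from the normalization constraint by bisection (the
        constraint is strictly increasing in y), the objective is
        evaluated, and the best feasible point — minimal F, or maximal
        F_s when f = 0 — is optionally polished by Nelder-Mead in
        (x, log ubar).  Returns ``(params, on_boundary)``.
        """
        spec = self.spec
        th = spec.theta
        # F already carries the spine term with a negative sign, so
        # minimizing F maximizes spine economy in the f = 0 case too
        sign = 1.0

        def y_from_constraint(x, ub):
            P = float(self._P(ub, th))

            def con(y):
                s = P * x * y
                g = spec.a * (s / ub) ** (2.0 / 3.0) if s > 0 else 0.0
                return x + y + s + g + g * s - 1.0

            hi = 1.0 - x
            if con(0.0) >= 0 or con(hi) <= 0:
                return None
            return optimize.brentq(con, 0.0, hi, xtol=1e-14)

        def value(x, ub):
            y = y_from_constraint(x, ub)
            if y is None:
                return None, None
            return sign * self.objective(x, y, ub), y

        xs = np.linspace(0.02, 0.95, n_x)
        ubs = np.geomspace(*ubar_range, n_ubar)
        best = (np.inf, None)
        for x in xs:
            for ub in ubs:
                v, y = value(x, ub)
                if v is not None and v < best[0]:
                    best = (v, (x, y, ub))
        if best[1] is None:
            raise RuntimeError("no feasible point found on the grid")
        x0, y0, ub0 = best[1]
        on_boundary = (
            x0 in (xs[0], xs[-1]) or ub0 in (ubs[0], ubs[-1])
        )
        if polish:
            def nm(v):
                x, logu = v
                if not 0 < x < 1:
                    return np.inf
                val, _ = value(x, math.exp(logu))
                return np.inf if val is None else val

            opt = optimize.minimize(
                nm, [x0, math.log(ub0)], method="Nelder-Mead",
                options={"xatol": 1e-10, "fatol": 1e-14, "maxiter": 2000},
            )
            x0, ub0 = opt.x[0], math.exp(opt.x[1])
            y0 = y_from_constraint(x0, ub0)
        return np.array([x0, y0, ub0]), on_boundary

    # -- extremum classification ----------------------------------------

    def classify_extremum(self, x: float, y: float, ubar: float) -> str:
        """Nature of the stationary point w.r.t. the principle's fitness.

        The reduced (constraint-projected) Hessian of the appropriate
        Lagrangian is evaluated numerically: for f = 0 the spine-economy
        fitness F_s (optimum expected to be a maximum), otherwise the
        (meta) fitness F (minimum).  Sign pattern of its eigenvalues
        gives 'min', 'max' or 'saddle'; near-singular Hessians are
        flagged 'indeterminate'.
        """
        spec = self.spec
        th = spec.theta

        if spec.f == 0.0:
            # classify w.r.t. F_s = s / ubar^gamma2 = -F
            def obj(z):
                return -self.objective(*z)
        else:
            def obj(z):
                return self.objective(*z)

        def con(z):
            xx, yy, uu = z
            P = float(self._P(uu, th))
            s = P * xx * yy
            g = spec.a * (s / uu) ** (2.0 / 3.0) if s > 0 else 0.0
            return xx + yy + s + g + g * s - 1.0

        z0 = np.array([x, y, ubar], dtype=float)

        def num_grad(fn, z, h=1e-6):
            out = np.zeros(3)
            for i in range(3):
                hp = h * max(1.0, abs(z[i]))
                zp, zm = z.copy(), z.copy()
                zp[i] += hp
                zm[i] -= hp
                out[i] = (fn(zp) - fn(zm)) / (2 * hp)
            return out

        gC = num_grad(con, z0)
        gO = num_grad(obj, z0)
        lam = -float(gO @ gC) / float(gC @ gC)

        def lagr(z):
            return obj(z) + lam * con(z)

        # numeric Hessian of the Lagrangian
        H = np.zeros((3, 3))
        h = 1e-4
        for i in range(3):
            hp = h * max(1.0, abs(z0[i]))
            zp, zm = z0.copy(), z0.copy()
            zp[i] += hp
            zm[i] -= hp
            H[i] = (num_grad(lagr, zp) - num_grad(lagr, zm)) / (2 * hp)
        H = 0.5 * (H + H.T)

        # tangent basis of the constraint surface
        n = gC / np.linalg.norm(gC)
        Q = np.linalg.qr(
            np.column_stack([n, np.eye(3)[:, :2]])
        )[0][:, 1:]
        red = Q.T @ H @ Q
        ev = np.linalg.eigvalsh(red)
        scale = max(np.abs(ev).max(), 1e-12)
        if np.any(np.abs(ev) / scale < 1e-6):
            return "indeterminate"
        if np.all(ev > 0):
            return "min"
        if np.all(ev < 0):
            return "max"
        return "saddle"


@dataclass(frozen=True)
class CompositionResults:
    """Stationary point of one fitness function, with diagnostics."""

    model: TissueCompositionModel
    params: np.ndarray | None  # (x, y, ubar); ubar = inf on the limit branch
    converged: bool
    extremum_class: str
    n_roots: int = 1

    # -- derived quantities ---------------------------------------------

    @property
    def spec(self) -> PrincipleSpec:
        return self.model.spec

    @property
    def divergent(self) -> bool:
        return self.extremum_class == "divergent-limit"

    @property
    def x(self) -> float:
        return float(self.params[0])

    @property
    def y(self) -> float:
        return float(self.params[1])

    @property
    def mean_spine_volume(self) -> float:
        return float(self.params[2])

    @property
    def P(self) -> float:
        if self.divergent:
            return 1.0
        return float(self.model._P(self.mean_spine_volume, self.spec.theta))

    @property
    def fractions(self) -> CompositionFractions:
        if self.divergent:
            x, y = self.x, self.y
            return CompositionFractions(x, y, x * y, 0.0, 0.0,
                                        mean_spine_volume=math.inf)
        return self.model.composition(*self.params)

    @property
    def fun(self) -> float:
        """Objective value F at the solution (0 on the limit branch)."""
        if self.divergent:
            return 0.0
        return self.model.objective(*self.params)

    @property
    def residual_norm(self) -> float:
        if self.divergent:
            return 0.0
        return float(np.linalg.norm(
            self.model.stationarity_residuals(*self.params)))

    @property
    def lagrange_multiplier(self) -> float:
        if self.divergent:
            return float("nan")
        return self.model.lagrange_multiplier(*self.params)

    # -- comparison with data -------------------------------------------

    def distance_to(self, reference=None):
        from .comparison import model_data_distance

        reference = reference or self.model.reference
        if reference is None:
            raise ValueError("no empirical reference supplied")
        return model_data_distance(self.fractions.as_array(), reference)

    def summary(self) -> str:
        sp = self.spec
        fr = self.fractions
        lines = [
            "Tissue composition optimum",
            "=" * 44,
            f"principle: f={sp.f:g}  gamma1={sp.gamma1:g}  gamma2={sp.gamma2:g}",
            f"distribution: {sp.family}"
            + (f" (shape={sp.shape:g})" if sp.shape is not None else ""),
            f"r={sp.r:g}  theta={sp.theta:g} um^3  a={sp.a:.4g} um^2",
            "-" * 44,
            f"converged: {self.converged}   class: {self.extremum_class}",
            f"x (axons)       = {fr.x:.4f}",
            f"y (dendrites)   = {fr.y:.4f}",
            f"s (spines)      = {fr.s:.4f}",
            f"g (glia)        = {fr.g:.4f}",
            f"c (capillaries) = {fr.c:.4f}",
            f"ubar            = {self.mean_spine_volume:.4g} um^3",
            f"P               = {self.P:.4f}",
        ]
        if self.converged and not self.divergent:
            lines += [
                f"F               = {self.fun:.6g}",
                f"lambda          = {self.lagrange_multiplier:.6g}",
                f"residual norm   = {self.residual_norm:.2e}",
            ]
        ref = self.model.reference
        if ref is not None:
            d = self.distance_to(ref)
            lines += [f"ED = {d.ed:.4f}   MD = {d.md:.4f}"]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        sp = self.spec
        fr = self.fractions if self.params is not None else None
        out = {
            "spec": {
                "family": sp.family, "shape": sp.shape, "f": sp.f,
                "gamma1": sp.gamma1, "gamma2": sp.gamma2, "r": sp.r,
                "theta": sp.theta, "a": sp.a,
            },
            "converged": self.converged,
            "extremum_class": self.extremum_class,
        }
        if fr is not None:
            out.update(
                x=fr.x, y=fr.y, s=fr.s, g=fr.g, c=fr.c,
                ubar=self.mean_spine_volume, P=self.P,
                objective=self.fun,
                residual_norm=self.residual_norm,
            )
        return out


# ---------------------------------------------------------------------------
# analytic wire-minimization limit (f*gamma1 > 0, ubar -> inf)


def wire_limit_solution(r: float) -> tuple[float, float]:
    """Limit composition for wire minimization with gamma1 > 0.

    As ubar -> inf, P -> 1 and g, c -> 0, so the constraint becomes
    x + y + x y = 1 while the first-order condition in (x, y) reduces to
    r x - y = 1 - r.  Substituting y = r x - 1 + r gives the quadratic
    r x^2 + 2 r x - (2 - r) = 0 with the positive root below.
    """
    if not 0 < r:
        raise ValueError("asymmetry r must be > 0")
    disc = 4 * r * r + 4 * r * (2 - r)
    x = (-2 * r + math.sqrt(disc)) / (2 * r)
    y = r * x - 1 + r
    if not (0 < x < 1 and 0 < y < 1):
        raise ValueError(f"limit composition infeasible for r={r}")
    return x, y


# ---------------------------------------------------------------------------
# printed reduced stationarity systems (test oracles)


def wire_stationarity_sides(spec: PrincipleSpec, x, y, ubar):
    """LHS and RHS of the reduced axon/dendrite condition for f = 1:

        (r x - y) [P + (a/3) (P^2/(x y ubar^2))^(1/3) (2 + 5 P x y)]
            = 1 - r
    """
    P_fn, _ = exceedance_functions(spec.family, spec.shape)
    P = float(P_fn(ubar, spec.theta))
    a = spec.a
    lhs = (spec.r * x - y) * (
        P + (a / 3.0) * (P * P / (x * y * ubar * ubar)) ** (1.0 / 3.0)
        * (2.0 + 5.0 * P * x * y)
    )
    return lhs, 1.0 - spec.r


def spine_stationarity_sides(spec: PrincipleSpec, x, ubar):
    """LHS and RHS of the reduced ubar condition for f = 0 (x = y):

        ubar^(2/3) dP/dubar
            = (P/ubar) (gamma2 ubar^(2/3) (1 + P x)
               + (a/3) P^(2/3) x^(1/3) [2(gamma2-1) + (5 gamma2-2) P x^2])
    """
    P_fn, dP_fn = exceedance_functions(spec.family, spec.shape)
    th, g2, a = spec.theta, spec.gamma2, spec.a
    P, dP = float(P_fn(ubar, th)), float(dP_fn(ubar, th))
    lhs = ubar ** (2.0 / 3.0) * dP
    rhs = (P / ubar) * (
        g2 * ubar ** (2.0 / 3.0) * (1.0 + P * x)
        + (a / 3.0) * P ** (2.0 / 3.0) * x ** (1.0 / 3.0)
        * (2.0 * (g2 - 1.0) + (5.0 * g2 - 2.0) * P * x * x)
    )
    return lhs, rhs
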