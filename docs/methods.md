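# Methods

## The model

The cortical gray matter is partitioned into five volume fractions —
axons x, dendrites y, spines s, glia/astrocytes g, capillaries c —
summing to one. Three of these are independent in the model: x, y and
the mean spine volume ū (µm³). The rest follow from coupling laws:

* **Spines.** A potential synapse forms where an axon and a dendrite
  coincide (geometric probability x·y) *and* the potential spine
  exceeds a volume threshold θ, so `s = P(ū; θ)·x·y` with
  `P = ∫_θ^∞ H(u) du`. The threshold encodes a minimum metabolic
  allocation for a stable spine; equivalently, spine density obeys
  ρ_s = s/ū.
* **Glia.** Each astrocyte tiles a non-overlapping domain and reaches
  its N_s spines through a process tree of minimal total length
  L = b·N_s^{2/3}·V^{1/3}, b = (3/4π)^{1/3} ≈ 0.6204. With cylindrical
  processes of mean diameter d_as, the domain-volume fraction is
  `g = a·ρ_s^{2/3} = a·(s/ū)^{2/3}`, `a = (π/4)·b·d_as²`. d_as =
  0.85 µm (from the process volume-to-surface ratio 4·350/1650 of
  reconstructed astrocytes) is the model's only fixed physical
  parameter; it gives a ≈ 0.352 µm².
* **Capillaries.** Capillaries concentrate where both spines and
  astrocytes are dense: `c = g·s = a·s^{5/3}/ū^{2/3}`. This implies
  c ~ g^{5/2}, hence c/g = s ≪ 1, reproducing the steep drop from the
  glia to the capillary fraction.

Two design principles, and their f-weighted mixture, are scored by the
fitness

    F(x, y, ū) = f·(r·x + y)/ū^γ₁ − (1−f)·s/ū^γ₂,   x+y+s+g+c = 1.

γ₁ selects the flavour of wire cost (0 volume, 1/3 surface, 2/3 length,
5/6 conduction delays — the ū-dependence arises because dendrite
diameter tracks spine size as d² ~ ū^{2/3}); γ₂ sets how steeply spine
size is penalized in the spine-economy term; r > 0 measures
axon/dendrite asymmetry. Minimizing F covers both principles because
the spine term carries a negative sign: at f = 0 the optimum is a
constrained *maximum* of F_s = s/ū^γ₂.

## Spine-size families

Six families of H(u), each calibrated so its mean equals ū, give closed
forms for P(ū; θ) and dP/dū:

| family | P(ū; θ) |
|---|---|
| exponential | exp(−θ/ū) |
| gamma n=1 | (1 + 2θ/ū)·e^{−2θ/ū} |
| gamma n=2 | (1 + 3θ/ū + (9/2)(θ/ū)²)·e^{−3θ/ū} |
| Rayleigh | exp(−(π/4)(θ/ū)²) |
| log-logistic (β > 1) | ū^β/(ū^β + θ̃^β), θ̃ = θ·(π/β)/sin(π/β) |
| log-normal (σ > 0) | ½[1 − erf((ln(θ/ū) + σ²/2)/(√2σ))] |

The gamma forms equal the regularized upper incomplete gamma
Q(n+1, (n+1)θ/ū); the log-logistic is a Hill function in ū that
sharpens to a step at the renormalized threshold as β grows. All
exceedances are strictly increasing in ū, approach 1 as ū → ∞, and are
verified in the tests against scipy survival functions, quadrature of
the density, and Monte-Carlo sampling.

## Numerics

**Stationarity.** The Lagrange multiplier is eliminated by cross
products: residuals (F_x·C_y − F_y·C_x, F_y·C_ū − F_ū·C_y, C − 1) with
C the fraction sum, all gradients analytic. At f = 0 the problem is
symmetric (x = y) and reduces to two equations. Roots are found with
scipy's hybrid Powell method from a battery of 28 starts (x ∈
{0.25…0.46} × ū ∈ {0.03…10}, plus an optional warm start during
sweeps); converged roots require residual norm < 1e-8, constraint
closure < 1e-9, and all fractions inside (1e-6, 1−1e-6).

**Branch selection.** The heavy-tailed families support several
stationary branches at the same parameters (a single-path continuation
demonstrably slides onto the wrong branch), so distinct roots are
deduplicated at 1e-6 and the one with the best objective is kept —
minimal F for f > 0, maximal F_s for f = 0 — matching its expected
extremum class.

**Divergent limit.** For f·γ₁ > 0 the wire term can drive ū → ∞, where
P → 1 and g, c → 0. The limit composition solves r·x − y = 1 − r with
x + y + x·y = 1 (closed-form quadratic; x = y = √2 − 1 at r = 1). Pure
wire minimization with γ₁ > 0 returns this branch directly; mixed
principles return it when the best root exceeds the ū cap of 1e4 µm³.
The stated r-dependence of the limit is mild (MD 18.2–18.7 over
r ∈ [0.9, 1.0]) and is reported as computed, not forced constant.

**Verification oracle.** An independent grid search eliminates the
constraint by construction — for each (x, ū) the dendrite fraction is
solved from C = 1 by bisection (C is strictly increasing in y) — then
scans a dense (x, ū) grid and polishes with Nelder-Mead in (x, ln ū).
It never touches the stationarity equations; tests require agreement
with the root solver to 1e-3 in every fraction across a matrix of
principle × family cases.

**Extremum classification.** In place of analytic second-order proofs,
the reduced Hessian of the principle's own Lagrangian (F_s for f = 0,
F otherwise) is computed by finite differences and projected onto the
tangent space of the constraint; the eigenvalue sign pattern yields
min/max/saddle, with near-singular cases flagged indeterminate.

## Empirical side

The packaged table compiles volume fractions (%) for mouse, rat,
rabbit, cat, macaque and human with gray-matter volumes 0.12–571.8 cm³;
several cells are missing and are dropped pairwise. The distance
reference is the *normalized mean* row — per-component species means
rescaled to sum to 100% — stored verbatim at its published precision,
means (40.8, 35.5, 10.0, 12.2, 1.5)% and standard deviations
(2.4, 5.5, 2.1, 1.2, 0.1)%. Recomputing the normalization from the raw
rows reproduces this row to 1 d.p. only when the species means are
first rounded to 1 d.p. (unrounded means give 40.7% for axons), and
the Mahalanobis scores are reproducible only with the stored row, so
the stored values are authoritative and the recomputation is kept as a
validation path. The ± values of the mean rows are not re-derivable
from the per-species entries and are stored as given.

Allometric invariance is assessed by OLS of log10(fraction %) on
log10(volume cm³) per component (statsmodels); all slopes are near
zero and non-significant (glia: slope 0.031, R² 0.180, p 0.477). The
spine and capillary slopes recompute 0.001–0.002 away from the
reference analysis on identical inputs (−0.014 vs −0.013 and 0.066 vs
0.064); the R² values agree, so the difference is attributed to
rounding in the source and tolerated at ±0.003.

## Synthetic data

The table generator draws log10 gray-matter volumes uniformly over
[−1, log10 600] (the span of the real table), then sets each
component's fraction to 10^(intercept + slope·log10 V + ε) with
ε ~ N(0, sd) — noise on the log keeps fractions positive and makes the
log-log OLS exactly well-specified, so imposed slopes are recoverable
(0.25 ± 0.05 at 20 species, sd 0.02). Defaults are 6 species, zero
slopes and the empirical composition. What it does *not* emulate:
correlated errors between components, within-species normalization to
100%, heteroscedastic measurement error, or missing cells — so passing
recovery tests validate the regression machinery, not the biology of
the real table. Spine populations are sampled by inverse CDF where
closed-form and scipy generators otherwise, always from an explicit
seed.

## Parameters and defaults

| parameter | meaning | default | rationale |
|---|---|---|---|
| d_as | astrocyte process diameter (µm) | 0.85 | 4·V_pr/S_pr from reconstruction data; brain-size invariant |
| θ | spine-formation threshold (µm³) | 0.321 | upper of the two analysis thresholds {0.100, 0.321} |
| r grid | axon/dendrite asymmetry | 0.50–1.20 step 0.01 | realistic optima cluster near r ≈ 0.95 |
| γ₂ grid | spine-cost exponent | 0.05–7.0 step 0.05 | optima fall below 1 for pure spine economy |
| σ grid | log-normal shape | 0.10–1.00 step 0.05 | spans reported spine-size fits |
| β grid | log-logistic shape | 1.5–7.0 step 0.5 | β > 1 required for a finite mean |
| ū cap | divergence flag (µm³) | 1e4 | far above every realistic spine volume |

Sweep minima are reported over the grid (matching the tabulated
procedure); a continuous polish exists but is off by default. Table
emission rounds to 3 decimals, half away from zero.

## Known limitations

* The log-normal family's reference wire-minimization optima cannot be
  reproduced by any (r, σ): their (ū, P) pairs are inconsistent with
  the mean-parametrized exceedance above, and mutually inconsistent
  between rows quoting the same σ. The self-consistent sweep bottoms
  out at ED ≈ 0.030 (σ ≈ 0.4, r ≈ 0.95) instead of 0.010; the package
  reports its own computed minima.
* Mahalanobis scores are extremely sensitive to the capillary standard
  deviation (0.001): small rounding differences in c move MD by ~0.01.
* The solver finds stationary points from a fixed start battery; it is
  thorough but not a global-optimality proof.
* Only local circuits are modelled — no spatial structure, no
  development, no white-matter coupling; the empirical table mixes
  cortical areas and methods across species.
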