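# Methods

This note documents the models implemented in `hospeff`, the numerical
choices behind them, what the synthetic-data generator does and does not
emulate, and the known limitations.

## 1. Input-oriented DEA

### Model

Each decision-making unit (DMU — one hospital in one year) uses three inputs
(beds, health workers excluding physicians, physicians) and produces two
outputs (DRG-weighted inpatient episodes, outpatient episodes).  Efficiency
is Farrell input efficiency: the largest uniform contraction θ of all inputs
that keeps the output bundle attainable within the envelopment of the
observed DMUs.  The package solves the envelopment (dual) linear program
directly, with decision variables (θ, λ) and objective min θ:

* **CCR / CRS**: λ ≥ 0 — the technology is the conical hull of the data;
* **BCC / VRS**: additionally Σλ = 1 — the convex hull, yielding pure
  technical efficiency;
* **scale efficiency** SE = θ_CRS / θ_VRS, clipped at 1 against round-off.

Returns to scale are read from the sum of the optimal CRS intensity weights:
Σλ > 1 decreasing, Σλ < 1 increasing, Σλ = 1 constant.  The classification
tolerance on |Σλ − 1| is 1e-6, well below the 4-decimal precision at which
scores are conventionally reported.

The orientation is input-oriented throughout: hospital managers control
staffing and beds far more directly than demand, and public hospitals are
not output(revenue)-maximising entities.  Output orientation,
super-efficiency and slack-based measures are out of scope.

### Solver and determinism

LPs are solved with HiGHS (`scipy.optimize.linprog`, method `"highs"`) with
a fixed variable ordering, so results are deterministic.  θ is unbounded
above (cross-period distances legitimately exceed 1) and reported unclipped
internally; within-period self-evaluations clip numerical noise above 1.

**Multiple optima.** The optimal intensity vector need not be unique, so
peer lists from different solvers can legitimately differ.  Two safeguards
are applied: (i) an efficient target (θ = 1) is always assigned the
canonical self-solution λ_self = 1 — any other optimal vertex is an
artefact of degeneracy and would break the identity "efficient ⇔ constant
returns ⇔ own peer"; (ii) an optional second phase (`two_phase=True`)
re-solves at fixed θ* maximising total slack, the standard way to obtain
canonical peers for inefficient units.  Peers are the DMUs with λ above
1e-6, ordered by weight.

Degenerate data (all DMUs identical) yields all-efficient scores by
construction and is accepted, not errored.

## 2. Malmquist productivity index

For each DMU and each **adjacent** year pair (t, t+1), four CRS Farrell
distances are computed: the two within-period scores and the two
cross-period distances (target data from one period, frontier from the
other).  The index and its decomposition

    TFPCH = ECH × TECH,  ECH = PECH × SECH

follow the standard geometric-mean form.  Distances are Farrell efficiency
values, **not** Shephard reciprocals; this convention makes index values
above 1 mean improvement and makes the whole-period efficiency change
telescope to `(score_last / score_first)^(1/(P−1))` — the property used to
validate against the published per-hospital values.

PECH is the ratio of within-period VRS scores; no cross-period VRS LPs are
required (cross-period VRS programs can be infeasible, and the CRS
technology is the standard basis for the productivity index).  SECH is the
residual ECH / PECH.

Whole-period per-DMU values and cross-DMU averages are **geometric** means,
the internally consistent choice for a multiplicative index; arithmetic
means are available behind a flag for comparison only.  The published
bottom-row averages do not state their convention; the geometric choice is
adopted because it reproduces the published per-hospital whole-period
values from the yearly score panel.

A balanced panel is required and enforced: a missing (dmu, year) pair is a
hard error naming the gap.

## 3. Second-stage censored regression

### Transformation

CRS scores θ ∈ (0, 1] become inefficiency `1/θ − 1 ∈ [0, ∞)`; efficient
hospitals land exactly on 0, the censoring point.  Scores within 1e-8 of 1
(on either side) are snapped to 1 first, so LP round-off on efficient units
still produces the censoring mass rather than a positive value of order
1e-16.  There is no upper censoring.

### Estimators

The pooled Tobit maximises the left-censored normal likelihood: density
`φ((y − x'β)/σ_e)/σ_e` for y > 0 and `Φ(−x'β/σ_e)` for y = 0.  σ_e is
parameterised as log σ_e to enforce positivity; the gradient is analytic
(inverse Mills ratio computed in log space via `log_ndtr` for stability).

The random-intercept panel Tobit adds a hospital-level effect
u_g ~ N(0, σ_u²) to the latent index and integrates it out with
Gauss–Hermite quadrature, matching the grouped structure of a hospital-year
panel (39 groups × 5 observations at the study scale).  **Quadrature nodes
default to 32**: with non-adaptive Gauss–Hermite and variance components at
the calibrated scale (σ_e ≈ 0.25, σ_u ≈ 0.2), 12 nodes leave the
log-likelihood about 1.5e-3 short of its converged value, while at 32 nodes
doubling to 64 changes it by less than 1e-9.  The cost is linear in nodes
and negligible at these problem sizes.

Optimisation uses BFGS from a least-squares start plus two fixed
perturbations (best likelihood kept), gradient tolerance 1e-8.  Standard
errors come from the inverse of the numerically differentiated observed
information at the MLE.

### Inference and model choice

The Wald χ² statistic is the quadratic form β_R' V_R⁻¹ β_R over all
non-constant coefficients (the conventional whole-model statistic printed
by standard packages).  `compare_models` fits each candidate covariate set
— the six published candidate sets ship as the defaults — and ranks by the
Wald statistic, reporting log-likelihoods alongside; a rank-deficient
candidate is reported with its error and does not abort the others.

VIFs are computed on the pooled covariate matrix as `1/(1 − R²_j)` from
auxiliary least-squares regressions with intercept.  Under standardised
covariates this equals the diagonal of the inverse correlation matrix, the
oracle used in the tests.

Coefficient signs follow the inefficiency scale: negative = associated with
better efficiency.

The published coefficient table itself is **not** reproducible from the
packaged data — the underlying 2015–2019 covariate panel is unpublished —
so the estimators are validated by simulation recovery instead, and the
published table is shipped as a fixture for structural checks only (which
covariates enter which candidate model, group counts).

## 4. Synthetic-data generator

The generator emulates the study's structure with exact ground truth:

* **Shape**: 39 DMUs × 5 years, 3 inputs, 2 outputs; 5 always-efficient
  units (~13%, matching the count of efficient hospitals in the reference
  year); input magnitudes log-normal around the study's descriptive scale
  (≈390 beds, ≈400 workers, ≈120 physicians).
* **Exact Farrell scores**: efficient units lie on a known technology
  y = A x (CRS) or y = A x + c with convex mixing (VRS), A strictly
  positive.  Every inefficient unit's frontier projection is a conic
  (resp. convex) combination of the efficient units' inputs, and its
  observed inputs are the projection inflated by 1/θ_true.  Because the
  projection is enveloped by construction and A > 0 forbids any deeper
  contraction, the DEA score equals θ_true exactly (LP tolerance) — the
  construction-oracle used throughout the tests.
* **Frontier drift**: outputs scale by a constant factor (default 1.07,
  near the published average frontier shift) per year, so TECH ≈ drift
  exactly under CRS.
* **Censored-regression DGP**: covariates drawn with ranges shaped like the
  published factor table, mutually exclusive size dummies with the
  published group shares, a hospital-level normal intercept and normal
  noise, left-censored at zero.  The default coefficient vector and scales
  (σ_e = 0.25, σ_u = 0.20, intercept 0.50) put the latent mean near the
  study's mean inefficiency (≈0.38) and the expected censoring fraction
  near 13%.

What the generator does **not** emulate: input-output correlation patterns
of real hospitals beyond the frontier construction, serial correlation of
inefficiency within a hospital (θ_true is redrawn each year), measurement
error in inputs, and any DRG case-mix structure.  Passing recovery tests
therefore demonstrates correctness of the estimators under the stated
models, not robustness to real-data violations of them.

## 5. Problem sizes and determinism

The shipped tests and the acceptance script run the LP stage at the study
scale (39 × 5 panels; a few thousand small LPs), the pooled-regression
oracles at n ≤ 2000, and the random-effects recovery at 200 groups × 5
observations — sizes chosen so every ground-truth parameter is comfortably
identified while the whole suite completes in a couple of minutes on one
CPU.  All randomness flows through a single seeded `numpy` generator per
generation call; identical configuration and seed give byte-identical
outputs.

## 6. Known limitations

* No inference on DEA scores (no bootstrap / Simar–Wilson correction); the
  two-stage procedure inherits the usual caveat that stage-1 scores are
  estimated, not observed.
* Peer sets of inefficient units are unique only up to LP degeneracy unless
  the two-phase option is used.
* The random-effects likelihood uses non-adaptive quadrature; for much
  larger group variances than calibrated here, the node count may need to
  rise further.
* Fixture tables carry the published rounding (4 decimals for scores,
  3 for indices); identities on them hold only to print precision
  (≤ 1.5e-3).
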