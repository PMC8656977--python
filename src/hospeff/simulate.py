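"""Synthetic hospital panels with exactly known Farrell efficiencies.

The generator mirrors the shape of the study data — 39 hospitals over five
years, three inputs (beds, non-physician health workers, physicians), two
outputs (DRG-weighted inpatient episodes, outpatient episodes), and roughly
13% of units on the frontier — while making the ground truth exact:

* A fixed set of efficient units is drawn with log-normal input vectors on a
  known technology y = A x (constant returns) or y = A x + c with convex
  combinations (variable returns, the affine offset bending the frontier).
* Every inefficient unit's frontier projection is built as a conic (CRS) or
  convex (VRS) combination of the efficient units' inputs, and its observed
  inputs are that projection radially inflated by 1/theta_true.  Because the
  projection lies inside the envelopment of the efficient units and the
  technology matrix is strictly positive, the input-oriented DEA score of
  the generated unit equals theta_true exactly (up to LP tolerance) — a
  bit-checkable oracle for the solver.
* A per-year technology drift scales the frontier outputs by a constant
  factor, so the Malmquist frontier-shift component equals the drift exactly.

A companion generator draws censored-regression panels (covariates shaped
like the published environmental factors, a hospital-level random intercept,
and left-censoring at zero) with known coefficients for recovery tests of
the second stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .panel import DEFAULT_INPUTS, DEFAULT_OUTPUTS, DMUPanel


@dataclass
class SyntheticConfig:
    """Study-shaped defaults: 39 DMUs, 5 years, ~13% efficient, mild drift."""

    n_dmus: int = 39
    n_years: int = 5
    start_year: int = 2015
    seed: int = 0
    n_efficient: int = 5
    #: log-scale mean/sd of the efficient units' inputs (beds, workers, physicians)
    input_log_mean: tuple = (5.85, 5.85, 4.70)
    input_log_sd: tuple = (0.55, 0.55, 0.55)
    #: Beta(a, b) for the inefficient units' true Farrell scores
    theta_beta: tuple = (5.0, 2.0)
    #: multiplicative frontier improvement per year (TECH ground truth)
    drift: float = 1.07
    rts: str = "crs"
    #: strictly positive technology matrix mapping inputs to frontier outputs
    tech_matrix: tuple = ((15.0, 8.0, 35.0), (180.0, 150.0, 600.0))
    #: affine frontier offset per output, active under rts="vrs"
    vrs_offset: tuple = (2000.0, 20000.0)
    # --- censored-regression DGP ---
    beta_true: dict = field(
        default_factory=lambda: {
            "const": 0.50,
            "Z1": -0.02,
            "Z3": 2.0,
            "Z5": -0.01,
            "Z6": -0.002,
            "D1": 0.05,
            "D2": -0.10,
            "D3": -0.03,
        }
    )
    sigma_e: float = 0.25
    sigma_u: float = 0.20
    #: "varying" redraws continuous covariates each year; "fixed" holds the
    #: first year's values across the panel
    covariate_time: str = "varying"

    def validate(self) -> None:
        if self.n_dmus < 2:
            raise ValueError("need at least 2 DMUs")
        if not 1 <= self.n_efficient <= self.n_dmus:
            raise ValueError("n_efficient must be in [1, n_dmus]")
        if self.drift <= 0:
            raise ValueError("drift must be positive")
        if self.rts not in ("crs", "vrs"):
            raise ValueError("rts must be 'crs' or 'vrs'")
        if self.sigma_e <= 0 or self.sigma_u < 0:
            raise ValueError("sigma_e must be > 0 and sigma_u >= 0")
        A = np.asarray(self.tech_matrix, dtype=float)
        if (A <= 0).any():
            raise ValueError("technology matrix must be strictly positive")


def generate_panel(config: SyntheticConfig) -> tuple[DMUPanel, pd.DataFrame]:
    """Generate a panel plus its ground-truth efficiency table.

    Returns ``(panel, truth)`` where ``truth`` has one row per hospital-year
    with the constructed Farrell score ``theta_true`` (1.0 for frontier
    units).  Fully reproducible from ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    A = np.asarray(config.tech_matrix, dtype=float)
    c = (
        np.asarray(config.vrs_offset, dtype=float)
        if config.rts == "vrs"
        else np.zeros(A.shape[0])
    )
    n, k = config.n_dmus, config.n_efficient
    ids = [f"H{i + 1:02d}" for i in range(n)]
    eff_ids = set(ids[:k])
    # efficient units' input bundles, shared across years
    X_eff = rng.lognormal(
        mean=np.asarray(config.input_log_mean),
        sigma=np.asarray(config.input_log_sd),
        size=(k, len(config.input_log_mean)),
    )
    rows, truth_rows = [], []
    for t in range(config.n_years):
        year = config.start_year + t
        scale_t = config.drift**t
        for i, dmu in enumerate(ids):
            if dmu in eff_ids:
                x_front = X_eff[i]
                theta = 1.0
            else:
                w = rng.dirichlet(np.ones(k))
                if config.rts == "crs":
                    w = w * rng.lognormal(0.0, 0.4)
                x_front = w @ X_eff
                a, b = config.theta_beta
                theta = float(np.clip(rng.beta(a, b), 0.05, 1.0 - 1e-9))
            y = scale_t * (A @ x_front + c)
            x_obs = x_front / theta
            rows.append(
                {
                    "dmu_id": dmu,
                    "year": year,
                    **dict(zip(DEFAULT_INPUTS, x_obs)),
                    **dict(zip(DEFAULT_OUTPUTS, y)),
                }
            )
            truth_rows.append({"dmu_id": dmu, "year": year, "theta_true": theta})
    panel = DMUPanel(pd.DataFrame(rows))
    truth = pd.DataFrame(truth_rows)
    truth.attrs["config"] = asdict(config)
    return panel, truth


def generate_tobit_panel(
    config: SyntheticConfig,
) -> tuple[pd.DataFrame, dict]:
    """Generate a censored-regression panel with known coefficients.

    Covariates imitate the environmental-factor table (outpatient/inpatient
    ratio, elderly share, bed turnover, occupancy, mutually exclusive size
    dummies); the latent inefficiency is x'beta + u_g + e with u_g a
    hospital-level normal effect, observed as max(latent, 0).  Returns the
    long table and a truth dict with the coefficient vector, both variance
    components and the realised censoring fraction.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n, T = config.n_dmus, config.n_years
    ids = [f"H{i + 1:02d}" for i in range(n)]
    # one size group per hospital, shares shaped like the published groups
    group_probs = np.array([8, 10, 12, 9], dtype=float)
    group_probs /= group_probs.sum()
    size_group = rng.choice(4, size=n, p=group_probs)  # 0:D1 1:D2 2:D3 3:small

    def draw_continuous(size):
        return {
            "Z1": rng.lognormal(np.log(2.0), 0.35, size),
            "Z2": rng.binomial(1, 0.2, size).astype(float),
            "Z3": np.clip(rng.normal(0.225, 0.03, size), 0.05, 0.6),
            "Z4": np.clip(rng.normal(0.008, 0.0015, size), 0.001, 0.03),
            "Z5": np.clip(rng.normal(42.0, 13.0, size), 3.0, None),
            "Z6": np.clip(rng.normal(61.0, 15.0, size), 5.0, 120.0),
            "Z7": np.clip(rng.normal(5.6, 1.7, size), 1.0, None),
        }

    base = draw_continuous(n)
    u = rng.normal(0.0, config.sigma_u, n)
    rows = []
    for t in range(T):
        year = config.start_year + t
        zs = draw_continuous(n) if config.covariate_time == "varying" else base
        if config.covariate_time == "varying":
            # Z2 (sole-hospital status) is structural: hold the base draw
            zs["Z2"] = base["Z2"]
        for i, dmu in enumerate(ids):
            row = {"dmu_id": dmu, "year": year}
            row.update({z: zs[z][i] for z in zs})
            row.update(
                {
                    "D1": float(size_group[i] == 0),
                    "D2": float(size_group[i] == 1),
                    "D3": float(size_group[i] == 2),
                }
            )
            xb = config.beta_true.get("const", 0.0) + sum(
                b * row[name]
                for name, b in config.beta_true.items()
                if name != "const"
            )
            latent = xb + u[i] + rng.normal(0.0, config.sigma_e)
            row["latent"] = latent
            row["ineff"] = max(latent, 0.0)
            row["censored"] = latent <= 0.0
            rows.append(row)
    df = pd.DataFrame(rows)
    truth = {
        "beta": dict(config.beta_true),
        "sigma_e": config.sigma_e,
        "sigma_u": config.sigma_u,
        "censored_fraction": float(df["censored"].mean()),
        "seed": config.seed,
    }
    return df, truth
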