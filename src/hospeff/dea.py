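"""Input-oriented data envelopment analysis (CCR and BCC envelopment models).

The Farrell input efficiency of a target DMU with inputs ``x0`` and outputs
``y0`` against reference units ``(X, Y)`` is the value of the envelopment LP

    min theta  s.t.  X' lam <= theta * x0   (each input)
                     Y' lam >= y0           (each output)
                     lam >= 0               (CRS / CCR)
                     sum(lam) = 1 added     (VRS / BCC)

Technical efficiency (CRS score) decomposes into pure technical efficiency
(VRS score) times scale efficiency; returns to scale are read off the sum of
the optimal CRS intensity weights.  Solved with the HiGHS simplex through
``scipy.optimize.linprog``; the vertex solution makes the reported intensity
vector deterministic, and an optional second phase maximising total slack at
fixed theta* yields canonical peer sets when the optimal lambdas are not
unique.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linprog

from .panel import DMUPanel, describe_columns

#: classification tolerance on |sum(lambda) - 1| and on |theta - 1|
RTS_TOL = 1e-6
#: lambdas below this threshold are numerical noise, not peers
PEER_THRESHOLD = 1e-6


class DEASolverError(RuntimeError):
    """The underlying LP failed; carries the solver status message."""


def solve_envelopment(
    x0: np.ndarray,
    y0: np.ndarray,
    X: np.ndarray,
    Y: np.ndarray,
    rts: str = "crs",
    two_phase: bool = False,
) -> tuple[float, np.ndarray]:
    """Solve the input-oriented envelopment LP for one target.

    Parameters
    ----------
    x0, y0 : arrays (m,), (q,)
        Target input/output bundle (need not belong to the reference set:
        cross-period distances reuse this routine and may return theta > 1).
    X, Y : arrays (n, m), (n, q)
        Reference technology, one row per DMU.
    rts : {"crs", "vrs"}
    two_phase : bool
        If True, re-solve at fixed theta* maximising the total slack, which
        canonicalises the intensity vector when the LP has multiple optima.

    Returns
    -------
    (theta, lambdas)
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    x0 = np.asarray(x0, dtype=float)
    y0 = np.asarray(y0, dtype=float)
    n, m = X.shape
    q = Y.shape[1]
    # variables: [theta, lam_1..lam_n]
    c = np.concatenate(([1.0], np.zeros(n)))
    A_ub = np.zeros((m + q, n + 1))
    A_ub[:m, 0] = -x0
    A_ub[:m, 1:] = X.T
    A_ub[m:, 1:] = -Y.T
    b_ub = np.concatenate((np.zeros(m), -y0))
    if rts == "vrs":
        A_eq = np.concatenate(([0.0], np.ones(n)))[None, :]
        b_eq = np.array([1.0])
    elif rts == "crs":
        A_eq = b_eq = None
    else:
        raise ValueError(f"rts must be 'crs' or 'vrs', got {rts!r}")
    res = linprog(
        c,
        A_ub=A_ub,
        b_ub=b_ub,
        A_eq=A_eq,
        b_eq=b_eq,
        bounds=[(0, None)] * (n + 1),
        method="highs",
    )
    if not res.success:
        raise DEASolverError(f"envelopment LP failed (rts={rts}): {res.message}")
    theta = float(res.x[0])
    lam = np.maximum(res.x[1:], 0.0)
    if two_phase:
        lam = _max_slack_lambdas(theta, x0, y0, X, Y, rts)
    return theta, lam


def _max_slack_lambdas(
    theta: float, x0, y0, X, Y, rts: str
) -> np.ndarray:
    """Phase-2 LP: at fixed theta*, maximise the sum of input/output slacks."""
    n, m = X.shape
    q = Y.shape[1]
    # variables: [lam (n), s_in (m), s_out (q)]
    c = np.concatenate((np.zeros(n), -np.ones(m + q)))
    A_eq = np.zeros((m + q, n + m + q))
    A_eq[:m, :n] = X.T
    A_eq[:m, n : n + m] = np.eye(m)
    A_eq[m:, :n] = Y.T
    A_eq[m:, n + m :] = -np.eye(q)
    b_eq = np.concatenate((theta * x0, y0))
    rows = [A_eq]
    rhs = [b_eq]
    if rts == "vrs":
        conv = np.zeros((1, n + m + q))
        conv[0, :n] = 1.0
        rows.append(conv)
        rhs.append(np.array([1.0]))
    res = linprog(
        c,
        A_eq=np.vstack(rows),
        b_eq=np.concatenate(rhs),
        bounds=[(0, None)] * (n + m + q),
        method="highs",
    )
    if not res.success:
        raise DEASolverError(f"slack-maximising phase failed: {res.message}")
    return np.maximum(res.x[:n], 0.0)


def solve_crs_input(target: int, X, Y, two_phase: bool = False):
    """CCR (constant returns) score and intensity vector of DMU ``target``."""
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    return solve_envelopment(X[target], Y[target], X, Y, "crs", two_phase)


def solve_vrs_input(target: int, X, Y, two_phase: bool = False):
    """BCC (variable returns) score and intensity vector of DMU ``target``."""
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    return solve_envelopment(X[target], Y[target], X, Y, "vrs", two_phase)


def scale_efficiency(theta_crs: float, theta_vrs: float) -> float:
    """SE = CRS score / VRS score, clipped at 1 against LP round-off."""
    if theta_vrs <= 0:
        raise ValueError("VRS score must be positive")
    return min(theta_crs / theta_vrs, 1.0)


def classify_rts(lambda_sum: float, theta_crs: float | None = None, tol: float = RTS_TOL) -> str:
    """Returns-to-scale label from the sum of CRS intensity weights.

    sum(lambda) > 1 -> decreasing, < 1 -> increasing, = 1 (within ``tol``)
    -> constant (the DMU operates at the most productive scale size).

    A CRS-efficient target (theta = 1) always admits the self-solution with
    sum(lambda) = 1, so it is classified constant regardless of which optimal
    vertex the solver happened to return.
    """
    if lambda_sum < 0:
        raise ValueError("lambda_sum must be non-negative")
    if theta_crs is not None and theta_crs >= 1 - tol:
        return "constant"
    if lambda_sum > 1 + tol:
        return "decreasing"
    if lambda_sum < 1 - tol:
        return "increasing"
    return "constant"


def reference_set(
    lambdas: dict[str, float], threshold: float = PEER_THRESHOLD
) -> list[str]:
    """Peers: DMUs with intensity weight above ``threshold``, by weight desc."""
    picked = [(d, w) for d, w in lambdas.items() if w > threshold]
    picked.sort(key=lambda t: (-t[1], t[0]))
    return [d for d, _ in picked]


@dataclass
class EfficiencyResult:
    """Per-DMU efficiency record: scores, intensity weights, RTS, peers."""

    dmu_id: str
    year: int
    theta_crs: float
    theta_vrs: float | None
    scale_eff: float | None
    lambdas: dict[str, float] = field(default_factory=dict)
    lambda_sum: float = 0.0
    rts: str = "constant"
    peers: list[str] = field(default_factory=list)


class DEA:
    """Input-oriented DEA model over one year-slice of a hospital panel.

    Examples
    --------
    >>> model = DEA(panel, year=2019)
    >>> res = model.fit()
    >>> res.scores.head()
    >>> res.summary()
    """

    def __init__(
        self,
        panel: DMUPanel,
        year: int | None = None,
        two_phase: bool = False,
        peer_threshold: float = PEER_THRESHOLD,
        rts_tol: float = RTS_TOL,
    ) -> None:
        if year is not None:
            panel = panel.slice_year(year)
        elif len(panel.years) > 1:
            raise ValueError("panel spans several years; pass year=")
        self.panel = panel
        self.year = panel.years[0]
        self.two_phase = two_phase
        self.peer_threshold = peer_threshold
        self.rts_tol = rts_tol

    def fit(self, models: str = "both") -> "DEAResults":
        """Solve the envelopment LPs for every DMU.

        ``models`` is ``"crs"``, ``"vrs"`` or ``"both"`` (default: both,
        which also yields scale efficiency).
        """
        X, Y = self.panel.matrices()
        ids = self.panel.data["dmu_id"].tolist()
        want_crs = models in ("crs", "both")
        want_vrs = models in ("vrs", "both")
        results = []
        for i, dmu in enumerate(ids):
            theta_c = lam = None
            if want_crs:
                theta_c, lam = solve_crs_input(i, X, Y, self.two_phase)
            theta_v = None
            if want_vrs:
                theta_v, lam_v = solve_vrs_input(i, X, Y, self.two_phase)
                if not want_crs:
                    lam = lam_v
            # within-period self-evaluation: clip numerical noise above 1
            if theta_c is not None:
                theta_c = min(theta_c, 1.0)
            if theta_v is not None:
                theta_v = min(theta_v, 1.0)
            # an efficient target envelopes itself; replace any alternative
            # optimal vertex by the canonical self-solution (lambda_self = 1)
            ref_theta = theta_c if theta_c is not None else theta_v
            if ref_theta >= 1 - self.rts_tol:
                lam = np.zeros(len(ids))
                lam[i] = 1.0
            lam_map = {ids[j]: float(lam[j]) for j in range(len(ids))}
            lam_sum = float(np.sum(lam))
            se = (
                scale_efficiency(theta_c, theta_v)
                if theta_c is not None and theta_v is not None
                else None
            )
            results.append(
                EfficiencyResult(
                    dmu_id=dmu,
                    year=self.year,
                    theta_crs=theta_c,
                    theta_vrs=theta_v,
                    scale_eff=se,
                    lambdas=lam_map,
                    lambda_sum=lam_sum,
                    rts=classify_rts(lam_sum, theta_c, self.rts_tol)
                    if want_crs
                    else "",
                    peers=reference_set(lam_map, self.peer_threshold),
                )
            )
        return DEAResults(self, results)


class DEAResults:
    """Fitted efficiency scores with summary and benchmarking accessors."""

    def __init__(self, model: DEA, results: list[EfficiencyResult]) -> None:
        self.model = model
        self.results = results

    @property
    def scores(self) -> pd.DataFrame:
        rows = [
            {
                "dmu": r.dmu_id,
                "year": r.year,
                "crs": r.theta_crs,
                "vrs": r.theta_vrs,
                "se": r.scale_eff,
                "lambda_sum": r.lambda_sum,
                "rts": r.rts,
                "peers": ";".join(r.peers),
            }
            for r in self.results
        ]
        return pd.DataFrame(rows)

    def summary(self, ddof: int = 1) -> pd.DataFrame:
        """Mean/median/max/min/sd of each score column (unrounded scores)."""
        return summarize_scores(self.scores, ddof=ddof)

    def rts_counts(self) -> pd.Series:
        return rts_counts(self.scores)

    def efficient(self, column: str = "crs", tol: float = RTS_TOL) -> list[str]:
        df = self.scores
        return df.loc[df[column] >= 1 - tol, "dmu"].tolist()

    def group_means(self, factors: pd.DataFrame, column: str = "crs") -> pd.Series:
        """Mean score per size group defined by the D1-D3 dummies."""
        return group_efficiency_means(self.scores, factors, column=column)


# -- summary helpers (shared with the packaged printed-score tables) ---------

def summarize_scores(scores: pd.DataFrame, ddof: int = 1) -> pd.DataFrame:
    """Descriptive statistics of the score columns present in ``scores``."""
    cols = [c for c in ("crs", "vrs", "se") if c in scores.columns]
    return describe_columns(scores[cols].astype(float), ddof=ddof)


def rts_counts(scores: pd.DataFrame) -> pd.Series:
    """Number of DMUs operating under each returns-to-scale regime."""
    return scores["rts"].value_counts().reindex(
        ["constant", "increasing", "decreasing"], fill_value=0
    )


def count_efficient(scores: pd.DataFrame, column: str = "crs", tol: float = RTS_TOL) -> int:
    return int((scores[column].astype(float) >= 1 - tol).sum())


def group_efficiency_means(
    scores: pd.DataFrame,
    factors: pd.DataFrame,
    column: str = "crs",
    dummies: tuple[str, ...] = ("D1", "D2", "D3"),
) -> pd.Series:
    """Mean efficiency per hospital size group.

    Groups are defined by the mutually exclusive dummies (D1 = very large,
    D2 = large, D3 = medium); rows with all dummies zero form the small
    group.  ``scores`` and ``factors`` are joined on the DMU label.
    """
    sc = scores.rename(columns={"dmu_id": "dmu"})
    fa = factors.rename(columns={"dmu_id": "dmu"})
    merged = sc.merge(fa[["dmu", *dummies]], on="dmu", validate="one_to_one")
    out = {}
    small_mask = np.ones(len(merged), dtype=bool)
    for d in dummies:
        mask = merged[d] == 1
        small_mask &= ~mask
        out[d] = float(merged.loc[mask, column].astype(float).mean())
    out["small"] = float(merged.loc[small_mask, column].astype(float).mean())
    return pd.Series(out)
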