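"""Adjacent-period Malmquist total-factor-productivity index and decomposition.

For each DMU and each adjacent year pair (t, t+1) four Farrell input-distance
values are computed under constant returns to scale: within-period distances
D^t(x^t, y^t) and D^{t+1}(x^{t+1}, y^{t+1}) (in (0, 1]) and cross-period
distances D^t(x^{t+1}, y^{t+1}) and D^{t+1}(x^t, y^t) (which may exceed 1
when the data lie outside the other period's technology).  The index and its
decomposition follow the standard Fare et al. construction:

    TFPCH = [ (D^t(t+1)/D^t(t)) * (D^{t+1}(t+1)/D^{t+1}(t)) ]^(1/2)
    ECH   = D^{t+1}(t+1) / D^t(t)                    (catch-up)
    TECH  = [ (D^t(t+1)/D^{t+1}(t+1)) * (D^t(t)/D^{t+1}(t)) ]^(1/2)
                                                      (frontier shift)
    ECH   = PECH * SECH, with PECH the analogous ratio of within-period
            VRS scores and SECH the residual scale component.

Distances are Farrell efficiency values (the theta of the envelopment LP),
not Shephard reciprocals, so index values above 1 mean improvement.  Whole-
period and cross-DMU averages are geometric, consistent with a multiplicative
index.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .dea import DEASolverError, solve_envelopment
from .panel import DMUPanel


def cross_period_distance(
    x_b: np.ndarray,
    y_b: np.ndarray,
    X_a: np.ndarray,
    Y_a: np.ndarray,
    rts: str = "crs",
) -> float:
    """Farrell distance of period-b data against period-a technology.

    Collapses to the ordinary within-period score when the target belongs to
    the reference slice; unbounded above when it does not.
    """
    try:
        theta, _ = solve_envelopment(x_b, y_b, X_a, Y_a, rts=rts)
    except DEASolverError as err:
        raise DEASolverError(f"cross-period distance failed: {err}") from err
    return theta


def malmquist_index(d_t_t: float, d_t_t1: float, d_t1_t: float, d_t1_t1: float) -> float:
    """TFP change between t and t+1 from the four distance values."""
    _check_positive(d_t_t, d_t_t1, d_t1_t, d_t1_t1)
    return float(np.sqrt((d_t_t1 / d_t_t) * (d_t1_t1 / d_t1_t)))


def efficiency_change(d_t_t: float, d_t1_t1: float) -> float:
    """Catch-up effect: ratio of within-period scores."""
    _check_positive(d_t_t, d_t1_t1)
    return d_t1_t1 / d_t_t


def technological_change(
    d_t_t: float, d_t_t1: float, d_t1_t: float, d_t1_t1: float
) -> float:
    """Frontier-shift effect between the period-t and period-(t+1) technologies."""
    _check_positive(d_t_t, d_t_t1, d_t1_t, d_t1_t1)
    return float(np.sqrt((d_t_t1 / d_t1_t1) * (d_t_t / d_t1_t)))


def decompose(ech: float, pech: float) -> float:
    """Scale-efficiency change: the part of catch-up not explained by PECH."""
    _check_positive(ech, pech)
    return ech / pech


def geometric_mean(values) -> float:
    arr = np.asarray(values, dtype=float)
    _check_positive(*arr.ravel())
    return float(np.exp(np.mean(np.log(arr))))


def _check_positive(*values: float) -> None:
    for v in values:
        if not v > 0:
            raise ValueError(f"distance/index values must be positive, got {v}")


class Malmquist:
    """Adjacent-period Malmquist model over a balanced multi-year panel.

    Parameters
    ----------
    panel : DMUPanel
        Must contain every DMU in every analysed year.
    years : sequence of int, optional
        Ordered years to analyse; defaults to all years in the panel.
    """

    def __init__(self, panel: DMUPanel, years=None) -> None:
        self.panel = panel
        self.years = panel.require_balanced(years)
        if len(self.years) < 2:
            raise ValueError("Malmquist analysis needs at least two years")

    def fit(self) -> "MalmquistResults":
        records = []
        slices = {y: self.panel.slice_year(y) for y in self.years}
        mats = {y: s.matrices() for y, s in slices.items()}
        order = {y: slices[y].data["dmu_id"].tolist() for y in self.years}
        dmus = order[self.years[0]]
        for t, t1 in zip(self.years[:-1], self.years[1:]):
            X_t, Y_t = mats[t]
            X_t1, Y_t1 = mats[t1]
            idx_t = {d: i for i, d in enumerate(order[t])}
            idx_t1 = {d: i for i, d in enumerate(order[t1])}
            for dmu in dmus:
                i, j = idx_t[dmu], idx_t1[dmu]
                d_t_t = cross_period_distance(X_t[i], Y_t[i], X_t, Y_t)
                d_t1_t1 = cross_period_distance(X_t1[j], Y_t1[j], X_t1, Y_t1)
                d_t_t1 = cross_period_distance(X_t1[j], Y_t1[j], X_t, Y_t)
                d_t1_t = cross_period_distance(X_t[i], Y_t[i], X_t1, Y_t1)
                v_t = cross_period_distance(X_t[i], Y_t[i], X_t, Y_t, rts="vrs")
                v_t1 = cross_period_distance(X_t1[j], Y_t1[j], X_t1, Y_t1, rts="vrs")
                ech = efficiency_change(d_t_t, d_t1_t1)
                tech = technological_change(d_t_t, d_t_t1, d_t1_t, d_t1_t1)
                pech = efficiency_change(v_t, v_t1)
                records.append(
                    {
                        "dmu": dmu,
                        "t": t,
                        "t1": t1,
                        "d_t_t": d_t_t,
                        "d_t_t1": d_t_t1,
                        "d_t1_t": d_t1_t,
                        "d_t1_t1": d_t1_t1,
                        "tfpch": malmquist_index(d_t_t, d_t_t1, d_t1_t, d_t1_t1),
                        "ech": ech,
                        "tech": tech,
                        "pech": pech,
                        "sech": decompose(ech, pech),
                    }
                )
        return MalmquistResults(self, pd.DataFrame(records))


class MalmquistResults:
    """Per-DMU per-pair records plus geometric whole-period summaries."""

    INDEX_COLS = ("tfpch", "tech", "ech", "pech", "sech")

    def __init__(self, model: Malmquist, records: pd.DataFrame) -> None:
        self.model = model
        self.records = records

    def dmu_summary(self, mean: str = "geometric") -> pd.DataFrame:
        """Whole-period index per DMU: geometric mean over adjacent pairs.

        ``mean="arithmetic"`` is offered for comparison only; the geometric
        mean is the one consistent with a multiplicative index (the per-DMU
        ECH then telescopes to (score_last / score_first)^(1/(P-1))).
        """
        agg = geometric_mean if mean == "geometric" else np.mean
        return (
            self.records.groupby("dmu", sort=False)[list(self.INDEX_COLS)]
            .agg(agg)
            .reset_index()
        )

    def period_summary(self, mean: str = "geometric") -> pd.DataFrame:
        """Cross-DMU average per adjacent year pair, plus a whole-period row."""
        agg = geometric_mean if mean == "geometric" else np.mean
        rows = []
        for (t, t1), grp in self.records.groupby(["t", "t1"], sort=True):
            row = {"period": f"{t}-{t1}"}
            row.update({c: agg(grp[c]) for c in self.INDEX_COLS})
            rows.append(row)
        overall = {"period": f"{self.model.years[0]}-{self.model.years[-1]}"}
        overall.update({c: agg(self.records[c]) for c in self.INDEX_COLS})
        rows.append(overall)
        return pd.DataFrame(rows)

    def summary(self) -> pd.DataFrame:
        return self.period_summary()
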