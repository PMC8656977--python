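"""Hospital-year panel data model and CSV I/O.

The unit of analysis is the decision-making unit (DMU): one hospital observed
in one calendar year.  Each DMU consumes three inputs (beds, health workers
excluding physicians, physicians) and produces two outputs (DRG-weighted
inpatient episodes, outpatient episodes).  The container is deliberately
generic in the number of inputs/outputs so toy problems (1 input / 1 output)
used by the oracles share the same code path as the study-shaped 3x2 panel.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

DEFAULT_INPUTS = ("beds", "workers", "physicians")
DEFAULT_OUTPUTS = ("inpatient_drg", "outpatient")

FACTOR_COLUMNS = ("Z1", "Z2", "Z3", "Z4", "Z5", "Z6", "Z7", "D1", "D2", "D3")
SIZE_DUMMIES = ("D1", "D2", "D3")


class PanelValidationError(ValueError):
    """A panel row violates a structural invariant (e.g. non-positive input)."""


class PanelConfigError(ValueError):
    """The CSV layout cannot be mapped onto the expected panel columns."""


@dataclass(frozen=True)
class DMUPanel:
    """Long-format hospital-year table with named input and output columns.

    Parameters
    ----------
    data : pandas.DataFrame
        Must contain ``dmu_id``, ``year``, and the listed input/output columns.
    input_cols, output_cols : sequence of str
        Ordered column names; the order fixes the row order of the LP
        constraint matrices.
    """

    data: pd.DataFrame
    input_cols: tuple[str, ...] = DEFAULT_INPUTS
    output_cols: tuple[str, ...] = DEFAULT_OUTPUTS

    def __post_init__(self) -> None:
        object.__setattr__(self, "input_cols", tuple(self.input_cols))
        object.__setattr__(self, "output_cols", tuple(self.output_cols))
        df = self.data
        required = ["dmu_id", "year", *self.input_cols, *self.output_cols]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise PanelConfigError(f"panel is missing columns: {missing}")
        dup = df.duplicated(subset=["dmu_id", "year"])
        if dup.any():
            pairs = df.loc[dup, ["dmu_id", "year"]].itertuples(index=False)
            raise PanelValidationError(
                "duplicate (dmu_id, year) pairs: " + ", ".join(map(str, pairs))
            )
        bad_rows = []
        for col in self.input_cols:
            sel = ~(df[col] > 0)
            for row in df.loc[sel].itertuples():
                bad_rows.append((row.dmu_id, row.year, col, getattr(row, col)))
        if bad_rows:
            detail = "; ".join(
                f"(dmu={d}, year={y}, column={c}, value={v})" for d, y, c, v in bad_rows
            )
            raise PanelValidationError(f"non-positive input values: {detail}")
        out = df[list(self.output_cols)].to_numpy(dtype=float)
        if (out < 0).any():
            raise PanelValidationError("negative output values present")
        no_output = ~(out > 0).any(axis=1)
        if no_output.any():
            who = df.loc[no_output, ["dmu_id", "year"]].itertuples(index=False)
            raise PanelValidationError(
                "DMUs with no positive output: " + ", ".join(map(str, who))
            )

    # -- basic introspection -------------------------------------------------
    @property
    def years(self) -> list[int]:
        return sorted(self.data["year"].unique().tolist())

    @property
    def dmu_ids(self) -> list[str]:
        return list(dict.fromkeys(self.data["dmu_id"]))

    @property
    def n_dmus(self) -> int:
        return self.data["dmu_id"].nunique()

    def slice_year(self, year: int) -> "DMUPanel":
        """Panel restricted to a single year; rows keep their original order."""
        sub = self.data[self.data["year"] == year].reset_index(drop=True)
        if sub.empty:
            raise PanelValidationError(f"year {year} not present in panel")
        return DMUPanel(sub, self.input_cols, self.output_cols)

    def matrices(self) -> tuple[np.ndarray, np.ndarray]:
        """(X, Y) with one row per DMU: X is n x m inputs, Y is n x q outputs."""
        X = self.data[list(self.input_cols)].to_numpy(dtype=float)
        Y = self.data[list(self.output_cols)].to_numpy(dtype=float)
        return X, Y

    def require_balanced(self, years: Sequence[int] | None = None) -> list[int]:
        """Check every DMU appears in every requested year; return the years.

        Raises ``PanelValidationError`` naming the first missing (dmu, year)
        pairs — a balanced panel is a precondition of the Malmquist index.
        """
        years = list(years) if years is not None else self.years
        dmus = set(self.dmu_ids)
        missing = []
        for y in years:
            present = set(self.data.loc[self.data["year"] == y, "dmu_id"])
            missing.extend((d, y) for d in sorted(dmus - present))
        if missing:
            raise PanelValidationError(f"unbalanced panel; missing (dmu, year): {missing}")
        return years


def read_panel(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    input_cols: Sequence[str] = DEFAULT_INPUTS,
    output_cols: Sequence[str] = DEFAULT_OUTPUTS,
) -> DMUPanel:
    """Read a long-format panel CSV and validate it.

    ``column_map`` maps CSV headers to canonical names (``dmu_id``, ``year``
    and the input/output names), so arbitrary source headers can be ingested.
    Rows violating positivity raise a ``PanelValidationError`` naming the
    offending (dmu, year, column); they are never silently dropped.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    if column_map:
        df = df.rename(columns=dict(column_map))
    required = ["dmu_id", "year", *input_cols, *output_cols]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise PanelConfigError(
            f"CSV {path} lacks columns {missing}; present: {list(df.columns)}"
        )
    df["year"] = df["year"].astype(int)
    return DMUPanel(df[required], tuple(input_cols), tuple(output_cols))


def write_panel(panel: DMUPanel, path: str | Path) -> None:
    """Write the panel back to CSV with full float precision (round-trip safe)."""
    # repr() is the shortest exact decimal representation of a float
    panel.data.to_csv(path, index=False, float_format=lambda v: repr(float(v)))


def read_factors(path: str | Path, column_map: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Read an environmental-factor table (Z1-Z7 plus size dummies D1-D3)."""
    df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns=dict(column_map))
    if "dmu" in df.columns and "dmu_id" not in df.columns:
        df = df.rename(columns={"dmu": "dmu_id"})
    missing = [c for c in FACTOR_COLUMNS if c not in df.columns]
    if missing:
        raise PanelConfigError(f"factor table lacks columns {missing}")
    return validate_factors(df)


def validate_factors(df: pd.DataFrame) -> pd.DataFrame:
    """Check factor-table invariants: dummy exclusivity and variable ranges."""
    dummies = df[list(SIZE_DUMMIES)].to_numpy()
    if not set(np.unique(dummies)) <= {0, 1}:
        raise PanelValidationError("size dummies must be 0/1")
    if (dummies.sum(axis=1) > 1).any():
        raise PanelValidationError("at most one size dummy may be 1 per row")
    for col, lo, hi in (("Z3", 0, 1), ("Z4", 0, 1)):
        if ((df[col] < lo) | (df[col] > hi)).any():
            raise PanelValidationError(f"{col} must lie in [{lo}, {hi}]")
    for col in ("Z5", "Z6", "Z7"):
        if (df[col] < 0).any():
            raise PanelValidationError(f"{col} must be non-negative")
    return df


def summarize(panel: DMUPanel, year: int, ddof: int = 1) -> pd.DataFrame:
    """Per-variable mean/median/max/min/sd for one year of the panel.

    ``ddof=1`` gives the sample standard deviation (the default convention);
    pass ``ddof=0`` for the population version.
    """
    sub = panel.slice_year(year)
    cols = list(panel.input_cols) + list(panel.output_cols)
    return describe_columns(sub.data[cols], ddof=ddof)


def describe_columns(df: pd.DataFrame, ddof: int = 1) -> pd.DataFrame:
    """mean/median/max/min/sd table for every column of ``df``."""
    if df.empty:
        raise PanelValidationError("cannot summarize an empty slice")
    out = pd.DataFrame(
        {
            "mean": df.mean(),
            "median": df.median(),
            "max": df.max(),
            "min": df.min(),
            "sd": df.std(ddof=ddof),
        }
    )
    return out
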