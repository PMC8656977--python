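"""Packaged reference tables from the published hospital-efficiency study.

Each fixture transcribes one printed result table, digit for digit, so the
summary routines and decomposition identities can be exercised against the
published numbers without access to the unpublished raw hospital data:

``factors_2019``
    Environmental covariates Z1-Z7 and size dummies D1-D3 per hospital.
``scores_2019``
    CRS/VRS/scale-efficiency scores, lambda sums, returns-to-scale labels
    and peer (benchmark) sets for the 39 hospitals in 2019.
``crs_panel``
    CRS efficiency per hospital for 2015-2019 plus frontier counts.
``malmquist``
    Per-hospital whole-period Malmquist decomposition (TFPCH, TECH, ECH,
    PECH, SECH).
``malmquist_periods``
    Cross-hospital averages per adjacent year pair and for the whole period.
``tobit_models``
    Coefficients, significance stars and fit statistics of the six candidate
    second-stage censored-regression models (long format).
"""

from importlib import resources

import pandas as pd

_FIXTURES = {
    "factors_2019": "factors_2019.csv",
    "scores_2019": "scores_2019.csv",
    "crs_panel": "crs_panel.csv",
    "malmquist": "malmquist.csv",
    "malmquist_periods": "malmquist_periods.csv",
    "tobit_models": "tobit_models.csv",
}

#: Bed-count boundaries of the published hospital size groups.  The small
#: group (< 200 beds) carries no dummy and is represented by the model
#: constant in the second-stage regression.
SIZE_GROUP_BOUNDS = {
    "D1": (600, None),   # very large: >= 600 beds
    "D2": (400, 600),    # large
    "D3": (200, 400),    # medium
    "small": (None, 200),
}


def available_fixtures() -> list[str]:
    return sorted(_FIXTURES)


def load_fixture(name: str) -> pd.DataFrame:
    """Load a packaged table by name, exactly as printed (no re-rounding)."""
    if name not in _FIXTURES:
        raise KeyError(
            f"unknown fixture {name!r}; available: {', '.join(available_fixtures())}"
        )
    ref = resources.files(__package__).joinpath(_FIXTURES[name])
    with resources.as_file(ref) as path:
        df = pd.read_csv(path)
    if "stars" in df.columns:
        df["stars"] = df["stars"].fillna("")
    return df
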