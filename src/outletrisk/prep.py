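"""Block-group data preparation for the disadvantage-index model.

Covers unit filtering, racial/ethnic segregation ratios, income inversion,
decile scoring of the nine sociodemographic covariates, expected outlet
counts under the statewide rates, and population-density categories.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: canonical covariate column order (x_1 .. x_9)
COVARIATE_COLUMNS = [
    "black_segregation",
    "hispanic_segregation",
    "pct_income_poverty_lt1",
    "pct_public_assistance",
    "pct_renter_occupied",
    "pct_built_pre1940",
    "pct_no_highschool",
    "pct_households_poverty",
    "per_capita_income",
]

#: covariates whose raw direction is advantage, inverted before indexing
INVERTED_COVARIATES = ["per_capita_income"]

COUNT_COLUMNS = ["n_tro", "n_aro", "n_taro"]
OUTLET_TYPES = ["TRO", "ARO", "TARO"]

REQUIRED_COLUMNS = ["block_group_id", "population", "area_sqmi"] + COVARIATE_COLUMNS + COUNT_COLUMNS

#: persons per square mile cutoffs: rural < 500 <= suburban < 1000 <= urban
DENSITY_CATEGORIES = ["rural", "suburban", "urban"]
DENSITY_BREAKS = (500.0, 1000.0)


@dataclass
class RemovalLog:
    """What filter_units dropped and why."""

    n_no_population: int
    n_missing_covariates: int
    removed_no_population: list[str] = field(default_factory=list)
    removed_missing_covariates: list[str] = field(default_factory=list)


@dataclass
class ExpectedCounts:
    """Expected counts E_ik = r_k * p_i under the overall per-type rates r_k."""

    E: np.ndarray          # (n_units, 3)
    rates: np.ndarray      # (3,)
    block_group_ids: list[str]


def filter_units(records: pd.DataFrame) -> tuple[pd.DataFrame, RemovalLog]:
    """Drop zero-population units, then units missing any covariate.

    Returns the retained records plus a log of both removal passes.
    Raises ``ValueError`` if nothing survives.
    """
    df = records.copy()
    no_pop = df["population"] <= 0
    removed_pop = df.loc[no_pop, "block_group_id"].tolist()
    df = df.loc[~no_pop]

    missing = df[COVARIATE_COLUMNS].isna().any(axis=1)
    removed_missing = df.loc[missing, "block_group_id"].tolist()
    df = df.loc[~missing].reset_index(drop=True)

    if df.empty:
        raise ValueError("all block groups removed by filtering")
    log = RemovalLog(
        n_no_population=len(removed_pop),
        n_missing_covariates=len(removed_missing),
        removed_no_population=removed_pop,
        removed_missing_covariates=removed_missing,
    )
    return df, log


def segregation_ratio(pct_group: np.ndarray, state_avg_pct: float) -> np.ndarray:
    """Block-group percent of a group divided by the state-average percent."""
    if state_avg_pct <= 0:
        raise ValueError("state average percent must be positive")
    return np.asarray(pct_group, dtype=float) / state_avg_pct


def invert_income(x: np.ndarray) -> np.ndarray:
    """Reverse the direction of an advantage variable: max(x) - x."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("empty vector")
    return x.max() - x


def decile_scores(x: np.ndarray) -> np.ndarray:
    """Empirical decile scores in {0, ..., 9}.

    Breakpoints are type-7 quantiles at probabilities 0.1 ... 0.9; values are
    assigned to left-closed bins with ties at a breakpoint going to the lower
    bin.  A constant vector scores all zeros (with a warning).
    """
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("empty vector")
    if np.isnan(x).any():
        raise ValueError("decile scoring requires complete data; filter units first")
    if np.unique(x).size == 1:
        warnings.warn("constant covariate: all decile scores set to 0", stacklevel=2)
        return np.zeros(x.shape, dtype=np.int64)
    breaks = np.quantile(x, np.arange(1, 10) / 10.0)  # type-7 (linear) quantiles
    return np.searchsorted(breaks, x, side="left").astype(np.int64)


def decile_matrix(records: pd.DataFrame) -> np.ndarray:
    """Decile-score all nine covariates (income inverted first).

    Returns an (n_units, 9) integer matrix in covariate canonical order.
    """
    q = np.empty((len(records), len(COVARIATE_COLUMNS)), dtype=np.int64)
    for j, col in enumerate(COVARIATE_COLUMNS):
        x = records[col].to_numpy(dtype=float)
        if col in INVERTED_COVARIATES:
            x = invert_income(x)
        q[:, j] = decile_scores(x)
    return q


def expected_counts(records: pd.DataFrame) -> ExpectedCounts:
    """E_ik = r_k * p_i with r_k the overall count-per-person rate of type k."""
    p = records["population"].to_numpy(dtype=float)
    total_pop = p.sum()
    if total_pop <= 0:
        raise ValueError("total population must be positive")
    y = records[COUNT_COLUMNS].to_numpy(dtype=float)
    rates = y.sum(axis=0) / total_pop
    if (rates == 0).any():
        degenerate = [OUTLET_TYPES[k] for k in np.flatnonzero(rates == 0)]
        warnings.warn(f"zero overall rate for outlet type(s) {degenerate}; "
                      "expected counts for these types are all zero", stacklevel=2)
    return ExpectedCounts(E=np.outer(p, rates), rates=rates,
                          block_group_ids=records["block_group_id"].tolist())


def population_density(records: pd.DataFrame) -> np.ndarray:
    area = records["area_sqmi"].to_numpy(dtype=float)
    if (area <= 0).any():
        raise ValueError("area must be positive for all block groups")
    return records["population"].to_numpy(dtype=float) / area


def population_density_category(records: pd.DataFrame) -> pd.Categorical:
    """rural (<500 / sq mi), suburban (>=500 and <1000), urban (>=1000)."""
    d = population_density(records)
    lo, hi = DENSITY_BREAKS
    labels = np.where(d < lo, "rural", np.where(d < hi, "suburban", "urban"))
    return pd.Categorical(labels, categories=DENSITY_CATEGORIES, ordered=True)
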