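"""Reported quantities from posterior draws.

Relative-risk surfaces with exceedance-probability elevation flags, the
shared (exp(u+v)) and outlet-specific (exp(s)) risk components, the
estimated disadvantage index and its weights, per-decile index effects as
relative risks, and mean-risk / percent-elevated tables by population
density category.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import PosteriorDraws
from .prep import DENSITY_CATEGORIES, OUTLET_TYPES

RR_THRESHOLD = 1.0
EXCEEDANCE_PROB_THRESHOLD = 0.90


def exceedance_probability(theta_draws: np.ndarray, threshold: float = RR_THRESHOLD) -> np.ndarray:
    """Fraction of draws strictly greater than ``threshold`` (first axis)."""
    theta_draws = np.asarray(theta_draws, dtype=float)
    if theta_draws.shape[0] < 1:
        raise ValueError("need at least one draw")
    return (theta_draws > threshold).mean(axis=0)


def relative_risk_draws(draws: PosteriorDraws, q: np.ndarray) -> np.ndarray:
    """Per-draw relative risks theta_ik; shape (draws, n_units, K)."""
    w = draws.flat("w")
    ndi = w @ np.asarray(q, dtype=float).T                      # (D, n)
    alpha = draws.flat("alpha")
    beta = draws.flat("beta")
    shared = draws.flat("u") + draws.flat("v")                  # (D, n)
    log_theta = (alpha[:, None, :] + beta[:, None, :] * ndi[:, :, None]
                 + shared[:, :, None] + draws.flat("s"))
    return np.exp(log_theta)


@dataclass
class RRSummary:
    """Per-unit, per-type relative-risk summaries."""

    unit_ids: list[str]
    rr_median: np.ndarray        # (n, K)
    rr_lo: np.ndarray
    rr_hi: np.ndarray
    exceedance_prob: np.ndarray  # (n, K)
    elevated: np.ndarray         # bool (n, K)
    shared_median: np.ndarray    # (n,)  exp(u+v)
    specific_median: np.ndarray  # (n, K) exp(s)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, uid in enumerate(self.unit_ids):
            for k, typ in enumerate(OUTLET_TYPES):
                rows.append({
                    "block_group_id": uid, "outlet_type": typ,
                    "rr_median": self.rr_median[i, k],
                    "rr_lo": self.rr_lo[i, k], "rr_hi": self.rr_hi[i, k],
                    "exceedance_prob": self.exceedance_prob[i, k],
                    "elevated": bool(self.elevated[i, k]),
                    "shared_rr_median": self.shared_median[i],
                    "specific_rr_median": self.specific_median[i, k],
                })
        return pd.DataFrame(rows)


def summarize_rr(
    draws: PosteriorDraws,
    q: np.ndarray,
    unit_ids: list[str] | None = None,
    rr_threshold: float = RR_THRESHOLD,
    prob_threshold: float = EXCEEDANCE_PROB_THRESHOLD,
) -> RRSummary:
    """Medians, equal-tailed 95% intervals and exceedance flags for theta_ik.

    A unit is flagged elevated when Pr(theta > rr_threshold) >= prob_threshold
    (boundary included).  Also summarizes the shared exp(u+v) and
    outlet-specific exp(s) risk components.
    """
    theta = relative_risk_draws(draws, q)
    lo, med, hi = np.percentile(theta, [2.5, 50.0, 97.5], axis=0)
    exc = exceedance_probability(theta, rr_threshold)
    shared = np.exp(draws.flat("u") + draws.flat("v"))
    specific = np.exp(draws.flat("s"))
    n = theta.shape[1]
    ids = unit_ids if unit_ids is not None else [f"unit{i}" for i in range(n)]
    return RRSummary(
        unit_ids=list(ids),
        rr_median=med, rr_lo=lo, rr_hi=hi,
        exceedance_prob=exc,
        elevated=exc >= prob_threshold,
        shared_median=np.median(shared, axis=0),
        specific_median=np.median(specific, axis=0),
    )


def ndi_effect_rr(draws: PosteriorDraws) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Index effects as relative risks per one-decile increase.

    Returns (effects, prob_greater): per type the median and equal-tailed
    95% interval of exp(beta_k), plus the pairwise posterior probabilities
    Pr(beta_j > beta_k) across draws.
    """
    beta = draws.flat("beta")
    rr = np.exp(beta)
    lo, med, hi = np.percentile(rr, [2.5, 50.0, 97.5], axis=0)
    effects = pd.DataFrame({
        "outlet_type": OUTLET_TYPES,
        "rr_median": med, "rr_lo": lo, "rr_hi": hi,
    })
    k = beta.shape[1]
    pg = np.array([[np.mean(beta[:, j] > beta[:, kk]) for kk in range(k)] for j in range(k)])
    prob_greater = pd.DataFrame(pg, index=OUTLET_TYPES, columns=OUTLET_TYPES)
    return effects, prob_greater


def ndi_summary(draws: PosteriorDraws, q: np.ndarray,
                unit_ids: list[str] | None = None) -> dict[str, pd.DataFrame]:
    """Posterior summaries of the disadvantage index and its weights.

    Weight medians need not sum to one; the renormalized column is flagged
    as such.
    """
    w = draws.flat("w")
    lo, med, hi = np.percentile(w, [2.5, 50.0, 97.5], axis=0)
    weights = pd.DataFrame({
        "covariate_rank": np.arange(1, w.shape[1] + 1),
        "weight_median": med, "weight_lo": lo, "weight_hi": hi,
        "weight_median_renormalized": med / med.sum(),
    })
    weights.attrs["renormalized"] = True

    ndi = w @ np.asarray(q, dtype=float).T
    nlo, nmed, nhi = np.percentile(ndi, [2.5, 50.0, 97.5], axis=0)
    ids = unit_ids if unit_ids is not None else [f"unit{i}" for i in range(q.shape[0])]
    units = pd.DataFrame({
        "block_group_id": ids, "ndi_median": nmed, "ndi_lo": nlo, "ndi_hi": nhi,
    })
    return {"weights": weights, "units": units}


def density_table(rr: RRSummary, categories: pd.Categorical | np.ndarray) -> pd.DataFrame:
    """Mean relative risk and fraction significantly elevated, by density
    category and outlet type.  Empty categories are reported as missing."""
    cats = pd.Categorical(categories, categories=DENSITY_CATEGORIES, ordered=True)
    if len(cats) != len(rr.unit_ids):
        raise ValueError("one density category per unit required")
    rows = []
    codes = np.asarray(cats.codes)
    for c_idx, cat in enumerate(DENSITY_CATEGORIES):
        mask = codes == c_idx
        for k, typ in enumerate(OUTLET_TYPES):
            if mask.any():
                rows.append({
                    "density_category": cat, "outlet_type": typ,
                    "mean_rr": float(rr.rr_median[mask, k].mean()),
                    "pct_significant": float(rr.elevated[mask, k].mean()),
                    "n_units": int(mask.sum()),
                })
            else:
                rows.append({
                    "density_category": cat, "outlet_type": typ,
                    "mean_rr": np.nan, "pct_significant": np.nan, "n_units": 0,
                })
    return pd.DataFrame(rows)
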