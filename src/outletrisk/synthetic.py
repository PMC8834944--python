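"""Synthetic data with known ground truth for every pipeline stage.

Two generators:

* :func:`generate_areal_dataset` draws a lattice of block groups with nine
  correlated sociodemographic covariates and Poisson outlet counts from the
  shared-component index model with known weights and effects, so parameter
  recovery can be checked against truth.
* :func:`generate_listing_pairs` creates noisy duplicate TRO/ARO business
  listings with known dual-product (TARO) ground truth, exercising the
  record-linkage stage end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats as st

from .adjacency import AdjacencyStructure
from .matching import EARTH_RADIUS_FT, BusinessListing, OutletClass
from .prep import COVARIATE_COLUMNS, decile_matrix

_FEET_PER_DEG_LAT = EARTH_RADIUS_FT * np.pi / 180.0


def _as_simplex(w, n_vars: int) -> np.ndarray:
    w = np.asarray(w, dtype=float)
    if w.shape != (n_vars,):
        raise ValueError(f"true_weights must have length {n_vars}")
    if (w < 0).any() or (w > 1).any() or abs(w.sum() - 1.0) > 1e-12:
        raise ValueError("true_weights must lie on the unit simplex (sum 1, elements in [0,1])")
    return w


def _default_weights() -> tuple[float, ...]:
    # three dominant covariates, remainder spread over the other six
    rest = (1.0 - (0.60 + 0.23 + 0.09)) / 6.0
    return (0.60, 0.23, 0.09) + (rest,) * 6


def _default_betas() -> tuple[float, ...]:
    return (float(np.log(1.12)), float(np.log(1.15)), float(np.log(1.21)))


@dataclass
class SyntheticConfig:
    """Generating parameters for the areal (block-group) simulator.

    Defaults reflect a moderate-signal study condition: per-decile index
    effects of RR 1.12/1.15/1.21 for the three outlet types, weights
    concentrated on the first three covariates, and mild unstructured plus
    spatially correlated heterogeneity.
    """

    lattice_rows: int = 15
    lattice_cols: int = 15
    n_vars: int = 9
    true_weights: tuple[float, ...] = field(default_factory=_default_weights)
    true_betas: tuple[float, float, float] = field(default_factory=_default_betas)
    true_intercepts: tuple[float, float, float] = (0.0, 0.0, 0.0)
    sd_u: float = 0.10
    sd_v: float = 0.20
    sd_s: tuple[float, float, float] = (0.10, 0.10, 0.10)
    population_range: tuple[int, int] = (200, 4000)
    area_range: tuple[float, float] = (0.2, 20.0)
    covariate_correlation: float = 0.30
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lattice_rows * self.lattice_cols < 4:
            raise ValueError("lattice must have at least 4 cells")
        self.true_weights = tuple(_as_simplex(self.true_weights, self.n_vars))
        if len(self.true_betas) != 3 or len(self.true_intercepts) != 3 or len(self.sd_s) != 3:
            raise ValueError("true_betas, true_intercepts and sd_s must have length 3")
        if self.sd_u < 0 or self.sd_v < 0 or min(self.sd_s) < 0:
            raise ValueError("spatial scales must be nonnegative")
        if self.population_range[0] < 1 or self.population_range[0] > self.population_range[1]:
            raise ValueError("population_range lower bound must be >= 1 and <= upper bound")
        if self.area_range[0] <= 0 or self.area_range[0] > self.area_range[1]:
            raise ValueError("area_range must be positive and ordered")
        if not 0.0 <= self.covariate_correlation < 1.0:
            raise ValueError("covariate_correlation must be in [0, 1)")


@dataclass
class SyntheticTruth:
    """Realized generating values, kept for recovery tests."""

    weights: np.ndarray
    betas: np.ndarray
    intercepts: np.ndarray
    u: np.ndarray
    v: np.ndarray
    s: np.ndarray
    ndi_true: np.ndarray


@dataclass
class SyntheticDataset:
    block_groups: pd.DataFrame
    adjacency: AdjacencyStructure
    truth: SyntheticTruth


def icar_draw(adj: AdjacencyStructure, rng: np.random.Generator) -> np.ndarray:
    """One exact draw from the unit-precision ICAR pseudo-density.

    Samples the non-null eigenvectors of the graph Laplacian with variances
    1/lambda_m, then centers to sum zero within each connected component.
    """
    lam, vec = np.linalg.eigh(adj.laplacian().toarray())
    keep = lam > 1e-8
    coefs = rng.standard_normal(keep.sum()) / np.sqrt(lam[keep])
    z = vec[:, keep] @ coefs
    for c in range(adj.n_components):
        mask = adj.component_labels == c
        z[mask] -= z[mask].mean()
    return z


# marginal distributions for the nine covariates (heterogeneous on purpose;
# decile scoring downstream discards the marginals anyway)
_MARGINALS = [
    st.lognorm(s=1.0),                      # black segregation ratio
    st.lognorm(s=0.9),                      # hispanic segregation ratio
    st.beta(2.0, 8.0),                      # pct income-to-poverty < 1 (x100)
    st.beta(1.5, 20.0),                     # pct public assistance (x100)
    st.beta(2.0, 4.0),                      # pct renter occupied (x100)
    st.beta(1.5, 10.0),                     # pct built 1939 or earlier (x100)
    st.beta(2.0, 10.0),                     # pct no high-school degree (x100)
    st.beta(2.0, 9.0),                      # pct households in poverty (x100)
    st.lognorm(s=0.4, scale=27_000.0),      # per-capita income (USD)
]
_PERCENT_SCALE = np.array([1, 1, 100, 100, 100, 100, 100, 100, 1], dtype=float)


def _correlated_covariates(n: int, rho: float, rng: np.random.Generator) -> np.ndarray:
    """Gaussian copula with common pairwise correlation, mapped through
    heterogeneous marginals."""
    k = len(_MARGINALS)
    z = rng.standard_normal((n, k))
    if rho > 0:
        shared = rng.standard_normal(n)
        z = np.sqrt(rho) * shared[:, None] + np.sqrt(1.0 - rho) * z
    uniforms = st.norm.cdf(z)
    x = np.column_stack([_MARGINALS[j].ppf(uniforms[:, j]) for j in range(k)])
    return x * _PERCENT_SCALE


def generate_areal_dataset(cfg: SyntheticConfig) -> SyntheticDataset:
    """Simulate block groups, covariates and Poisson counts from the model.

    Counts are drawn as y_ik ~ Poisson(theta_ik * E0_i) with
    log theta_ik = alpha_k + beta_k * NDI_i + u_i + v_i + s_ik and provisional
    exposure E0_i = p_i / mean(p).  Downstream expected counts are recomputed
    from the realized totals, exactly as on real data; the true intercepts are
    therefore on the E0 scale (beta and weights are unaffected).
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.lattice_rows * cfg.lattice_cols
    adj = AdjacencyStructure.from_lattice(cfg.lattice_rows, cfg.lattice_cols)

    x = _correlated_covariates(n, cfg.covariate_correlation, rng)
    population = rng.integers(cfg.population_range[0], cfg.population_range[1] + 1, size=n)
    area = rng.uniform(cfg.area_range[0], cfg.area_range[1], size=n)

    df = pd.DataFrame({"block_group_id": adj.ids, "population": population, "area_sqmi": area})
    for j, col in enumerate(COVARIATE_COLUMNS):
        df[col] = x[:, j]

    # decile-score exactly as the preparation stage will, so ndi_true matches
    df_for_q = df.copy()
    df_for_q[["n_tro", "n_aro", "n_taro"]] = 0
    q = decile_matrix(df_for_q)
    w = np.asarray(cfg.true_weights)
    ndi = q @ w

    u = rng.normal(0.0, cfg.sd_u, size=n) if cfg.sd_u > 0 else np.zeros(n)
    v = cfg.sd_v * icar_draw(adj, rng) if cfg.sd_v > 0 else np.zeros(n)
    s = np.column_stack(
        [cfg.sd_s[k] * icar_draw(adj, rng) if cfg.sd_s[k] > 0 else np.zeros(n) for k in range(3)]
    )

    alphas = np.asarray(cfg.true_intercepts, dtype=float)
    betas = np.asarray(cfg.true_betas, dtype=float)
    log_theta = alphas[None, :] + betas[None, :] * ndi[:, None] + (u + v)[:, None] + s
    e0 = population / population.mean()
    y = rng.poisson(np.exp(log_theta) * e0[:, None])

    df[["n_tro", "n_aro", "n_taro"]] = y
    truth = SyntheticTruth(weights=w, betas=betas, intercepts=alphas, u=u, v=v, s=s, ndi_true=ndi)
    return SyntheticDataset(block_groups=df, adjacency=adj, truth=truth)


# ---------------------------------------------------------------------------
# business-listing simulator
# ---------------------------------------------------------------------------

@dataclass
class ListingSimConfig:
    """Configuration for the noisy duplicate-listing simulator."""

    n_blockgroups: int = 40
    chain_pool_size: int = 60
    n_taro_true: int = 200
    n_tro_only: int = 150
    n_aro_only: int = 150
    typo_rate: float = 0.02
    coord_jitter_ft: float = 100.0
    known_chain_fraction: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_taro_true, self.n_tro_only, self.n_aro_only) < 0:
            raise ValueError("listing counts must be nonnegative")
        if not 0.0 <= self.typo_rate <= 1.0 or not np.isfinite(self.typo_rate):
            raise ValueError("typo_rate must be a finite probability")
        if self.coord_jitter_ft < 0 or not np.isfinite(self.coord_jitter_ft):
            raise ValueError("coord_jitter_ft must be finite and nonnegative")
        if self.n_blockgroups < 1 or self.chain_pool_size < 1:
            raise ValueError("n_blockgroups and chain_pool_size must be positive")
        if not 0.0 <= self.known_chain_fraction <= 1.0:
            raise ValueError("known_chain_fraction must be in [0, 1]")


_CHAIN_FIRST = ["CIRCLE", "FOOD", "SPEEDY", "QUALITY", "GOLDEN", "RIVER", "SUMMIT", "COASTAL",
                "PIEDMONT", "LIBERTY", "UNION", "CAPITAL", "SUNRISE", "BLUE RIDGE", "CAROLINA",
                "EAGLE", "PINE", "CEDAR", "HARBOR", "VALLEY"]
_CHAIN_SECOND = ["K STORES INC", "LION LLC", "MART INC", "MARKET CO", "FUELS LLC", "GROCERY INC",
                 "EXPRESS LLC", "TRADING CO", "STOP INC", "PANTRY LLC", "DEPOT INC", "CORNER LLC"]
_LOCAL_FIRST = ["ANDERSON", "BAKER", "CARTER", "DAVIS", "EVANS", "FISHER", "GRANT", "HARRIS",
                "IRWIN", "JORDAN", "KELLER", "LAWSON", "MILLER", "NORRIS", "OWENS", "PARKER",
                "QUINN", "ROGERS", "SUTTON", "TURNER", "UNDERWOOD", "VANCE", "WALKER", "YOUNG"]
_LOCAL_SECOND = ["SMOKE SHOP", "TOBACCO OUTLET", "VAPE CO", "CIGAR ROOM", "BOTTLE SHOP",
                 "WINE CELLAR", "BREW SUPPLY", "PACKAGE STORE", "QUICK STOP", "CORNER STORE"]
_STREET_NAMES = ["MAIN", "OAK", "ELM", "MAPLE", "PINE", "CHURCH", "MILL", "RIVER", "LAKE",
                 "HILL", "FOREST", "SPRING", "WASHINGTON", "JEFFERSON", "FRANKLIN", "MARKET"]
_SUFFIX_VARIANTS = [["STREET", "ST"], ["AVENUE", "AVE"], ["ROAD", "RD"], ["BOULEVARD", "BLVD"],
                    ["DRIVE", "DR"], ["HIGHWAY", "HWY"], ["LANE", "LN"], ["COURT", "CT"],
                    ["PLACE", "PL"], ["PARKWAY", "PKWY"]]
_ALPHABET = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"


def _chain_pool(size: int, rng: np.random.Generator) -> list[str]:
    combos = [f"{a} {b}" for a in _CHAIN_FIRST for b in _CHAIN_SECOND]
    idx = rng.choice(len(combos), size=min(size, len(combos)), replace=False)
    return [combos[i] for i in sorted(idx)]


def _local_name(rng: np.random.Generator) -> str:
    return f"{rng.choice(_LOCAL_FIRST)} {rng.choice(_LOCAL_SECOND)}"


def _typo(text: str, rate: float, rng: np.random.Generator) -> str:
    """Per-character edits: substitution, deletion or insertion at `rate`."""
    if rate <= 0:
        return text
    out = []
    for ch in text:
        if rng.random() < rate:
            op = rng.integers(3)
            if op == 0:  # substitute
                out.append(_ALPHABET[rng.integers(26)])
            elif op == 1:  # delete
                continue
            else:  # insert
                out.append(ch)
                out.append(_ALPHABET[rng.integers(26)])
        else:
            out.append(ch)
    return "".join(out) or text[:1]


def generate_listing_pairs(
    cfg: ListingSimConfig,
) -> tuple[list[BusinessListing], list[tuple[str, str]], list[str]]:
    """Simulate TRO/ARO registries with known dual-product ground truth.

    Each true TARO appears once in each registry: the alcohol-registry copy
    carries per-character typos in name and address at ``typo_rate`` and an
    isotropic Gaussian coordinate perturbation with per-axis standard
    deviation ``coord_jitter_ft``.  Returns the listings, the ground-truth
    (tro_id, aro_id) pairs, and the commonly-appearing-chain name list.
    """
    rng = np.random.default_rng(cfg.seed)
    pool = _chain_pool(cfg.chain_pool_size, rng)
    n_known = int(round(cfg.known_chain_fraction * len(pool)))
    known = pool[:n_known]

    # block-group anchor coordinates on a coarse grid (~1.4 mi spacing)
    bg_ids = [f"BG{i + 1:04d}" for i in range(cfg.n_blockgroups)]
    grid_cols = int(np.ceil(np.sqrt(cfg.n_blockgroups)))
    centers = {
        bg: (35.0 + 0.02 * (i // grid_cols), -79.0 + 0.02 * (i % grid_cols))
        for i, bg in enumerate(bg_ids)
    }

    def base_point(bg: str) -> tuple[float, float]:
        lat0, lon0 = centers[bg]
        return (lat0 + rng.uniform(-0.005, 0.005), lon0 + rng.uniform(-0.005, 0.005))

    def address_pair() -> tuple[str, str]:
        num = rng.integers(100, 10_000)
        street = rng.choice(_STREET_NAMES)
        variants = _SUFFIX_VARIANTS[rng.integers(len(_SUFFIX_VARIANTS))]
        return (
            f"{num} {street} {variants[rng.integers(len(variants))]}",
            f"{num} {street} {variants[rng.integers(len(variants))]}",
        )

    listings: list[BusinessListing] = []
    truth_pairs: list[tuple[str, str]] = []
    jitter_deg_lat = cfg.coord_jitter_ft / _FEET_PER_DEG_LAT

    for i in range(cfg.n_taro_true):
        bg = bg_ids[int(rng.integers(cfg.n_blockgroups))]
        lat, lon = base_point(bg)
        name = pool[int(rng.integers(len(pool)))]
        addr_t, addr_a = address_pair()
        tro_name = name + (f" #{rng.integers(1, 10_000)}" if rng.random() < 0.3 else "")
        tid, aid = f"T{i + 1:05d}", f"A{i + 1:05d}"
        listings.append(BusinessListing(tid, tro_name, addr_t, lat, lon, OutletClass.TRO, bg))
        dlat = rng.normal(0.0, jitter_deg_lat) if cfg.coord_jitter_ft > 0 else 0.0
        dlon = (rng.normal(0.0, jitter_deg_lat) / np.cos(np.radians(lat))
                if cfg.coord_jitter_ft > 0 else 0.0)
        listings.append(
            BusinessListing(
                aid,
                _typo(name, cfg.typo_rate, rng),
                _typo(addr_a, cfg.typo_rate, rng),
                lat + dlat,
                lon + dlon,
                OutletClass.ARO,
                bg,
            )
        )
        truth_pairs.append((tid, aid))

    for i in range(cfg.n_tro_only):
        bg = bg_ids[int(rng.integers(cfg.n_blockgroups))]
        lat, lon = base_point(bg)
        addr, _ = address_pair()
        listings.append(
            BusinessListing(f"T{cfg.n_taro_true + i + 1:05d}", _local_name(rng), addr,
                            lat, lon, OutletClass.TRO, bg)
        )
    for i in range(cfg.n_aro_only):
        bg = bg_ids[int(rng.integers(cfg.n_blockgroups))]
        lat, lon = base_point(bg)
        addr, _ = address_pair()
        listings.append(
            BusinessListing(f"A{cfg.n_taro_true + i + 1:05d}", _local_name(rng), addr,
                            lat, lon, OutletClass.ARO, bg)
        )

    return listings, truth_pairs, known
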