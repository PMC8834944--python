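"""Record linkage of tobacco (TRO) and alcohol (ARO) retail listings.

Two business registries describe overlapping sets of stores with slightly
discordant names, addresses and geocodes.  A store selling both products
(TARO) appears once in each registry; this module identifies such pairs per
block group with a weighted similarity score

    sim(t, a) = 0.25 * namesim + 0.25 * addresssim
              + 0.20 * I(dist < 520.9 ft) + 0.30 * I(dist < 260.45 ft)

where the string similarities are normalized optimal-string-alignment (OSA)
similarities and dist is the great-circle distance between the geocodes.
Pairs scoring at least 0.70 are declared matches.  Block groups whose
listings fall in a single registry use a fallback list of chains known to
sell both products.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, NamedTuple, Sequence

import pandas as pd

EARTH_RADIUS_FT = 20_902_259.0  # spherical earth, 6371.0088 km in feet

#: Eq-style component weights: name, address, outer indicator, inner indicator.
DEFAULT_WEIGHTS = (0.25, 0.25, 0.20, 0.30)
OUTER_THRESHOLD_FT = 520.9
INNER_THRESHOLD_FT = 260.45
MATCH_THRESHOLD = 0.70

_SUFFIX_CANON = {
    "STREET": "ST", "STR": "ST", "ST": "ST",
    "AVENUE": "AVE", "AV": "AVE", "AVE": "AVE",
    "ROAD": "RD", "RD": "RD",
    "BOULEVARD": "BLVD", "BLVD": "BLVD",
    "DRIVE": "DR", "DR": "DR",
    "HIGHWAY": "HWY", "HWY": "HWY",
    "LANE": "LN", "LN": "LN",
    "COURT": "CT", "CT": "CT",
    "PLACE": "PL", "PL": "PL",
    "PARKWAY": "PKWY", "PKWY": "PKWY",
}

# trailing store-identification tokens: "#1234", "NO 12", "NO. 12", "STORE 7"
_STORE_NUM_RE = re.compile(r"(?:\s*#\s*\d+|\s+NO\.?\s*\d+|\s+STORE\s*\d+)\s*$")
# punctuation to drop (everything non-alphanumeric except '&' and spaces)
_PUNCT_RE = re.compile(r"[^A-Z0-9& ]")


class OutletClass(str, Enum):
    TRO = "TRO"
    ARO = "ARO"


class ListingValidationError(ValueError):
    """Raised when a business listing fails validation."""


@dataclass(frozen=True)
class BusinessListing:
    """One raw retail record from either registry."""

    listing_id: str
    name_raw: str
    address_raw: str
    latitude: float
    longitude: float
    outlet_class: OutletClass
    block_group_id: str

    def __post_init__(self) -> None:
        if not self.name_raw or not self.name_raw.strip():
            raise ListingValidationError(f"listing {self.listing_id!r}: empty business name")
        if not -90.0 <= self.latitude <= 90.0:
            raise ListingValidationError(f"listing {self.listing_id!r}: latitude {self.latitude} out of range")
        if not -180.0 <= self.longitude <= 180.0:
            raise ListingValidationError(f"listing {self.listing_id!r}: longitude {self.longitude} out of range")
        object.__setattr__(self, "outlet_class", OutletClass(self.outlet_class))


@dataclass(frozen=True)
class NormalizedListing:
    listing_id: str
    name_norm: str
    address_norm: str
    latitude: float
    longitude: float
    outlet_class: OutletClass
    block_group_id: str


@dataclass(frozen=True)
class KnownTaroList:
    """Normalized names of chains known to sell both tobacco and alcohol."""

    names_norm: frozenset[str]

    @classmethod
    def from_raw_names(cls, names: Iterable[str]) -> "KnownTaroList":
        return cls(frozenset(normalize_name(n) for n in names if n.strip()))

    def __contains__(self, name_norm: str) -> bool:
        return name_norm in self.names_norm


class BlockGroupCounts(NamedTuple):
    n_tro: int
    n_aro: int
    n_taro: int


@dataclass
class MatchResult:
    """Matched TRO/ARO pairs and per-block-group outlet counts."""

    matched_pairs: list[tuple[str, str, float]]
    counts_per_block_group: dict[str, BlockGroupCounts]

    def pairs_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matched_pairs, columns=["tro_id", "aro_id", "similarity"])

    def counts_frame(self) -> pd.DataFrame:
        rows = [
            {"block_group_id": bg, "n_tro": c.n_tro, "n_aro": c.n_aro, "n_taro": c.n_taro}
            for bg, c in sorted(self.counts_per_block_group.items())
        ]
        return pd.DataFrame(rows, columns=["block_group_id", "n_tro", "n_aro", "n_taro"])


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def _collapse(s: str) -> str:
    return " ".join(s.split())


def _strip_store_numbers(name: str) -> str:
    prev = None
    while prev != name:
        prev = name
        name = _STORE_NUM_RE.sub("", name)
    # a bare trailing all-digit token is a store id unless it is the whole name
    toks = name.split()
    while len(toks) > 1 and toks[-1].isdigit():
        toks.pop()
    return " ".join(toks)


def _canonical_suffixes(address: str) -> str:
    return " ".join(_SUFFIX_CANON.get(tok, tok) for tok in address.split())


def normalize_name(name: str) -> str:
    """Upper-case, drop store-id tokens and punctuation (keeping '&')."""
    s = _collapse(name.upper())
    s = _strip_store_numbers(s)
    s = _collapse(_PUNCT_RE.sub(" ", s))
    return s


def normalize_address(address: str) -> str:
    """Upper-case, drop punctuation, map street-suffix variants to one token."""
    s = _collapse(address.upper())
    s = _collapse(_PUNCT_RE.sub(" ", s))
    return _canonical_suffixes(s)


def normalize_listing(listing: BusinessListing) -> NormalizedListing:
    name = normalize_name(listing.name_raw)
    if not name:
        raise ListingValidationError(
            f"listing {listing.listing_id!r}: name {listing.name_raw!r} empty after normalization"
        )
    return NormalizedListing(
        listing_id=listing.listing_id,
        name_norm=name,
        address_norm=normalize_address(listing.address_raw),
        latitude=listing.latitude,
        longitude=listing.longitude,
        outlet_class=listing.outlet_class,
        block_group_id=listing.block_group_id,
    )


# ---------------------------------------------------------------------------
# similarity components
# ---------------------------------------------------------------------------

def osa_distance(a: str, b: str) -> int:
    """Optimal string alignment distance.

    Restricted Damerau-Levenshtein: unit-cost insertions, deletions,
    substitutions and adjacent transpositions, with no substring edited
    twice (so e.g. d("CA", "ABC") = 3, not 2).
    """
    la, lb = len(a), len(b)
    if la == 0:
        return lb
    if lb == 0:
        return la
    prev2: list[int] | None = None
    prev = list(range(lb + 1))
    for i in range(1, la + 1):
        cur = [i] + [0] * lb
        ai = a[i - 1]
        for j in range(1, lb + 1):
            cost = 0 if ai == b[j - 1] else 1
            d = min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + cost)
            if i > 1 and j > 1 and ai == b[j - 2] and a[i - 2] == b[j - 1]:
                d = min(d, prev2[j - 2] + 1)
            cur[j] = d
        prev2, prev = prev, cur
    return prev[lb]


def string_similarity(a: str, b: str) -> float:
    """1 - OSA(a, b) / max(len(a), len(b)); 1.0 when both strings are empty."""
    m = max(len(a), len(b))
    if m == 0:
        return 1.0
    return 1.0 - osa_distance(a, b) / m


def great_circle_ft(lat1: float, lon1: float, lat2: float, lon2: float) -> float:
    """Haversine great-circle distance in feet on a sphere of 6371.0088 km."""
    phi1, phi2 = math.radians(lat1), math.radians(lat2)
    dphi = phi2 - phi1
    dlmb = math.radians(lon2 - lon1)
    h = math.sin(dphi / 2.0) ** 2 + math.cos(phi1) * math.cos(phi2) * math.sin(dlmb / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_FT * math.asin(min(1.0, math.sqrt(h)))


def total_similarity(
    t: NormalizedListing,
    a: NormalizedListing,
    *,
    weights: Sequence[float] = DEFAULT_WEIGHTS,
    outer_ft: float = OUTER_THRESHOLD_FT,
    inner_ft: float = INNER_THRESHOLD_FT,
) -> float:
    """Weighted name/address/spatial similarity of a TRO and an ARO listing.

    Distance indicators use strict '<' against the printed thresholds.
    """
    w_name, w_addr, w_outer, w_inner = weights
    d = great_circle_ft(t.latitude, t.longitude, a.latitude, a.longitude)
    return (
        w_name * string_similarity(t.name_norm, a.name_norm)
        + w_addr * string_similarity(t.address_norm, a.address_norm)
        + w_outer * (1.0 if d < outer_ft else 0.0)
        + w_inner * (1.0 if d < inner_ft else 0.0)
    )


# ---------------------------------------------------------------------------
# per-block-group counting
# ---------------------------------------------------------------------------

def count_outlets_block_group(
    tros: Sequence[NormalizedListing],
    aros: Sequence[NormalizedListing],
    known: KnownTaroList,
    threshold: float = MATCH_THRESHOLD,
    *,
    weights: Sequence[float] = DEFAULT_WEIGHTS,
    outer_ft: float = OUTER_THRESHOLD_FT,
    inner_ft: float = INNER_THRESHOLD_FT,
) -> tuple[BlockGroupCounts, list[tuple[str, str, float]]]:
    """Classify one block group's listings into TRO / ARO / TARO counts.

    With listings from both registries present, all TRO x ARO pairs are
    scored and matched greedily in descending similarity, one-to-one, with
    matches declared at ``similarity >= threshold``.  A single-registry
    block group instead counts listings whose normalized name is on the
    known dual-product chain list as TAROs.
    """
    bgs = {l.block_group_id for l in list(tros) + list(aros)}
    if len(bgs) > 1:
        raise ListingValidationError(f"listings from multiple block groups: {sorted(bgs)}")

    if tros and aros:
        scored = [
            (total_similarity(t, a, weights=weights, outer_ft=outer_ft, inner_ft=inner_ft),
             t.listing_id, a.listing_id)
            for t in tros
            for a in aros
        ]
        # descending similarity, lexicographic (tro_id, aro_id) tie-break
        scored.sort(key=lambda x: (-x[0], x[1], x[2]))
        used_t: set[str] = set()
        used_a: set[str] = set()
        pairs: list[tuple[str, str, float]] = []
        for sim, tid, aid in scored:
            if sim < threshold:
                break
            if tid in used_t or aid in used_a:
                continue
            used_t.add(tid)
            used_a.add(aid)
            pairs.append((tid, aid, sim))
        counts = BlockGroupCounts(
            n_tro=len(tros) - len(pairs), n_aro=len(aros) - len(pairs), n_taro=len(pairs)
        )
        return counts, pairs

    # single-registry fallback: known dual-product chains are TAROs
    single = list(tros) if tros else list(aros)
    n_known = sum(1 for l in single if l.name_norm in known)
    n_rest = len(single) - n_known
    counts = BlockGroupCounts(
        n_tro=n_rest if tros else 0, n_aro=n_rest if aros else 0, n_taro=n_known
    )
    return counts, []


class OutletMatcher:
    """Estimator-style interface to the per-block-group linkage procedure.

    Parameters mirror the similarity rule; ``fit`` groups listings by block
    group, normalizes them, runs the matcher and exposes the results as
    fitted attributes (``pairs_``, ``counts_``, ``match_result_``).
    """

    def __init__(
        self,
        threshold: float = MATCH_THRESHOLD,
        name_weight: float = 0.25,
        address_weight: float = 0.25,
        outer_weight: float = 0.20,
        inner_weight: float = 0.30,
        outer_ft: float = OUTER_THRESHOLD_FT,
        inner_ft: float = INNER_THRESHOLD_FT,
    ):
        self.threshold = threshold
        self.name_weight = name_weight
        self.address_weight = address_weight
        self.outer_weight = outer_weight
        self.inner_weight = inner_weight
        self.outer_ft = outer_ft
        self.inner_ft = inner_ft

    def get_params(self, deep: bool = True) -> dict:
        return {
            "threshold": self.threshold,
            "name_weight": self.name_weight,
            "address_weight": self.address_weight,
            "outer_weight": self.outer_weight,
            "inner_weight": self.inner_weight,
            "outer_ft": self.outer_ft,
            "inner_ft": self.inner_ft,
        }

    def set_params(self, **params) -> "OutletMatcher":
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(
        self,
        listings: Sequence[BusinessListing],
        known: KnownTaroList | None = None,
    ) -> "OutletMatcher":
        known = known if known is not None else KnownTaroList(frozenset())
        weights = (self.name_weight, self.address_weight, self.outer_weight, self.inner_weight)
        by_bg: dict[str, dict[OutletClass, list[NormalizedListing]]] = {}
        for raw in listings:
            nl = normalize_listing(raw)
            by_bg.setdefault(nl.block_group_id, {OutletClass.TRO: [], OutletClass.ARO: []})[
                nl.outlet_class
            ].append(nl)

        pairs: list[tuple[str, str, float]] = []
        counts: dict[str, BlockGroupCounts] = {}
        for bg in sorted(by_bg):
            c, p = count_outlets_block_group(
                by_bg[bg][OutletClass.TRO],
                by_bg[bg][OutletClass.ARO],
                known,
                self.threshold,
                weights=weights,
                outer_ft=self.outer_ft,
                inner_ft=self.inner_ft,
            )
            counts[bg] = c
            pairs.extend(p)

        self.pairs_ = pairs
        self.counts_ = counts
        self.match_result_ = MatchResult(matched_pairs=pairs, counts_per_block_group=counts)
        return self


def run_matching(
    listings: Sequence[BusinessListing],
    known: KnownTaroList | None = None,
    threshold: float = MATCH_THRESHOLD,
) -> MatchResult:
    """Group listings by block group, match, and aggregate counts."""
    return OutletMatcher(threshold=threshold).fit(listings, known=known).match_result_
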