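"""Listing normalization, similarity components and per-block-group matching."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st_h

from outletrisk.matching import (
    EARTH_RADIUS_FT,
    BusinessListing,
    KnownTaroList,
    ListingValidationError,
    NormalizedListing,
    OutletClass,
    count_outlets_block_group,
    great_circle_ft,
    normalize_address,
    normalize_listing,
    normalize_name,
    osa_distance,
    run_matching,
    string_similarity,
    total_similarity,
)


def _nl(listing_id="x", name="STORE", address="1 MAIN ST", lat=35.0, lon=-79.0,
        cls=OutletClass.TRO, bg="BG1"):
    return NormalizedListing(listing_id, name, address, lat, lon, cls, bg)


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "raw, expected",
    [
        ("Circle K Stores Inc #1234", "CIRCLE K STORES INC"),
        ("FOOD LION LLC", "FOOD LION LLC"),
        ("Quick  Stop   Market", "QUICK STOP MARKET"),
        ("SPEEDWAY NO. 42", "SPEEDWAY"),
        ("KWIK SHOP STORE 17", "KWIK SHOP"),
        ("SAVE-MART 991", "SAVE MART"),
        ("H & H GROCERY", "H & H GROCERY"),
        ("711", "711"),  # an all-digit name is kept, not treated as a store id
    ],
)
def test_name_normalization(raw, expected):
    assert normalize_name(raw) == expected


@pytest.mark.parametrize(
    "raw, expected",
    [
        ("12 Main Street", "12 MAIN ST"),
        ("12 MAIN STR", "12 MAIN ST"),
        ("987 Oak Avenue", "987 OAK AVE"),
        ("5 Pine Boulevard", "5 PINE BLVD"),
        ("44 Lake  Hwy.", "44 LAKE HWY"),
        ("3 Mill Parkway", "3 MILL PKWY"),
    ],
)
def test_address_suffix_canonicalization(raw, expected):
    assert normalize_address(raw) == expected


def test_normalize_listing_rejects_name_that_vanishes():
    listing = BusinessListing("id1", "#99", "1 MAIN ST", 35.0, -79.0, OutletClass.TRO, "BG1")
    with pytest.raises(ListingValidationError):
        normalize_listing(listing)


def test_listing_validation_rejects_bad_coordinates():
    with pytest.raises(ListingValidationError):
        BusinessListing("id1", "STORE", "1 MAIN ST", 95.0, 0.0, OutletClass.TRO, "BG1")
    with pytest.raises(ListingValidationError):
        BusinessListing("id1", "STORE", "1 MAIN ST", 0.0, 181.0, OutletClass.ARO, "BG1")


# ---------------------------------------------------------------------------
# optimal string alignment
# ---------------------------------------------------------------------------

def _osa_oracle(a: str, b: str) -> int:
    """Independent full-matrix OSA oracle."""
    la, lb = len(a), len(b)
    d = np.zeros((la + 1, lb + 1), dtype=int)
    d[:, 0] = np.arange(la + 1)
    d[0, :] = np.arange(lb + 1)
    for i in range(1, la + 1):
        for j in range(1, lb + 1):
            cost = int(a[i - 1] != b[j - 1])
            d[i, j] = min(d[i - 1, j] + 1, d[i, j - 1] + 1, d[i - 1, j - 1] + cost)
            if i > 1 and j > 1 and a[i - 1] == b[j - 2] and a[i - 2] == b[j - 1]:
                d[i, j] = min(d[i, j], d[i - 2, j - 2] + 1)
    return int(d[la, lb])


@pytest.mark.parametrize(
    "a, b, expected",
    [
        ("ABC", "ABC", 0),
        ("AB", "BA", 1),           # single adjacent transposition
        ("CA", "ABC", 3),          # OSA exceeds unrestricted Damerau-Levenshtein (2)
        ("", "XYZ", 3),
        ("KITTEN", "SITTING", 3),
    ],
)
def test_osa_distance_examples(a, b, expected):
    assert osa_distance(a, b) == expected
    assert _osa_oracle(a, b) == expected


@settings(max_examples=200, deadline=None, derandomize=True)
@given(
    st_h.text(alphabet="ABCDE ", max_size=12),
    st_h.text(alphabet="ABCDE ", max_size=12),
)
def test_osa_distance_matches_oracle(a, b):
    assert osa_distance(a, b) == _osa_oracle(a, b)


@pytest.mark.parametrize(
    "a, b, expected",
    [
        ("STORE", "STORE", 1.0),
        ("AB", "BA", 0.5),
        ("", "XYZ", 0.0),
        ("", "", 1.0),
    ],
)
def test_string_similarity(a, b, expected):
    assert string_similarity(a, b) == pytest.approx(expected)


@settings(max_examples=200, deadline=None, derandomize=True)
@given(
    st_h.text(alphabet="ABCDE", max_size=10),
    st_h.text(alphabet="ABCDE", max_size=10),
)
def test_string_similarity_bounded_and_symmetric(a, b):
    s = string_similarity(a, b)
    assert 0.0 <= s <= 1.0
    assert s == string_similarity(b, a)


# ---------------------------------------------------------------------------
# great-circle distance
# ---------------------------------------------------------------------------

def test_great_circle_zero_and_antipodal():
    assert great_circle_ft(35.0, -79.0, 35.0, -79.0) == 0.0
    assert great_circle_ft(0.0, 0.0, 0.0, 180.0) == pytest.approx(math.pi * EARTH_RADIUS_FT)


def test_great_circle_small_latitude_offset():
    # 0.001 deg of latitude = radius * 0.001 * pi/180
    expected = EARTH_RADIUS_FT * 0.001 * math.pi / 180.0
    assert great_circle_ft(0.0, 0.0, 0.001, 0.0) == pytest.approx(expected, rel=1e-9)
    assert expected == pytest.approx(364.8, abs=0.5)


# ---------------------------------------------------------------------------
# total similarity
# ---------------------------------------------------------------------------

def _points_apart_ft(feet: float) -> tuple[float, float]:
    """Latitudes for two equal-longitude points `feet` apart."""
    dlat = math.degrees(feet / EARTH_RADIUS_FT)
    return 35.0, 35.0 + dlat


def test_total_similarity_identical_pair_scores_one():
    t = _nl(cls=OutletClass.TRO)
    a = _nl(listing_id="y", cls=OutletClass.ARO)
    assert total_similarity(t, a) == pytest.approx(1.0)


def test_total_similarity_300ft_boundary_is_exactly_070():
    lat_t, lat_a = _points_apart_ft(300.0)
    t = _nl(lat=lat_t, cls=OutletClass.TRO)
    a = _nl(listing_id="y", lat=lat_a, cls=OutletClass.ARO)
    # only the 520.9-ft indicator fires: 0.25 + 0.25 + 0.20
    assert total_similarity(t, a) == pytest.approx(0.70)


def test_total_similarity_all_components_zero():
    lat_t, lat_a = _points_apart_ft(10_000.0)
    t = _nl(name="AAAA", address="BBBB", lat=lat_t, cls=OutletClass.TRO)
    a = _nl(listing_id="y", name="ZZZZ", address="YYYY", lat=lat_a, cls=OutletClass.ARO)
    assert total_similarity(t, a) == pytest.approx(0.0)


def test_total_similarity_nonincreasing_in_distance():
    t = _nl(cls=OutletClass.TRO)
    sims = []
    for feet in [0.0, 100.0, 260.44, 260.46, 520.89, 520.91, 5000.0]:
        _, lat_a = _points_apart_ft(feet)
        sims.append(total_similarity(t, _nl(listing_id="y", lat=lat_a, cls=OutletClass.ARO)))
    assert all(s1 >= s2 for s1, s2 in zip(sims, sims[1:]))
    # strict '<' against the printed thresholds
    assert sims[2] == pytest.approx(1.0) and sims[3] == pytest.approx(0.70)
    assert sims[4] == pytest.approx(0.70) and sims[5] == pytest.approx(0.50)


# ---------------------------------------------------------------------------
# block-group counting
# ---------------------------------------------------------------------------

def test_single_class_group_uses_known_chain_fallback():
    tro = _nl(listing_id="t1", name="CIRCLE K STORES INC")
    known = KnownTaroList(frozenset({"CIRCLE K STORES INC"}))
    counts, pairs = count_outlets_block_group([tro], [], known)
    assert (counts.n_tro, counts.n_aro, counts.n_taro) == (0, 0, 1)
    assert pairs == []
    # symmetric for an ARO-only group
    aro = _nl(listing_id="a1", name="CIRCLE K STORES INC", cls=OutletClass.ARO)
    counts, _ = count_outlets_block_group([], [aro], known)
    assert (counts.n_tro, counts.n_aro, counts.n_taro) == (0, 0, 1)


def test_exact_duplicate_pair_is_matched():
    t = _nl(listing_id="t1", cls=OutletClass.TRO)
    a = _nl(listing_id="a1", cls=OutletClass.ARO)
    counts, pairs = count_outlets_block_group([t], [a], KnownTaroList(frozenset()))
    assert (counts.n_tro, counts.n_aro, counts.n_taro) == (0, 0, 1)
    assert pairs == [("t1", "a1", pytest.approx(1.0))]


def test_pair_just_below_threshold_is_not_matched():
    # identical strings at 300 ft score exactly 0.70; pushing the name
    # similarity below 1 drops the total under the cutoff
    lat_t, lat_a = _points_apart_ft(300.0)
    t = _nl(listing_id="t1", name="ABCDEFGHIJ", lat=lat_t, cls=OutletClass.TRO)
    a = _nl(listing_id="a1", name="ABCDEFGHIX", lat=lat_a, cls=OutletClass.ARO)
    sim = total_similarity(t, a)
    assert sim == pytest.approx(0.70 - 0.25 * 0.1)
    counts, pairs = count_outlets_block_group([t], [a], KnownTaroList(frozenset()))
    assert (counts.n_tro, counts.n_aro, counts.n_taro) == (1, 1, 0)


def test_known_chain_fallback_not_applied_in_mixed_groups():
    t1 = _nl(listing_id="t1", name="CIRCLE K STORES INC")
    t2 = _nl(listing_id="t2", name="UNRELATED TOBACCO", address="9 OAK AVE", lat=35.2)
    a2 = _nl(listing_id="a2", name="UNRELATED TOBACCO", address="9 OAK AVE", lat=35.2,
             cls=OutletClass.ARO)
    known = KnownTaroList(frozenset({"CIRCLE K STORES INC"}))
    counts, pairs = count_outlets_block_group([t1, t2], [a2], known)
    # t2/a2 match by similarity; the known chain t1 stays a plain TRO
    assert (counts.n_tro, counts.n_aro, counts.n_taro) == (1, 0, 1)
    assert [(p[0], p[1]) for p in pairs] == [("t2", "a2")]


def test_mixed_block_group_ids_rejected():
    t = _nl(listing_id="t1", bg="BG1")
    a = _nl(listing_id="a1", bg="BG2", cls=OutletClass.ARO)
    with pytest.raises(ListingValidationError):
        count_outlets_block_group([t], [a], KnownTaroList(frozenset()))


def test_count_conservation(rng):
    """Original class counts equal residual counts plus matched pairs."""
    from outletrisk.synthetic import ListingSimConfig, generate_listing_pairs

    cfg = ListingSimConfig(n_blockgroups=8, n_taro_true=30, n_tro_only=20, n_aro_only=25,
                           typo_rate=0.05, coord_jitter_ft=200.0, seed=3)
    listings, _, known = generate_listing_pairs(cfg)
    result = run_matching(listings, KnownTaroList.from_raw_names(known))
    by_bg_orig = {}
    for l in listings:
        c = by_bg_orig.setdefault(l.block_group_id, [0, 0])
        c[0 if l.outlet_class == OutletClass.TRO else 1] += 1
    matched_by_bg = {}
    tro_bg = {l.listing_id: l.block_group_id for l in listings}
    for tid, aid, _ in result.matched_pairs:
        matched_by_bg[tro_bg[tid]] = matched_by_bg.get(tro_bg[tid], 0) + 1
    for bg, (nt, na) in by_bg_orig.items():
        c = result.counts_per_block_group[bg]
        taro_from_pairs = matched_by_bg.get(bg, 0)
        if nt and na:
            assert c.n_tro + taro_from_pairs == nt
            assert c.n_aro + taro_from_pairs == na
        else:  # single-class fallback: TAROs come out of the single class
            assert c.n_tro + c.n_aro + c.n_taro == nt + na


def test_run_matching_empty_and_permutation_invariant():
    assert run_matching([]).matched_pairs == []
    t = BusinessListing("t1", "STORE A", "1 MAIN ST", 35.0, -79.0, OutletClass.TRO, "BG1")
    a = BusinessListing("a1", "STORE A", "1 MAIN ST", 35.0, -79.0, OutletClass.ARO, "BG1")
    t2 = BusinessListing("t2", "STORE B", "2 OAK AVE", 36.0, -78.0, OutletClass.TRO, "BG2")
    r1 = run_matching([t, a, t2])
    r2 = run_matching([t2, a, t])
    assert r1.matched_pairs == r2.matched_pairs
    assert r1.counts_per_block_group == r2.counts_per_block_group


def brute_force_matching(tros, aros, threshold=0.70):
    """Exhaustive one-to-one assignment: max pair count, then max total
    similarity, over pairs scoring at least the threshold."""
    best = (0, -1.0, frozenset())
    nt, na = len(tros), len(aros)
    small, large = (tros, aros) if nt <= na else (aros, tros)
    for k in range(len(small) + 1):
        for subset in itertools.combinations(range(len(small)), k):
            for perm in itertools.permutations(range(len(large)), k):
                pairs = []
                ok = True
                total = 0.0
                for i_s, i_l in zip(subset, perm):
                    t, a = (small[i_s], large[i_l]) if nt <= na else (large[i_l], small[i_s])
                    sim = total_similarity(t, a)
                    if sim < threshold:
                        ok = False
                        break
                    pairs.append((t.listing_id, a.listing_id))
                    total += sim
                if ok and (len(pairs), total) > (best[0], best[1]):
                    best = (len(pairs), total, frozenset(pairs))
    return best[2]


def test_greedy_equals_brute_force_on_small_groups():
    """Spot-check the greedy matcher against exhaustive assignment."""
    from outletrisk.matching import normalize_listing
    from outletrisk.synthetic import ListingSimConfig, generate_listing_pairs

    mismatches = 0
    for trial in range(40):
        cfg = ListingSimConfig(n_blockgroups=1, chain_pool_size=10,
                               n_taro_true=trial % 4, n_tro_only=(trial // 4) % 3,
                               n_aro_only=(trial // 12) % 3, typo_rate=0.08,
                               coord_jitter_ft=250.0, seed=9000 + trial)
        listings, _, _ = generate_listing_pairs(cfg)
        norm = [normalize_listing(l) for l in listings]
        tros = [l for l in norm if l.outlet_class == OutletClass.TRO][:3]
        aros = [l for l in norm if l.outlet_class == OutletClass.ARO][:3]
        if not tros or not aros:
            continue
        _, greedy_pairs = count_outlets_block_group(tros, aros, KnownTaroList(frozenset()))
        greedy_set = frozenset((t, a) for t, a, _ in greedy_pairs)
        if greedy_set != brute_force_matching(tros, aros):
            mismatches += 1
    assert mismatches == 0
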