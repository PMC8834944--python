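"""Readers/writers for the pipeline's plain-text formats, plus run manifests.

Dialects: block-group table and listings as headered UTF-8 CSV, adjacency as
one ``id: neighbor neighbor ...`` line per unit, known-chain list as one name
per line (normalized on load), run manifests as JSON.
"""

from __future__ import annotations

import hashlib
import json
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .adjacency import AdjacencyError, AdjacencyStructure
from .matching import BusinessListing, KnownTaroList, ListingValidationError
from .prep import REQUIRED_COLUMNS

LISTING_COLUMNS = ["listing_id", "name", "address", "latitude", "longitude",
                   "outlet_class", "block_group_id"]


def read_block_groups(path: str | Path) -> pd.DataFrame:
    """Read the block-group CSV; missing covariates stay missing (NaN) so the
    filtering stage can log them.  Malformed numeric cells raise with the
    offending line numbers."""
    df = pd.read_csv(path, dtype={"block_group_id": str})
    missing_cols = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"{path}: missing required columns {missing_cols}")
    numeric = [c for c in REQUIRED_COLUMNS if c != "block_group_id"]
    for col in numeric:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            lines = (df.index[bad] + 2).tolist()  # +2: header plus 1-indexing
            raise ValueError(f"{path}: non-numeric values in column {col!r} at line(s) {lines}")
        df[col] = coerced
    return df[REQUIRED_COLUMNS]


def write_block_groups(df: pd.DataFrame, path: str | Path) -> None:
    df[REQUIRED_COLUMNS].to_csv(path, index=False)


def read_listings(path: str | Path) -> list[BusinessListing]:
    df = pd.read_csv(path, dtype={"listing_id": str, "block_group_id": str})
    missing = [c for c in LISTING_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    listings = []
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            listings.append(
                BusinessListing(
                    listing_id=row.listing_id,
                    name_raw=row.name,
                    address_raw=row.address,
                    latitude=float(row.latitude),
                    longitude=float(row.longitude),
                    outlet_class=row.outlet_class,
                    block_group_id=row.block_group_id,
                )
            )
        except (ListingValidationError, ValueError) as exc:
            raise ValueError(f"{path}: line {i + 2}: {exc}") from exc
    return listings


def write_listings(listings: list[BusinessListing], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "listing_id": l.listing_id, "name": l.name_raw, "address": l.address_raw,
                "latitude": l.latitude, "longitude": l.longitude,
                "outlet_class": l.outlet_class.value, "block_group_id": l.block_group_id,
            }
            for l in listings
        ],
        columns=LISTING_COLUMNS,
    ).to_csv(path, index=False)


def read_known_chains(path: str | Path) -> KnownTaroList:
    names = [ln.strip() for ln in Path(path).read_text(encoding="utf-8").splitlines()]
    return KnownTaroList.from_raw_names(n for n in names if n)


def write_known_chains(names: list[str], path: str | Path) -> None:
    Path(path).write_text("\n".join(names) + "\n", encoding="utf-8")


def read_adjacency(path: str | Path) -> AdjacencyStructure:
    """Parse the ``id: neighbor neighbor ...`` dialect (symmetry enforced)."""
    mapping: dict[str, list[str]] = {}
    for lineno, line in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if ":" not in line:
            raise AdjacencyError(f"{path}: line {lineno}: expected 'id: neighbors'")
        uid, _, rest = line.partition(":")
        uid = uid.strip()
        if uid in mapping:
            raise AdjacencyError(f"{path}: line {lineno}: duplicate unit {uid!r}")
        mapping[uid] = rest.split()
    return AdjacencyStructure.from_neighbor_ids(mapping)


def write_adjacency(adj: AdjacencyStructure, path: str | Path) -> None:
    lines = [
        f"{adj.ids[i]}: " + " ".join(adj.ids[j] for j in adj.neighbors[i])
        for i in range(adj.n)
    ]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# run manifests
# ---------------------------------------------------------------------------

def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def build_manifest(stage: str, config: dict, seeds: list[int],
                   inputs: list[str | Path]) -> dict:
    cfg_json = json.dumps(config, sort_keys=True, default=str)
    return {
        "stage": stage,
        "package_version": __version__,
        "timestamp_utc": datetime.now(timezone.utc).isoformat(),
        "seeds": seeds,
        "config": config,
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "input_checksums": {str(p): _sha256(p) for p in inputs if Path(p).exists()},
    }


def write_manifest(manifest: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(manifest, indent=2, default=str) + "\n", encoding="utf-8")


def save_draws_npz(draws, path: str | Path) -> None:
    """Persist full posterior draws (spatial fields included) for later
    summarization; binary runtime artifact."""
    np.savez_compressed(
        path,
        **{k: getattr(draws, k)
           for k in ("alpha", "beta", "w", "u", "v", "s", "tau_u", "tau_v", "tau_s", "tau_beta")},
    )


def load_draws_npz(path: str | Path):
    from .model import PosteriorDraws

    with np.load(path) as z:
        return PosteriorDraws(**{k: z[k] for k in z.files})


def draws_scalar_frame(draws) -> pd.DataFrame:
    """Scalar parameters, one row per stored iteration per chain (CSV-friendly)."""
    rows = []
    for c in range(draws.n_chains):
        for d in range(draws.n_draws):
            row = {"chain": c, "draw": d}
            for k, name in enumerate(["tro", "aro", "taro"]):
                row[f"alpha_{name}"] = draws.alpha[c, d, k]
                row[f"beta_{name}"] = draws.beta[c, d, k]
                row[f"tau_s_{name}"] = draws.tau_s[c, d, k]
            for j in range(draws.w.shape[2]):
                row[f"w{j + 1}"] = draws.w[c, d, j]
            row["tau_u"] = draws.tau_u[c, d]
            row["tau_v"] = draws.tau_v[c, d]
            row["tau_beta"] = draws.tau_beta[c, d]
            rows.append(row)
    return pd.DataFrame(rows)
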