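"""CSV/GeoJSON readers and writers, config loading, and run manifests.

CSV dialect: comma-separated, UTF-8, header required, "." decimal, ISO-8601
dates, empty fields meaning missing. Files written by this package carry a
leading comment line ``# ecolattice seed=<seed> config_hash=<hash>`` so every
output is traceable to the run that produced it; readers skip ``#`` lines.
Coordinates are projected metres (single-UTM-zone convention, e.g.
ETRS89/UTM 31N); all distances are Euclidean.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import design as design_mod
from .errors import ConfigError, RecodeError, ValidationError
from .spde import MaternSpec, PCPriorSpec

__all__ = [
    "read_stations",
    "write_stations",
    "read_cells",
    "write_cells",
    "load_config",
    "config_hash",
    "write_manifest",
    "generator_config_from_dict",
    "model_spec_from_dict",
]

STATION_COLUMNS = ["station_id", "x", "y", "date", "tmax_c", "tmin_c"]
CELL_REQUIRED = [
    "cell_id", "x", "y", "slope", "aspect", "hillshade", "elevation",
    "dist_urban", "dist_road", "dist_rail", "landuse8",
]


def _header_comment(seed=None, config_hash_=None) -> str | None:
    parts = ["# ecolattice"]
    if seed is not None:
        parts.append(f"seed={seed}")
    if config_hash_ is not None:
        parts.append(f"config_hash={config_hash_}")
    return " ".join(parts) if len(parts) > 1 else None


def _write_csv(df: pd.DataFrame, path, seed=None, config_hash_=None) -> None:
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        header = _header_comment(seed, config_hash_)
        if header:
            fh.write(header + "\n")
        df.to_csv(fh, index=False)


def _leading_comments(path) -> int:
    n = 0
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if line.startswith("#"):
                n += 1
            else:
                break
    return n


def read_stations(path) -> pd.DataFrame:
    """Read and validate a station series CSV.

    Raises :class:`ValidationError` naming the physical line for malformed
    dates or non-numeric temperatures, and for duplicate (station, date)
    rows; warns (with a count) when tmin > tmax.
    """
    path = Path(path)
    offset = _leading_comments(path) + 2  # comments + header + 1-based
    df = pd.read_csv(path, comment="#", dtype=str)
    missing = [c for c in STATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")
    dates = pd.to_datetime(df["date"], format="%Y-%m-%d", errors="coerce")
    if dates.isna().any():
        line = int(np.flatnonzero(dates.isna())[0]) + offset
        raise ValidationError(
            f"{path}:{line}: unparseable date {df['date'].iloc[line - offset]!r}"
        )
    out = pd.DataFrame({"station_id": df["station_id"], "date": dates})
    for col in ("x", "y", "tmax_c", "tmin_c"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() & df[col].notna() & (df[col].str.strip() != "")
        if bad.any():
            line = int(np.flatnonzero(bad)[0]) + offset
            raise ValidationError(
                f"{path}:{line}: non-numeric {col} value {df[col].iloc[line - offset]!r}"
            )
        out[col] = vals
    dup = out.duplicated(subset=["station_id", "date"])
    if dup.any():
        line = int(np.flatnonzero(dup)[0]) + offset
        raise ValidationError(f"{path}:{line}: duplicate (station_id, date) row")
    both = out["tmax_c"].notna() & out["tmin_c"].notna()
    n_inverted = int((out.loc[both, "tmin_c"] > out.loc[both, "tmax_c"]).sum())
    if n_inverted:
        warnings.warn(
            f"{path}: {n_inverted} rows with tmin_c > tmax_c", stacklevel=2
        )
    return out[STATION_COLUMNS]


def write_stations(df: pd.DataFrame, path, seed=None, config_hash_=None) -> None:
    out = df.copy()
    out["date"] = pd.to_datetime(out["date"]).dt.strftime("%Y-%m-%d")
    _write_csv(out[STATION_COLUMNS], path, seed, config_hash_)


def read_cells(path, geojson_path=None) -> pd.DataFrame:
    """Read and validate a lattice cell CSV, optionally joining GeoJSON geometry.

    ``species_count`` (if present) must be a non-negative integer;
    ``landuse8`` labels must belong to the 8-class vocabulary; aspect and
    hillshade must lie in [0, 360). GeoJSON features are matched on
    ``cell_id`` and must cover exactly the same cells.
    """
    path = Path(path)
    df = pd.read_csv(path, comment="#")
    missing = [c for c in CELL_REQUIRED if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")
    if "species_count" in df.columns:
        counts = df["species_count"]
        if counts.isna().any() or (counts < 0).any() or (counts != counts.round()).any():
            bad = df.loc[counts.isna() | (counts < 0) | (counts != counts.round()), "cell_id"]
            raise ValidationError(
                f"{path}: invalid species_count for cells {list(bad.head(5))}"
            )
        df["species_count"] = counts.astype(int)
    unknown = set(df["landuse8"]) - set(design_mod.LANDUSE8)
    if unknown:
        raise RecodeError(f"{path}: unknown land-use labels {sorted(unknown)}")
    for col in ("aspect", "hillshade"):
        out_of_range = df.loc[(df[col] < 0) | (df[col] >= 360), "cell_id"]
        if len(out_of_range):
            raise ValidationError(
                f"{path}: {col} outside [0, 360) for cells {list(out_of_range.head(5))}"
            )
    neg = df.loc[(df[["dist_urban", "dist_road", "dist_rail", "elevation", "slope"]] < 0).any(axis=1), "cell_id"]
    if len(neg):
        raise ValidationError(f"{path}: negative covariates for cells {list(neg.head(5))}")
    if geojson_path is not None:
        with open(geojson_path, encoding="utf-8") as fh:
            gj = json.load(fh)
        feats = gj.get("features", [])
        gj_ids = {f.get("properties", {}).get("cell_id") for f in feats}
        csv_ids = set(df["cell_id"])
        if gj_ids != csv_ids:
            raise ValidationError(
                f"GeoJSON/CSV cell_id mismatch: only in GeoJSON "
                f"{sorted(gj_ids - csv_ids)[:5]}, only in CSV "
                f"{sorted(csv_ids - gj_ids)[:5]}"
            )
        df.attrs["geometry"] = {
            f["properties"]["cell_id"]: f["geometry"] for f in feats
        }
    return df


def write_cells(df: pd.DataFrame, path, seed=None, config_hash_=None) -> None:
    _write_csv(df, path, seed, config_hash_)


def load_config(path) -> dict:
    with open(path, encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ConfigError(f"{path}: config must be a YAML mapping")
    return cfg


def config_hash(cfg: dict) -> str:
    """Stable short hash of a config mapping (sorted-key JSON, sha256)."""
    blob = json.dumps(cfg, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def write_manifest(path, stage: str, seed, cfg_hash: str, **extra) -> None:
    """Plain-text run manifest: seed, config hash, versions, record counts."""
    from . import __version__

    lines = {
        "stage": stage,
        "seed": seed,
        "config_hash": cfg_hash,
        "ecolattice_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
    }
    lines.update(extra)
    with open(path, "w", encoding="utf-8") as fh:
        for k, v in lines.items():
            fh.write(f"{k}={v}\n")


def _matern_from_dict(d: dict) -> MaternSpec:
    return MaternSpec(range_m=float(d["range_m"]), sd=float(d["sd"]))


def generator_config_from_dict(d: dict, seed=None):
    """Build a :class:`~ecolattice.simulate.GeneratorConfig` from a mapping."""
    from .simulate import GeneratorConfig
    import datetime as dt

    kwargs = dict(d)
    for key in ("matern_temp", "matern_count"):
        if key in kwargs:
            kwargs[key] = _matern_from_dict(kwargs[key])
    for key in ("date_start", "date_end"):
        if key in kwargs and isinstance(kwargs[key], str):
            kwargs[key] = dt.date.fromisoformat(kwargs[key])
    if seed is not None:
        kwargs["seed"] = int(seed)
    return GeneratorConfig(**kwargs)


def model_spec_from_dict(d: dict, seed=None):
    """Build a :class:`~ecolattice.model.ModelSpec` from a mapping."""
    from .model import ModelSpec

    kwargs = dict(d)
    if "field" in kwargs:
        kwargs["field"] = _matern_from_dict(kwargs["field"])
    if "pc_field" in kwargs and kwargs["pc_field"] is not None:
        kwargs["pc_field"] = PCPriorSpec(**kwargs["pc_field"])
    if "pc_iid" in kwargs:
        kwargs["pc_iid"] = tuple(kwargs["pc_iid"])
    if seed is not None:
        kwargs["seed"] = int(seed)
    return ModelSpec(**kwargs)
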