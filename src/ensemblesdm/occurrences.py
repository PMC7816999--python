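"""Occurrence cleaning and the buffered calibration region.

Presence-only compilations mix field GPS points, database downloads and
geocoded literature sites; records with missing or malformed coordinates
and exact duplicate locations are dropped before modelling.  Predictors
are then masked to a buffer around the presences (optionally intersected
with a biogeographic domain polygon) so the models are calibrated only
in environments near where the species was observed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .geo import GridSpec, RegionLayer, rasterize_regions

logger = logging.getLogger(__name__)

_LON_ALIASES = ("lon", "longitude", "long", "x", "decimallongitude")
_LAT_ALIASES = ("lat", "latitude", "y", "decimallatitude")


@dataclass
class OccurrenceSet:
    """Cleaned presence coordinates (degrees) with free-text source tags."""

    lon: np.ndarray
    lat: np.ndarray
    source: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.lon = np.asarray(self.lon, dtype=float)
        self.lat = np.asarray(self.lat, dtype=float)
        if self.source is None:
            self.source = np.repeat("unknown", self.lon.size)
        self.source = np.asarray(self.source, dtype=object)
        if not (self.lon.size == self.lat.size == self.source.size):
            raise ValueError("lon, lat and source must have equal length")

    def __len__(self) -> int:
        return self.lon.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"lon": self.lon, "lat": self.lat, "source": self.source})

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "OccurrenceSet":
        return cls(
            df["lon"].to_numpy(float),
            df["lat"].to_numpy(float),
            df.get("source", pd.Series(["unknown"] * len(df))).to_numpy(object),
        )


@dataclass
class CalibrationRegion:
    """Boolean cell mask plus the provenance that produced it."""

    grid: GridSpec
    mask: np.ndarray
    buffer_deg: float
    domain_label: str | None = None

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.grid.shape:
            raise ValueError("mask shape does not match grid")

    @property
    def n_cells(self) -> int:
        return int(self.mask.sum())


def _find_column(columns, aliases) -> str | None:
    lowered = {c.lower().strip(): c for c in columns}
    for a in aliases:
        if a in lowered:
            return lowered[a]
    return None


def clean_occurrences(
    raw: pd.DataFrame,
    exclude_sources: list[str] | None = None,
) -> OccurrenceSet:
    """Drop unusable rows and collapse exact duplicate coordinates.

    Removal rules, applied in order: rows whose source tag is on the
    exclusion list (non-natural locations such as trade or captive
    sites); rows with missing or unparseable coordinates; rows with
    out-of-range coordinates; exact (lon, lat) duplicates (first kept).
    Retention counts are logged.
    """
    lon_col = _find_column(raw.columns, _LON_ALIASES)
    lat_col = _find_column(raw.columns, _LAT_ALIASES)
    if lon_col is None or lat_col is None:
        raise ValueError("input table has no recognisable longitude/latitude columns")
    src_col = _find_column(raw.columns, ("source", "src", "origin"))

    df = pd.DataFrame(
        {
            "lon": pd.to_numeric(raw[lon_col], errors="coerce"),
            "lat": pd.to_numeric(raw[lat_col], errors="coerce"),
            "source": raw[src_col].astype(str) if src_col else "unknown",
        }
    )
    n0 = len(df)
    if exclude_sources:
        df = df[~df["source"].isin(set(exclude_sources))]
    n_source = len(df)
    df = df.dropna(subset=["lon", "lat"])
    df = df[(df["lon"].abs() <= 180) & (df["lat"].abs() <= 90)]
    n_coord = len(df)
    df = df.drop_duplicates(subset=["lon", "lat"], keep="first")
    logger.info(
        "occurrence cleaning: %d raw, %d after source filter, %d with valid "
        "coordinates, %d unique locations",
        n0, n_source, n_coord, len(df),
    )
    return OccurrenceSet.from_frame(df.reset_index(drop=True))


def build_calibration_mask(
    occ: OccurrenceSet,
    grid: GridSpec,
    buffer_deg: float = 1.0,
    domain: RegionLayer | None = None,
) -> CalibrationRegion:
    """Cells whose centers lie within ``buffer_deg`` (Euclidean degrees)
    of at least one occurrence, optionally intersected with a domain polygon."""
    if buffer_deg <= 0:
        raise ValueError("buffer_deg must be positive")
    if len(occ) == 0:
        raise ValueError("no occurrences to buffer")
    lon, lat = grid.center_mesh()
    tree = cKDTree(np.column_stack([occ.lon, occ.lat]))
    d, _ = tree.query(np.column_stack([lon.ravel(), lat.ravel()]), k=1)
    mask = (d <= buffer_deg).reshape(grid.shape)
    label = None
    if domain is not None:
        dom = rasterize_regions(domain, grid) > 0
        mask &= dom
        label = ",".join(domain.labels)
    if not mask.any():
        raise ValueError("calibration mask is empty: no occurrence on or near the grid")
    return CalibrationRegion(grid, mask, buffer_deg, label)
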