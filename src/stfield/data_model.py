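"""Core data structures for unbalanced multi-tier air-monitoring data.

The observable is a sparse site-by-period matrix of log 2-week average
concentrations.  Periods live on a fixed 14-day grid anchored on a weekday
(Wednesday for the classic deployment), and sites carry planar km
coordinates plus a named geographic-covariate vector.
"""

from __future__ import annotations

import enum
import json
import math
from dataclasses import dataclass, field
from datetime import date, timedelta
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

PERIOD_DAYS = 14
EARTH_RADIUS_KM = 6371.0


class SiteType(str, enum.Enum):
    """Monitoring tiers: regulatory long-series, study fixed, rotating home,
    clustered snapshot, and the reference/distributed tiers of auxiliary
    community campaigns (treated like fixed/home respectively)."""

    AQS = "aqs"
    FIXED = "fixed"
    HOME = "home"
    SNAPSHOT = "snapshot"
    REFERENCE = "reference"
    DISTRIBUTED = "distributed"


#: site types providing long time series, used for trend estimation and as
#: PLS regression outcomes
LONG_SERIES_TYPES = (SiteType.AQS, SiteType.FIXED, SiteType.REFERENCE)

_WEEKDAYS = {
    "monday": 0, "tuesday": 1, "wednesday": 2, "thursday": 3,
    "friday": 4, "saturday": 5, "sunday": 6,
}


@dataclass
class Site:
    site_id: str
    site_type: SiteType
    x_km: float
    y_km: float
    cluster_id: str | None = None
    covariates: dict[str, float] = field(default_factory=dict)
    lon: float | None = None
    lat: float | None = None

    def __post_init__(self) -> None:
        self.site_type = SiteType(self.site_type)
        if not (math.isfinite(self.x_km) and math.isfinite(self.y_km)):
            raise ValueError(f"site {self.site_id}: non-finite coordinates")
        if (self.cluster_id is not None) != (self.site_type == SiteType.SNAPSHOT):
            raise ValueError(
                f"site {self.site_id}: cluster_id is required for snapshot "
                "sites and disallowed otherwise"
            )


def project_lonlat(
    lon: np.ndarray | float, lat: np.ndarray | float, center: tuple[float, float]
) -> tuple[np.ndarray, np.ndarray]:
    """Equirectangular projection to km about a region centroid.

    Adequate at metropolitan scale (~75 km) where the distortion of the
    cosine-latitude approximation is far below monitor-siting uncertainty.
    """
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    lon0, lat0 = center
    x = np.radians(lon - lon0) * math.cos(math.radians(lat0)) * EARTH_RADIUS_KM
    y = np.radians(lat - lat0) * EARTH_RADIUS_KM
    return x, y


@dataclass(frozen=True)
class TimeAxis:
    """Ordered 14-day periods, each starting on the anchor weekday.

    Period ``t`` covers the half-open interval ``[start_t, start_t + 14)``.
    """

    period_starts: tuple[date, ...]

    def __post_init__(self) -> None:
        starts = self.period_starts
        if len(starts) < 1:
            raise ValueError("time axis needs at least one period")
        for a, b in zip(starts, starts[1:]):
            if (b - a).days != PERIOD_DAYS:
                raise ValueError("period starts must be spaced exactly 14 days")

    def __len__(self) -> int:
        return len(self.period_starts)

    @property
    def n_periods(self) -> int:
        return len(self.period_starts)

    @property
    def span_years(self) -> float:
        return len(self.period_starts) * PERIOD_DAYS / 365.25

    def index_of(self, timestamp: date) -> int | None:
        """Period index containing ``timestamp``, or None if off-axis."""
        first = self.period_starts[0]
        delta = (timestamp - first).days
        if delta < 0:
            return None
        t = delta // PERIOD_DAYS
        if t >= len(self.period_starts):
            return None
        return t

    def years_elapsed(self) -> np.ndarray:
        """Fractional years since the first period start, per period."""
        first = self.period_starts[0]
        return np.array(
            [(s - first).days / 365.25 for s in self.period_starts]
        )


def build_time_axis(
    start_date: date, end_date: date, anchor_weekday: str = "wednesday"
) -> TimeAxis:
    """14-day grid whose first period starts on the first anchor weekday on
    or after ``start_date``; the last period must end by ``end_date``."""
    if start_date >= end_date:
        raise ValueError("start_date must precede end_date")
    anchor = _WEEKDAYS[anchor_weekday.lower()]
    first = start_date + timedelta(days=(anchor - start_date.weekday()) % 7)
    starts = []
    s = first
    while s <= end_date - timedelta(days=PERIOD_DAYS):
        starts.append(s)
        s = s + timedelta(days=PERIOD_DAYS)
    if not starts:
        raise ValueError("date span shorter than one 14-day period")
    return TimeAxis(tuple(starts))


def assign_period(timestamp: date, axis: TimeAxis) -> int | None:
    """Map a timestamp to its 2-week period index (half-open intervals)."""
    return axis.index_of(timestamp)


def realign_offgrid_sample(sample_start: date, axis: TimeAxis) -> int:
    """Map a 14-day sample whose start is off-grid by exactly one week onto
    the grid, treating it as if taken one week earlier or later.

    Only +-7-day offsets (or exact alignment) are sanctioned; anything else
    is an error rather than silently snapped.
    """
    first = axis.period_starts[0]
    offset = (sample_start - first).days % PERIOD_DAYS
    if offset == 0:
        t = axis.index_of(sample_start)
        if t is None:
            raise ValueError(f"sample start {sample_start} outside the axis")
        return t
    if offset != 7:
        raise ValueError(
            f"sample start {sample_start} is off-grid by {offset} days; "
            "only 1-week shifts are allowed"
        )
    # shift to the nearer grid start (7 days earlier), falling back to 7 later
    for shift in (-7, 7):
        t = axis.index_of(sample_start + timedelta(days=shift))
        if t is not None:
            return t
    raise ValueError(f"sample start {sample_start} outside the axis")


@dataclass
class STDataset:
    """Sparse, unbalanced site-by-period observations.

    ``obs`` has columns ``site_id``, ``t`` (period index) and ``value``; at
    most one value per cell.  ``scale`` records whether values are natural
    logs or on the original concentration scale; ``units`` is a free-text
    note about the original units.
    """

    sites: list[Site]
    axis: TimeAxis
    obs: pd.DataFrame
    scale: str = "original"  # "original" | "log"
    units: str = ""

    def __post_init__(self) -> None:
        ids = [s.site_id for s in self.sites]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate site_id in dataset")
        self.obs = self.obs.reset_index(drop=True)
        if self.obs.duplicated(subset=["site_id", "t"]).any():
            raise ValueError("duplicate (site_id, period) observation")
        if not np.isfinite(self.obs["value"].to_numpy(float)).all():
            raise ValueError("non-finite observation values")
        known = set(ids)
        bad = set(self.obs["site_id"]) - known
        if bad:
            raise ValueError(f"observations reference unknown sites: {sorted(bad)[:5]}")
        t = self.obs["t"].to_numpy()
        if len(t) and (t.min() < 0 or t.max() >= len(self.axis)):
            raise ValueError("observation period index outside axis")
        names = None
        for s in self.sites:
            cur = tuple(sorted(s.covariates))
            if names is None:
                names = cur
            elif cur != names:
                raise ValueError("covariate names differ across sites")

    # -- views -------------------------------------------------------------
    @property
    def site_ids(self) -> list[str]:
        return [s.site_id for s in self.sites]

    def site(self, site_id: str) -> Site:
        for s in self.sites:
            if s.site_id == site_id:
                return s
        raise KeyError(site_id)

    def sites_of_type(self, *types: SiteType) -> list[Site]:
        types = tuple(SiteType(t) for t in types)
        return [s for s in self.sites if s.site_type in types]

    def coords(self, site_ids: Sequence[str] | None = None) -> np.ndarray:
        ids = site_ids if site_ids is not None else self.site_ids
        by_id = {s.site_id: s for s in self.sites}
        return np.array([[by_id[i].x_km, by_id[i].y_km] for i in ids])

    def to_matrix(self, site_ids: Sequence[str] | None = None) -> pd.DataFrame:
        """Dense T-by-n frame (NaN where unobserved), columns in site order."""
        ids = list(site_ids) if site_ids is not None else self.site_ids
        mat = pd.DataFrame(
            np.nan, index=range(len(self.axis)), columns=pd.Index(ids, name="site_id")
        )
        sub = self.obs[self.obs["site_id"].isin(ids)]
        for sid, t, v in sub[["site_id", "t", "value"]].itertuples(index=False):
            mat.at[t, sid] = v
        return mat

    def subset_sites(self, site_ids: Iterable[str]) -> "STDataset":
        keep = set(site_ids)
        sites = [s for s in self.sites if s.site_id in keep]
        obs = self.obs[self.obs["site_id"].isin(keep)].reset_index(drop=True)
        return STDataset(sites, self.axis, obs, scale=self.scale, units=self.units)

    def n_obs_per_site(self) -> pd.Series:
        return self.obs.groupby("site_id").size().reindex(self.site_ids, fill_value=0)


# -- CSV interchange -------------------------------------------------------

def write_dataset(ds: STDataset, out_dir: str | Path) -> None:
    """Write observations.csv / sites.csv / axis.json (round-trip exact)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for s in ds.sites:
        rows.append(
            {
                "site_id": s.site_id,
                "site_type": s.site_type.value,
                "lon": s.lon if s.lon is not None else "",
                "lat": s.lat if s.lat is not None else "",
                "cluster_id": s.cluster_id or "",
                "x_km": repr(float(s.x_km)),
                "y_km": repr(float(s.y_km)),
            }
        )
    pd.DataFrame(rows).to_csv(out / "sites.csv", index=False)
    obs = ds.obs.copy()
    starts = ds.axis.period_starts
    obs["date"] = [starts[t].isoformat() for t in obs["t"]]
    obs["resolution"] = "2week"
    obs["value"] = [repr(float(v)) for v in obs["value"]]
    by_id = {s.site_id: s.site_type.value for s in ds.sites}
    obs["site_type"] = obs["site_id"].map(by_id)
    obs[["site_id", "site_type", "date", "resolution", "value"]].to_csv(
        out / "observations.csv", index=False
    )
    cov_names = sorted(ds.sites[0].covariates) if ds.sites else []
    cov = pd.DataFrame(
        [[s.site_id] + [repr(float(s.covariates[c])) for c in cov_names] for s in ds.sites],
        columns=["site_id"] + cov_names,
    )
    cov.to_csv(out / "covariates.csv", index=False)
    meta = {
        "first_period_start": starts[0].isoformat(),
        "n_periods": len(starts),
        "scale": ds.scale,
        "units": ds.units,
    }
    (out / "axis.json").write_text(json.dumps(meta, indent=2))


def read_dataset(in_dir: str | Path) -> STDataset:
    """Inverse of :func:`write_dataset`."""
    p = Path(in_dir)
    meta = json.loads((p / "axis.json").read_text())
    first = date.fromisoformat(meta["first_period_start"])
    starts = tuple(first + timedelta(days=PERIOD_DAYS * k) for k in range(meta["n_periods"]))
    axis = TimeAxis(starts)
    sites_df = pd.read_csv(p / "sites.csv", dtype={"site_id": str, "cluster_id": str},
                           float_precision="round_trip")
    cov_df = pd.read_csv(p / "covariates.csv", dtype={"site_id": str},
                         float_precision="round_trip").set_index("site_id")
    sites = []
    for row in sites_df.itertuples(index=False):
        cl = getattr(row, "cluster_id", None)
        cl = None if (cl is None or (isinstance(cl, float) and math.isnan(cl)) or cl == "") else str(cl)
        lon = getattr(row, "lon", None)
        lat = getattr(row, "lat", None)
        lon = None if (lon is None or lon == "" or (isinstance(lon, float) and math.isnan(lon))) else float(lon)
        lat = None if (lat is None or lat == "" or (isinstance(lat, float) and math.isnan(lat))) else float(lat)
        covs = {c: float(cov_df.at[row.site_id, c]) for c in cov_df.columns}
        sites.append(
            Site(
                site_id=str(row.site_id),
                site_type=SiteType(row.site_type),
                x_km=float(row.x_km),
                y_km=float(row.y_km),
                cluster_id=cl,
                covariates=covs,
                lon=lon,
                lat=lat,
            )
        )
    obs_df = pd.read_csv(p / "observations.csv", dtype={"site_id": str},
                         float_precision="round_trip")
    t_idx = [axis.index_of(date.fromisoformat(d)) for d in obs_df["date"]]
    if any(t is None for t in t_idx):
        raise ValueError("observation date outside the stored axis")
    obs = pd.DataFrame(
        {"site_id": obs_df["site_id"], "t": t_idx, "value": obs_df["value"].astype(float)}
    )
    return STDataset(sites, axis, obs, scale=meta.get("scale", "original"),
                     units=meta.get("units", ""))


def read_sites_csv(path: str | Path, center: tuple[float, float] | None = None) -> list[Site]:
    """Read a sites.csv with lon/lat columns, projecting to planar km.

    If ``center`` is omitted the centroid of the listed sites is used.
    """
    df = pd.read_csv(path, dtype={"site_id": str, "cluster_id": str})
    if "x_km" in df.columns and "y_km" in df.columns:
        xs, ys = df["x_km"].to_numpy(float), df["y_km"].to_numpy(float)
    else:
        if center is None:
            center = (float(df["lon"].mean()), float(df["lat"].mean()))
        xs, ys = project_lonlat(df["lon"].to_numpy(float), df["lat"].to_numpy(float), center)
    sites = []
    for i, row in enumerate(df.itertuples(index=False)):
        cl = getattr(row, "cluster_id", None)
        cl = None if (cl is None or (isinstance(cl, float) and math.isnan(cl)) or cl == "") else str(cl)
        sites.append(
            Site(
                site_id=str(row.site_id),
                site_type=SiteType(row.site_type),
                x_km=float(xs[i]),
                y_km=float(ys[i]),
                cluster_id=cl,
                lon=float(getattr(row, "lon", math.nan)) if hasattr(row, "lon") else None,
                lat=float(getattr(row, "lat", math.nan)) if hasattr(row, "lat") else None,
            )
        )
    return sites


def attach_covariates(sites: list[Site], cov: pd.DataFrame) -> None:
    """Attach covariate vectors (frame indexed by site_id) to sites in place."""
    if cov.index.name != "site_id":
        cov = cov.set_index("site_id")
    for s in sites:
        if s.site_id not in cov.index:
            raise KeyError(f"no covariates for site {s.site_id}")
        s.covariates = {c: float(cov.at[s.site_id, c]) for c in cov.columns}
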