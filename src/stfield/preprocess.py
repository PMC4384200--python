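"""Data-cleaning rules for one region-pollutant monitoring dataset.

Covers below-detection-limit substitution, aggregation of hourly/daily
records to the 2-week grid, the long-series monitor inclusion rule, the
four geographic-covariate exclusion filters, and the log transform.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date

import numpy as np
import pandas as pd

from .data_model import (
    PERIOD_DAYS,
    Site,
    SiteType,
    STDataset,
    TimeAxis,
    assign_period,
    realign_offgrid_sample,
)

#: default completeness requirement at both aggregation steps (fraction of
#: hours per day / days per period); the conventional regulatory criterion
DEFAULT_COMPLETENESS = 0.75


@dataclass
class FilterReport:
    """Record of exclusions; each item carries the first triggering rule in
    a-d order, with every violated rule kept alongside."""

    excluded_covariates: list[tuple[str, str]] = field(default_factory=list)
    covariate_violations: dict[str, list[str]] = field(default_factory=dict)
    excluded_sites: list[tuple[str, str]] = field(default_factory=list)
    n_below_lod: int = 0
    frac_below_lod: float = 0.0
    n_dropped_offaxis: int = 0

    def to_dict(self) -> dict:
        return {
            "excluded_covariates": [list(x) for x in self.excluded_covariates],
            "covariate_violations": self.covariate_violations,
            "excluded_sites": [list(x) for x in self.excluded_sites],
            "n_below_lod": self.n_below_lod,
            "frac_below_lod": self.frac_below_lod,
            "n_dropped_offaxis": self.n_dropped_offaxis,
        }


def substitute_lod(value: float, lod: float) -> float:
    """Replace a below-detection-limit measurement by LOD/2."""
    if lod < 0:
        raise ValueError("LOD must be nonnegative")
    return lod / 2.0 if value < lod else value


def substitute_lod_series(
    values: np.ndarray, lod: np.ndarray | float, report: FilterReport | None = None
) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    lod = np.broadcast_to(np.asarray(lod, dtype=float), values.shape)
    if np.any(lod[np.isfinite(lod)] < 0):
        raise ValueError("LOD must be nonnegative")
    below = np.isfinite(lod) & (values < lod)
    out = np.where(below, lod / 2.0, values)
    if report is not None:
        report.n_below_lod += int(below.sum())
        report.frac_below_lod = report.n_below_lod / max(len(values), 1)
    return out


def aggregate_to_periods(
    raw: pd.DataFrame,
    axis: TimeAxis,
    sites: list[Site],
    completeness_min: float = DEFAULT_COMPLETENESS,
    report: FilterReport | None = None,
) -> STDataset:
    """Aggregate raw records onto the 2-week grid (original scale).

    ``raw`` columns: site_id, date (ISO or datetime.date), resolution
    ({hourly, daily, 2week}), value, and optionally lod.  Hourly records
    are averaged to days, days to periods; a mean at either step requires
    at least ``completeness_min`` of the nominal count (24 h, 14 d).
    2-week records are assigned directly, with off-grid starts realigned
    by one week where sanctioned.  Incomplete periods are absent, not zero.
    """
    if not 0.0 <= completeness_min <= 1.0:
        raise ValueError("completeness_min must be in [0, 1]")
    raw = raw.copy()
    if report is None:
        report = FilterReport()
    raw["date"] = [d if isinstance(d, date) else date.fromisoformat(str(d)) for d in raw["date"]]
    if "lod" in raw.columns:
        raw["value"] = substitute_lod_series(
            raw["value"].to_numpy(float), raw["lod"].to_numpy(float), report
        )
    bad = set(raw["resolution"]) - {"hourly", "daily", "2week"}
    if bad:
        raise ValueError(f"unknown resolution(s): {sorted(bad)}")

    records: list[tuple[str, int, float]] = []
    for (sid, res), grp in raw.groupby(["site_id", "resolution"], sort=False):
        if res == "2week":
            for d, v in zip(grp["date"], grp["value"]):
                try:
                    t = realign_offgrid_sample(d, axis)
                except ValueError:
                    report.n_dropped_offaxis += 1
                    continue
                records.append((sid, t, float(v)))
            continue
        if res == "hourly":
            daily = grp.groupby("date")["value"].agg(["mean", "count"])
            daily = daily[daily["count"] >= completeness_min * 24]["mean"]
        else:  # daily
            daily = grp.groupby("date")["value"].mean()
        t_idx = np.array([assign_period(d, axis) for d in daily.index], dtype=object)
        keep = t_idx != None  # noqa: E711
        report.n_dropped_offaxis += int((~keep).sum())
        df = pd.DataFrame({"t": t_idx[keep].astype(int), "v": daily.to_numpy(float)[keep]})
        per = df.groupby("t")["v"].agg(["mean", "count"])
        per = per[per["count"] >= completeness_min * PERIOD_DAYS]
        for t, v in per["mean"].items():
            records.append((sid, int(t), float(v)))

    obs = pd.DataFrame(records, columns=["site_id", "t", "value"])
    obs = obs.groupby(["site_id", "t"], as_index=False)["value"].mean()
    used = set(obs["site_id"])
    return STDataset([s for s in sites if s.site_id in used], axis, obs,
                     scale="original")


def filter_monitors(
    data: STDataset,
    min_years: float = 2.0,
    min_quarter_frac: float = 0.10,
    report: FilterReport | None = None,
) -> tuple[STDataset, FilterReport]:
    """Drop long-series regulatory monitors with short or irregular records.

    An AQS site is removed if its observed span is under ``min_years`` or if
    its temporal coverage is irregular: some calendar quarter holds fewer
    than ``min_quarter_frac`` of its observations (a seasonal-only monitor
    fails this).  Study-specific home/snapshot/fixed sites are never removed.
    """
    if len(data.obs) == 0:
        raise ValueError("empty dataset")
    if report is None:
        report = FilterReport()
    starts = data.axis.period_starts
    drop: list[str] = []
    for s in data.sites_of_type(SiteType.AQS):
        ts = data.obs.loc[data.obs["site_id"] == s.site_id, "t"].to_numpy(int)
        if len(ts) == 0:
            drop.append(s.site_id)
            report.excluded_sites.append((s.site_id, "no_observations"))
            continue
        span_years = (ts.max() - ts.min() + 1) * PERIOD_DAYS / 365.25
        if span_years < min_years:
            drop.append(s.site_id)
            report.excluded_sites.append((s.site_id, "short_record"))
            continue
        quarters = np.array([(starts[t].month - 1) // 3 for t in ts])
        counts = np.bincount(quarters, minlength=4)
        if counts.min() < min_quarter_frac * len(ts):
            drop.append(s.site_id)
            report.excluded_sites.append((s.site_id, "irregular_coverage"))
    keep = [i for i in data.site_ids if i not in set(drop)]
    return data.subset_sites(keep), report


def filter_covariates(
    cov: pd.DataFrame,
    monitor_ids: set[str],
    participant_ids: set[str] | None = None,
    landuse_names: set[str] | None = None,
    modal_frac: float = 0.80,
    outlier_sd: float = 5.0,
    outlier_frac: float = 0.02,
    extrapolation_ratio: float = 5.0,
    landuse_max: float = 0.10,
    report: FilterReport | None = None,
) -> FilterReport:
    """Apply the four covariate exclusion rules.

    a) the modal value occurs at more than 80% of monitoring sites;
    b) more than 2% of monitoring-site values lie over 5 SDs from the mean;
    c) the SD over participant locations exceeds 5x the SD over monitors
       (extrapolation risk);
    d) a land-use fraction whose maximum over monitors is at most 10%.

    The excluded set is the union of rule hits; each covariate's primary
    rule is the first violated in a-d order.
    """
    if cov.index.name != "site_id":
        cov = cov.set_index("site_id")
    if not monitor_ids:
        raise ValueError("empty monitor set")
    if report is None:
        report = FilterReport()
    landuse_names = landuse_names or set()
    participant_ids = participant_ids or set()
    mon = cov.loc[sorted(monitor_ids & set(cov.index))]
    par = cov.loc[sorted(participant_ids & set(cov.index))]
    for name in cov.columns:
        x = mon[name].to_numpy(float)
        hits: list[str] = []
        _, counts = np.unique(x, return_counts=True)
        if counts.max() > modal_frac * len(x):
            hits.append("a_constant")
        sd = x.std(ddof=1) if len(x) > 1 else 0.0
        if sd > 0 and np.mean(np.abs(x - x.mean()) > outlier_sd * sd) > outlier_frac:
            hits.append("b_outlier")
        if len(par) > 1 and sd >= 0:
            psd = par[name].to_numpy(float).std(ddof=1)
            if psd > extrapolation_ratio * sd:
                hits.append("c_extrapolation")
        if name in landuse_names and x.max() <= landuse_max:
            hits.append("d_landuse_max")
        if hits:
            report.excluded_covariates.append((name, hits[0]))
            report.covariate_violations[name] = hits
    return report


def apply_covariate_filter(cov: pd.DataFrame, report: FilterReport) -> pd.DataFrame:
    """Drop the covariate columns flagged in ``report``."""
    drop = [name for name, _ in report.excluded_covariates]
    return cov.drop(columns=[c for c in drop if c in cov.columns])


def log_transform(data: STDataset) -> STDataset:
    """Elementwise natural log of a positive, original-scale dataset."""
    if data.scale == "log":
        raise ValueError("dataset is already on the log scale")
    vals = data.obs["value"].to_numpy(float)
    if np.any(vals <= 0):
        i = int(np.argmax(vals <= 0))
        row = data.obs.iloc[i]
        raise ValueError(
            f"nonpositive concentration at site {row['site_id']}, period "
            f"{row['t']}: {row['value']} (was LOD substitution applied?)"
        )
    obs = data.obs.copy()
    obs["value"] = np.log(vals)
    return STDataset(data.sites, data.axis, obs, scale="log", units=data.units)
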