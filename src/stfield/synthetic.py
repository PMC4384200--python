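"""Synthetic monitoring campaigns with the multi-tier unbalanced design.

Generates a region's worth of monitoring data from the generative model
with known parameters: long regulatory (AQS-like) series with missing
stretches, ~4-year fixed-site series, rotating home sites visited 1-3
times in different seasons, and clustered snapshot sites observed in
three seasonal periods (winter, summer, and spring or fall).  Geographic
covariates are smooth spatial Gaussian fields (plus skewed distance-like
transforms and pure-noise columns), so the whole pipeline — trend
estimation, PLS, ML fitting, kriging, cross-validation — can be
exercised and checked against ground truth without any external data.

The default scenario is sized like a mid-sized metropolitan deployment
(29 regulatory monitors, 5 fixed, 86 home, 26 snapshot clusters of 4)
over a 13.25-year study window.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .data_model import (
    Site,
    SiteType,
    STDataset,
    TimeAxis,
    build_time_axis,
)
from .st_model import CovarianceSpec, ResidualSpec, simulate_field


@dataclass
class TrueParams:
    """Generative parameters on the log-concentration scale."""

    beta_specs: list[CovarianceSpec] = field(
        default_factory=lambda: [
            CovarianceSpec("exponential", phi=10.0, sigma2=0.03, tau2=0.005),
            CovarianceSpec("independent", tau2=0.005),
            CovarianceSpec("independent", tau2=0.003),
        ]
    )
    residual: ResidualSpec = field(
        default_factory=lambda: ResidualSpec(
            sigma2=0.015, phi=20.0, tau2=0.01, lambda2=0.03
        )
    )
    #: long-term mean level (log scale; exp(2.56) ~ 13 ug/m3) and the
    #: covariate weights of each field's mean surface
    intercepts: tuple[float, ...] = (2.56, 0.30, 0.15)
    covariate_weight: tuple[float, ...] = (0.15, 0.05, 0.03)


@dataclass
class ScenarioConfig:
    n_aqs: int = 29
    n_fixed: int = 5
    n_home: int = 86
    n_snapshot_clusters: int = 26
    cluster_size: int = 4
    n_holdout: int = 25
    region_size_km: float = 75.0
    start: date = date(1999, 1, 6)
    years: float = 13.25
    m_true: int = 1
    n_informative: int = 5
    n_distance_like: int = 2
    n_noise: int = 4
    cov_range_km: float = 15.0
    aqs_gap_rate: float = 0.10
    fixed_years: float = 4.0
    home_visits: tuple[int, int] = (1, 3)
    snapshot_seasons: int = 3
    lod_quantile: float | None = None
    true_params: TrueParams = field(default_factory=TrueParams)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_aqs + self.n_fixed < 2 and self.m_true > 0:
            raise ValueError("need at least 2 long-series sites to estimate trends")
        if self.m_true not in (1, 2):
            raise ValueError("m_true must be 1 or 2")


def _gp_draw(D: np.ndarray, range_km: float, rng: np.random.Generator) -> np.ndarray:
    C = np.exp(-D / range_km) + 1e-8 * np.eye(len(D))
    return np.linalg.cholesky(C) @ rng.standard_normal(len(D))


def true_trends(axis: TimeAxis, m: int) -> np.ndarray:
    """Deterministic generating trends: annual cycle with a slow decline,
    plus a semiannual cycle for m = 2; zero mean / unit RMS."""
    yr = axis.years_elapsed()
    cols = [np.cos(2 * np.pi * yr) + 0.3 * (yr - yr.mean()) / max(yr.max(), 1.0)]
    if m == 2:
        cols.append(np.sin(4 * np.pi * yr))
    F = np.column_stack(cols[:m])
    F = F - F.mean(axis=0)
    return F / np.sqrt((F**2).mean(axis=0))


def generate_covariates(
    config: ScenarioConfig, coords: np.ndarray, rng: np.random.Generator
) -> tuple[pd.DataFrame, np.ndarray]:
    """Covariate table for the given locations plus the informative block.

    Informative covariates are smooth unit-variance spatial fields;
    distance-like covariates are lognormal transforms of such fields
    (right-skewed, as road/coast distances are); noise covariates are
    i.i.d. standard normal.  Returns (table, informative matrix).
    """
    D = cdist(coords, coords)
    n = len(coords)
    cols: dict[str, np.ndarray] = {}
    Z = np.zeros((n, max(config.n_informative, 1)))
    for j in range(config.n_informative):
        Z[:, j] = _gp_draw(D, config.cov_range_km, rng)
        cols[f"field_{j}"] = Z[:, j]
    for j in range(config.n_distance_like):
        cols[f"log_dist_{j}"] = np.exp(0.8 * _gp_draw(D, config.cov_range_km, rng))
    for j in range(config.n_noise):
        cols[f"noise_{j}"] = rng.standard_normal(n)
    return pd.DataFrame(cols), Z[:, : config.n_informative]


def _mean_fields(
    config: ScenarioConfig, Z: np.ndarray, n_loc: int, rng: np.random.Generator
) -> np.ndarray:
    tp = config.true_params
    m1 = config.m_true + 1
    out = np.zeros((m1, n_loc))
    for i in range(m1):
        icpt = tp.intercepts[i] if i < len(tp.intercepts) else 0.1
        wscale = tp.covariate_weight[i] if i < len(tp.covariate_weight) else 0.05
        out[i] = icpt
        if Z.shape[1] > 0:
            w = wscale * rng.normal(1.0, 0.3, size=Z.shape[1]) * np.sign(
                rng.standard_normal(Z.shape[1])
            )
            out[i] += Z @ w
    return out


def _quarter(axis: TimeAxis, t: int) -> int:
    return (axis.period_starts[t].month - 1) // 3


def _schedule(
    config: ScenarioConfig,
    axis: TimeAxis,
    sites: list[Site],
    rng: np.random.Generator,
) -> list[tuple[int, int]]:
    """Observation cells (site_index, period) for the unbalanced design."""
    T = len(axis)
    campaign_len = min(int(round(config.fixed_years * 365.25 / 14)), T)
    c0 = max((T - campaign_len) // 2, 0)
    campaign = np.arange(c0, c0 + campaign_len)
    by_quarter: dict[int, list[int]] = {}
    for t in campaign:
        by_quarter.setdefault(_quarter(axis, int(t)), []).append(int(t))

    pattern: list[tuple[int, int]] = []
    cluster_periods: dict[str, list[int]] = {}
    for i, s in enumerate(sites):
        if s.site_type == SiteType.AQS:
            keep = np.ones(T, bool)
            # missing stretches totalling ~gap_rate of the record
            n_gap = int(round(config.aqs_gap_rate * T))
            while n_gap > 0:
                g = int(min(rng.integers(2, 14), n_gap))
                start = int(rng.integers(0, T - g))
                keep[start : start + g] = False
                n_gap -= g
            pattern += [(i, int(t)) for t in np.where(keep)[0]]
        elif s.site_type in (SiteType.FIXED, SiteType.REFERENCE):
            pattern += [(i, int(t)) for t in campaign]
        elif s.site_type in (SiteType.HOME, SiteType.DISTRIBUTED):
            lo, hi = config.home_visits
            n_visits = int(rng.integers(lo, hi + 1))
            quarters = rng.permutation(sorted(by_quarter))[:n_visits]
            pattern += [
                (i, int(rng.choice(by_quarter[q]))) for q in quarters
            ]
        elif s.site_type == SiteType.SNAPSHOT:
            cid = s.cluster_id
            if cid not in cluster_periods:
                # winter, summer, and one of spring/fall; all cluster
                # members share the same three periods
                qs = [0, 2, int(rng.choice([1, 3]))][: config.snapshot_seasons]
                cluster_periods[cid] = [
                    int(rng.choice(by_quarter[q])) for q in qs if q in by_quarter
                ]
            pattern += [(i, t) for t in cluster_periods[cid]]
    return pattern


def generate_campaign(config: ScenarioConfig) -> tuple[STDataset, dict]:
    """Generate one region's monitoring campaign plus a truth bundle.

    Returns a log-scale dataset of monitored cells and a dict with the
    generating trends, coefficient-field draws, mean surfaces, covariate
    table (monitored sites and held-out locations), and realized
    long-term averages at the held-out locations.
    """
    rng = np.random.default_rng(config.seed)
    end_days = int(round(config.years * 365.25))
    axis = build_time_axis(
        config.start, config.start + pd.Timedelta(days=end_days).to_pytimedelta()
    )
    T = len(axis)

    # site locations
    L = config.region_size_km
    sites: list[Site] = []
    for j in range(config.n_aqs):
        x, y = rng.uniform(0, L, 2)
        sites.append(Site(f"aqs_{j:03d}", SiteType.AQS, x, y))
    for j in range(config.n_fixed):
        x, y = rng.uniform(0, L, 2)
        sites.append(Site(f"fix_{j:02d}", SiteType.FIXED, x, y))
    for j in range(config.n_home):
        x, y = rng.uniform(0, L, 2)
        sites.append(Site(f"home_{j:03d}", SiteType.HOME, x, y))
    for c in range(config.n_snapshot_clusters):
        cx, cy = rng.uniform(0, L, 2)
        for j in range(config.cluster_size):
            x = float(np.clip(cx + rng.normal(0, 0.5), 0, L))
            y = float(np.clip(cy + rng.normal(0, 0.5), 0, L))
            sites.append(
                Site(f"snap_{c:02d}_{j}", SiteType.SNAPSHOT, x, y,
                     cluster_id=f"cl_{c:02d}")
            )
    holdout_coords = rng.uniform(0, L, (config.n_holdout, 2))
    holdout_ids = [f"hold_{j:03d}" for j in range(config.n_holdout)]

    all_coords = np.vstack([[(s.x_km, s.y_km) for s in sites], holdout_coords])
    n_sites = len(sites)

    cov_table, Z = generate_covariates(config, all_coords, rng)
    cov_table.index = pd.Index([s.site_id for s in sites] + holdout_ids,
                               name="site_id")
    for i, s in enumerate(sites):
        s.covariates = {c: float(cov_table.iloc[i][c]) for c in cov_table.columns}

    mean_fields = _mean_fields(config, Z, len(all_coords), rng)
    Ftrue = np.column_stack([np.ones(T), true_trends(axis, config.m_true)])

    pattern = _schedule(config, axis, sites, rng)
    holdout_cells = [
        (n_sites + j, t) for j in range(config.n_holdout) for t in range(T)
    ]
    tp = config.true_params
    values, truth_draw = simulate_field(
        all_coords,
        Ftrue,
        mean_fields,
        tp.beta_specs[: config.m_true + 1],
        tp.residual,
        pattern + holdout_cells,
        rng,
    )
    obs_vals = values[: len(pattern)]
    hold_vals = values[len(pattern):].reshape(config.n_holdout, T)

    n_below = 0
    if config.lod_quantile is not None:
        conc = np.exp(obs_vals)
        lod = float(np.quantile(conc, config.lod_quantile))
        below = conc < lod
        obs_vals = np.where(below, np.log(lod / 2.0), obs_vals)
        n_below = int(below.sum())

    obs = pd.DataFrame(
        {
            "site_id": [sites[i].site_id for i, _ in pattern],
            "t": [t for _, t in pattern],
            "value": obs_vals,
        }
    )
    data = STDataset(sites, axis, obs, scale="log", units="ug/m3 (synthetic)")
    truth = {
        "config": config,
        "axis": axis,
        "trend_matrix": Ftrue,
        "betas": truth_draw["betas"],
        "mean_fields": mean_fields,
        "covariates": cov_table,
        "holdout_ids": holdout_ids,
        "holdout_coords": holdout_coords,
        "holdout_log_field": hold_vals,
        "holdout_lta": np.exp(hold_vals).mean(axis=1),
        "n_below_lod": n_below,
        "beta_specs": tp.beta_specs[: config.m_true + 1],
        "residual": tp.residual,
    }
    return data, truth


def small_scenario(seed: int = 0, **overrides) -> ScenarioConfig:
    """A reduced scenario for quick studies: same design, smaller counts
    and a 4-year window."""
    defaults = dict(
        n_aqs=10,
        n_fixed=3,
        n_home=30,
        n_snapshot_clusters=5,
        cluster_size=3,
        n_holdout=15,
        years=4.0,
        fixed_years=3.0,
        seed=seed,
    )
    defaults.update(overrides)
    return ScenarioConfig(**defaults)
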