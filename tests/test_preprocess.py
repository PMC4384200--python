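from datetime import date, timedelta

import numpy as np
import pandas as pd
import pytest

from stfield.data_model import Site, SiteType, STDataset, build_time_axis
from stfield.preprocess import (
    FilterReport,
    aggregate_to_periods,
    filter_covariates,
    filter_monitors,
    log_transform,
    substitute_lod,
)


class TestSubstituteLod:
    @pytest.mark.parametrize(
        "value, lod, expected",
        [(0.1, 0.4, 0.2), (0.4, 0.4, 0.4), (5.0, 0.4, 5.0)],
    )
    def test_half_lod_below_detection(self, value, lod, expected):
        assert substitute_lod(value, lod) == expected

    def test_negative_lod_rejected(self):
        with pytest.raises(ValueError):
            substitute_lod(1.0, -0.1)


def _daily_frame(sid, start, values):
    return pd.DataFrame(
        {
            "site_id": sid,
            "date": [start + timedelta(days=k) for k in range(len(values))],
            "resolution": "daily",
            "value": values,
        }
    )


class TestAggregate:
    axis = build_time_axis(date(1999, 1, 6), date(1999, 3, 3))
    sites = [Site("a", SiteType.AQS, 0.0, 0.0)]

    def test_mean_of_constant_days(self):
        raw = _daily_frame("a", date(1999, 1, 6), [10.0] * 14)
        ds = aggregate_to_periods(raw, self.axis, self.sites)
        assert ds.obs["value"].tolist() == [10.0]

    def test_arithmetic_mean_of_days(self):
        raw = _daily_frame("a", date(1999, 1, 6), list(range(1, 15)))
        ds = aggregate_to_periods(raw, self.axis, self.sites)
        assert ds.obs["value"].tolist() == [7.5]

    def test_incomplete_period_absent_not_zero(self):
        raw = _daily_frame("a", date(1999, 1, 6), [5.0] * 6)  # 6/14 < 0.75
        ds = aggregate_to_periods(raw, self.axis, self.sites, completeness_min=0.75)
        assert len(ds.obs) == 0

    def test_hourly_day_completeness(self):
        # 18 of 24 hours on each of 14 days: day means kept at 0.75
        rows = []
        for d in range(14):
            for h in range(18):
                rows.append(
                    {
                        "site_id": "a",
                        "date": date(1999, 1, 6) + timedelta(days=d),
                        "resolution": "hourly",
                        "value": float(h),
                    }
                )
        ds = aggregate_to_periods(pd.DataFrame(rows), self.axis, self.sites)
        assert ds.obs["value"].tolist() == [8.5]

    def test_unknown_resolution_rejected(self):
        raw = _daily_frame("a", date(1999, 1, 6), [1.0]).assign(resolution="weekly")
        with pytest.raises(ValueError, match="resolution"):
            aggregate_to_periods(raw, self.axis, self.sites)

    @pytest.mark.parametrize("c", [0.5, 3.0])
    def test_scaling_commutes_with_lod_and_aggregation(self, c):
        vals = [0.1, 0.5, 1.0] * 5  # includes below-LOD values
        raw = _daily_frame("a", date(1999, 1, 6), vals[:14])
        raw["lod"] = 0.4
        base = aggregate_to_periods(raw.copy(), self.axis, self.sites)
        scaled_raw = raw.assign(value=raw["value"] * c, lod=raw["lod"] * c)
        scaled = aggregate_to_periods(scaled_raw, self.axis, self.sites)
        np.testing.assert_allclose(
            scaled.obs["value"].to_numpy(), c * base.obs["value"].to_numpy()
        )


class TestFilterMonitors:
    def _dataset(self, site_periods):
        axis = build_time_axis(date(1999, 1, 6), date(2003, 1, 6))
        sites, rows = [], []
        for sid, stype, periods in site_periods:
            cl = "c0" if stype == SiteType.SNAPSHOT else None
            sites.append(Site(sid, stype, 0.0, 0.0, cluster_id=cl))
            rows += [{"site_id": sid, "t": t, "value": 1.0} for t in periods]
        return STDataset(sites, axis, pd.DataFrame(rows))

    def test_short_record_excluded(self):
        ds = self._dataset(
            [("a", SiteType.AQS, range(0, 39)),      # ~18 months
             ("b", SiteType.AQS, range(0, 80))]
        )
        kept, report = filter_monitors(ds, min_years=2.0)
        assert kept.site_ids == ["b"]
        assert ("a", "short_record") in report.excluded_sites

    def test_summer_only_monitor_excluded(self):
        axis_start = date(1999, 1, 6)
        axis = build_time_axis(axis_start, date(2003, 1, 6))
        summer = [t for t in range(len(axis))
                  if axis.period_starts[t].month in (6, 7, 8)]
        ds = self._dataset(
            [("s", SiteType.AQS, summer), ("b", SiteType.AQS, range(0, 100))]
        )
        kept, report = filter_monitors(ds)
        assert kept.site_ids == ["b"]
        assert ("s", "irregular_coverage") in report.excluded_sites

    def test_home_sites_never_removed(self):
        ds = self._dataset(
            [("h", SiteType.HOME, [3, 10]), ("b", SiteType.AQS, range(0, 100))]
        )
        kept, _ = filter_monitors(ds)
        assert "h" in kept.site_ids


class TestFilterCovariates:
    def _cov(self, rng):
        n = 100
        df = pd.DataFrame(
            {
                "site_id": [f"m{i}" for i in range(n)],
                "mostly_constant": [7.0] * 85 + list(rng.normal(0, 1, 15)),
                "gaussian": rng.normal(0, 1, n),
                "landuse_small": rng.uniform(0, 0.08, n),
            }
        ).set_index("site_id")
        return df

    def test_rules_and_union(self, rng):
        cov = self._cov(rng)
        monitors = set(cov.index)
        rep = filter_covariates(
            cov, monitors, landuse_names={"landuse_small"}
        )
        excluded = dict(rep.excluded_covariates)
        assert excluded["mostly_constant"] == "a_constant"
        assert excluded["landuse_small"] == "d_landuse_max"
        assert "gaussian" not in excluded  # no |z| > 5 in 100 standard normals

    def test_extrapolation_rule(self, rng):
        n = 50
        cov = pd.DataFrame(
            {
                "site_id": [f"m{i}" for i in range(n)] + [f"p{i}" for i in range(n)],
                "wild": list(rng.normal(0, 1, n)) + list(rng.normal(0, 10, n)),
            }
        ).set_index("site_id")
        rep = filter_covariates(
            cov,
            monitor_ids={f"m{i}" for i in range(n)},
            participant_ids={f"p{i}" for i in range(n)},
        )
        assert dict(rep.excluded_covariates)["wild"] == "c_extrapolation"

    def test_idempotent_and_order_free(self, rng):
        cov = self._cov(rng)
        monitors = set(cov.index)
        r1 = filter_covariates(cov, monitors, landuse_names={"landuse_small"})
        r2 = filter_covariates(cov[cov.columns[::-1]], monitors,
                               landuse_names={"landuse_small"})
        assert dict(r1.excluded_covariates) == dict(r2.excluded_covariates)

    def test_empty_monitor_set_rejected(self, rng):
        with pytest.raises(ValueError):
            filter_covariates(self._cov(rng), set())


class TestLogTransform:
    def _dataset(self, values):
        axis = build_time_axis(date(1999, 1, 6), date(1999, 3, 3))
        sites = [Site("a", SiteType.AQS, 0.0, 0.0)]
        obs = pd.DataFrame(
            {"site_id": "a", "t": range(len(values)), "value": values}
        )
        return STDataset(sites, axis, obs)

    def test_natural_log(self):
        out = log_transform(self._dataset([1.0, np.e]))
        np.testing.assert_allclose(out.obs["value"], [0.0, 1.0])
        assert out.scale == "log"

    def test_nonpositive_value_names_site_and_period(self):
        with pytest.raises(ValueError, match="site a, period 1"):
            log_transform(self._dataset([1.0, 0.0]))
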