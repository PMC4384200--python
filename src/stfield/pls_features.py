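"""Reduced-dimension covariate summaries via partial least squares.

Hundreds of geographic covariates (road proximities, land-use buffers,
vegetation indices, dispersion-model output, ...) cannot enter the mean
model directly.  Instead, each long-series site's observation series is
regressed on the smoothed time trends to yield per-trend coefficients
(one number per site per trend), and a univariate-outcome PLS regression
per trend compresses the standardized covariates into 2-3 scores that
maximize covariance with those coefficients.  The resulting score
definitions are fixed linear maps, so scores can be computed at any
location with known covariates — in particular at unmonitored prediction
locations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cross_decomposition import PLSRegression

from .data_model import LONG_SERIES_TYPES, STDataset
from .trend_basis import TrendBasis


@dataclass
class SiteTrendCoef:
    site_id: str
    gamma_hat: np.ndarray  # length m+1, intercept first


@dataclass
class PlsModel:
    """One fitted PLS1 score map: affine in the standardized covariates."""

    trend_index: int
    covariate_names: list[str]
    center: np.ndarray
    scale: np.ndarray
    rotations: np.ndarray  # p x n_comp
    n_comp: int

    def score(self, cov: pd.DataFrame) -> np.ndarray:
        missing = [c for c in self.covariate_names if c not in cov.columns]
        if missing:
            raise KeyError(f"missing covariate columns: {missing}")
        X = cov[self.covariate_names].to_numpy(float)
        return ((X - self.center) / self.scale) @ self.rotations

    def to_dict(self) -> dict:
        return {
            "trend_index": self.trend_index,
            "covariate_names": self.covariate_names,
            "center": self.center.tolist(),
            "scale": self.scale.tolist(),
            "rotations": self.rotations.tolist(),
            "n_comp": self.n_comp,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PlsModel":
        return cls(
            trend_index=d["trend_index"],
            covariate_names=list(d["covariate_names"]),
            center=np.asarray(d["center"], float),
            scale=np.asarray(d["scale"], float),
            rotations=np.asarray(d["rotations"], float),
            n_comp=int(d["n_comp"]),
        )


@dataclass
class PlsFeatureSet:
    """Per-trend design matrices X_i(s) = [1, scores] for every site."""

    site_ids: list[str]
    designs: list[np.ndarray]  # one (n_sites, 1 + n_comp) matrix per trend i
    models: list[PlsModel]
    gamma: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def m(self) -> int:
        return len(self.designs) - 1

    def design_for(self, i: int, site_ids: list[str]) -> np.ndarray:
        idx = [self.site_ids.index(s) for s in site_ids]
        return self.designs[i][idx]

    def score_new(self, cov: pd.DataFrame) -> list[np.ndarray]:
        """Design matrices for new locations from their covariates."""
        return [
            np.column_stack([np.ones(len(cov)), mdl.score(cov)]) for mdl in self.models
        ]


def fit_site_trend_coefs(
    data: STDataset, basis: TrendBasis, site_ids: list[str] | None = None
) -> list[SiteTrendCoef]:
    """Per-site OLS of the observed series on [1, f_1, ..., f_m].

    Defaults to the long-series sites; errors on any site whose design is
    rank deficient (too few distinct observed periods).
    """
    if site_ids is None:
        site_ids = [s.site_id for s in data.sites_of_type(*LONG_SERIES_TYPES)]
    out = []
    bad = []
    for sid in site_ids:
        sub = data.obs[data.obs["site_id"] == sid]
        t = sub["t"].to_numpy(int)
        y = sub["value"].to_numpy(float)
        X = basis.design_matrix(t)
        if len(y) < basis.m + 1 or np.linalg.matrix_rank(X) < basis.m + 1:
            bad.append(sid)
            continue
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        out.append(SiteTrendCoef(site_id=sid, gamma_hat=coef))
    if bad:
        raise ValueError(f"rank-deficient trend regression at sites: {bad}")
    return out


def fit_pls(
    gamma_i: np.ndarray, covariates: pd.DataFrame, n_comp: int, trend_index: int = 0
) -> PlsModel:
    """Univariate-outcome (PLS1) NIPALS regression of one trend coefficient
    on the standardized covariate matrix."""
    y = np.asarray(gamma_i, float)
    X = covariates.to_numpy(float)
    n, p = X.shape
    if n <= n_comp:
        raise ValueError("need more training sites than PLS components")
    center = X.mean(axis=0)
    scale = X.std(axis=0, ddof=1)
    if np.any(scale == 0):
        zero = [covariates.columns[j] for j in np.where(scale == 0)[0]]
        raise ValueError(
            f"zero-variance covariates reached PLS (filter upstream): {zero}"
        )
    Xs = (X - center) / scale
    pls = PLSRegression(n_components=n_comp, scale=False)
    pls.fit(Xs, y)
    return PlsModel(
        trend_index=trend_index,
        covariate_names=list(covariates.columns),
        center=center,
        scale=scale,
        rotations=np.asarray(pls.x_rotations_, float),
        n_comp=n_comp,
    )


def score_sites(model: PlsModel, covariates: pd.DataFrame) -> np.ndarray:
    """Apply a fitted score map to any covariate table (no re-fitting)."""
    return model.score(covariates)


def build_feature_set(
    data: STDataset,
    basis: TrendBasis,
    covariates: pd.DataFrame,
    n_comp: int,
    training_site_ids: list[str] | None = None,
) -> PlsFeatureSet:
    """Fit one PLS model per trend coefficient (including the long-term
    mean, i = 0) on the long-series sites and score every site in the
    dataset, prepending the constant column to each design."""
    if covariates.index.name != "site_id":
        covariates = covariates.set_index("site_id")
    coefs = fit_site_trend_coefs(data, basis, training_site_ids)
    train_ids = [c.site_id for c in coefs]
    gamma = pd.DataFrame(
        [c.gamma_hat for c in coefs],
        index=pd.Index(train_ids, name="site_id"),
        columns=[f"gamma_{i}" for i in range(basis.m + 1)],
    )
    cov_train = covariates.loc[train_ids]
    models = [
        fit_pls(gamma.iloc[:, i].to_numpy(), cov_train, n_comp, trend_index=i)
        for i in range(basis.m + 1)
    ]
    all_ids = data.site_ids
    cov_all = covariates.loc[all_ids]
    designs = [
        np.column_stack([np.ones(len(all_ids)), mdl.score(cov_all)]) for mdl in models
    ]
    return PlsFeatureSet(site_ids=list(all_ids), designs=designs, models=models,
                         gamma=gamma)
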