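"""Independent dense-matrix oracles and random-instance builders.

Everything here works from the covariance identity of the model — the
marginal covariance of the stacked observations is

    V = sum_i F_i Sigma_i F_i' + blockdiag_t(B_t)

— assembled entry by entry into a dense N x N matrix, with a dense GLS
mean profile and a dense conditional-Gaussian prediction.  No code from
the structured likelihood/kriging path is reused.
"""

from __future__ import annotations

from datetime import date

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from stfield.data_model import Site, SiteType, STDataset, TimeAxis, build_time_axis
from stfield.pls_features import PlsFeatureSet
from stfield.st_model import CovarianceSpec, ModelStructure, ResidualSpec
from stfield.trend_basis import TrendBasis


def beta_cov_entry(spec: CovarianceSpec, d: float) -> float:
    out = spec.tau2 if d == 0 else 0.0
    if spec.kind == "exponential":
        out += spec.sigma2 * np.exp(-d / spec.phi)
    return out


def dense_V(cells, coords, F_all, specs, resid):
    """Dense marginal covariance over the listed (site, period) cells."""
    D = cdist(coords, coords)
    N = len(cells)
    V = np.zeros((N, N))
    for a, (ia, ta) in enumerate(cells):
        for b, (ib, tb) in enumerate(cells):
            v = sum(
                F_all[ta, i] * F_all[tb, i] * beta_cov_entry(specs[i], D[ia, ib])
                for i in range(len(specs))
            )
            if ta == tb:
                v += resid.lambda2 + resid.sigma2 * np.exp(-D[ia, ib] / resid.phi)
                if ia == ib:
                    v += resid.tau2
            V[a, b] = v
    return V


def dense_loglik(cells, coords, F_all, designs, specs, resid, y):
    """Profile Gaussian log-density with dense linear algebra."""
    N = len(cells)
    V = dense_V(cells, coords, F_all, specs, resid)
    p = sum(X.shape[1] for X in designs)
    M = np.zeros((N, p))
    for a, (ia, ta) in enumerate(cells):
        off = 0
        for i, X in enumerate(designs):
            M[a, off : off + X.shape[1]] = F_all[ta, i] * X[ia]
            off += X.shape[1]
    Vi = np.linalg.inv(V)
    if p:
        alpha = np.linalg.solve(M.T @ Vi @ M, M.T @ Vi @ y)
    else:
        alpha = np.zeros(0)
    r = y - M @ alpha
    ll = -0.5 * (N * np.log(2 * np.pi) + np.linalg.slogdet(V)[1] + r @ Vi @ r)
    return float(ll), alpha


def dense_predict(cells, coords, F_all, designs, specs, resid, y,
                  tcoords, tdesigns, t_star, alpha=None):
    """Dense conditional mean and SD for targets at one period.

    ``alpha`` is the plug-in mean coefficient vector (GLS-profiled from
    the data when omitted).  A target at zero distance from a site shares
    that site's coefficient fields (including their nuggets) but draws a
    fresh residual sample (no residual nugget in the cross-covariance).
    """
    V = dense_V(cells, coords, F_all, specs, resid)
    N = len(cells)
    p = sum(X.shape[1] for X in designs)
    M = np.zeros((N, p))
    for a, (ia, ta) in enumerate(cells):
        off = 0
        for i, X in enumerate(designs):
            M[a, off : off + X.shape[1]] = F_all[ta, i] * X[ia]
            off += X.shape[1]
    Vi = np.linalg.inv(V)
    if alpha is None:
        if p:
            alpha = np.linalg.solve(M.T @ Vi @ M, M.T @ Vi @ y)
        else:
            alpha = np.zeros(0)
    resid_vec = y - M @ alpha
    Dx = cdist(tcoords, coords)
    means, sds = [], []
    m1 = len(specs)
    for l in range(len(tcoords)):
        off = 0
        mu = 0.0
        for i, X in enumerate(tdesigns):
            mu += F_all[t_star, i] * X[l] @ alpha[off : off + X.shape[1]]
            off += X.shape[1]
        qv = np.zeros(N)
        for a, (ia, ta) in enumerate(cells):
            qv[a] = sum(
                F_all[t_star, i] * F_all[ta, i] * beta_cov_entry(specs[i], Dx[l, ia])
                for i in range(m1)
            )
            if ta == t_star:
                qv[a] += resid.lambda2 + resid.sigma2 * np.exp(-Dx[l, ia] / resid.phi)
        means.append(float(mu + qv @ Vi @ resid_vec))
        prior = sum(
            F_all[t_star, i] ** 2
            * (specs[i].sigma2 + specs[i].tau2 if specs[i].kind == "exponential"
               else specs[i].tau2)
            for i in range(m1)
        ) + resid.lambda2 + resid.sigma2 + resid.tau2
        sds.append(float(np.sqrt(max(prior - qv @ Vi @ qv, 0.0))))
    return np.array(means), np.array(sds)


def random_instance(rng: np.random.Generator, max_sites: int = 15,
                    max_periods: int = 25, m: int | None = None):
    """A random small model instance with an unbalanced observation set.

    Returns a dict with the dataset, basis, per-field designs, a random
    parameter draw (random covariance kinds), and the raw pieces the
    dense oracles need.
    """
    S = int(rng.integers(4, max_sites + 1))
    T = int(rng.integers(6, max_periods + 1))
    m = int(rng.integers(1, 3)) if m is None else m
    axis = TimeAxis(
        build_time_axis(date(2004, 1, 7), date(2006, 12, 27)).period_starts[:T]
    )
    coords = rng.uniform(0, 40, (S, 2))
    sites = [Site(f"s{i}", SiteType.AQS, coords[i, 0], coords[i, 1]) for i in range(S)]
    fvals = rng.standard_normal((T, m))
    fvals -= fvals.mean(0)
    fvals /= np.sqrt((fvals**2).mean(0))
    basis = TrendBasis(m=m, values=fvals, axis=axis, df_per_year=4)
    designs = [
        np.column_stack([np.ones(S), rng.standard_normal((S, 2))])
        for _ in range(m + 1)
    ]
    features = PlsFeatureSet(
        site_ids=[s.site_id for s in sites], designs=designs, models=[]
    )
    cells = [(i, t) for i in range(S) for t in range(T) if rng.random() < 0.7]
    # every site observed at least once so the fields stay relevant
    seen = {i for i, _ in cells}
    cells += [(i, int(rng.integers(0, T))) for i in range(S) if i not in seen]
    cells = sorted(set(cells))
    y = rng.standard_normal(len(cells))
    obs = pd.DataFrame(
        {
            "site_id": [f"s{i}" for i, _ in cells],
            "t": [t for _, t in cells],
            "value": y,
        }
    )
    data = STDataset(sites, axis, obs, scale="log")
    specs = []
    for _ in range(m + 1):
        if rng.random() < 0.5:
            specs.append(
                CovarianceSpec(
                    "exponential",
                    phi=float(rng.uniform(3, 20)),
                    sigma2=float(rng.uniform(0.1, 0.8)),
                    tau2=float(rng.uniform(0.02, 0.3)),
                )
            )
        else:
            specs.append(CovarianceSpec("independent", tau2=float(rng.uniform(0.05, 0.5))))
    resid = ResidualSpec(
        sigma2=float(rng.uniform(0.05, 0.5)),
        phi=float(rng.uniform(3, 20)),
        tau2=float(rng.uniform(0.02, 0.3)),
        lambda2=float(rng.uniform(0.02, 0.4)),
    )
    structure = ModelStructure(beta_kinds=[s.kind for s in specs])
    y_sorted = data.obs["value"].to_numpy()  # STDataset may reorder; keep aligned
    cells_sorted = list(zip(
        [int(s[1:]) for s in data.obs["site_id"]], data.obs["t"].to_numpy(int)
    ))
    return {
        "data": data, "basis": basis, "features": features, "designs": designs,
        "coords": coords, "F_all": basis.design_matrix(), "specs": specs,
        "resid": resid, "structure": structure, "cells": cells_sorted,
        "y": y_sorted, "axis": axis,
    }
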