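"""Universal-kriging prediction at arbitrary locations and periods.

Predictions are conditional expectations of the log-concentration field
given every observation in the region, under the fitted Gaussian model
with the GLS mean coefficients plugged in.  Targets far from all
monitors revert smoothly to the covariate-driven mean surface plus the
per-period shared time-effect adjustment.  Back-transformation to the
concentration scale is plain exponentiation (no lognormal bias
correction, though one is available), and long-term averages are
arithmetic means of the back-transformed 2-week predictions.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date, timedelta

import numpy as np
import pandas as pd
import scipy.linalg as sla
from scipy.spatial.distance import cdist

from .data_model import PERIOD_DAYS, STDataset, TimeAxis
from .pls_features import PlsFeatureSet
from .st_model import (
    ModelParams,
    ModelStructure,
    STModelEvaluator,
    designs_for_data,
)
from .trend_basis import TrendBasis


@dataclass
class PredictionSet:
    location_ids: list[str]
    axis: TimeAxis
    periods: np.ndarray          # period indices predicted (P,)
    log_pred: np.ndarray         # L x P
    se_log: np.ndarray | None = None

    @property
    def pred(self) -> np.ndarray:
        return np.exp(self.log_pred)

    def to_frame(self) -> pd.DataFrame:
        starts = self.axis.period_starts
        rows = []
        for li, loc in enumerate(self.location_ids):
            for pi, t in enumerate(self.periods):
                rows.append(
                    {
                        "location_id": loc,
                        "period_start": starts[int(t)].isoformat(),
                        "log_pred": self.log_pred[li, pi],
                        "pred": float(np.exp(self.log_pred[li, pi])),
                        "se_log": (
                            float(self.se_log[li, pi]) if self.se_log is not None else np.nan
                        ),
                    }
                )
        return pd.DataFrame(rows)


def predict(
    params: ModelParams,
    data: STDataset,
    basis: TrendBasis,
    features: PlsFeatureSet,
    target_ids: list[str],
    target_coords: np.ndarray,
    target_designs: list[np.ndarray] | None = None,
    target_covariates: pd.DataFrame | None = None,
    periods: np.ndarray | None = None,
    compute_se: bool = False,
    bias_correct: bool = False,
) -> PredictionSet:
    """Kriging prediction of log concentration at the target locations.

    Targets are specified by coordinates plus either precomputed per-trend
    design matrices or a covariate table to be scored through the fitted
    PLS maps.  ``periods`` defaults to the full axis.  ``compute_se``
    additionally returns the plug-in kriging standard error of each
    log-scale prediction (exact, but quadratic in the number of sites per
    period, so off by default for large grids).
    """
    if target_designs is None:
        if target_covariates is None:
            raise ValueError("provide target_designs or target_covariates")
        target_designs = features.score_new(target_covariates)
    structure = ModelStructure(
        beta_kinds=[b.kind for b in params.beta_specs],
        residual_nugget=params.residual.tau2 > 0,
        time_effect=params.residual.lambda2 > 0,
    )
    ev = STModelEvaluator(data, basis, designs_for_data(features, data), structure)
    state = _posterior_state(ev, params)

    L = len(target_ids)
    periods = (
        np.arange(len(data.axis)) if periods is None else np.asarray(periods, int)
    )
    Fp = ev.F_all[periods]  # P x (m+1)
    Dcross = cdist(np.asarray(target_coords, float), data.coords())  # L x S

    # mean surface
    mu_loc = np.column_stack(
        [target_designs[i] @ params.alpha[i] for i in range(ev.m1)]
    )  # L x (m+1)
    log_pred = mu_loc @ Fp.T  # L x P

    # coefficient-field adjustment: sum_i f_i(t) * (C_i w_i)
    Ccross = [params.beta_specs[i].cross(Dcross) for i in range(ev.m1)]
    w = state["w"]
    badj = np.column_stack(
        [Ccross[i] @ w[i * ev.S : (i + 1) * ev.S] for i in range(ev.m1)]
    )  # L x (m+1)
    log_pred += badj @ Fp.T

    # residual adjustment for observed periods
    u_by_t = state["u_by_t"]
    for pi, t in enumerate(periods):
        ut = u_by_t.get(int(t))
        if ut is None:
            continue
        idx, u = ut
        Rx = params.residual.cross(Dcross[:, idx])  # L x n_t
        log_pred[:, pi] += Rx @ u

    se = None
    if compute_se:
        se = _prediction_se(ev, params, state, Dcross, Ccross, periods, Fp)
        if bias_correct:
            log_pred = log_pred + 0.5 * se**2
    elif bias_correct:
        raise ValueError("bias correction requires compute_se=True")
    return PredictionSet(
        location_ids=list(target_ids),
        axis=data.axis,
        periods=periods,
        log_pred=log_pred,
        se_log=se,
    )


def _posterior_state(ev: STModelEvaluator, params: ModelParams) -> dict:
    """Shared Woodbury pieces for conditioning on the observations."""
    m1, S, q = ev.m1, ev.S, ev.q
    asm = ev._assemble(params.beta_specs, params.residual)
    G, h = asm["G"], asm["h"]
    cS, lowS = asm["chol_S"]
    binv_by_group = asm["binvs"]

    alpha_cat = np.concatenate([np.asarray(a, float) for a in params.alpha])
    cvec = ev.Xtil @ alpha_cat
    h_r = h - G @ cvec
    z = sla.cho_solve((cS, lowS), h_r, check_finite=False)
    w = h_r - G @ z
    gq = cvec + z

    # per-period u_t = B_t^{-1} (y_t - A_g f(t))
    u_by_t: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    patt = {}
    for gi, g in enumerate(ev.groups):
        patt[tuple(g.idx)] = gi
    for t, (idx, y) in ev._by_t.items():
        gi = patt[tuple(idx)]
        g = ev.groups[gi]
        Ag = np.column_stack([gq[i * S + g.idx] for i in range(m1)])
        a_t = y - Ag @ ev.F_all[t]
        u_by_t[t] = (g.idx, binv_by_group[gi] @ a_t)
    return {
        "G": G,
        "h": h,
        "cS": (cS, lowS),
        "w": w,
        "gq": gq,
        "u_by_t": u_by_t,
        "binv_by_group": binv_by_group,
        "group_index": patt,
    }


def _prediction_se(
    ev: STModelEvaluator,
    params: ModelParams,
    state: dict,
    Dcross: np.ndarray,
    Ccross: list[np.ndarray],
    periods: np.ndarray,
    Fp: np.ndarray,
) -> np.ndarray:
    """Plug-in kriging SD of the log-scale predictions (alpha fixed)."""
    m1, S, q = ev.m1, ev.S, ev.q
    resid = params.residual
    G = state["G"]
    cS = state["cS"]
    Sinv = sla.cho_solve(cS, np.eye(q), check_finite=False)
    Pq = G - G @ Sinv @ G
    L = Dcross.shape[0]

    # Q_ij(l) = C_i[l] Pq[block ij] C_j[l]
    Qij = np.zeros((m1, m1, L))
    for i in range(m1):
        for j in range(m1):
            Pb = Pq[i * S : (i + 1) * S, j * S : (j + 1) * S]
            Qij[i, j] = np.einsum("ls,st,lt->l", Ccross[i], Pb, Ccross[j])

    prior_beta = np.array(
        [spec.sigma2 + spec.tau2 if spec.kind == "exponential" else spec.tau2
         for spec in params.beta_specs]
    )
    prior_resid = resid.lambda2 + resid.sigma2 + resid.tau2
    var = np.empty((L, len(periods)))
    patt = state["group_index"]
    for pi, t in enumerate(periods):
        f = Fp[pi]
        prior = float(f**2 @ prior_beta) + prior_resid
        red = np.einsum("i,j,ijl->l", f, f, Qij)
        tt = int(t)
        if tt in state["u_by_t"]:
            idx, _ = state["u_by_t"][tt]
            gi = patt[tuple(idx)]
            Binv = state["binv_by_group"][gi]
            Rx = resid.cross(Dcross[:, idx])          # L x n_t
            J = Binv @ Rx.T                           # n_t x L
            k_raw = np.zeros((q, L))
            for i in range(m1):
                k_raw[i * S + idx] = f[i] * J
            Sk = Sinv @ k_raw
            k_full = k_raw - G @ Sk
            qb = np.zeros((q, L))
            for i in range(m1):
                qb[i * S : (i + 1) * S] = f[i] * Ccross[i].T
            red = red + 2.0 * np.einsum("ql,ql->l", qb, k_full)
            red = red + np.einsum("lt,tl->l", Rx, J) - np.einsum(
                "ql,ql->l", k_raw, Sinv @ k_raw
            )
        var[:, pi] = np.maximum(prior - red, 0.0)
    return np.sqrt(var)


def long_term_average(
    pred: PredictionSet, date_from: date, date_to: date
) -> pd.Series:
    """Arithmetic mean of back-transformed 2-week predictions over the
    periods intersecting [date_from, date_to]."""
    starts = pred.axis.period_starts
    keep = [
        pi
        for pi, t in enumerate(pred.periods)
        if starts[int(t)] + timedelta(days=PERIOD_DAYS) > date_from
        and starts[int(t)] <= date_to
    ]
    if not keep:
        raise ValueError("no predicted periods intersect the requested range")
    lta = np.exp(pred.log_pred[:, keep]).mean(axis=1)
    return pd.Series(lta, index=pd.Index(pred.location_ids, name="location_id"),
                     name="lta")
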