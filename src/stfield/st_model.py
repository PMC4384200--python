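"""Hierarchical spatiotemporal Gaussian model and its ML estimation.

The log 2-week concentration field decomposes as

    C(s,t) = beta_0(s) + sum_i f_i(t) beta_i(s) + nu(s,t),

where the f_i are fixed smoothed time trends, each coefficient field
beta_i(s) is Gaussian with covariate-driven mean X_i(s) alpha_i and either
an independent or an exponential spatial covariance (range phi_i, partial
sill sigma2_i, nugget tau2_i), and the residual nu is independent across
periods with, within a period, a shared time random effect (variance
lambda2) plus an exponential spatial term plus a nugget.

The marginal covariance of the stacked observation vector is

    V = sum_i F_i Sigma_i F_i' + blockdiag_t(B_t),

with F_i the diagonal-in-site expansion of f_i(t) (f_0 == 1) and B_t the
within-period residual covariance over the sites observed at t.  The
mean-field coefficients alpha are profiled out by generalized least
squares at each covariance evaluation, and the profile log-likelihood and
its analytic gradient are computed with the matrix determinant lemma /
Woodbury identity so that cost scales with the number of sites and
distinct observation patterns, never with a dense N x N covariance.
Per-period residual factorizations are shared across periods that observe
the same site set, which is what makes long balanced panels cheap.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.linalg as sla
from scipy.optimize import minimize
from scipy.spatial.distance import cdist

from .data_model import STDataset
from .pls_features import PlsFeatureSet
from .trend_basis import TrendBasis

LOG2PI = math.log(2.0 * math.pi)


# ---------------------------------------------------------------------------
# parameter containers


@dataclass
class CovarianceSpec:
    """Spatial covariance of one coefficient field.

    ``independent``: tau2 * I.  ``exponential``: sigma2 * exp(-d/phi) +
    tau2 * I, distances in km.
    """

    kind: str
    tau2: float
    sigma2: float = 0.0
    phi: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("independent", "exponential"):
            raise ValueError(f"unknown covariance kind {self.kind!r}")
        if min(self.tau2, self.sigma2) < 0 or self.phi <= 0:
            raise ValueError("invalid covariance parameters")

    def matrix(self, D: np.ndarray) -> np.ndarray:
        if self.kind == "independent":
            return self.tau2 * np.eye(D.shape[0])
        return self.sigma2 * np.exp(-D / self.phi) + self.tau2 * np.eye(D.shape[0])

    def cross(self, Dcross: np.ndarray) -> np.ndarray:
        """Covariance between new locations and sites; the nugget applies
        at exactly zero distance (same physical location => same field
        value, including its micro-scale component)."""
        out = np.zeros_like(Dcross)
        if self.kind == "exponential":
            out += self.sigma2 * np.exp(-Dcross / self.phi)
        out[Dcross == 0] += self.tau2
        return out


@dataclass
class ResidualSpec:
    """Within-period residual covariance: lambda2 (shared time effect) +
    sigma2 * exp(-d/phi) + tau2 * I; independent across periods."""

    sigma2: float
    phi: float
    tau2: float
    lambda2: float

    def matrix(self, D: np.ndarray) -> np.ndarray:
        n = D.shape[0]
        return (
            self.lambda2 * np.ones((n, n))
            + self.sigma2 * np.exp(-D / self.phi)
            + self.tau2 * np.eye(n)
        )

    def cross(self, Dcross: np.ndarray) -> np.ndarray:
        """Cross-covariance to a fresh 2-week sample at a new location in
        the same period: no nugget (independent micro-scale/sampling
        error), but the shared time effect and spatial term carry over."""
        return self.lambda2 + self.sigma2 * np.exp(-Dcross / self.phi)


@dataclass
class ModelStructure:
    """Which covariance family each coefficient field uses, and which
    residual variance components are present."""

    beta_kinds: list[str]
    residual_nugget: bool = True
    time_effect: bool = True

    @property
    def n_fields(self) -> int:
        return len(self.beta_kinds)


@dataclass
class ModelParams:
    beta_specs: list[CovarianceSpec]
    residual: ResidualSpec
    alpha: list[np.ndarray]
    loglik: float = math.nan
    converged: bool = True
    n_obs: int = 0

    def to_dict(self) -> dict:
        return {
            "beta_specs": [
                {"kind": b.kind, "tau2": b.tau2, "sigma2": b.sigma2, "phi": b.phi}
                for b in self.beta_specs
            ],
            "residual": {
                "sigma2": self.residual.sigma2,
                "phi": self.residual.phi,
                "tau2": self.residual.tau2,
                "lambda2": self.residual.lambda2,
            },
            "alpha": [a.tolist() for a in self.alpha],
            "loglik": self.loglik,
            "converged": self.converged,
            "n_obs": self.n_obs,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        return cls(
            beta_specs=[CovarianceSpec(**b) for b in d["beta_specs"]],
            residual=ResidualSpec(**d["residual"]),
            alpha=[np.asarray(a, float) for a in d["alpha"]],
            loglik=float(d.get("loglik", math.nan)),
            converged=bool(d.get("converged", True)),
            n_obs=int(d.get("n_obs", 0)),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "ModelParams":
        return cls.from_dict(json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# parameter packing (log scale, enforcing positivity)


def pack_params(
    specs: list[CovarianceSpec], residual: ResidualSpec, structure: ModelStructure
) -> np.ndarray:
    theta = []
    for spec in specs:
        if spec.kind == "exponential":
            theta += [math.log(spec.phi), math.log(spec.sigma2), math.log(spec.tau2)]
        else:
            theta.append(math.log(spec.tau2))
    theta += [math.log(residual.phi), math.log(residual.sigma2)]
    if structure.residual_nugget:
        theta.append(math.log(residual.tau2))
    if structure.time_effect:
        theta.append(math.log(residual.lambda2))
    return np.array(theta)


def unpack_params(
    theta: np.ndarray, structure: ModelStructure
) -> tuple[list[CovarianceSpec], ResidualSpec]:
    theta = np.asarray(theta, float)
    specs = []
    j = 0
    for kind in structure.beta_kinds:
        if kind == "exponential":
            specs.append(
                CovarianceSpec(
                    kind="exponential",
                    phi=math.exp(theta[j]),
                    sigma2=math.exp(theta[j + 1]),
                    tau2=math.exp(theta[j + 2]),
                )
            )
            j += 3
        else:
            specs.append(CovarianceSpec(kind="independent", tau2=math.exp(theta[j])))
            j += 1
    phi, s2 = math.exp(theta[j]), math.exp(theta[j + 1])
    j += 2
    t2 = math.exp(theta[j]) if structure.residual_nugget else 0.0
    j += int(structure.residual_nugget)
    l2 = math.exp(theta[j]) if structure.time_effect else 0.0
    residual = ResidualSpec(sigma2=s2, phi=phi, tau2=max(t2, 0.0), lambda2=max(l2, 0.0))
    return specs, residual


# ---------------------------------------------------------------------------
# likelihood evaluator


class _Group:
    """Periods sharing an identical observed-site set; their residual
    covariance block is identical and is factorized once per evaluation."""

    __slots__ = ("idx", "D", "n_periods", "YYt", "Yf", "Fsum", "mesh")


class STModelEvaluator:
    """Profile log-likelihood (and gradient) of the model on one dataset.

    ``designs`` are the per-field mean design matrices X_i aligned with
    ``data.site_ids``; build them from a :class:`PlsFeatureSet` via
    :func:`designs_for_data`.
    """

    def __init__(
        self,
        data: STDataset,
        basis: TrendBasis,
        designs: list[np.ndarray],
        structure: ModelStructure,
    ):
        if data.scale != "log":
            raise ValueError("model operates on log-scale data")
        if len(designs) != basis.m + 1:
            raise ValueError("need one design matrix per trend (incl. constant)")
        if len(structure.beta_kinds) != basis.m + 1:
            raise ValueError("structure must name a kind per coefficient field")
        self.structure = structure
        self.site_ids = data.site_ids
        self.S = len(self.site_ids)
        coords = data.coords()
        self.D = cdist(coords, coords)
        self.max_dist = float(self.D.max()) if self.S > 1 else 1.0
        self.m1 = basis.m + 1
        self.F_all = basis.design_matrix()  # T x (m+1)
        self.designs = [np.asarray(X, float) for X in designs]
        self.p_alpha = sum(X.shape[1] for X in self.designs)
        self.q = self.m1 * self.S

        # block-diagonal mean map from alpha to the q beta-field means
        self.Xtil = np.zeros((self.q, self.p_alpha))
        off = 0
        for i, X in enumerate(self.designs):
            self.Xtil[i * self.S : (i + 1) * self.S, off : off + X.shape[1]] = X
            off += X.shape[1]

        # group periods by identical observed-site sets (pure numpy; this
        # constructor runs once per CV fold, so it must stay cheap)
        sid_to_i = {s: i for i, s in enumerate(self.site_ids)}
        si_arr = np.fromiter(
            (sid_to_i[s] for s in data.obs["site_id"]), dtype=int, count=len(data.obs)
        )
        t_arr = data.obs["t"].to_numpy(int)
        v_arr = data.obs["value"].to_numpy(float)
        order = np.lexsort((si_arr, t_arr))
        si_arr, t_arr, v_arr = si_arr[order], t_arr[order], v_arr[order]
        uniq_t, start = np.unique(t_arr, return_index=True)
        bounds = np.append(start, len(t_arr))
        by_t: dict[int, tuple[np.ndarray, np.ndarray]] = {}
        patt: dict[tuple, list[int]] = {}
        for k, t in enumerate(uniq_t):
            sl = slice(bounds[k], bounds[k + 1])
            si = si_arr[sl]
            by_t[int(t)] = (si, v_arr[sl])
            patt.setdefault(tuple(si), []).append(int(t))
        self.groups: list[_Group] = []
        for key, ts in patt.items():
            idx = np.array(key, dtype=int)
            Y = np.column_stack([by_t[t][1] for t in ts])  # n_t x T_g
            Fg = self.F_all[np.array(ts, int)]             # T_g x (m+1)
            g = _Group.__new__(_Group)
            g.idx = idx
            g.D = self.D[np.ix_(idx, idx)]
            g.n_periods = len(ts)
            g.YYt = Y @ Y.T
            g.Yf = Y @ Fg
            g.Fsum = Fg.T @ Fg
            g.mesh = np.ix_(idx, idx)
            self.groups.append(g)
        self.n_obs = int(sum(g.idx.size * g.n_periods for g in self.groups))
        self._by_t = by_t  # kept for prediction

        # bucket groups by block size so per-evaluation linear algebra runs
        # as stacked batched operations instead of a Python loop
        m1, S, q = self.m1, self.S, self.q
        by_size: dict[int, list[int]] = {}
        for gi, g in enumerate(self.groups):
            by_size.setdefault(len(g.idx), []).append(gi)
        self.buckets = []
        ii = np.arange(m1)
        for k, gidx in sorted(by_size.items()):
            gs = [self.groups[gi] for gi in gidx]
            idxs = np.stack([g.idx for g in gs])                     # (n_b, k)
            cols = (ii[None, :, None] * S + idxs[:, None, :])         # (n_b, m1, k)
            flat = (
                cols[:, :, None, :, None] * q + cols[:, None, :, None, :]
            )                                                         # (n_b,m1,m1,k,k)
            self.buckets.append(
                {
                    "gidx": np.array(gidx),
                    "k": k,
                    "idx": idxs,
                    "D": np.stack([g.D for g in gs]),
                    "YYt": np.stack([g.YYt for g in gs]),
                    "Yf": np.stack([g.Yf for g in gs]),
                    "Fsum": np.stack([g.Fsum for g in gs]),
                    "n_periods": np.array([g.n_periods for g in gs], float),
                    "flatG": flat.reshape(-1),
                    "cols": cols,
                }
            )

    # -- core evaluation ---------------------------------------------------
    def _beta_blocks(self, specs: list[CovarianceSpec], want_grad: bool):
        """Inverse, logdet and (for gradients) the correlation matrix of
        each coefficient-field covariance."""
        invs, logdets, Es = [], [], []
        I = np.eye(self.S)
        for spec in specs:
            if spec.kind == "independent":
                invs.append(I / spec.tau2)
                logdets.append(self.S * math.log(spec.tau2))
                Es.append(None)
            else:
                E = np.exp(-self.D / spec.phi)
                Sig = spec.sigma2 * E + spec.tau2 * I
                c, low = sla.cho_factor(Sig, lower=True, check_finite=False)
                logdets.append(2.0 * float(np.sum(np.log(np.diag(c)))))
                invs.append(sla.cho_solve((c, low), I, check_finite=False))
                Es.append(E if want_grad else None)
        return invs, logdets, Es

    def _assemble(self, specs: list[CovarianceSpec], resid: ResidualSpec,
                  want_grad: bool = False):
        """Shared Woodbury pieces: per-group residual inverses, the
        low-rank cross-products G = F'B^{-1}F and h = F'B^{-1}y, and the
        Cholesky factor of the inner matrix S = Sigma_beta^{-1} + G."""
        m1, S, q = self.m1, self.S, self.q
        invs, logdets_beta, Es = self._beta_blocks(specs, want_grad)
        h2 = np.zeros((m1, S))
        yBy = 0.0
        logdetB = 0.0
        binvs: list = [None] * len(self.groups)
        Gflat = np.zeros(q * q)
        for bk in self.buckets:
            D = bk["D"]
            B = resid.lambda2 + resid.sigma2 * np.exp(-D / resid.phi)
            dd = np.arange(bk["k"])
            B[:, dd, dd] += resid.tau2
            L = np.linalg.cholesky(B)
            logdetB += float(
                bk["n_periods"] @ (2.0 * np.log(L[:, dd, dd]).sum(axis=1))
            )
            Binv = np.linalg.inv(B)
            Binv = 0.5 * (Binv + Binv.transpose(0, 2, 1))
            yBy += float(np.einsum("gij,gij->", Binv, bk["YYt"]))
            H = Binv @ bk["Yf"]  # (n_b, k, m1)
            np.add.at(
                h2,
                (np.arange(m1)[:, None, None], bk["idx"][None]),
                H.transpose(2, 0, 1),
            )
            vals = bk["Fsum"][:, :, :, None, None] * Binv[:, None, None, :, :]
            Gflat += np.bincount(
                bk["flatG"], weights=vals.reshape(-1), minlength=q * q
            )
            for row, gi in enumerate(bk["gidx"]):
                binvs[int(gi)] = Binv[row]
        G = Gflat.reshape(q, q)
        h = h2.ravel()
        Smat = G.copy()
        for i in range(m1):
            Smat[i * S : (i + 1) * S, i * S : (i + 1) * S] += invs[i]
        cS, lowS = sla.cho_factor(Smat, lower=True, check_finite=False)
        return {
            "G": G, "h": h, "yBy": yBy, "logdetB": logdetB,
            "logdets_beta": logdets_beta, "Es": Es, "chol_S": (cS, lowS),
            "binvs": binvs,
        }

    def loglik(
        self, theta: np.ndarray, want_grad: bool = False
    ):
        """Profile log-likelihood at packed parameters ``theta``.

        Returns ``(ll, alpha_hat)`` or ``(ll, grad, alpha_hat)``.
        """
        specs, resid = unpack_params(theta, self.structure)
        m1, S, q = self.m1, self.S, self.q
        asm = self._assemble(specs, resid, want_grad)
        G, h, yBy = asm["G"], asm["h"], asm["yBy"]
        logdetB, logdets_beta, Es = asm["logdetB"], asm["logdets_beta"], asm["Es"]
        cS, lowS = asm["chol_S"]
        ginfo = asm["binvs"]
        logdetS = 2.0 * float(np.sum(np.log(np.diag(cS))))

        GX = G @ self.Xtil
        Sinv_GX = sla.cho_solve((cS, lowS), GX, check_finite=False)
        Sinv_h = sla.cho_solve((cS, lowS), h, check_finite=False)
        A = self.Xtil.T @ GX - GX.T @ Sinv_GX
        b = self.Xtil.T @ h - GX.T @ Sinv_h
        if self.p_alpha == 0:
            alpha = np.zeros(0)
        else:
            try:
                alpha = sla.solve(A, b, assume_a="pos")
            except (sla.LinAlgError, ValueError):
                alpha, *_ = np.linalg.lstsq(A, b, rcond=None)
        quad = yBy - float(h @ Sinv_h) - float(b @ alpha)
        ll = -0.5 * (self.n_obs * LOG2PI + logdetB + sum(logdets_beta) + logdetS + quad)

        offs = np.cumsum([0] + [X.shape[1] for X in self.designs])
        alpha_list = [alpha[offs[i] : offs[i + 1]] for i in range(m1)]
        if not want_grad:
            return ll, alpha_list

        # -- gradient (envelope theorem: alpha-hat terms vanish) ----------
        cvec = self.Xtil @ alpha
        h_r = h - G @ cvec
        z = sla.cho_solve((cS, lowS), h_r, check_finite=False)
        w = h_r - G @ z           # F' V^{-1} r
        gq = cvec + z
        Sinv = sla.cho_solve((cS, lowS), np.eye(q), check_finite=False)
        Pq = G - G @ Sinv @ G     # F' V^{-1} F
        Sinv4 = Sinv.reshape(m1, S, m1, S)
        gq2 = gq.reshape(m1, S)

        grad = []
        for i, spec in enumerate(specs):
            wi = w[i * S : (i + 1) * S]
            Pb = Pq[i * S : (i + 1) * S, i * S : (i + 1) * S]
            if spec.kind == "exponential":
                E = Es[i]
                M = spec.sigma2 * (self.D / spec.phi) * E
                grad.append(0.5 * float(wi @ M @ wi) - 0.5 * float(np.sum(Pb * M)))
                M = spec.sigma2 * E
                grad.append(0.5 * float(wi @ M @ wi) - 0.5 * float(np.sum(Pb * M)))
            grad.append(
                0.5 * spec.tau2 * float(wi @ wi) - 0.5 * spec.tau2 * float(np.trace(Pb))
            )

        # residual parameters, accumulated per size bucket (batched)
        dphi = dsig = dtau = dlam = 0.0
        Sflat = Sinv.reshape(-1)
        for bk in self.buckets:
            Binv = np.stack([ginfo[int(gi)] for gi in bk["gidx"]])
            Ag = gq2[:, bk["idx"]].transpose(1, 2, 0)       # (n_b, k, m1)
            YfA = bk["Yf"] @ Ag.transpose(0, 2, 1)          # (n_b, k, k)
            Saa = bk["YYt"] - YfA - YfA.transpose(0, 2, 1) + Ag @ bk["Fsum"] @ Ag.transpose(0, 2, 1)
            Usum = Binv @ Saa @ Binv                        # sum_t u_t u_t'
            # Ssub[g,i,a,j,b] = Sinv[i*S+idx_a, j*S+idx_b]
            Ssub = Sflat[bk["flatG"]].reshape(
                len(bk["gidx"]), m1, m1, bk["k"], bk["k"]
            )
            Msum = np.einsum("gij,gijab->gab", bk["Fsum"], Ssub)
            Tr = bk["n_periods"][:, None, None] * Binv - Binv @ Msum @ Binv
            W = Usum - Tr
            Eg = np.exp(-bk["D"] / resid.phi)
            dphi += 0.5 * float(
                np.sum(W * (resid.sigma2 * (bk["D"] / resid.phi) * Eg))
            )
            dsig += 0.5 * float(np.sum(W * (resid.sigma2 * Eg)))
            dd = np.arange(bk["k"])
            if self.structure.residual_nugget:
                dtau += 0.5 * resid.tau2 * float(np.sum(W[:, dd, dd]))
            if self.structure.time_effect:
                dlam += 0.5 * resid.lambda2 * float(np.sum(W))
        grad += [dphi, dsig]
        if self.structure.residual_nugget:
            grad.append(dtau)
        if self.structure.time_effect:
            grad.append(dlam)
        return ll, np.array(grad), alpha_list


def designs_for_data(features: PlsFeatureSet, data: STDataset) -> list[np.ndarray]:
    """Restrict a feature set's design matrices to the dataset's sites,
    in the dataset's site order."""
    pos = {s: i for i, s in enumerate(features.site_ids)}
    idx = [pos[s] for s in data.site_ids]
    return [X[idx] for X in features.designs]


# ---------------------------------------------------------------------------
# fitting


def _default_init(
    ev: STModelEvaluator, structure: ModelStructure, data: STDataset
) -> np.ndarray:
    v = float(np.var(data.obs["value"].to_numpy(float)))
    v = max(v, 1e-4)
    phi0 = max(ev.max_dist / 4.0, 1e-2)
    specs = []
    for kind in structure.beta_kinds:
        if kind == "exponential":
            specs.append(
                CovarianceSpec("exponential", phi=phi0, sigma2=v / 4, tau2=v / 8)
            )
        else:
            specs.append(CovarianceSpec("independent", tau2=v / 4))
    resid = ResidualSpec(sigma2=v / 4, phi=phi0, tau2=v / 8, lambda2=v / 8)
    return pack_params(specs, resid, structure)


def fit_ml(
    data: STDataset,
    basis: TrendBasis,
    features: PlsFeatureSet,
    structure: ModelStructure,
    init: np.ndarray | None = None,
    n_starts: int = 3,
    seed: int = 0,
    maxiter: int = 500,
) -> ModelParams:
    """Maximize the profile likelihood over log covariance parameters.

    Quasi-Newton (L-BFGS-B) with analytic gradients; ``n_starts`` seeded
    restarts with multiplicative jitter on the initial variances, keeping
    the best optimum.  Deterministic given (data, init, seed).
    """
    ev = STModelEvaluator(data, basis, designs_for_data(features, data), structure)
    x0 = _default_init(ev, structure, data) if init is None else np.asarray(init, float)
    rng = np.random.default_rng(seed)
    fail = {"count": 0}

    def objective(theta):
        try:
            ll, grad, _ = ev.loglik(theta, want_grad=True)
        except (sla.LinAlgError, np.linalg.LinAlgError, FloatingPointError):
            fail["count"] += 1
            return 1e12, np.zeros_like(theta)
        if not np.isfinite(ll):
            return 1e12, np.zeros_like(theta)
        return -ll, -grad

    best = None
    diagnostics = []
    for s in range(max(n_starts, 1)):
        start = x0 if s == 0 else x0 + rng.normal(0.0, 0.5, size=x0.shape)
        res = minimize(
            objective,
            start,
            jac=True,
            method="L-BFGS-B",
            bounds=[(-18.0, 18.0)] * len(start),
            options={"maxiter": maxiter, "ftol": 1e-10, "gtol": 1e-7},
        )
        diagnostics.append((res.status, res.message, float(res.fun)))
        if np.isfinite(res.fun) and res.fun < 1e11 and (best is None or res.fun < best.fun):
            best = res
    if best is None:
        raise RuntimeError(f"ML optimization failed at all starts: {diagnostics}")
    ll, alpha = ev.loglik(best.x, want_grad=False)
    specs, resid = unpack_params(best.x, structure)
    return ModelParams(
        beta_specs=specs,
        residual=resid,
        alpha=[np.asarray(a) for a in alpha],
        loglik=float(ll),
        converged=bool(best.success),
        n_obs=ev.n_obs,
    )


def marginal_loglik(
    data: STDataset,
    basis: TrendBasis,
    features: PlsFeatureSet,
    beta_specs: list[CovarianceSpec],
    residual: ResidualSpec,
) -> tuple[float, list[np.ndarray]]:
    """Profile log-likelihood at given covariance parameters, with the
    GLS-profiled mean coefficients."""
    structure = ModelStructure(
        beta_kinds=[b.kind for b in beta_specs],
        residual_nugget=residual.tau2 > 0,
        time_effect=residual.lambda2 > 0,
    )
    ev = STModelEvaluator(data, basis, designs_for_data(features, data), structure)
    theta = pack_params(beta_specs, residual, structure)
    return ev.loglik(theta, want_grad=False)


# ---------------------------------------------------------------------------
# generative counterpart


def _draw_mvn(mean: np.ndarray, cov: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    if not np.any(cov):
        return mean.copy()
    try:
        L = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        L = np.linalg.cholesky(cov + 1e-10 * np.trace(cov) / len(cov) * np.eye(len(cov)))
    return mean + L @ rng.standard_normal(len(mean))


def simulate_field(
    coords: np.ndarray,
    trend_matrix: np.ndarray,
    mean_fields: np.ndarray,
    beta_specs: list[CovarianceSpec],
    residual: ResidualSpec,
    obs_pattern: list[tuple[int, int]],
    seed: int | np.random.Generator = 0,
) -> tuple[np.ndarray, dict]:
    """Draw one realization of the model.

    ``trend_matrix`` is T x (m+1) including the constant column;
    ``mean_fields`` is (m+1) x S with row i holding X_i(s) alpha_i;
    ``obs_pattern`` lists (site_index, period_index) cells to emit.
    Returns the values in pattern order and a truth bundle with the drawn
    coefficient fields.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    S = coords.shape[0]
    m1 = trend_matrix.shape[1]
    D = cdist(coords, coords)
    betas = np.empty((m1, S))
    for i in range(m1):
        betas[i] = _draw_mvn(np.asarray(mean_fields[i], float), beta_specs[i].matrix(D), rng)
    by_t: dict[int, list[int]] = {}
    for k, (si, t) in enumerate(obs_pattern):
        by_t.setdefault(int(t), []).append(k)
    values = np.empty(len(obs_pattern))
    for t in sorted(by_t):
        ks = by_t[t]
        sidx = np.array([obs_pattern[k][0] for k in ks], dtype=int)
        Dsub = D[np.ix_(sidx, sidx)]
        nu = _draw_mvn(np.zeros(len(sidx)), residual.matrix(Dsub), rng)
        mean_t = trend_matrix[t] @ betas[:, sidx]
        values[np.array(ks)] = mean_t + nu
    return values, {"betas": betas, "D": D}


def simulate(
    params: ModelParams,
    data_template: STDataset,
    basis: TrendBasis,
    features: PlsFeatureSet,
    obs_pattern: list[tuple[str, int]],
    seed: int | np.random.Generator = 0,
) -> STDataset:
    """Simulate a dataset over the template's sites with the given
    observation pattern of (site_id, period) cells."""
    sid_to_i = {s: i for i, s in enumerate(data_template.site_ids)}
    designs = designs_for_data(features, data_template)
    mean_fields = np.vstack(
        [designs[i] @ params.alpha[i] for i in range(len(designs))]
    )
    pattern_idx = [(sid_to_i[s], t) for s, t in obs_pattern]
    values, _ = simulate_field(
        data_template.coords(),
        basis.design_matrix(),
        mean_fields,
        params.beta_specs,
        params.residual,
        pattern_idx,
        seed,
    )
    import pandas as pd

    obs = pd.DataFrame(
        {"site_id": [s for s, _ in obs_pattern], "t": [t for _, t in obs_pattern],
         "value": values}
    )
    return STDataset(data_template.sites, data_template.axis, obs, scale="log",
                     units=data_template.units)
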