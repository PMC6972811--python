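"""Bivariate animal-model REML: G and E estimation over a pedigree.

Model: for measured individuals, stacking the two traits,

    y = X b + Z a + e,    a ~ N(0, G (x) A),    e ~ N(0, E (x) I),

with per-trait intercepts as the only fixed effects and A the additive
relationship matrix over the whole pedigree.  Marginally over the
unmeasured pedigree members, var(y) = G (x) A_mm + E (x) I where A_mm is
the relationship matrix among measured individuals, so the restricted
likelihood only needs A_mm; BLUPs for unmeasured ancestors come back in
via cov(a, y) = G (x) A_{all,m}.

Computation: with the spectral decomposition A_mm = U D U', rotating the
data by U' makes var(y) block-diagonal with 2x2 blocks d_i*G + E, so one
restricted-log-likelihood evaluation costs O(n) after a single
eigendecomposition.  G and E are optimized through their log-Cholesky
factors (PSD by construction); the constrained fit pins the off-diagonal
Cholesky element of G so that cov_A = 0 exactly.
"""

from __future__ import annotations

import hashlib
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import chi2 as chi2_dist

from .pedigree import Pedigree, additive_relationship_matrix

_LOG2PI = float(np.log(2.0 * np.pi))


class GMatrixError(ValueError):
    pass


# --------------------------------------------------------------------- #
# data container


@dataclass
class RemlData:
    """Pre-rotated data for fast restricted-likelihood evaluations."""

    ids: list[str]                 # measured individual ids
    d: np.ndarray                  # eigenvalues of A_mm, clipped at 0
    Yt: np.ndarray                 # (n, 2) rotated phenotypes U' y_t
    xt: np.ndarray                 # (n,) rotated intercept column U' 1
    U: np.ndarray                  # eigenvectors of A_mm
    P_sample: np.ndarray           # sample phenotypic covariance (start values)
    fingerprint: str
    A_all_m: np.ndarray | None = None   # (N, n) relationships pedigree x measured
    all_ids: list[str] | None = None

    @property
    def n(self) -> int:
        return len(self.ids)

    @classmethod
    def from_arrays(
        cls,
        Y: np.ndarray,
        A_mm: np.ndarray,
        ids: list[str],
        A_all_m: np.ndarray | None = None,
        all_ids: list[str] | None = None,
    ) -> "RemlData":
        Y = np.asarray(Y, dtype=float)
        n = Y.shape[0]
        if Y.shape != (n, 2) or A_mm.shape != (n, n):
            raise GMatrixError("shape mismatch between phenotypes and A matrix")
        w, U = np.linalg.eigh(A_mm)
        if w.min() < -1e-6:
            raise GMatrixError("relationship matrix is not PSD")
        d = np.clip(w, 0.0, None)
        h = hashlib.sha256()
        h.update(("|".join(ids)).encode())
        h.update(np.round(Y, 10).tobytes())
        return cls(
            ids=list(ids),
            d=d,
            Yt=U.T @ Y,
            xt=U.T @ np.ones(n),
            U=U,
            P_sample=np.cov(Y, rowvar=False, ddof=1),
            fingerprint=h.hexdigest()[:16],
            A_all_m=A_all_m,
            all_ids=all_ids,
        )

    @classmethod
    def from_phenotypes(cls, phenos: pd.DataFrame, ped: Pedigree) -> "RemlData":
        meas = phenos[phenos["measured"]].copy()
        if len(meas) < 2:
            raise GMatrixError("need at least 2 measured individuals")
        if len(meas) < 30:
            warnings.warn("fewer than 30 measured individuals; estimates will be weak")
        A, ids = additive_relationship_matrix(ped)
        idx = {iid: k for k, iid in enumerate(ids)}
        missing = [i for i in meas["id"] if i not in idx]
        if missing:
            raise GMatrixError(f"measured ids missing from pedigree: {missing[:5]}")
        meas = meas.sort_values("id", kind="stable")
        m_idx = np.array([idx[i] for i in meas["id"]])
        A_mm = A[np.ix_(m_idx, m_idx)]
        if np.allclose(A_mm, np.eye(len(m_idx))):
            warnings.warn(
                "relationship matrix among measured individuals is the identity; "
                "G and E are confounded"
            )
        Y = meas[["flower_scaled", "sla"]].to_numpy(dtype=float)
        return cls.from_arrays(
            Y, A_mm, list(meas["id"]), A_all_m=A[:, m_idx], all_ids=ids
        )


# --------------------------------------------------------------------- #
# likelihood


def _cov_from_theta(t0: float, t1: float, t2: float) -> np.ndarray:
    # LL' for L = [[exp(t0), 0], [t1, exp(t2)]], with overflow guards
    a = math.exp(min(max(t0, -20.0), 20.0))
    c = math.exp(min(max(t2, -20.0), 20.0))
    return np.array([[a * a, a * t1], [a * t1, t1 * t1 + c * c]])


def _unpack(theta: np.ndarray, constrain_cov: bool) -> tuple[np.ndarray, np.ndarray]:
    if constrain_cov:
        g0, g2, e0, e1, e2 = theta
        g1 = 0.0
    else:
        g0, g1, g2, e0, e1, e2 = theta
    return _cov_from_theta(g0, g1, g2), _cov_from_theta(e0, e1, e2)


def reml_neg_loglik(G: np.ndarray, E: np.ndarray, data: RemlData) -> float:
    """-2 restricted log-likelihood is avoided; this returns the negative
    restricted log-likelihood itself (with constants)."""
    d, Yt, xt = data.d, data.Yt, data.xt
    a = d * G[0, 0] + E[0, 0]
    b = d * G[0, 1] + E[0, 1]
    c = d * G[1, 1] + E[1, 1]
    det = a * c - b * b
    if det.min() <= 0 or a.min() <= 0:
        return np.inf
    logdetV = float(np.log(det).sum())
    y1, y2 = Yt[:, 0], Yt[:, 1]
    inv_det = 1.0 / det
    w1 = (c * y1 - b * y2) * inv_det
    w2 = (a * y2 - b * y1) * inv_det
    yVy = float(y1 @ w1 + y2 @ w2)
    x2 = xt * xt * inv_det
    xx11 = float(x2 @ c)
    xx12 = -float(x2 @ b)
    xx22 = float(x2 @ a)
    xy1 = float(xt @ w1)
    xy2 = float(xt @ w2)
    det_xx = xx11 * xx22 - xx12 * xx12
    if det_xx <= 0:
        return np.inf
    b1 = (xx22 * xy1 - xx12 * xy2) / det_xx
    b2 = (xx11 * xy2 - xx12 * xy1) / det_xx
    yPy = yVy - (xy1 * b1 + xy2 * b2)
    n_y, p = 2 * data.n, 2
    ll = -0.5 * (logdetV + math.log(det_xx) + yPy + (n_y - p) * _LOG2PI)
    return -ll


def _gls_mu(G: np.ndarray, E: np.ndarray, data: RemlData) -> np.ndarray:
    d, Yt, xt = data.d, data.Yt, data.xt
    a = d * G[0, 0] + E[0, 0]
    b = d * G[0, 1] + E[0, 1]
    c = d * G[1, 1] + E[1, 1]
    det = a * c - b * b
    y1, y2 = Yt[:, 0], Yt[:, 1]
    w1 = (c * y1 - b * y2) / det
    w2 = (a * y2 - b * y1) / det
    x2 = xt * xt
    XtViX = np.array(
        [
            [float((x2 * c / det).sum()), float(-(x2 * b / det).sum())],
            [float(-(x2 * b / det).sum()), float((x2 * a / det).sum())],
        ]
    )
    XtViy = np.array([float(xt @ w1), float(xt @ w2)])
    return np.linalg.solve(XtViX, XtViy)


# --------------------------------------------------------------------- #
# estimate container


@dataclass
class GEstimate:
    """REML estimate of the bivariate G and E with summaries.

    ``blups`` maps every pedigree individual (measured or not) to predicted
    breeding values for (flower_scaled, sla); empty if not requested.
    """

    G: np.ndarray
    E: np.ndarray
    se_G: np.ndarray
    se_E: np.ndarray
    mu: np.ndarray
    loglik: float
    h2: np.ndarray
    se_h2: np.ndarray
    converged: bool
    constrained: bool
    n_measured: int
    fingerprint: str
    blups: pd.DataFrame = field(default_factory=pd.DataFrame)

    def to_dict(self) -> dict:
        return {
            "G": self.G.tolist(),
            "E": self.E.tolist(),
            "se_G": self.se_G.tolist(),
            "se_E": self.se_E.tolist(),
            "mu": self.mu.tolist(),
            "loglik": self.loglik,
            "h2": self.h2.tolist(),
            "se_h2": self.se_h2.tolist(),
            "converged": self.converged,
            "constrained": self.constrained,
            "n_measured": self.n_measured,
            "fingerprint": self.fingerprint,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GEstimate":
        return cls(
            G=np.array(d["G"]), E=np.array(d["E"]),
            se_G=np.array(d["se_G"]), se_E=np.array(d["se_E"]),
            mu=np.array(d["mu"]), loglik=float(d["loglik"]),
            h2=np.array(d["h2"]), se_h2=np.array(d["se_h2"]),
            converged=bool(d["converged"]), constrained=bool(d["constrained"]),
            n_measured=int(d["n_measured"]), fingerprint=str(d["fingerprint"]),
        )


# --------------------------------------------------------------------- #
# fitting


def _starts(P: np.ndarray, constrain_cov: bool) -> list[np.ndarray]:
    """Three starting points: balanced, G-dominant, E-dominant splits of
    the sample phenotypic covariance."""
    out = []
    for gshare in (0.5, 0.8, 0.2):
        Gs, Es = gshare * P, (1 - gshare) * P
        theta = []
        for M in (Gs, Es):
            L = np.linalg.cholesky(M + 1e-8 * np.eye(2) * np.trace(M))
            t = [np.log(L[0, 0]), L[1, 0], np.log(L[1, 1])]
            if M is Gs and constrain_cov:
                t = [np.log(L[0, 0]), np.log(np.sqrt(max(M[1, 1], 1e-10)))]
            theta.extend(t)
        out.append(np.array(theta))
    return out


def fit_reml_data(
    data: RemlData,
    constrain_cov: bool = False,
    n_starts: int = 3,
    start_theta: np.ndarray | None = None,
    compute_se: bool = True,
    maxiter: int = 4000,
    fast: bool = False,
) -> GEstimate:
    """Maximize the restricted likelihood on prepared data.

    Nelder-Mead from each start, then an L-BFGS-B polish of the best
    candidate; relative log-likelihood tolerance 1e-8.  With ``fast=True``
    (used for refits inside resampling loops) a single quasi-Newton run
    from the balanced start replaces the multi-start Nelder-Mead stage,
    with a Nelder-Mead fallback if it fails.
    """
    nll = lambda th: reml_neg_loglik(*_unpack(th, constrain_cov), data)
    starts = _starts(data.P_sample, constrain_cov)[: max(1, n_starts)]
    if start_theta is not None:
        starts = [np.asarray(start_theta, dtype=float)] + starts[: max(0, n_starts - 1)]
    best, best_f = None, np.inf
    ok = False
    if fast:
        res = optimize.minimize(
            nll, _starts(data.P_sample, constrain_cov)[0], method="L-BFGS-B",
            options={"maxiter": 500},
        )
        if res.success and np.isfinite(res.fun):
            best, best_f, ok = res.x, res.fun, True
            return _finalize(best, best_f, ok, data, constrain_cov, compute_se)
        starts = starts[:1]
    for th0 in starts:
        res = optimize.minimize(
            nll, th0, method="Nelder-Mead",
            options={"maxiter": maxiter, "fatol": 1e-9, "xatol": 1e-7},
        )
        if res.fun < best_f:
            best, best_f, ok = res.x, res.fun, bool(res.success)
    res = optimize.minimize(nll, best, method="L-BFGS-B", options={"maxiter": 500})
    if np.isfinite(res.fun) and res.fun <= best_f + 1e-12:
        rel = abs(best_f - res.fun) / max(1.0, abs(best_f))
        best, best_f = res.x, res.fun
        ok = ok or res.success or rel < 1e-8
    return _finalize(best, best_f, ok, data, constrain_cov, compute_se)


def _finalize(
    theta: np.ndarray, neg_ll: float, ok: bool, data: RemlData,
    constrain_cov: bool, compute_se: bool,
) -> GEstimate:
    G, E = _unpack(theta, constrain_cov)
    if constrain_cov:
        G[0, 1] = G[1, 0] = 0.0
    mu = _gls_mu(G, E, data)
    h2 = np.diag(G) / (np.diag(G) + np.diag(E))
    if compute_se:
        se_G, se_E, se_h2 = _standard_errors(G, E, data, constrain_cov, theta)
    else:
        se_G = np.full((2, 2), np.nan)
        se_E = np.full((2, 2), np.nan)
        se_h2 = np.full(2, np.nan)
    est = GEstimate(
        G=G, E=E, se_G=se_G, se_E=se_E, mu=mu, loglik=-neg_ll,
        h2=h2, se_h2=se_h2, converged=bool(ok and np.isfinite(neg_ll)),
        constrained=constrain_cov, n_measured=data.n,
        fingerprint=data.fingerprint,
    )
    est._theta = theta  # stashed so callers can warm-start refits
    return est


def _component_cov(
    G: np.ndarray, E: np.ndarray, data: RemlData, constrain_cov: bool
) -> np.ndarray | None:
    """Covariance of the variance-component estimates from the inverse of
    a central-difference Hessian in (G11, [G12,] G22, E11, E12, E22) space."""
    if constrain_cov:
        pack = lambda v: (
            np.array([[v[0], 0.0], [0.0, v[1]]]),
            np.array([[v[2], v[3]], [v[3], v[4]]]),
        )
        phi = np.array([G[0, 0], G[1, 1], E[0, 0], E[0, 1], E[1, 1]])
    else:
        pack = lambda v: (
            np.array([[v[0], v[1]], [v[1], v[2]]]),
            np.array([[v[3], v[4]], [v[4], v[5]]]),
        )
        phi = np.array([G[0, 0], G[0, 1], G[1, 1], E[0, 0], E[0, 1], E[1, 1]])
    f = lambda v: reml_neg_loglik(*pack(v), data)
    k = len(phi)
    scale = np.trace(G + E) / 4.0
    h = 1e-4 * (np.abs(phi) + 1e-3 * scale)
    H = np.empty((k, k))
    f0 = f(phi)
    if not np.isfinite(f0):
        return None
    for i in range(k):
        ei = np.zeros(k); ei[i] = h[i]
        H[i, i] = (f(phi + ei) - 2 * f0 + f(phi - ei)) / h[i] ** 2
        for j in range(i + 1, k):
            ej = np.zeros(k); ej[j] = h[j]
            H[i, j] = H[j, i] = (
                f(phi + ei + ej) - f(phi + ei - ej) - f(phi - ei + ej) + f(phi - ei - ej)
            ) / (4 * h[i] * h[j])
    if not np.all(np.isfinite(H)):
        return None
    try:
        C = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        return None
    if np.any(np.diag(C) < 0):
        C = np.linalg.pinv(H)
        if np.any(np.diag(C) < 0):
            return None
    return C


def _standard_errors(
    G: np.ndarray, E: np.ndarray, data: RemlData, constrain_cov: bool,
    theta: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    C = _component_cov(G, E, data, constrain_cov)
    nanG = np.full((2, 2), np.nan)
    if C is None:
        return nanG, nanG.copy(), np.full(2, np.nan)
    se = np.sqrt(np.diag(C))
    if constrain_cov:
        se_G = np.array([[se[0], 0.0], [0.0, se[1]]])
        se_E = np.array([[se[2], se[3]], [se[3], se[4]]])
        ig = {0: 0, 1: 1}   # indices of (G11, G22) in phi
        ie = {0: 2, 1: 4}
    else:
        se_G = np.array([[se[0], se[1]], [se[1], se[2]]])
        se_E = np.array([[se[3], se[4]], [se[4], se[5]]])
        ig = {0: 0, 1: 2}
        ie = {0: 3, 1: 5}
    # delta method for h2_t = g/(g+e)
    se_h2 = np.empty(2)
    for t in range(2):
        g, e = G[t, t], E[t, t]
        grad = np.zeros(C.shape[0])
        grad[ig[t]] = e / (g + e) ** 2
        grad[ie[t]] = -g / (g + e) ** 2
        v = grad @ C @ grad
        se_h2[t] = np.sqrt(v) if v >= 0 else np.nan
    return se_G, se_E, se_h2


def reml_fit(
    phenos: pd.DataFrame,
    ped: Pedigree,
    constrain_cov: bool = False,
    n_starts: int = 3,
    compute_se: bool = True,
    include_blups: bool = True,
) -> GEstimate:
    """Fit the bivariate animal model to the measured rows of ``phenos``
    using the full pedigree ``ped`` (unmeasured ancestors contribute
    through the relationship matrix and receive BLUPs)."""
    data = RemlData.from_phenotypes(phenos, ped)
    est = fit_reml_data(
        data, constrain_cov=constrain_cov, n_starts=n_starts, compute_se=compute_se
    )
    if include_blups:
        est.blups = _blups(est, data)
    return est


def _blups(est: GEstimate, data: RemlData) -> pd.DataFrame:
    """Mixed-model-equation solutions for breeding values at the REML
    estimates, for every pedigree individual."""
    G, E, mu = est.G, est.E, est.mu
    d, Yt, xt, U = data.d, data.Yt, data.xt, data.U
    a = d * G[0, 0] + E[0, 0]
    b = d * G[0, 1] + E[0, 1]
    c = d * G[1, 1] + E[1, 1]
    det = a * c - b * b
    r1t = Yt[:, 0] - mu[0] * xt
    r2t = Yt[:, 1] - mu[1] * xt
    w1 = (c * r1t - b * r2t) / det
    w2 = (a * r2t - b * r1t) / det
    r1 = U @ w1
    r2 = U @ w2
    A_am = data.A_all_m if data.A_all_m is not None else np.eye(data.n)
    ids = data.all_ids if data.all_ids is not None else data.ids
    q1 = A_am @ r1
    q2 = A_am @ r2
    blup_flower = G[0, 0] * q1 + G[0, 1] * q2
    blup_sla = G[1, 0] * q1 + G[1, 1] * q2
    return pd.DataFrame({"id": ids, "blup_flower": blup_flower, "blup_sla": blup_sla})


def extract_blups(est: GEstimate) -> pd.DataFrame:
    """Predicted breeding values (id, blup_flower, blup_sla) from a
    converged fit."""
    if not est.converged:
        raise GMatrixError("cannot extract BLUPs from a non-converged estimate")
    if est.blups.empty:
        raise GMatrixError("estimate was fitted without BLUPs")
    return est.blups


# --------------------------------------------------------------------- #
# derived statistics


def lrt_covariance(full: GEstimate, constrained: GEstimate) -> tuple[float, float]:
    """Likelihood-ratio test of cov_A = 0: chi2 on 1 df comparing the full
    fit to the covariance-constrained fit on the same data."""
    if not constrained.constrained:
        raise GMatrixError("second estimate must be the constrained fit")
    if full.fingerprint != constrained.fingerprint:
        raise GMatrixError("estimates come from different datasets")
    stat = max(0.0, 2.0 * (full.loglik - constrained.loglik))
    return stat, float(chi2_dist.sf(stat, df=1))


def chi2_pvalue(stat: float, df: int = 1) -> float:
    """Upper-tail chi-square probability."""
    return float(chi2_dist.sf(stat, df=df))


def genetic_correlation(G: np.ndarray) -> float:
    """r_G = cov_A / sqrt(V_A1 * V_A2)."""
    G = np.asarray(G, dtype=float)
    if G[0, 0] <= 0 or G[1, 1] <= 0:
        raise GMatrixError("genetic correlation undefined with zero variance")
    return float(G[0, 1] / np.sqrt(G[0, 0] * G[1, 1]))


def phenotypic_correlation(phenos: pd.DataFrame, line: str | None = None) -> float:
    """Pearson correlation of the two analysis-scale traits over measured
    individuals (optionally restricted to one line)."""
    df = phenos[phenos["measured"]]
    if line is not None:
        df = df[df["line"] == line]
    if len(df) < 3:
        raise GMatrixError("need at least 3 measured individuals")
    x = df["flower_scaled"].to_numpy(dtype=float)
    y = df["sla"].to_numpy(dtype=float)
    return float(np.corrcoef(x, y)[0, 1])
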