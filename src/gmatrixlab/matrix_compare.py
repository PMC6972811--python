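"""Comparison of 2x2 G matrices: eigenstructure ellipses, subsample
randomization nulls, random skewers, and BLUP founder resampling.

Angle convention: trait 0 (flower number, analysis scale) is the x axis
and trait 1 (SLA) the y axis; the ellipse angle is that of the leading
eigenvector, mapped into [0, 180) degrees, so a positive genetic
covariance gives an angle below 90 degrees and a negative covariance an
angle above 90.

The random-skewers statistic is the mean over random selection gradients
of the absolute vector correlation (cosine) between the two response
vectors Delta z_i = G_i beta; the absolute convention measures alignment
of response directions irrespective of orientation sign and is the one
under which published comparisons of this kind are reported.  The signed
mean is returned alongside.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2 as chi2_dist

from . import gmatrix
from .pedigree import Pedigree, additive_relationship_matrix


class CompareError(ValueError):
    pass


# --------------------------------------------------------------------- #
# eigenstructure ellipse


@dataclass(frozen=True)
class EllipseParams:
    major_axis: float
    minor_axis: float
    angle_deg: float

    def as_array(self) -> np.ndarray:
        return np.array([self.major_axis, self.minor_axis, self.angle_deg])


def eigen_ellipse(G: np.ndarray, coverage: float = 0.95) -> EllipseParams:
    """Ellipse summarizing a 2x2 G matrix's eigenstructure.

    Axis lengths are sqrt(eigenvalue * q) with q the chi-square(2)
    quantile at ``coverage`` (~5.991 at 0.95), so the ellipse covers that
    fraction of a bivariate normal with covariance G.  The angle is the
    leading eigenvector's direction in [0, 180) degrees; isotropic
    matrices return 0 by convention.
    """
    G = np.asarray(G, dtype=float)
    if G.shape != (2, 2) or not np.allclose(G, G.T):
        raise CompareError("G must be 2x2 symmetric")
    w, V = np.linalg.eigh(G)
    if w[0] < -1e-8:
        raise CompareError(f"negative eigenvalue {w[0]:.3g}")
    w = np.clip(w, 0.0, None)
    q = float(chi2_dist.ppf(coverage, df=2))
    major, minor = np.sqrt(w[1] * q), np.sqrt(w[0] * q)
    if np.isclose(w[0], w[1]):
        angle = 0.0
    else:
        v = V[:, 1]
        angle = float(np.degrees(np.arctan2(v[1], v[0])) % 180.0)
    return EllipseParams(float(major), float(minor), angle)


# --------------------------------------------------------------------- #
# random skewers


@dataclass(frozen=True)
class SkewersResult:
    mean_vector_correlation: float     # mean |cos| between response vectors
    mean_signed_correlation: float
    mc_se: float                       # Monte-Carlo SE of the mean
    p_similarity: float                # P(random-pair |cos| >= observed mean)
    n_skewers: int


def _unit_skewers(rng: np.random.Generator, n: int, dim: int = 2) -> np.ndarray:
    b = rng.uniform(-1.0, 1.0, size=(n, dim))
    norm = np.linalg.norm(b, axis=1, keepdims=True)
    # resample the (measure-zero) zero vector defensively
    bad = norm[:, 0] == 0
    while bad.any():
        b[bad] = rng.uniform(-1.0, 1.0, size=(int(bad.sum()), dim))
        norm = np.linalg.norm(b, axis=1, keepdims=True)
        bad = norm[:, 0] == 0
    return b / norm


def random_skewers(
    G1: np.ndarray,
    G2: np.ndarray,
    n_skewers: int = 1000,
    seed: int | np.random.Generator = 0,
) -> SkewersResult:
    """Random-skewers similarity of two G matrices.

    Selection gradients beta are uniform on [-1, 1]^2 normalized to unit
    length; responses are G_i @ beta.  A small ``p_similarity`` means the
    matrices produce more similar responses than random vector pairs do.
    """
    G1 = np.asarray(G1, dtype=float)
    G2 = np.asarray(G2, dtype=float)
    for M in (G1, G2):
        if M.shape != (2, 2) or not np.allclose(M, M.T):
            raise CompareError("G matrices must be 2x2 symmetric")
        if np.linalg.eigvalsh(M).min() < -1e-8:
            raise CompareError("G matrices must be PSD")
        if np.allclose(M, 0):
            raise CompareError("zero matrix has no selection response")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    B = _unit_skewers(rng, n_skewers)
    R1 = B @ G1.T
    R2 = B @ G2.T
    cos = np.sum(R1 * R2, axis=1) / (
        np.linalg.norm(R1, axis=1) * np.linalg.norm(R2, axis=1)
    )
    obs = float(np.abs(cos).mean())
    # null: |cos| between independent random unit-vector pairs
    null = np.abs(
        np.sum(_unit_skewers(rng, n_skewers) * _unit_skewers(rng, n_skewers), axis=1)
    )
    p = float((1 + np.count_nonzero(null >= obs)) / (1 + n_skewers))
    return SkewersResult(
        mean_vector_correlation=obs,
        mean_signed_correlation=float(cos.mean()),
        mc_se=float(np.abs(cos).std(ddof=1) / np.sqrt(n_skewers)),
        p_similarity=p,
        n_skewers=n_skewers,
    )


# --------------------------------------------------------------------- #
# randomization test of eigenstructure


@dataclass
class RandomizationResult:
    null_major: np.ndarray
    null_minor: np.ndarray
    null_angle: np.ndarray
    p_major: float
    p_minor: float
    p_angle: float
    n_iter: int
    n_dropped: int
    reliable: bool

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"major": self.null_major, "minor": self.null_minor, "angle": self.null_angle}
        )


def _two_sided_p(null: np.ndarray, observed: float) -> float:
    n = len(null)
    lo = int(np.count_nonzero(null <= observed))
    hi = int(np.count_nonzero(null >= observed))
    return float(min(1.0, 2.0 * (1 + min(lo, hi)) / (1 + n)))


def randomization_test(
    phenosA: pd.DataFrame,
    pedA: Pedigree,
    phenosB: pd.DataFrame,
    pedB: Pedigree,
    observed: EllipseParams,
    n_iter: int = 1000,
    subsample: int = 100,
    seed: int | np.random.Generator = 0,
    coverage: float = 0.95,
) -> RandomizationResult:
    """Null distribution of ellipse parameters under 'no difference'.

    Each iteration pools ``subsample`` measured individuals drawn from each
    population, refits the bivariate animal model on the pooled data with
    the joint pedigree, and records the fitted G's ellipse parameters.
    Two-sided p-values use the doubled smaller tail with an add-one
    correction.  Non-converged iterations are dropped; more than 20%
    dropped flags the result unreliable.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    idsA = set(pedA.table["id"])
    idsB = set(pedB.table["id"])
    if idsA & idsB:
        raise CompareError("pedigrees must have disjoint individual ids")
    combined = Pedigree(pd.concat([pedA.table, pedB.table], ignore_index=True))
    A_full, all_ids = additive_relationship_matrix(combined)
    pos = {iid: k for k, iid in enumerate(all_ids)}

    def measured_arrays(ph: pd.DataFrame):
        m = ph[ph["measured"]].sort_values("id", kind="stable")
        if len(m) < subsample:
            raise CompareError(
                f"population has {len(m)} measured individuals, need {subsample}"
            )
        Y = m[["flower_scaled", "sla"]].to_numpy(dtype=float)
        idx = np.array([pos[i] for i in m["id"]])
        return Y, idx, list(m["id"])

    YA, idxA, idsA_m = measured_arrays(phenosA)
    YB, idxB, idsB_m = measured_arrays(phenosB)
    null = np.full((n_iter, 3), np.nan)
    for it in range(n_iter):
        selA = rng.choice(len(idsA_m), size=subsample, replace=False)
        selB = rng.choice(len(idsB_m), size=subsample, replace=False)
        Y = np.vstack([YA[selA], YB[selB]])
        midx = np.concatenate([idxA[selA], idxB[selB]])
        sub_ids = [idsA_m[k] for k in selA] + [idsB_m[k] for k in selB]
        data = gmatrix.RemlData.from_arrays(
            Y, A_full[np.ix_(midx, midx)], sub_ids
        )
        est = gmatrix.fit_reml_data(data, compute_se=False, fast=True)
        if not est.converged:
            continue
        ell = eigen_ellipse(est.G, coverage=coverage)
        null[it] = ell.as_array()
    valid = ~np.isnan(null[:, 0])
    n_dropped = int(n_iter - valid.sum())
    null = null[valid]
    if len(null) == 0:
        raise CompareError("no randomization iteration converged")
    obs = observed.as_array()
    return RandomizationResult(
        null_major=null[:, 0],
        null_minor=null[:, 1],
        null_angle=null[:, 2],
        p_major=_two_sided_p(null[:, 0], obs[0]),
        p_minor=_two_sided_p(null[:, 1], obs[1]),
        p_angle=_two_sided_p(null[:, 2], obs[2]),
        n_iter=n_iter,
        n_dropped=n_dropped,
        reliable=n_dropped <= 0.2 * n_iter,
    )


# --------------------------------------------------------------------- #
# BLUP founder resampling


@dataclass
class BlupResampleResult:
    correlations: np.ndarray       # length n_reps, NaN for degenerate samples
    mean: float
    n_excluded: int
    threshold_counts: dict[float, int] = field(default_factory=dict)


def blup_resample_correlation(
    blups: pd.DataFrame,
    k: int = 12,
    n_reps: int = 1000,
    seed: int | np.random.Generator = 0,
    thresholds: tuple[float, ...] = (0.5, 0.2),
) -> BlupResampleResult:
    """Sampling distribution of the BLUP correlation in founder-sized draws.

    Each replicate samples ``k`` individuals without replacement and
    records the Pearson correlation between their two BLUP components —
    the distribution of genetic correlations a line founded by k random
    individuals could start from.  Samples with zero variance in either
    component are recorded as missing.
    """
    if k < 3:
        raise CompareError("k must be at least 3")
    X = blups[["blup_flower", "blup_sla"]].to_numpy(dtype=float)
    n = len(X)
    if n < k:
        raise CompareError(f"need at least k={k} individuals, have {n}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    cors = np.full(n_reps, np.nan)
    for r in range(n_reps):
        sub = X[rng.choice(n, size=k, replace=False)]
        sd = sub.std(axis=0, ddof=1)
        if np.any(sd == 0):
            continue
        cors[r] = np.corrcoef(sub[:, 0], sub[:, 1])[0, 1]
    valid = cors[~np.isnan(cors)]
    counts = {t: int(np.count_nonzero(valid < t)) for t in thresholds}
    return BlupResampleResult(
        correlations=cors,
        mean=float(valid.mean()) if len(valid) else float("nan"),
        n_excluded=int(np.isnan(cors).sum()),
        threshold_counts=counts,
    )
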