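"""Disruptive correlational selection on PCA of full-sib family means.

Selection acts on families, not individuals: trait means over measured
males are computed per family, z-standardized, and decomposed into
principal components.  PC1 is the major axis of the among-family trait
correlation; PC2 is orthogonal to it, and families at both PC2 extremes
are chosen to erode the trait covariance while leaving the means alone.
The control line draws the same number of families uniformly at random.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


class SelectionError(ValueError):
    pass


def family_means(
    phenos: pd.DataFrame, line: str | None = None, generation: int | None = None
) -> pd.DataFrame:
    """Per-family trait means over measured males.

    Families without any measured male are dropped.  Returns columns
    ``family, mean_flower, mean_sla, n_males`` sorted by family id.
    """
    df = phenos
    if line is not None:
        df = df[df["line"] == line]
    if generation is not None:
        df = df[df["generation"] == generation]
    df = df[(df["sex"] == "male") & df["measured"]]
    if df.empty:
        raise SelectionError("no measured males in the requested cohort")
    out = (
        df.groupby("family")
        .agg(
            mean_flower=("flower_scaled", "mean"),
            mean_sla=("sla", "mean"),
            n_males=("id", "size"),
        )
        .reset_index()
        .sort_values("family", kind="stable")
        .reset_index(drop=True)
    )
    return out


def pca_family_means(
    means: pd.DataFrame, standardize: bool = True
) -> pd.DataFrame:
    """Principal components of the (standardized) family means.

    Returns the input frame with ``pc1`` and ``pc2`` score columns plus a
    ``selected`` placeholder; the orthonormal loading matrix is attached as
    ``result.attrs["loadings"]`` (columns = components, rows = traits in
    (flower, sla) order) and eigenvalues as ``attrs["eigvals"]``.

    Sign convention: PC1's loading on SLA is non-negative and the loading
    matrix has determinant +1, so with a positive trait association PC1
    points along (+,+) and angles are reproducible across runs.
    """
    if len(means) < 3:
        raise SelectionError("PCA needs at least 3 families")
    X = means[["mean_flower", "mean_sla"]].to_numpy(dtype=float)
    sd = X.std(axis=0, ddof=1)
    if np.any(sd <= 0):
        raise SelectionError("a trait has zero variance across family means")
    if standardize:
        X = (X - X.mean(axis=0)) / sd
    else:
        X = X - X.mean(axis=0)
    C = np.cov(X, rowvar=False, ddof=1)
    w, V = np.linalg.eigh(C)          # ascending
    w, V = w[::-1], V[:, ::-1]        # PC1 first
    if V[1, 0] < 0:
        V[:, 0] = -V[:, 0]
    if np.linalg.det(V) < 0:
        V[:, 1] = -V[:, 1]
    scores = X @ V
    out = means.copy()
    out["pc1"] = scores[:, 0]
    out["pc2"] = scores[:, 1]
    out["selected"] = False
    out.attrs["loadings"] = V
    out.attrs["eigvals"] = w
    out.attrs["standardized"] = bool(standardize)
    return out


def select_families_disruptive(scores: pd.DataFrame, k_each: int = 4) -> set[str]:
    """The ``k_each`` families with the largest PC2 scores plus the
    ``k_each`` with the smallest; ties broken by family id."""
    if len(scores) < 2 * k_each:
        raise SelectionError(
            f"need at least {2 * k_each} families, have {len(scores)}"
        )
    top = scores.sort_values(
        ["pc2", "family"], ascending=[False, True], kind="stable"
    )["family"].head(k_each)
    bottom = scores.sort_values(
        ["pc2", "family"], ascending=[True, True], kind="stable"
    )["family"].head(k_each)
    return set(top) | set(bottom)


def select_families_random(
    scores: pd.DataFrame, k: int = 8, seed: int | np.random.Generator = 0
) -> set[str]:
    """Uniform sample of ``k`` families without replacement."""
    fams = sorted(scores["family"])
    if len(fams) < k:
        raise SelectionError(f"need at least {k} families, have {len(fams)}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return set(rng.choice(fams, size=k, replace=False))


def fallback_ranking(
    scores: pd.DataFrame, chosen: set[str], disruptive: bool = True
) -> list[str]:
    """Chosen families first, then the remaining families in the order a
    substitution should try them (by |PC2| for disruptive selection,
    family-id order for random selection)."""
    rest = scores[~scores["family"].isin(chosen)]
    first = scores[scores["family"].isin(chosen)]
    if disruptive:
        key = lambda df: df.reindex(
            df["pc2"].abs().sort_values(ascending=False, kind="stable").index
        )
        first, rest = key(first), key(rest)
    return list(first["family"]) + list(rest["family"])


def disruptive_differential(scores: pd.DataFrame, selected: set[str]) -> float:
    """mean(|PC2|) over selected families minus mean(|PC2|) over all."""
    if not selected:
        raise SelectionError("empty selection")
    sel_scores = scores[scores["family"].isin(selected)]
    return float(sel_scores["pc2"].abs().mean() - scores["pc2"].abs().mean())


def directional_differential(
    scores: pd.DataFrame, selected: set[str], axis: str = "pc1"
) -> float:
    """mean(axis score) over selected minus mean over all families."""
    if axis not in ("pc1", "pc2"):
        raise SelectionError(f"axis must be pc1 or pc2, got {axis!r}")
    if not selected:
        raise SelectionError("empty selection")
    sel_scores = scores[scores["family"].isin(selected)]
    return float(sel_scores[axis].mean() - scores[axis].mean())


def choose_parents(
    phenos: pd.DataFrame, family: str, seed: int | np.random.Generator = 0
) -> tuple[str, str]:
    """Pick the breeding pair of one family: a uniformly random female and
    the measured male closest to the family's trait mean.

    Distances are Euclidean in trait space standardized over all measured
    males in ``phenos`` (the cohort), so the two traits weigh equally.
    Ties go to the lexicographically smallest male id.
    """
    fam = phenos[phenos["family"] == family]
    females = fam[fam["sex"] == "female"].sort_values("id", kind="stable")
    males = fam[(fam["sex"] == "male") & fam["measured"]].sort_values("id", kind="stable")
    if females.empty or males.empty:
        raise SelectionError(
            f"family {family!r} lacks a female or a measured male"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    dam = str(rng.choice(females["id"].to_numpy()))
    cohort_males = phenos[(phenos["sex"] == "male") & phenos["measured"]]
    mu = cohort_males[["flower_scaled", "sla"]].mean().to_numpy()
    sd = cohort_males[["flower_scaled", "sla"]].std(ddof=1).to_numpy()
    sd = np.where(sd > 0, sd, 1.0)
    Z = (males[["flower_scaled", "sla"]].to_numpy() - mu) / sd
    target = Z.mean(axis=0)
    d = np.linalg.norm(Z - target, axis=1)
    sire = str(males["id"].to_numpy()[int(np.argmin(d))])
    return dam, sire
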