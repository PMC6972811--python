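"""Shared builders and independent oracles for the test suite.

Everything here is generated programmatically; no stored fixtures.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from gmatrixlab import TraitModel, simulate_breeding_values, simulate_phenotypes
from gmatrixlab.pedigree import UNKNOWN, Pedigree


def make_fullsib_population(
    n_fam: int,
    n_off: int,
    G: np.ndarray,
    E: np.ndarray,
    mu: np.ndarray,
    seed: int,
    prefix: str = "",
    measure_parents: bool = False,
) -> tuple[Pedigree, pd.DataFrame]:
    """Unrelated parent pairs, each with ``n_off`` male offspring; the
    standard independent full-sib-family design for variance-component
    checks."""
    rng = np.random.default_rng(seed)
    rows = []
    for f in range(n_fam):
        rows.append({"id": f"{prefix}s{f}", "sire": UNKNOWN, "dam": UNKNOWN,
                     "sex": "male", "generation": 0, "line": "x",
                     "family": f"{prefix}p{f}"})
        rows.append({"id": f"{prefix}d{f}", "sire": UNKNOWN, "dam": UNKNOWN,
                     "sex": "female", "generation": 0, "line": "x",
                     "family": f"{prefix}p{f}"})
        for k in range(n_off):
            rows.append({"id": f"{prefix}f{f}o{k}", "sire": f"{prefix}s{f}",
                         "dam": f"{prefix}d{f}", "sex": "male", "generation": 1,
                         "line": "x", "family": f"{prefix}fam{f}"})
    ped = Pedigree(pd.DataFrame(rows))
    bv = simulate_breeding_values(ped, G, rng)
    phenos = simulate_phenotypes(ped, bv, TraitModel(G=G, E=E, mu=mu), seed=rng)
    if not measure_parents:
        phenos.loc[phenos["generation"] == 0, "measured"] = False
    return ped, phenos


def kinship_oracle(ped: Pedigree):
    """Independent recursive coancestry: f(i,i) = (1 + f(s,d))/2,
    f(i,j) = (f(s_i,j) + f(d_i,j))/2 recursing on the later-born member.
    Returns a function f(i, j); the additive relationship is 2*f."""
    t = ped.table.set_index("id")
    sire, dam = t["sire"].to_dict(), t["dam"].to_dict()
    depth: dict[str, int] = {}
    for iid in ped.ids:
        s = sire[iid]
        depth[iid] = 0 if s == UNKNOWN else 1 + max(depth[s], depth[dam[iid]])
    memo: dict[tuple[str, str], float] = {}

    def f(i: str, j: str) -> float:
        if i > j:
            i, j = j, i
        if (i, j) in memo:
            return memo[(i, j)]
        if i == j:
            s = sire[i]
            val = 0.5 if s == UNKNOWN else 0.5 * (1.0 + f(s, dam[i]))
        else:
            a, b = (i, j) if depth[i] >= depth[j] else (j, i)
            s = sire[a]
            val = 0.0 if s == UNKNOWN else 0.5 * (f(s, b) + f(dam[a], b))
        memo[(i, j)] = val
        return val

    return f


def random_pedigree(rng: np.random.Generator, n_founders: int = 12,
                    n_gens: int = 3, per_gen: int = 20) -> Pedigree:
    """Random multigeneration pedigree (possibly inbred) for property tests."""
    rows = []
    males, females = [], []
    for k in range(n_founders):
        sex = "male" if k % 2 == 0 else "female"
        iid = f"F{k}"
        rows.append({"id": iid, "sire": UNKNOWN, "dam": UNKNOWN, "sex": sex,
                     "generation": 0, "line": "L", "family": f"fam{k}"})
        (males if sex == "male" else females).append(iid)
    for g in range(1, n_gens + 1):
        new_m, new_f = [], []
        for k in range(per_gen):
            s = males[rng.integers(len(males))]
            d = females[rng.integers(len(females))]
            sex = "male" if rng.random() < 0.5 else "female"
            iid = f"G{g}_{k}"
            rows.append({"id": iid, "sire": s, "dam": d, "sex": sex,
                         "generation": g, "line": "L", "family": f"{s}x{d}"})
            (new_m if sex == "male" else new_f).append(iid)
        males = males + new_m
        females = females + new_f
    return Pedigree(pd.DataFrame(rows))


@pytest.fixture(scope="session")
def unit_G():
    return np.array([[100.0, 50.0], [50.0, 100.0]])


@pytest.fixture(scope="session")
def unit_E():
    return np.diag([100.0, 100.0])


@pytest.fixture(scope="session")
def medium_G():
    # strong genetic correlation (0.8) so the covariance is detectable at n=360
    return np.array([[100.0, 80.0], [80.0, 100.0]])


@pytest.fixture(scope="session")
def medium_fit(medium_G, unit_E):
    """One moderately sized REML fit (full and covariance-constrained)
    shared across tests: 60 full-sib families of 6, n = 360 measured."""
    from gmatrixlab import reml_fit

    ped, phenos = make_fullsib_population(
        60, 6, medium_G, unit_E, np.array([50.0, 50.0]), seed=42
    )
    full = reml_fit(phenos, ped)
    constrained = reml_fit(phenos, ped, constrain_cov=True, include_blups=False)
    return {"ped": ped, "phenos": phenos, "full": full, "constrained": constrained}
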