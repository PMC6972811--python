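"""Generative model for pedigreed bivariate phenotypes and the selection experiment.

Traits live on the analysis scale throughout: trait 0 is flower number
log-transformed and multiplied by 50 (``flower_scaled = 50*ln(flower_count)``),
trait 1 is specific leaf area (SLA) in cm^2/g.  Breeding values follow the
additive infinitesimal model over the pedigree: founders are MVN(0, G),
offspring are the midparent value plus a Mendelian-sampling deviation with
covariance ``0.5*G*(1 - (F_sire + F_dam)/2)``, so that for any pair of
individuals cov(a_i, a_j) = A_ij * G.  Phenotypes add an independent
MVN(0, E) environmental deviation to the trait means.

``simulate_experiment`` reproduces the structure of a disruptive
correlational selection experiment: a base population bred with a circulant
crossing design, then per line and generation measurement of males only,
PCA of full-sib family means, selection of families at both PC2 extremes
(or at random for the control line), parent choice, and another circulant
round of crosses.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from . import selection as sel
from .pedigree import (
    UNKNOWN,
    CrossPlan,
    Pedigree,
    PedigreeError,
    make_circulant_design,
)

TRAIT_NAMES = ("flower_scaled", "sla")

PHENOTYPE_COLUMNS = [
    "id", "family", "line", "generation", "sex",
    "sla", "flower_count", "flower_scaled", "measured",
]


def _check_psd(M: np.ndarray, name: str) -> np.ndarray:
    M = np.asarray(M, dtype=float)
    if M.shape != (2, 2):
        raise ValueError(f"{name} must be 2x2, got {M.shape}")
    if not np.allclose(M, M.T):
        raise ValueError(f"{name} must be symmetric")
    if np.linalg.eigvalsh(M).min() < -1e-8:
        raise ValueError(f"{name} is not positive semidefinite")
    return M


def _psd_factor(M: np.ndarray) -> np.ndarray:
    """Matrix square root usable for singular covariance matrices."""
    w, v = np.linalg.eigh(M)
    return v @ np.diag(np.sqrt(np.clip(w, 0.0, None)))


def _stage_rng(seed: int, label: str) -> np.random.Generator:
    """Independent, replayable substream for a named simulation stage."""
    return np.random.default_rng([int(seed), zlib.crc32(label.encode())])


@dataclass
class TraitModel:
    """Ground-truth additive-genetic (G) and environmental (E) covariance
    matrices with trait means, in (flower_scaled, sla) order."""

    G: np.ndarray
    E: np.ndarray
    mu: np.ndarray

    def __post_init__(self) -> None:
        self.G = _check_psd(self.G, "G")
        self.E = _check_psd(self.E, "E")
        self.mu = np.asarray(self.mu, dtype=float).reshape(2)
        if np.linalg.eigvalsh(self.G + self.E).min() <= 0:
            raise ValueError("phenotypic covariance G + E must be positive definite")

    @classmethod
    def default(cls) -> "TraitModel":
        """Base-population model: G from the study population's estimates,
        E set for heritability 0.30 in both traits and a phenotypic
        correlation of 0.08, means at ~100 flowers and SLA 250 cm^2/g."""
        G = np.array([[47.0, 116.0], [116.0, 697.0]])
        h2 = 0.30
        P = np.diag(G) / h2
        cov_P = 0.08 * np.sqrt(P[0] * P[1])
        E = np.array(
            [[P[0] - G[0, 0], cov_P - G[0, 1]], [cov_P - G[0, 1], P[1] - G[1, 1]]]
        )
        return cls(G=G, E=E, mu=np.array([230.0, 250.0]))

    def to_dict(self) -> dict:
        return {"G": self.G.tolist(), "E": self.E.tolist(), "mu": self.mu.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "TraitModel":
        return cls(G=np.array(d["G"]), E=np.array(d["E"]), mu=np.array(d["mu"]))


@dataclass
class ExperimentConfig:
    """Sizes and seeds of the simulated selection experiment.

    Offspring counts are seeds grown per full-sib family; with an even sex
    ratio roughly half of each family's offspring are measurable males.
    The defaults mirror the study scale: 103 founder capsules thinned to a
    120-family base population, ~5 offspring per family in the selection
    generations, and a larger final generation for G estimation.
    """

    n_capsules: int = 103
    n_base_families: int = 120
    offspring_per_family: int = 5
    n_final_offspring_per_family: int = 18
    n_generations: int = 4
    lines: tuple[str, ...] = ("control", "selection_1", "selection_2")
    n_families_selected: int = 8
    offsets: tuple[int, ...] = (1, 2, 3)
    sex_ratio: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "n_capsules", "n_base_families", "offspring_per_family",
            "n_final_offspring_per_family", "n_families_selected",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.n_generations < 0:
            raise ValueError("n_generations must be >= 0")
        if self.n_families_selected % 2:
            raise ValueError("n_families_selected must be even (split between PC2 extremes)")
        if self.n_base_families > self.n_capsules * len(self.offsets):
            raise ValueError("n_base_families exceeds the crosses the design can produce")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["lines"] = list(self.lines)
        d["offsets"] = list(self.offsets)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        if "lines" in d:
            d["lines"] = tuple(d["lines"])
        if "offsets" in d:
            d["offsets"] = tuple(d["offsets"])
        return cls(**d)


def load_config(path) -> tuple[ExperimentConfig, TraitModel]:
    """Read an experiment configuration (YAML or JSON) with keys
    ``experiment`` and ``trait_model``."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    cfg = ExperimentConfig.from_dict(doc.get("experiment", {}))
    model = (
        TraitModel.from_dict(doc["trait_model"])
        if "trait_model" in doc
        else TraitModel.default()
    )
    return cfg, model


# --------------------------------------------------------------------- #
# breeding values and phenotypes


class _KinshipCache:
    """Memoized recursive coancestry over a growing parent map."""

    def __init__(self) -> None:
        self.parent: dict[str, tuple[str, str]] = {}
        self.depth: dict[str, int] = {}
        self.memo: dict[tuple[str, str], float] = {}

    def add(self, iid: str, sire: str, dam: str) -> None:
        self.parent[iid] = (sire, dam)
        if sire == UNKNOWN:
            self.depth[iid] = 0
        else:
            self.depth[iid] = 1 + max(self.depth[sire], self.depth[dam])

    def kinship(self, i: str, j: str) -> float:
        if i > j:
            i, j = j, i
        key = (i, j)
        if key in self.memo:
            return self.memo[key]
        if i == j:
            s, d = self.parent[i]
            f = 0.5 if s == UNKNOWN else 0.5 * (1.0 + self.kinship(s, d))
        else:
            a, b = (i, j) if self.depth[i] >= self.depth[j] else (j, i)
            s, d = self.parent[a]
            f = 0.0 if s == UNKNOWN else 0.5 * (self.kinship(s, b) + self.kinship(d, b))
        self.memo[key] = f
        return f

    def inbreeding(self, i: str) -> float:
        return 2.0 * self.kinship(i, i) - 1.0


def simulate_breeding_values(
    ped: Pedigree, G: np.ndarray, seed: int | np.random.Generator
) -> dict[str, np.ndarray]:
    """Draw bivariate breeding values for every pedigree member.

    Founders ~ MVN(0, G); non-founders get the midparent value plus a
    Mendelian deviation with covariance 0.5*G*(1 - (F_sire + F_dam)/2),
    where F is the parent's inbreeding coefficient.
    """
    G = _check_psd(G, "G")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    L = _psd_factor(G)
    kin = _KinshipCache()
    t = ped.table.set_index("id")
    sires, dams = t["sire"].to_dict(), t["dam"].to_dict()
    bv: dict[str, np.ndarray] = {}
    for iid in ped.ids:
        s, d = sires[iid], dams[iid]
        kin.add(iid, s, d)
        z = rng.standard_normal(2)
        if s == UNKNOWN:
            bv[iid] = L @ z
        else:
            scale = np.sqrt(0.5 * (1.0 - 0.5 * (kin.inbreeding(s) + kin.inbreeding(d))))
            bv[iid] = 0.5 * (bv[s] + bv[d]) + scale * (L @ z)
    return bv


def simulate_phenotypes(
    ped: Pedigree,
    breeding_values: dict[str, np.ndarray],
    model: TraitModel,
    sex_ratio: float = 0.5,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Phenotypes = mu + breeding value + MVN(0, E) deviation, per individual.

    Sex is taken from the pedigree where known, otherwise drawn
    Bernoulli(sex_ratio) for male.  The integer ``flower_count`` column is
    materialized as round(exp(flower_scaled / 50)); all rows start with
    ``measured = True`` (callers model measurement protocols on top).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    Le = _psd_factor(model.E)
    rows = []
    t = ped.table.set_index("id")
    for iid in ped.ids:
        rec = t.loc[iid]
        a = breeding_values[iid]
        y = model.mu + a + Le @ rng.standard_normal(2)
        sex = rec["sex"]
        if sex == "unknown":
            sex = "male" if rng.random() < sex_ratio else "female"
        flower_scaled, sla = float(y[0]), float(y[1])
        rows.append(
            {
                "id": iid,
                "family": rec["family"],
                "line": rec["line"],
                "generation": int(rec["generation"]),
                "sex": sex,
                "sla": sla,
                "flower_count": max(0, int(round(np.exp(flower_scaled / 50.0)))),
                "flower_scaled": flower_scaled,
                "measured": True,
            }
        )
    return pd.DataFrame(rows, columns=PHENOTYPE_COLUMNS)


# --------------------------------------------------------------------- #
# the full experiment


@dataclass
class ExperimentResult:
    pedigree: Pedigree
    phenotypes: pd.DataFrame
    family_records: pd.DataFrame
    differentials: pd.DataFrame
    warnings: list[str] = field(default_factory=list)


class _Breeder:
    """Accumulates pedigree rows, breeding values and phenotypes cohort by
    cohort so that selection can read phenotypes before the next cohort
    exists."""

    def __init__(self, model: TraitModel, cfg: ExperimentConfig):
        self.model = model
        self.cfg = cfg
        self.LG = _psd_factor(model.G)
        self.LE = _psd_factor(model.E)
        self.kin = _KinshipCache()
        self.bv: dict[str, np.ndarray] = {}
        self.ped_rows: list[dict] = []
        self.phe_rows: list[dict] = []
        self.sex: dict[str, str] = {}
        self.counter = 0

    def _phenotype(self, iid, family, line, gen, sex, a, measured, rng):
        y = self.model.mu + a + self.LE @ rng.standard_normal(2)
        self.phe_rows.append(
            {
                "id": iid, "family": family, "line": line, "generation": gen,
                "sex": sex, "sla": float(y[1]),
                "flower_count": max(0, int(round(np.exp(y[0] / 50.0)))),
                "flower_scaled": float(y[0]), "measured": measured,
            }
        )

    def add_founder(self, iid, family, sex, rng) -> None:
        self.kin.add(iid, UNKNOWN, UNKNOWN)
        a = self.LG @ rng.standard_normal(2)
        self.bv[iid] = a
        self.sex[iid] = sex
        self.ped_rows.append(
            {"id": iid, "sire": UNKNOWN, "dam": UNKNOWN, "sex": sex,
             "generation": 0, "line": "base", "family": family}
        )
        self._phenotype(iid, family, "base", 0, sex, a, False, rng)

    def add_offspring(self, iid, sire, dam, family, line, gen, rng) -> None:
        self.kin.add(iid, sire, dam)
        scale = np.sqrt(
            0.5 * (1.0 - 0.5 * (self.kin.inbreeding(sire) + self.kin.inbreeding(dam)))
        )
        a = 0.5 * (self.bv[sire] + self.bv[dam]) + scale * (self.LG @ rng.standard_normal(2))
        self.bv[iid] = a
        sex = "male" if rng.random() < self.cfg.sex_ratio else "female"
        self.sex[iid] = sex
        self.ped_rows.append(
            {"id": iid, "sire": sire, "dam": dam, "sex": sex,
             "generation": gen, "line": line, "family": family}
        )
        self._phenotype(iid, family, line, gen, sex, a, sex == "male", rng)

    def breed_family(self, family_id, sire, dam, line, gen, n_offspring, rng) -> None:
        for k in range(n_offspring):
            self.add_offspring(f"{family_id}_o{k}", sire, dam, family_id, line, gen, rng)


def simulate_experiment(
    config: ExperimentConfig, model: TraitModel | None = None
) -> ExperimentResult:
    """Run the full selection experiment.

    Base population: one male and one female founder per capsule, crossed
    circulantly and thinned to ``n_base_families`` full-sib families whose
    offspring form generation 1 (shared by all lines).  Each of
    ``n_generations`` rounds then, per line: measure males, compute family
    means, PCA, select ``n_families_selected`` families (PC2 extremes for
    selection lines, at random for the control line), pick a random dam and
    the male nearest the family mean as sire, and breed the next generation
    with the same circulant design.  The final round grows
    ``n_final_offspring_per_family`` offspring per family to give the
    G-estimation sample.  Bit-reproducible given (config, model).
    """
    if model is None:
        model = TraitModel.default()
    cfg = config
    br = _Breeder(model, cfg)
    warn_log: list[str] = []

    # founders: a male and a female from each capsule
    rng = _stage_rng(cfg.seed, "founders")
    capsules = [f"cap{c:03d}" for c in range(cfg.n_capsules)]
    for cap in capsules:
        br.add_founder(f"{cap}F", cap, "female", rng)
        br.add_founder(f"{cap}M", cap, "male", rng)

    # base crosses: circulant over capsules, thinned to n_base_families
    plan = make_circulant_design(capsules, cfg.offsets)
    rng = _stage_rng(cfg.seed, "base_subsample")
    keep_idx = sorted(rng.choice(len(plan), size=cfg.n_base_families, replace=False))
    rng = _stage_rng(cfg.seed, "base_breed")
    base_families = []
    for j, idx in enumerate(keep_idx):
        cross = plan.crosses[idx]
        fam = f"base{j:03d}"
        base_families.append(fam)
        br.breed_family(
            fam, f"{cross.sire_family}M", f"{cross.dam_family}F",
            "base", 1, cfg.offspring_per_family, rng,
        )

    fam_records: list[pd.DataFrame] = []
    diff_rows: list[dict] = []

    def phenos() -> pd.DataFrame:
        return pd.DataFrame(br.phe_rows, columns=PHENOTYPE_COLUMNS)

    for line in cfg.lines:
        disruptive = line != "control"
        current_line, current_gen = "base", 1
        for rnd in range(cfg.n_generations):
            df = phenos()
            means = sel.family_means(df, line=current_line, generation=current_gen)
            scores = sel.pca_family_means(means)
            if disruptive:
                chosen = sel.select_families_disruptive(
                    scores, k_each=cfg.n_families_selected // 2
                )
            else:
                chosen = sel.select_families_random(
                    scores, k=cfg.n_families_selected,
                    seed=_stage_rng(cfg.seed, f"{line}_round{rnd}_pick"),
                )
            # parent availability fallback: substitute the next-ranked family
            ranking = sel.fallback_ranking(scores, chosen, disruptive=disruptive)
            cohort = df[(df["line"] == current_line) & (df["generation"] == current_gen)]
            prng = _stage_rng(cfg.seed, f"{line}_round{rnd}_parents")
            parents: dict[str, tuple[str, str]] = {}
            final_set: list[str] = []
            for fam in ranking:
                if len(final_set) == cfg.n_families_selected:
                    break
                try:
                    dam, sire = sel.choose_parents(cohort, fam, seed=prng)
                except sel.SelectionError:
                    if fam in chosen:
                        msg = (
                            f"{line} round {rnd}: family {fam} lacks a usable "
                            "parent pair; substituting next-ranked family"
                        )
                        warnings.warn(msg)
                        warn_log.append(msg)
                    continue
                parents[fam] = (dam, sire)
                final_set.append(fam)
            if len(final_set) < cfg.n_families_selected:
                raise PedigreeError(
                    f"{line} round {rnd}: fewer than {cfg.n_families_selected} "
                    "families with a measurable male and a female"
                )
            selected = set(final_set)
            scores = scores.assign(selected=scores["family"].isin(selected))
            rec = scores.assign(line=line, generation=current_gen, round=rnd)
            rec.attrs = {}  # PCA metadata arrays break pd.concat
            fam_records.append(rec)
            diff_rows.append(
                {
                    "line": line,
                    "generation": current_gen,
                    "round": rnd,
                    "disruptive_pc2": sel.disruptive_differential(scores, selected),
                    "directional_pc1": sel.directional_differential(scores, selected, "pc1"),
                    "directional_pc2": sel.directional_differential(scores, selected, "pc2"),
                    "n_males": int(means["n_males"].sum()),
                }
            )
            # breed the next cohort
            next_gen = current_gen + 1
            last = rnd == cfg.n_generations - 1
            n_off = cfg.n_final_offspring_per_family if last else cfg.offspring_per_family
            fam_order = sorted(final_set)
            newplan: CrossPlan = make_circulant_design(fam_order, cfg.offsets)
            brng = _stage_rng(cfg.seed, f"{line}_round{rnd}_breed")
            for j, cross in enumerate(newplan):
                fam = f"{line}_g{next_gen}_f{j:02d}"
                dam, _ = parents[cross.dam_family]
                _, sire = parents[cross.sire_family]
                br.breed_family(fam, sire, dam, line, next_gen, n_off, brng)
            current_line, current_gen = line, next_gen

    ped = Pedigree(pd.DataFrame(br.ped_rows))
    family_records = (
        pd.concat(fam_records, ignore_index=True)
        if fam_records
        else pd.DataFrame(
            columns=["family", "mean_flower", "mean_sla", "n_males", "pc1", "pc2",
                     "selected", "line", "generation", "round"]
        )
    )
    differentials = pd.DataFrame(
        diff_rows,
        columns=["line", "generation", "round", "disruptive_pc2",
                 "directional_pc1", "directional_pc2", "n_males"],
    )
    return ExperimentResult(ped, phenos(), family_records, differentials, warn_log)
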