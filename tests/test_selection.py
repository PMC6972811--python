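"""PCA-on-family-means selection rule and its differentials."""

import numpy as np
import pandas as pd
import pytest

from gmatrixlab import selection as sel


def phenos_frame(records):
    cols = ["id", "family", "line", "generation", "sex", "sla",
            "flower_count", "flower_scaled", "measured"]
    return pd.DataFrame(records, columns=cols)


def scores_frame(pc2, pc1=None, fams=None):
    n = len(pc2)
    return pd.DataFrame({
        "family": fams or [f"f{k}" for k in range(n)],
        "mean_flower": np.zeros(n), "mean_sla": np.zeros(n),
        "n_males": np.ones(n, dtype=int),
        "pc1": pc1 if pc1 is not None else np.zeros(n),
        "pc2": np.asarray(pc2, dtype=float),
        "selected": False,
    })


class TestFamilyMeans:
    def make(self):
        rows = [
            ("a1", "A", "L", 1, "male", 200.0, 10, 115.1, True),
            ("a2", "A", "L", 1, "male", 300.0, 12, 124.2, True),
            ("a3", "A", "L", 1, "female", 250.0, 11, 119.9, True),
            ("b1", "B", "L", 1, "female", 100.0, 9, 109.9, True),
            ("c1", "C", "L", 1, "male", 150.0, 20, 149.8, False),
        ]
        return phenos_frame(rows)

    def test_means_over_measured_males_only(self):
        out = sel.family_means(self.make(), line="L", generation=1)
        assert list(out["family"]) == ["A"]
        assert out["mean_sla"].iloc[0] == pytest.approx(250.0)
        assert out["n_males"].iloc[0] == 2

    def test_row_order_invariance(self):
        df = self.make()
        out1 = sel.family_means(df)
        out2 = sel.family_means(df.sample(frac=1, random_state=3))
        pd.testing.assert_frame_equal(out1, out2)

    def test_no_males_anywhere_errors(self):
        df = self.make()
        df["sex"] = "female"
        with pytest.raises(sel.SelectionError):
            sel.family_means(df)


class TestPCA:
    def corners(self):
        # four families at standardized corners with positive association
        return pd.DataFrame({
            "family": ["f0", "f1", "f2", "f3"],
            "mean_flower": [1.0, -1.0, 1.0, -1.0],
            "mean_sla": [1.0, -1.0, -1.0, 1.0],
            "n_males": [2, 2, 2, 2],
        })

    def test_loadings_match_closed_form_eigendecomposition(self):
        means = self.corners()
        # stretch the (1,1) direction so PC1 is along it
        means.loc[[0, 1], ["mean_flower", "mean_sla"]] *= 2.0
        out = sel.pca_family_means(means, standardize=False)
        V = out.attrs["loadings"]
        # independent 2x2 closed form: C = [[a,b],[b,c]]
        X = means[["mean_flower", "mean_sla"]].to_numpy()
        X = X - X.mean(axis=0)
        C = X.T @ X / (len(X) - 1)
        a, b, c = C[0, 0], C[0, 1], C[1, 1]
        lam1 = 0.5 * (a + c + np.hypot(a - c, 2 * b))
        v1 = np.array([b, lam1 - a])
        v1 = v1 / np.linalg.norm(v1)
        assert abs(abs(V[:, 0] @ v1) - 1) < 1e-10
        assert np.allclose(out.attrs["eigvals"][0], lam1)

    def test_standardized_variance_totals_two(self):
        rng = np.random.default_rng(0)
        means = pd.DataFrame({
            "family": [f"f{k}" for k in range(30)],
            "mean_flower": rng.normal(230, 5, 30),
            "mean_sla": rng.normal(250, 30, 30),
            "n_males": 3,
        })
        out = sel.pca_family_means(means)
        total = out["pc1"].var(ddof=1) + out["pc2"].var(ddof=1)
        assert total == pytest.approx(2.0)
        assert out["pc1"].mean() == pytest.approx(0.0, abs=1e-12)
        assert out["pc2"].mean() == pytest.approx(0.0, abs=1e-12)
        V = out.attrs["loadings"]
        assert np.allclose(V @ V.T, np.eye(2))
        assert np.linalg.det(V) == pytest.approx(1.0)
        assert V[1, 0] >= 0

    def test_perfectly_correlated_traits_have_zero_pc2(self):
        means = pd.DataFrame({
            "family": ["a", "b", "c", "d"],
            "mean_flower": [1.0, 2.0, 3.0, 4.0],
            "mean_sla": [10.0, 20.0, 30.0, 40.0],
            "n_males": 1,
        })
        out = sel.pca_family_means(means)
        assert np.allclose(out["pc2"], 0.0, atol=1e-10)

    def test_zero_variance_trait_rejected(self):
        means = pd.DataFrame({
            "family": ["a", "b", "c"], "mean_flower": [1.0, 1.0, 1.0],
            "mean_sla": [1.0, 2.0, 3.0], "n_males": 1,
        })
        with pytest.raises(sel.SelectionError):
            sel.pca_family_means(means)


class TestSelectionRules:
    def test_disruptive_matches_sort_oracle(self):
        rng = np.random.default_rng(1)
        pc2 = rng.normal(size=24)
        scores = scores_frame(pc2)
        chosen = sel.select_families_disruptive(scores, k_each=4)
        assert len(chosen) == 8
        order = scores.sort_values("pc2")
        oracle = set(order["family"].head(4)) | set(order["family"].tail(4))
        assert chosen == oracle

    def test_k_each_half_selects_everyone(self):
        scores = scores_frame([1.0, -1.0, 2.0, -2.0])
        assert sel.select_families_disruptive(scores, k_each=2) == set(scores["family"])

    def test_too_few_families_rejected(self):
        with pytest.raises(sel.SelectionError):
            sel.select_families_disruptive(scores_frame([1.0, 2.0]), k_each=2)

    def test_random_selection_deterministic_under_seed(self):
        scores = scores_frame(np.arange(10.0))
        assert (sel.select_families_random(scores, k=4, seed=7)
                == sel.select_families_random(scores, k=4, seed=7))
        assert sel.select_families_random(scores, k=10, seed=0) == set(scores["family"])

    def test_random_selection_is_uniform(self):
        scores = scores_frame(np.arange(6.0))
        rng = np.random.default_rng(0)
        counts = {f: 0 for f in scores["family"]}
        reps = 4000
        for _ in range(reps):
            for f in sel.select_families_random(scores, k=2, seed=rng):
                counts[f] += 1
        freqs = np.array([counts[f] / reps for f in scores["family"]])
        assert np.allclose(freqs, 2 / 6, atol=0.03)


class TestDifferentials:
    def test_hand_computed_disruptive_value(self):
        scores = scores_frame([-2.0, -1.0, 0.0, 1.0, 2.0])
        selected = {"f0", "f4"}
        assert sel.disruptive_differential(scores, selected) == pytest.approx(0.8)

    def test_select_all_gives_zero(self):
        scores = scores_frame([-1.0, 0.5, 2.0])
        assert sel.disruptive_differential(scores, set(scores["family"])) == 0.0
        assert sel.directional_differential(scores, set(scores["family"]), "pc2") == 0.0

    def test_disruptive_rule_always_nonnegative(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            scores = scores_frame(rng.normal(size=12))
            chosen = sel.select_families_disruptive(scores, k_each=2)
            assert sel.disruptive_differential(scores, chosen) >= -1e-12

    def test_directional_hand_value_and_symmetry(self):
        scores = scores_frame(pc2=[0.0] * 4, pc1=[1.0, 2.0, 3.0, 4.0])
        assert sel.directional_differential(scores, {"f2", "f3"}, "pc1") == \
            pytest.approx(1.0)
        sym = scores_frame([-2.0, -1.0, 1.0, 2.0])
        assert sel.directional_differential(sym, {"f0", "f3"}, "pc2") == \
            pytest.approx(0.0)


class TestChooseParents:
    def cohort(self, seed=0, n_fam=4, n_per=6):
        rng = np.random.default_rng(seed)
        rows = []
        for f in range(n_fam):
            for k in range(n_per):
                sex = "male" if k % 2 == 0 else "female"
                rows.append((f"i{f}_{k}", f"fam{f}", "L", 1, sex,
                             rng.normal(250, 30), 10,
                             rng.normal(230, 10), sex == "male"))
        return phenos_frame(rows)

    def test_single_male_is_chosen(self):
        rows = [("m1", "A", "L", 1, "male", 250.0, 10, 230.0, True),
                ("f1", "A", "L", 1, "female", 250.0, 10, 230.0, False)]
        dam, sire = sel.choose_parents(phenos_frame(rows), "A", seed=0)
        assert (dam, sire) == ("f1", "m1")

    def test_sire_matches_brute_force_scan(self):
        ph = self.cohort(seed=5)
        males = ph[(ph["sex"] == "male") & ph["measured"]]
        mu = males[["flower_scaled", "sla"]].mean().to_numpy()
        sd = males[["flower_scaled", "sla"]].std(ddof=1).to_numpy()
        for fam in ph["family"].unique():
            _, sire = sel.choose_parents(ph, fam, seed=1)
            fam_males = males[males["family"] == fam]
            Z = (fam_males[["flower_scaled", "sla"]].to_numpy() - mu) / sd
            d = np.linalg.norm(Z - Z.mean(axis=0), axis=1)
            best = fam_males["id"].to_numpy()[np.argmin(d)]
            assert sire == best

    def test_family_without_female_errors(self):
        rows = [("m1", "A", "L", 1, "male", 250.0, 10, 230.0, True)]
        with pytest.raises(sel.SelectionError, match="A"):
            sel.choose_parents(phenos_frame(rows), "A", seed=0)
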