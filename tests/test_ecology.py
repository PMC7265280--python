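"""Community statistics: formulas, permutation correctness, NMDS quality."""

import itertools
import math
import subprocess
import tempfile
import textwrap

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import cdist
from skbio import DistanceMatrix

from operonscope import ecology as eco
from operonscope.bbh import CountTable


from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays


def _table(rows, ids=None, cols=None):
    rows = np.asarray(rows, dtype=float)
    ids = ids or [f"s{i}" for i in range(rows.shape[0])]
    cols = cols or [f"t{i}" for i in range(rows.shape[1])]
    return CountTable(pd.DataFrame(rows, index=ids, columns=cols))


def _meta(ids, activity=None, genotype=None):
    n = len(ids)
    return pd.DataFrame({
        "sample_id": ids,
        "genotype": genotype or ["WT"] * n,
        "activity": activity or ["exercise"] * n,
    })


class TestTransformsAndBrayCurtis:
    def test_fourth_root_closed_forms(self):
        t = _table([[0, 1, 16, 81]])
        out = eco.fourth_root(t)
        assert list(out.counts.iloc[0]) == [0, 1, 2, 3]

    def test_fourth_root_rejects_negative(self):
        with pytest.raises(ValueError):
            eco.fourth_root(_table([[-1, 2]]))

    def test_bray_curtis_hand_examples(self):
        d = eco.bray_curtis(_table([[1, 1, 0], [0, 1, 1]]))
        assert d.data[0, 1] == pytest.approx(0.5)
        d2 = eco.bray_curtis(_table([[3, 1, 2], [3, 1, 2]]))
        assert d2.data[0, 1] == 0.0
        d3 = eco.bray_curtis(_table([[1, 1, 0, 0], [0, 0, 2, 5]]))
        assert d3.data[0, 1] == pytest.approx(1.0)

    def test_bray_curtis_axioms_on_random_tables(self, rng):
        for _ in range(10):
            X = rng.integers(0, 40, (6, 8)).astype(float)
            X[0] = X[1]  # force one identical pair
            d = eco.bray_curtis(_table(X))
            assert np.allclose(d.data, d.data.T, atol=1e-12)
            assert np.allclose(np.diag(d.data), 0)
            assert d.data[0, 1] == pytest.approx(0.0)
            assert ((d.data >= 0) & (d.data <= 1)).all()

    def test_all_zero_pair_is_zero_with_warning(self, caplog):
        d = eco.bray_curtis(_table([[0, 0], [0, 0], [1, 2]]))
        assert d.data[0, 1] == 0.0

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(arrays(float, (4, 6), elements=st.integers(0, 50).map(float)))
    def test_bray_curtis_semimetric_properties(self, X):
        """Identity and symmetry hold for every non-negative table (the
        triangle inequality is deliberately not asserted: Bray-Curtis
        is a semimetric)."""
        d = eco.bray_curtis(_table(X))
        assert np.allclose(d.data, d.data.T, atol=1e-12)
        assert np.allclose(np.diag(d.data), 0.0)
        assert ((d.data > -1e-12) & (d.data < 1 + 1e-12)).all()


class TestNMDS:
    def test_exact_planar_distances_embed_below_stress_001(self, rng):
        P = rng.standard_normal((6, 2))
        d = DistanceMatrix(cdist(P, P), ids=list("abcdef"))
        res = eco.nmds(d, n_starts=4, seed=1)
        assert res.stress < 0.01

    def test_best_of_starts_is_monotone(self, rng):
        X = rng.integers(0, 30, (7, 5)).astype(float)
        d = eco.bray_curtis(_table(X))
        s1 = eco.nmds(d, n_starts=1, seed=2).stress
        s8 = eco.nmds(d, n_starts=8, seed=2).stress
        assert s8 <= s1 + 1e-12

    def test_three_equidistant_points_embed_exactly(self):
        d = DistanceMatrix(np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]], float),
                           ids=list("abc"))
        res = eco.nmds(d, n_starts=2, seed=0)
        assert res.stress == pytest.approx(0.0, abs=1e-6)

    def test_stress_invariant_under_similarity_transform(self, rng):
        """Kruskal stress-1 depends only on the configuration's distances,
        which rotation/translation/uniform scaling preserve up to the
        monotone regression's scale freedom."""
        X = rng.integers(0, 30, (6, 4)).astype(float)
        d = eco.bray_curtis(_table(X))
        res = eco.nmds(d, n_starts=4, seed=3)
        Y = res.coordinates.values
        theta = 0.7
        R = np.array([[math.cos(theta), -math.sin(theta)],
                      [math.sin(theta), math.cos(theta)]])
        for Z in (Y @ R, Y + 3.5, Y * 2.0):
            iu = np.triu_indices(len(Z), 1)
            cd = cdist(Z, Z)[iu]
            diss = d.data[iu]
            dhat = eco._disparities(diss, cd)
            assert eco.kruskal_stress(cd, dhat) == pytest.approx(res.stress, abs=1e-9)

    def test_requires_enough_samples(self):
        d = DistanceMatrix(np.zeros((2, 2)), ids=["a", "b"])
        with pytest.raises(ValueError):
            eco.nmds(d, k=2)


def _oracle_two_group_permanova(D, labels):
    """Independent PERMANOVA oracle from the group-sum formulation:
    SS_total = sum d^2 / n; SS_within = per-group sums; F from the ratio."""
    n = len(labels)
    D2 = D ** 2
    iu = np.triu_indices(n, 1)
    ss_total = D2[iu].sum() / n
    ss_within = 0.0
    for g in set(labels):
        idx = [i for i, l in enumerate(labels) if l == g]
        sub = D2[np.ix_(idx, idx)]
        ss_within += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
    ss_between = ss_total - ss_within
    a = len(set(labels))
    return (ss_between / (a - 1)) / (ss_within / (n - a))


class TestPermanova:
    def test_exact_p_matches_exhaustive_oracle(self):
        """For a 6-sample two-group design the permutation p equals the
        fraction of all label assignments with F >= observed, computed by
        an independent enumeration of the 20 splits."""
        rng = np.random.default_rng(5)
        X = rng.integers(0, 30, (6, 5)).astype(float)
        ids = [f"s{i}" for i in range(6)]
        d = eco.bray_curtis(_table(X, ids=ids))
        labels = ["a", "a", "a", "b", "b", "b"]
        meta = _meta(ids, activity=["exercise" if l == "a" else "sedentary"
                                    for l in labels])
        res = eco.permanova(d, meta, terms=("activity",), n_perm=None)

        F_obs = _oracle_two_group_permanova(d.data, labels)
        assert res.table.loc["activity", "pseudo_F"] == pytest.approx(F_obs)
        count = total = 0
        for pos in itertools.combinations(range(6), 3):
            lab = ["b"] * 6
            for i in pos:
                lab[i] = "a"
            F = _oracle_two_group_permanova(d.data, lab)
            count += F >= F_obs - 1e-12
            total += 1
        assert res.table.loc["activity", "p_value"] == pytest.approx(count / total)

    def test_perfectly_separated_groups_reach_minimum_p(self):
        X = np.array([[1, 0]] * 3 + [[0, 1]] * 3, dtype=float)
        ids = [f"s{i}" for i in range(6)]
        d = eco.bray_curtis(_table(X, ids=ids))
        meta = _meta(ids, activity=["exercise"] * 3 + ["sedentary"] * 3)
        res = eco.permanova(d, meta, terms=("activity",), n_perm=None)
        assert res.table.loc["activity", "R2"] == pytest.approx(1.0, abs=1e-9)
        assert res.table.loc["activity", "p_value"] == pytest.approx(2 / 20)

    def test_matches_vegan_adonis2_sequential_decomposition(self):
        """SS, R2 and pseudo-F for the two-factor model with interaction
        agree with vegan's adonis2 (by='terms') on a random table."""
        rng = np.random.default_rng(42)
        X = rng.integers(1, 50, (10, 6)).astype(float)
        ids = [f"s{i}" for i in range(10)]
        d = eco.bray_curtis(_table(X, ids=ids))
        meta = _meta(ids, genotype=["WT"] * 5 + ["AC5KO"] * 5,
                     activity=["exercise", "sedentary"] * 5)
        res = eco.permanova(d, meta, n_perm=99, seed=1)
        with tempfile.TemporaryDirectory() as td:
            np.savetxt(f"{td}/d.tsv", d.data, delimiter="\t")
            meta.to_csv(f"{td}/m.tsv", sep="\t", index=False)
            script = textwrap.dedent(f"""
                suppressMessages(library(vegan))
                d <- as.dist(as.matrix(read.table("{td}/d.tsv")))
                m <- read.table("{td}/m.tsv", header=TRUE, sep="\\t")
                a <- adonis2(d ~ activity * genotype, data=m,
                             permutations=9, by="terms")
                write.csv(data.frame(SS=a$SumOfSqs, R2=a$R2, F=a$F),
                          "{td}/out.csv", row.names=FALSE)
            """)
            subprocess.run(["Rscript", "-e", script], check=True,
                           capture_output=True, timeout=120)
            ref = pd.read_csv(f"{td}/out.csv")
        for i, term in enumerate(["activity", "genotype", "activity:genotype"]):
            assert res.table.loc[term, "SS"] == pytest.approx(ref["SS"][i], rel=1e-9)
            assert res.table.loc[term, "R2"] == pytest.approx(ref["R2"][i], rel=1e-9)
            assert res.table.loc[term, "pseudo_F"] == pytest.approx(ref["F"][i], rel=1e-9)

    def test_null_rejection_rate_is_calibrated(self):
        """Under a null with shuffled labels the test rejects at the
        nominal 5% rate (95% binomial interval over 500 simulations)."""
        rng = np.random.default_rng(17)
        ids = [f"s{i}" for i in range(12)]
        rejections = 0
        n_sim = 500
        for k in range(n_sim):
            X = rng.integers(0, 30, (12, 6)).astype(float) + 1
            d = eco.bray_curtis(_table(X, ids=ids))
            meta = _meta(ids, activity=list(rng.permutation(
                ["exercise"] * 6 + ["sedentary"] * 6)))
            res = eco.permanova(d, meta, terms=("activity",), n_perm=199, seed=k)
            rejections += res.table.loc["activity", "p_value"] <= 0.05
        rate = rejections / n_sim
        half = 1.96 * math.sqrt(0.05 * 0.95 / n_sim)
        assert 0.05 - half <= rate <= 0.05 + half

    def test_term_order_and_r2_bookkeeping(self):
        rng = np.random.default_rng(3)
        X = rng.integers(1, 40, (12, 5)).astype(float)
        ids = [f"s{i}" for i in range(12)]
        d = eco.bray_curtis(_table(X, ids=ids))
        meta = _meta(ids, genotype=["WT"] * 6 + ["AC5KO"] * 6,
                     activity=["exercise", "sedentary"] * 6)
        res = eco.permanova(d, meta, n_perm=49, seed=0)
        assert list(res.table.index) == ["activity", "genotype",
                                         "activity:genotype", "Residual", "Total"]
        non_total = res.table.loc[res.table.index != "Total", "R2"].sum()
        assert non_total == pytest.approx(1.0, abs=1e-9)
        pmin = 1 / (49 + 1)
        pvals = res.table.loc[["activity", "genotype"], "p_value"]
        assert ((pvals >= pmin) & (pvals <= 1)).all()

    def test_underdetermined_designs_rejected(self):
        ids = [f"s{i}" for i in range(4)]
        d = DistanceMatrix(np.ones((4, 4)) - np.eye(4), ids=ids)
        meta = _meta(ids, genotype=["WT", "WT", "AC5KO", "AC5KO"],
                     activity=["exercise", "sedentary"] * 2)
        with pytest.raises(ValueError):
            eco.permanova(d, meta, terms=("activity", "genotype", "activity:genotype"))


class TestAlphaDiversity:
    def test_uniform_shannon_is_log_richness(self):
        t = _table([[5, 5, 5, 5]])
        out = eco.alpha_diversity(t)
        assert out["shannon"].iloc[0] == pytest.approx(math.log(4))

    def test_chao1_equals_observed_without_rares(self):
        t = _table([[5, 5, 5, 5]])
        assert eco.alpha_diversity(t)["chao1"].iloc[0] == pytest.approx(4.0)

    def test_chao1_and_shannon_bounds(self, rng):
        for _ in range(10):
            x = rng.integers(0, 20, 15)
            if x.sum() == 0:
                continue
            out = eco.alpha_diversity(_table([x]))
            s_obs = (x > 0).sum()
            assert out["chao1"].iloc[0] >= s_obs - 1e-9
            assert out["shannon"].iloc[0] <= math.log(max(s_obs, 1)) + 1e-9

    def test_rarefaction_full_depth_and_monotonicity(self):
        counts = np.array([5, 5, 5, 5])
        curve = eco.rarefaction_curve(counts, [1, 4, 10, 20])
        assert curve["expected_richness"].iloc[-1] == pytest.approx(4.0)
        assert curve["expected_richness"].is_monotonic_increasing
        assert curve["expected_richness"].iloc[0] == pytest.approx(1.0)

    def test_rarefaction_hand_value(self):
        # E[S | depth 4 of (5,5,5,5)] = 4 * (1 - C(15,4)/C(20,4))
        expected = 4 * (1 - (math.comb(15, 4) / math.comb(20, 4)))
        curve = eco.rarefaction_curve(np.array([5, 5, 5, 5]), [4])
        assert curve["expected_richness"].iloc[0] == pytest.approx(expected)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            eco.alpha_diversity(_table([[0, 0]]))
        with pytest.raises(ValueError):
            eco.rarefaction_curve(np.array([0, 0]), [1])


class TestEnrichment:
    def test_exclusive_taxon_difference_is_group_mean(self):
        ids = [f"s{i}" for i in range(4)]
        t = _table([[10, 1], [14, 1], [0, 1], [0, 1]], ids=ids, cols=["A", "B"])
        meta = _meta(ids, activity=["exercise"] * 2 + ["sedentary"] * 2)
        out = eco.enrichment(t, meta, "activity", top_k=2)
        row = out[out["taxon"] == "A"].iloc[0]
        assert row["difference"] == pytest.approx(12.0)
        assert row["enriched_group"] == "exercise"

    def test_programmed_threefold_enrichment_ranks_first(self):
        rng = np.random.default_rng(8)
        ids = [f"s{i}" for i in range(6)]
        base = rng.integers(20, 30, (6, 5)).astype(float)
        base[:3, 2] *= 3  # taxon t2 enriched in the first group
        meta = _meta(ids, activity=["exercise"] * 3 + ["sedentary"] * 3)
        out = eco.enrichment(_table(base, ids=ids), meta, "activity")
        assert out.iloc[0]["taxon"] == "t2"

    def test_equal_means_rank_last(self):
        ids = [f"s{i}" for i in range(4)]
        t = _table([[5, 9], [5, 11], [5, 2], [5, 4]], ids=ids, cols=["A", "B"])
        meta = _meta(ids, activity=["exercise"] * 2 + ["sedentary"] * 2)
        out = eco.enrichment(t, meta, "activity", top_k=1)
        assert list(out["taxon"]) == ["B"]

    def test_requires_two_level_grouping(self):
        ids = ["s0", "s1"]
        t = _table([[1, 2], [3, 4]], ids=ids)
        with pytest.raises(ValueError):
            eco.enrichment(t, _meta(ids), "activity")
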