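import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from relapsegrn.config import PipelineConfig
from relapsegrn.containers import CountMatrix, DEGSet
from relapsegrn.diffexpr import (
    call_degs,
    filter_functional_terms,
    nb_wald_test,
    overlap_sets,
    size_factors,
)
from relapsegrn.simulate import simulate_counts


def brute_force_size_factors(mat: pd.DataFrame) -> np.ndarray:
    """Median-of-ratios straight from the definition."""
    vals = mat.to_numpy(dtype=float)
    keep = (vals > 0).all(axis=1)
    ref = np.exp(np.log(vals[keep]).mean(axis=1))
    ratios = vals[keep] / ref[:, None]
    f = np.median(ratios, axis=0)
    return f / np.exp(np.mean(np.log(f)))


def make_cm(values: np.ndarray) -> CountMatrix:
    n = values.shape[1]
    cols = [f"s{i}" for i in range(n)]
    counts = pd.DataFrame(
        values.astype("int64"),
        index=[f"g{i}" for i in range(values.shape[0])],
        columns=cols,
    )
    groups = pd.Series(["A"] * (n // 2) + ["B"] * (n - n // 2), index=cols)
    return CountMatrix(counts=counts, groups=groups)


class TestSizeFactors:
    def test_identical_columns_give_unit_factors(self):
        v = np.tile(np.array([[5], [10], [20], [7]]), (1, 4))
        f = size_factors(make_cm(v))
        np.testing.assert_allclose(f, 1.0)

    def test_doubled_column_scale_equivariance(self):
        base = np.array([[5, 5, 5, 5], [10, 10, 10, 10], [20, 20, 20, 20]])
        v = base.copy()
        v[:, 1] *= 2
        f = size_factors(make_cm(v))
        np.testing.assert_allclose(f.iloc[1] / f.iloc[0], 2.0)
        np.testing.assert_allclose(np.exp(np.mean(np.log(f))), 1.0)

    def test_matches_brute_force_on_random_matrices(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            v = rng.integers(1, 500, size=(50, 4))
            cm = make_cm(v)
            np.testing.assert_allclose(
                size_factors(cm).to_numpy(),
                brute_force_size_factors(cm.counts),
                rtol=1e-12,
            )

    def test_no_all_positive_gene_errors(self):
        v = np.array([[0, 1, 1, 1], [1, 0, 1, 1], [1, 1, 0, 1], [1, 1, 1, 0]])
        with pytest.raises(ValueError, match="positive"):
            size_factors(make_cm(v))


class TestNbWaldTest:
    def test_all_zero_gene_reported_not_dropped(self):
        v = np.array([[10, 12, 11, 9], [0, 0, 0, 0], [5, 6, 30, 33]])
        res = nb_wald_test(make_cm(v))
        assert res.loc["g1", "log2FC"] == 0.0
        assert res.loc["g1", "pvalue"] == 1.0
        assert len(res) == 3

    def test_fold_change_arithmetic(self):
        """Group means ~100 vs ~400 give log2FC ~ 2 (pseudocount 0.5)."""
        v = np.array([[100, 100, 400, 400], [50, 50, 50, 50]] * 2)
        res = nb_wald_test(make_cm(v), factors=pd.Series(1.0, index=[f"s{i}" for i in range(4)]))
        expected = np.log2(400.5 / 100.5)
        np.testing.assert_allclose(res.loc["g0", "log2FC"], expected, rtol=1e-12)

    def test_recovery_of_planted_genes(self):
        """Ranking by p-value separates planted DE genes (AUROC > 0.95)."""
        cm, truth = simulate_counts(2000, 5, 0.1, 2.0, 0.1, seed=17)
        res = nb_wald_test(cm)
        labels = np.array([g in truth.de_genes for g in res.index])
        order = np.argsort(res["pvalue"].to_numpy(), kind="stable")
        ranks = np.empty(len(labels))
        ranks[order] = np.arange(len(labels))
        # AUROC via rank-sum (smaller p should mean DE)
        pos = ranks[labels]
        neg = ranks[~labels]
        auroc = 1.0 - (pos.mean() - (len(pos) - 1) / 2) / len(neg)
        assert auroc > 0.95

    def test_bh_applied(self):
        cm, _ = simulate_counts(100, 3, 0.0, seed=2)
        res = nb_wald_test(cm)
        assert (res["padj"] >= res["pvalue"] - 1e-15).all()
        assert res["padj"].between(0, 1).all()


class TestCallDegs:
    @pytest.mark.parametrize(
        "padj,lfc,kept,direction",
        [
            (0.04, 2.0, True, 1),
            (0.04, 1.5, True, 1),  # inclusive boundary
            (0.05, -1.5, True, -1),  # both boundaries inclusive
            (0.06, 3.0, False, None),
            (0.04, 1.49, False, None),
        ],
    )
    def test_threshold_rules(self, padj, lfc, kept, direction):
        table = pd.DataFrame(
            {"log2FC": [lfc], "pvalue": [padj], "padj": [padj]},
            index=pd.Index(["g1"], name="gene"),
        )
        degs = call_degs(table, PipelineConfig())
        assert ("g1" in degs) is kept
        if kept:
            assert degs.direction["g1"] == direction

    @given(
        alpha=st.floats(0.01, 0.2),
        tighter=st.floats(0.0, 0.9),
        lfc_t=st.floats(0.0, 3.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_monotone_under_tightening(self, alpha, tighter, lfc_t):
        rng = np.random.default_rng(0)
        table = pd.DataFrame(
            {
                "log2FC": rng.normal(0, 2, 50),
                "padj": rng.uniform(0, 1, 50),
            },
            index=pd.Index([f"g{i}" for i in range(50)], name="gene"),
        )
        loose = call_degs(table, PipelineConfig(fdr_alpha=alpha, lfc_threshold=lfc_t))
        tight = call_degs(
            table,
            PipelineConfig(fdr_alpha=alpha * (1 - tighter) or 1e-9, lfc_threshold=lfc_t + 0.5),
        )
        assert tight.genes <= loose.genes


class TestFilterFunctionalTerms:
    def test_direct_and_descendant_removal(self, small_dag):
        degs = DEGSet(genes={"x", "y", "z"})
        annot = {"x": {"a"}, "y": {"c"}, "z": {"e"}}
        filtered, removed = filter_functional_terms(degs, annot, small_dag, ["a"])
        # x annotated to 'a' itself, y to its is_a child 'c'; z unaffected
        assert removed == ["x", "y"]
        assert filtered.genes == {"z"}

    def test_part_of_descendants_excluded(self, small_dag):
        degs = DEGSet(genes={"w"})
        annot = {"w": {"f"}}  # f -part_of-> a
        filtered, removed = filter_functional_terms(degs, annot, small_dag, ["a"])
        assert removed == ["w"]

    def test_empty_exclusion_is_identity(self, small_dag):
        degs = DEGSet(genes={"x"})
        filtered, removed = filter_functional_terms(degs, {"x": {"a"}}, small_dag, [])
        assert filtered.genes == degs.genes and removed == []

    def test_unknown_term_errors(self, small_dag):
        with pytest.raises(ValueError, match="nope"):
            filter_functional_terms(DEGSet(genes={"x"}), {}, small_dag, ["nope"])

    def test_idempotent(self, small_dag):
        degs = DEGSet(genes={"x", "y"})
        annot = {"x": {"c"}, "y": {"e"}}
        once, _ = filter_functional_terms(degs, annot, small_dag, ["a"])
        twice, removed2 = filter_functional_terms(once, annot, small_dag, ["a"])
        assert twice.genes == once.genes and removed2 == []


class TestOverlapSets:
    def test_two_set_regions(self):
        df = overlap_sets({"s1": {"a", "b"}, "s2": {"b", "c"}})
        regions = dict(zip(df["region"], df["genes"]))
        assert regions["s1|s2"] == "b"
        assert regions["s1"] == "a"
        assert regions["s2"] == "c"

    def test_identical_sets(self):
        df = overlap_sets({"x": {"a", "b"}, "y": {"a", "b"}})
        assert df.loc[df["region"] == "x|y", "count"].item() == 2

    def test_four_sets_against_pattern_enumeration(self):
        rng = np.random.default_rng(23)
        universe = [f"g{i}" for i in range(60)]
        sets = {
            f"s{j}": set(rng.choice(universe, rng.integers(5, 30), replace=False))
            for j in range(4)
        }
        df = overlap_sets(sets)
        # brute force: every membership pattern over the 4 sets
        names = list(sets)
        expect = {}
        for pattern in itertools.product([True, False], repeat=4):
            if not any(pattern):
                continue
            members = set.union(*sets.values())
            for name, inside in zip(names, pattern):
                members = members & sets[name] if inside else members - sets[name]
            if members:
                expect["|".join(n for n, p in zip(names, pattern) if p)] = members
        got = {
            r: set(g.split(","))
            for r, g in zip(df["region"], df["genes"])
        }
        assert got == expect
        assert df["count"].sum() == len(set.union(*sets.values()))

    def test_requires_two_sets(self):
        with pytest.raises(ValueError):
            overlap_sets({"only": {"a"}})
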