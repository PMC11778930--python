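import numpy as np
import pandas as pd
import pytest

from utrterm.quant import (
    size_factors_median_of_ratios,
    normalize_counts,
    spearman_trimmed,
    top_n_intersection,
    translation_efficiency,
    utr3_rpkm,
)


def log_space_oracle(counts):
    """Independent median-of-ratios: median of log-ratios, exponentiated."""
    v = counts.to_numpy(dtype=float)
    mask = (v > 0).all(axis=1)
    logs = np.log(v[mask])
    ref = logs.mean(axis=1)
    return np.exp(np.median(logs - ref[:, None], axis=0))


class TestSizeFactors:
    def test_identical_samples_give_unit_factors(self, rng):
        col = rng.integers(1, 500, 50)
        counts = pd.DataFrame({"s1": col, "s2": col})
        assert size_factors_median_of_ratios(counts).to_numpy() == pytest.approx([1.0, 1.0])

    def test_doubled_sample_gives_sqrt2_factors(self, rng):
        a = rng.integers(1, 500, 100)
        counts = pd.DataFrame({"A": a, "B": 2 * a})
        sf = size_factors_median_of_ratios(counts)
        assert sf["A"] == pytest.approx(1 / np.sqrt(2), abs=1e-12)
        assert sf["B"] == pytest.approx(np.sqrt(2), abs=1e-12)
        norm = normalize_counts(counts)
        assert np.allclose(norm["A"], norm["B"], atol=1e-10)

    def test_matches_log_space_oracle(self, rng):
        counts = pd.DataFrame(
            rng.integers(0, 1000, size=(100, 4)), columns=list("wxyz")
        )
        counts.iloc[:50] += 1  # ensure all-positive genes exist
        sf = size_factors_median_of_ratios(counts)
        assert sf.to_numpy() == pytest.approx(log_space_oracle(counts), abs=1e-10)

    def test_scale_equivariance(self, rng):
        counts = pd.DataFrame(rng.integers(1, 1000, size=(80, 3)), columns=list("abc"))
        base = size_factors_median_of_ratios(counts)
        for c in (2, 5):
            scaled = counts.copy()
            scaled["b"] = scaled["b"] * c
            sf = size_factors_median_of_ratios(scaled)
            assert sf["b"] == pytest.approx(c * base["b"] * (1 / c) ** (1 / 3), rel=1e-10)
            # equivalently: ratios to the other samples scale by c
            assert sf["b"] / sf["a"] == pytest.approx(c * base["b"] / base["a"], rel=1e-10)

    def test_no_all_positive_gene_rejected(self):
        counts = pd.DataFrame({"s1": [0, 5], "s2": [5, 0]})
        with pytest.raises(ValueError, match="positive"):
            size_factors_median_of_ratios(counts)


class TestTranslationEfficiency:
    def test_identical_matrices_give_unit_te(self, rng):
        m = pd.DataFrame(
            rng.integers(1, 500, size=(40, 4)),
            columns=["u1", "u2", "d1", "d2"],
            index=[f"g{i}" for i in range(40)],
        )
        cond = {"u1": "undiff", "u2": "undiff", "d1": "diff", "d2": "diff"}
        table, excluded = translation_efficiency(m, m.copy(), cond,
                                                 log2fc_conditions=("diff", "undiff"))
        assert excluded == []
        assert table["te_undiff"].to_numpy() == pytest.approx(1.0)
        assert table["te_diff"].to_numpy() == pytest.approx(1.0)
        assert table["log2fc_te"].to_numpy() == pytest.approx(0.0, abs=1e-12)

    def test_doubled_rpf_condition_doubles_te(self, rng):
        genes = [f"g{i}" for i in range(100)]
        base = rng.integers(50, 500, size=100)
        mrna = pd.DataFrame({"u1": base, "d1": base}, index=genes)
        rpf = pd.DataFrame({"u1": base, "d1": base}, index=genes)
        # double RPF in 'diff' for 10% of genes while keeping size factors
        # pinned by the unchanged 90% majority
        rpf_mod = rpf.copy()
        rpf_mod.loc[genes[:10], "d1"] = 2 * rpf_mod.loc[genes[:10], "d1"]
        cond = {"u1": "undiff", "d1": "diff"}
        table, _ = translation_efficiency(rpf_mod, mrna, cond)
        ratio = table["te_diff"] / table["te_undiff"]
        assert ratio.loc[genes[:10]].to_numpy() == pytest.approx(2.0)
        assert ratio.loc[genes[10:]].to_numpy() == pytest.approx(1.0)

    def test_zero_mrna_gene_excluded_and_flagged(self):
        rpf = pd.DataFrame({"s": [10, 20]}, index=["g1", "g2"])
        mrna = pd.DataFrame({"s": [10, 0]}, index=["g1", "g2"])
        table, excluded = translation_efficiency(rpf, mrna, {"s": "c"})
        assert excluded == ["g2"]
        assert list(table.index) == ["g1"]

    def test_disjoint_gene_sets_rejected(self):
        rpf = pd.DataFrame({"s": [1]}, index=["g1"])
        mrna = pd.DataFrame({"s": [1]}, index=["g2"])
        with pytest.raises(ValueError, match="shared gene"):
            translation_efficiency(rpf, mrna, {"s": "c"})


class TestUtr3Rpkm:
    def test_analytic_value(self):
        out = utr3_rpkm(
            pd.Series({"g1": 10}), pd.Series({"g1": 1000}), library_size=1e6
        )
        assert out.loc["g1", "rpkm"] == 10.0

    def test_zero_count(self):
        out = utr3_rpkm(pd.Series({"g1": 0}), pd.Series({"g1": 500}), 1e6)
        assert out.loc["g1", "rpkm"] == 0.0

    def test_min_length_is_strict(self):
        out = utr3_rpkm(
            pd.Series({"g1": 5, "g2": 5}),
            pd.Series({"g1": 50, "g2": 51}),
            1e6,
        )
        assert list(out.index) == ["g2"]


class TestSpearmanTrimmed:
    def test_monotone_pairs(self):
        x = np.arange(100.0)
        rho, n = spearman_trimmed(x, x**3)
        assert rho == pytest.approx(1.0, abs=1e-12)
        rho, _ = spearman_trimmed(x, -x)
        assert rho == pytest.approx(-1.0, abs=1e-12)

    def test_matches_closed_form_without_ties(self, rng):
        for _ in range(20):
            n = int(rng.integers(5, 11))
            x = rng.permutation(n).astype(float)
            y = rng.permutation(n).astype(float)
            rho, n_used = spearman_trimmed(x, y, trim_pct=100.0)
            d = np.argsort(np.argsort(x)) - np.argsort(np.argsort(y))
            expected = 1 - 6 * (d**2).sum() / (n * (n**2 - 1))
            assert n_used == n and rho == pytest.approx(expected, abs=1e-12)

    def test_trim_drops_top_percentile_of_y_only(self):
        x = np.arange(200.0)
        y = np.arange(200.0)
        y[-1] = 1e9  # extreme y outlier
        rho, n_used = spearman_trimmed(x, y, trim_pct=99.0)
        assert n_used == 198  # 99th percentile cutoff (linear interpolation)
        assert rho == 1.0

    def test_invariant_under_monotone_x_transform(self, rng):
        x = rng.lognormal(0, 1, 300)
        y = rng.lognormal(0, 1, 300)
        r1, _ = spearman_trimmed(x, y)
        r2, _ = spearman_trimmed(np.log(x), y)
        r3, _ = spearman_trimmed(x**2, y)
        assert r1 == pytest.approx(r2, abs=1e-12)
        assert r1 == pytest.approx(r3, abs=1e-12)

    def test_too_few_pairs_after_trim_rejected(self):
        with pytest.raises(ValueError):
            spearman_trimmed([1.0, 2.0], [1.0, 2.0])


class TestTopNIntersection:
    def test_identical_lists(self):
        lists = [[f"g{i}" for i in range(20)]] * 3
        common, pairwise = top_n_intersection(lists, 10)
        assert len(common) == 10
        assert pairwise == {(0, 1): 10, (0, 2): 10, (1, 2): 10}

    def test_disjoint_lists(self):
        common, pairwise = top_n_intersection([["a", "b"], ["c", "d"]], 2)
        assert common == set() and pairwise == {(0, 1): 0}

    def test_constructed_lists_match_hand_tally(self):
        l1 = ["a", "b", "c", "d", "e"]
        l2 = ["b", "a", "x", "y", "c"]
        l3 = ["z", "b", "a", "q", "r"]
        common, pairwise = top_n_intersection([l1, l2, l3], 3)
        assert common == {"a", "b"}
        assert pairwise == {(0, 1): 2, (0, 2): 2, (1, 2): 2}

    def test_duplicates_rejected(self):
        with pytest.raises(ValueError, match="duplicates"):
            top_n_intersection([["a", "a"], ["b", "c"]], 2)
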