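"""Gene-set registry and the combined z-score activity statistic."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from melanotx.activity import (
    cell_cycle_phase_profile,
    class_summary,
    combined_zscore_activity,
    compare_groups,
    ora_enrichment,
    pca_explained_variance,
    pearson_correlation,
)
from melanotx.genesets import GeneSet, load_gmt, packaged_gene_sets
from melanotx.preprocess import NormalizedMatrix


def z_matrix(values: np.ndarray, genes, samples, classes) -> NormalizedMatrix:
    """NormalizedMatrix carrying given z-scores directly."""
    z = pd.DataFrame(values, index=genes, columns=samples)
    ann = pd.DataFrame({"class": classes, "replicate": range(1, len(samples) + 1)},
                       index=samples)
    return NormalizedMatrix(
        size_factors=pd.Series(1.0, index=samples),
        normalized=z.copy(),
        samples=ann,
        zscores=z,
    )


class TestGeneSetRegistry:
    @pytest.mark.parametrize(
        "name,size",
        [
            ("MAPK_TARGETS_WAGLE", 10),
            ("FERROPTOSIS", 8),
            ("QUIESCENCE_G0", 3),
            ("APOPTOSIS", 6),
            ("INTRINSIC_RESISTANCE", 8),
            ("DIFF_MARKER_PANEL", 10),
        ],
    )
    def test_packaged_panel_sizes(self, name, size):
        reg = packaged_gene_sets(include_reconstructed=False)
        assert len(reg[name]) == size

    def test_mapk_panel_membership(self):
        reg = packaged_gene_sets()
        assert set(reg["MAPK_TARGETS_WAGLE"].genes) == {
            "SPRY2", "SPRY4", "DUSP4", "DUSP6", "CCND1",
            "EPHA2", "EPHA4", "ETV4", "ETV5", "PHLDA1",
        }

    def test_gmt_roundtrip_and_uppercasing(self, tmp_path):
        f = tmp_path / "x.gmt"
        f.write_text("myset\tcustom\tmitf\tAxl\tsox10\n")
        reg = load_gmt(f)
        assert len(reg) == 1
        assert reg["myset"].genes == ("MITF", "AXL", "SOX10")

    def test_malformed_line_reports_line_number(self, tmp_path):
        f = tmp_path / "bad.gmt"
        f.write_text("ok\tdesc\tA\tB\nshort\tdesc\n")
        with pytest.raises(ValueError, match="line 2"):
            load_gmt(f)

    def test_duplicate_names_and_symbols_rejected(self, tmp_path):
        f = tmp_path / "dup.gmt"
        f.write_text("s\td\tA\tB\ns\td\tC\tD\n")
        with pytest.raises(ValueError, match="duplicate"):
            load_gmt(f)
        with pytest.raises(ValueError, match="duplicate"):
            GeneSet("x", ("A", "a"))

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            GeneSet("x", ())


class TestCombinedZscore:
    def test_unit_z_closed_form(self):
        gs = GeneSet("four", ("A", "B", "C", "D"))
        nm = z_matrix(np.ones((4, 2)), ["A", "B", "C", "D"], ["s1", "s2"], ["x", "x"])
        scores = combined_zscore_activity(nm, gs)
        assert np.allclose(scores["score"], 2.0)  # sum 4 / sqrt(4)
        assert (scores["n_used"] == 4).all()

    def test_zero_z_and_denominator_switch(self):
        gs = GeneSet("four", ("A", "B", "C", "D"))
        nm = z_matrix(np.zeros((4, 2)), ["A", "B", "C", "D"], ["s1", "s2"], ["x", "x"])
        assert np.allclose(combined_zscore_activity(nm, gs)["score"], 0.0)
        nm2 = z_matrix(np.ones((4, 2)), ["A", "B", "C", "D"], ["s1", "s2"], ["x", "x"])
        assert np.allclose(
            combined_zscore_activity(nm2, gs, denominator="n")["score"], 1.0
        )

    def test_missing_genes_tracked_absent_set_fatal(self):
        gs = GeneSet("s", ("A", "B", "MISSING1", "MISSING2"))
        nm = z_matrix(np.ones((2, 2)), ["A", "B"], ["s1", "s2"], ["x", "x"])
        scores = combined_zscore_activity(nm, gs)
        assert (scores["n_used"] == 2).all()
        assert np.allclose(scores["score"], 2 / np.sqrt(2))
        gs2 = GeneSet("none", ("NOPE",))
        with pytest.raises(ValueError, match="none"):
            combined_zscore_activity(nm, gs2)

    def test_disjoint_set_linearity(self):
        rng = np.random.default_rng(12)
        genes = [f"G{i}" for i in range(30)]
        nm = z_matrix(rng.normal(size=(30, 5)), genes,
                      [f"s{i}" for i in range(5)], ["x"] * 5)
        a = GeneSet("a", tuple(genes[:12]))
        b = GeneSet("b", tuple(genes[12:30]))
        ab = GeneSet("ab", tuple(genes))
        za = combined_zscore_activity(nm, a)["score"]
        zb = combined_zscore_activity(nm, b)["score"]
        zab = combined_zscore_activity(nm, ab)["score"]
        lhs = zab * np.sqrt(30)
        rhs = za * np.sqrt(12) + zb * np.sqrt(18)
        assert np.allclose(lhs, rhs, atol=1e-10)

    def test_null_is_standard_normal(self):
        """Z_gamma over i.i.d. standard-normal gene z-scores has sd ~ 1."""
        rng = np.random.default_rng(99)
        n_genes, n_samples = 25, 10_000
        genes = [f"G{i}" for i in range(n_genes)]
        nm = z_matrix(rng.normal(size=(n_genes, n_samples)), genes,
                      [f"s{i}" for i in range(n_samples)], ["x"] * n_samples)
        scores = combined_zscore_activity(nm, GeneSet("all", tuple(genes)))["score"]
        assert 0.95 <= scores.std(ddof=1) <= 1.05
        assert abs(scores.mean()) < 0.05


class TestGroupComparison:
    def test_identical_vectors(self):
        df = pd.DataFrame({"score": [1.0, 2.0, 1.0, 2.0], "class": ["a", "a", "b", "b"]})
        out = compare_groups(df, "a", "b")
        assert out["difference"] == 0.0 and out["p"] == 1.0

    def test_hand_welch(self):
        df = pd.DataFrame({"score": [1, 2, 3, 4, 5, 6],
                           "class": ["a"] * 3 + ["b"] * 3})
        out = compare_groups(df, "a", "b")
        # equal variances/sizes: Welch df = 4, t = -3/sqrt(2/3)
        t = -3 / np.sqrt(2 / 3)
        p = 2 * stats.t.sf(abs(t), df=4)
        assert out["difference"] == pytest.approx(-3.0)
        assert out["p"] == pytest.approx(p, rel=1e-10)
        assert out["test"] == "welch_t_two_sided"

    def test_antisymmetry_and_replicate_guard(self):
        df = pd.DataFrame({"score": [1, 2, 4, 8], "class": ["a", "a", "b", "b"]})
        fwd = compare_groups(df, "a", "b")
        rev = compare_groups(df, "b", "a")
        assert fwd["difference"] == -rev["difference"]
        assert fwd["p"] == rev["p"]
        single = pd.DataFrame({"score": [1, 2, 3], "class": ["a", "b", "b"]})
        with pytest.raises(ValueError):
            compare_groups(single, "a", "b")

    def test_class_summary_se(self):
        df = pd.DataFrame({"score": [1.0, 2.0, 3.0], "class": ["a"] * 3})
        cs = class_summary(df)
        assert cs.loc["a", "mean"] == 2.0
        assert cs.loc["a", "se"] == pytest.approx(1 / np.sqrt(3))


class TestPearson:
    def test_perfect_correlations(self):
        x = np.array([1.0, 2, 3, 5, 8])
        assert pearson_correlation(x, 2 * x + 1)[0] == pytest.approx(1.0)
        assert pearson_correlation(x, -x)[0] == pytest.approx(-1.0)

    def test_hand_computed_five_points(self):
        x = np.array([1.0, 2, 3, 4, 5])
        y = np.array([2.0, 1, 4, 3, 6])
        r_hand = np.cov(x, y, ddof=1)[0, 1] / (x.std(ddof=1) * y.std(ddof=1))
        r, p = pearson_correlation(x, y)
        assert r == pytest.approx(r_hand, rel=1e-12)
        t = r_hand * np.sqrt(3 / (1 - r_hand**2))
        assert p == pytest.approx(2 * stats.t.sf(abs(t), df=3), rel=1e-8)

    def test_zero_variance_is_error(self):
        with pytest.raises(ValueError, match="zero variance"):
            pearson_correlation([1, 1, 1], [1, 2, 3])


class TestPCA:
    def test_collinear_samples_give_pc1_everything(self):
        genes = ["A", "B", "C"]
        base = np.array([1.0, -2.0, 0.5])
        X = np.outer(base, np.array([0.0, 1.0, 2.0, 3.0]))  # samples on a line
        nm = z_matrix(X, genes, [f"s{i}" for i in range(4)], ["x"] * 4)
        out = pca_explained_variance(nm, GeneSet("s", tuple(genes)))
        assert out["variance_fractions"][0] == pytest.approx(1.0, abs=1e-10)
        assert out["pc1_pc2_fraction"] == pytest.approx(1.0, abs=1e-10)

    def test_fractions_sum_to_one(self):
        rng = np.random.default_rng(5)
        genes = [f"G{i}" for i in range(8)]
        nm = z_matrix(rng.normal(size=(8, 6)), genes, [f"s{i}" for i in range(6)],
                      ["x"] * 6)
        out = pca_explained_variance(nm, GeneSet("s", tuple(genes)))
        assert out["variance_fractions"].sum() == pytest.approx(1.0, abs=1e-10)
        assert out["projections"].shape == (6, 2)


class TestORA:
    def test_exact_combinatorial_example(self):
        universe = {f"u{i}" for i in range(15)} | {"A", "B", "C", "D", "E"}
        registry = {"hit": GeneSet("hit", ("A", "B", "C", "D", "E"))}
        query = {"A", "B", "C", "D", "E"}
        table = ora_enrichment(query, registry, universe)
        from math import comb
        assert table.loc["hit", "p"] == pytest.approx(1 / comb(20, 5), rel=1e-9)

    def test_no_overlap_is_null(self):
        universe = {f"u{i}" for i in range(30)} | {"A", "B"}
        registry = {"s": GeneSet("s", ("A", "B"))}
        table = ora_enrichment({f"u{i}" for i in range(3)}, registry, universe)
        assert table.loc["s", "p"] == pytest.approx(1.0)

    def test_matches_exhaustive_enumeration(self):
        """Tail probability equals brute-force enumeration of all draws for a
        small universe."""
        universe = [f"u{i}" for i in range(12)]
        members = set(universe[:5])
        query = set(universe[2:8])  # overlap 3
        registry = {"s": GeneSet("s", tuple(members))}
        table = ora_enrichment(set(query), registry, set(universe))
        k_obs = len(query & members)
        total = hits = 0
        for draw in itertools.combinations(universe, len(query)):
            total += 1
            if len(set(draw) & members) >= k_obs:
                hits += 1
        assert table.loc["s", "p"] == pytest.approx(hits / total, rel=1e-12)

    def test_guards(self):
        with pytest.raises(ValueError, match="universe"):
            ora_enrichment({"A"}, {}, set())
        with pytest.raises(ValueError, match="subset"):
            ora_enrichment({"A"}, {}, {"B"})


class TestCellCyclePhases:
    def phase_sets(self):
        return {
            "g1": GeneSet("g1", ("A", "B"), category="cell_cycle_phase:G1"),
            "m": GeneSet("m", ("C", "D"), category="cell_cycle_phase:M"),
        }

    def test_hand_averaged_toy(self):
        vals = np.array([[1.0, 2.0], [3.0, 4.0], [0.0, -1.0], [2.0, 1.0]])
        nm = z_matrix(vals, ["A", "B", "C", "D"], ["s1", "s2"], ["x", "y"])
        out = cell_cycle_phase_profile(nm, self.phase_sets())
        means = out["phase_means"]
        assert means.loc["s1", "G1"] == pytest.approx(2.0)  # (1+3)/2
        assert means.loc["s2", "M"] == pytest.approx(0.0)  # (-1+1)/2

    def test_planted_elevation_ranks_first(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(size=(4, 6)) * 0.1
        vals[0:2, 0:3] += 3.0  # G1 markers high in class x
        nm = z_matrix(vals, ["A", "B", "C", "D"], [f"s{i}" for i in range(6)],
                      ["x"] * 3 + ["y"] * 3)
        out = cell_cycle_phase_profile(nm, self.phase_sets(), compare=[("x", "y")])
        means = out["phase_means"].groupby("class")["G1"].mean()
        assert means.idxmax() == "x"
        assert out["comparisons"]["G1:x_vs_y"]["difference"] > 0

    def test_all_zero_z(self):
        nm = z_matrix(np.zeros((4, 4)), ["A", "B", "C", "D"],
                      [f"s{i}" for i in range(4)], ["x"] * 4)
        out = cell_cycle_phase_profile(nm, self.phase_sets())
        assert (out["phase_means"][["G1", "M"]] == 0).all().all()

    def test_absent_phase_skipped(self):
        sets = self.phase_sets()
        sets["s"] = GeneSet("s", ("NOPE",), category="cell_cycle_phase:S")
        nm = z_matrix(np.zeros((4, 2)), ["A", "B", "C", "D"], ["s1", "s2"], ["x", "x"])
        out = cell_cycle_phase_profile(nm, sets)
        assert "S" not in out["phase_means"].columns
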