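import numpy as np
import pandas as pd
import pytest

from lctgsa import (
    GeneSet,
    bh_fdr,
    filter_genesets,
    make_gsa_fixture,
    read_gmt,
    read_matrix,
    run_gsa,
)
from lctgsa.gsa import storey_qvalues, write_matrix

from _oracles import bh_stepup_loop


@pytest.fixture
def gmt_file(tmp_path):
    path = tmp_path / "sets.gmt"
    path.write_text(
        "SETA\tfirst\tG1\tG2\tG3\n"
        "SETB\tsecond\tG2\tG4\n"
        "SETC\tthird\tG5\tG5\tG6\n"
    )
    return path


class TestReadGMT:
    def test_minimal_records_order_preserved(self, gmt_file):
        sets = read_gmt(gmt_file)
        assert [s.name for s in sets] == ["SETA", "SETB", "SETC"]
        assert sets[0].genes == ["G1", "G2", "G3"]
        assert sets[1].description == "second"

    def test_duplicate_genes_deduplicated(self, gmt_file):
        sets = read_gmt(gmt_file)
        assert sets[2].genes == ["G5", "G6"]

    def test_malformed_line_reports_line_number(self, tmp_path):
        path = tmp_path / "bad.gmt"
        path.write_text("SETA\tok\tG1\nBROKEN\tonly-two-fields\n")
        with pytest.raises(ValueError, match="line 2"):
            read_gmt(path)


class TestReadMatrix:
    def test_expression_orientation_transposed(self, tmp_path):
        path = tmp_path / "expr.tsv"
        pd.DataFrame(np.arange(12.0).reshape(3, 4),
                     index=["G1", "G2", "G3"],
                     columns=["S1", "S2", "S3", "S4"]).to_csv(path, sep="\t")
        mat = read_matrix(path, orientation="genes-in-rows")
        assert mat.shape == (4, 3)  # samples x genes internally
        assert list(mat.columns) == ["G1", "G2", "G3"]

    def test_phenotype_orientation_kept(self, tmp_path):
        path = tmp_path / "pheno.tsv"
        pd.DataFrame(np.ones((4, 2)), index=list("abcd"),
                     columns=["p1", "p2"]).to_csv(path, sep="\t")
        assert read_matrix(path, orientation="samples-in-rows").shape == (4, 2)

    def test_round_trip(self, tmp_path, rng):
        df = pd.DataFrame(rng.normal(size=(5, 3)), index=[f"s{i}" for i in range(5)],
                          columns=["g1", "g2", "g3"])
        path = tmp_path / "m.tsv"
        write_matrix(df, path, orientation="genes-in-rows")
        back = read_matrix(path, orientation="genes-in-rows")
        pd.testing.assert_frame_equal(back, df)

    def test_non_numeric_cell_located(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("id\ts1\ts2\nG1\t1.0\toops\n")
        with pytest.raises(ValueError, match="G1.*s2"):
            read_matrix(path, orientation="genes-in-rows")

    def test_duplicate_identifiers_rejected(self, tmp_path):
        path = tmp_path / "dup.tsv"
        path.write_text("id\ts1\ts2\nG1\t1\t2\nG1\t3\t4\n")
        with pytest.raises(ValueError, match="duplicate"):
            read_matrix(path, orientation="genes-in-rows")


class TestFilterGenesets:
    def test_size_bounds_on_matched_genes(self):
        universe = [f"G{i}" for i in range(600)]
        small = GeneSet("small", genes=["G1", "G2", "G3"])
        big = GeneSet("big", genes=[f"G{i}" for i in range(501)])
        ok = GeneSet("ok", genes=["G1", "G2", "G3", "G4", "G5"])
        kept = filter_genesets([small, big, ok], universe)
        assert [s.name for s in kept] == ["ok"]

    def test_intersection_not_raw_size(self):
        # 6 nominal genes but only 3 measured -> below the default minimum
        s = GeneSet("s", genes=["G1", "G2", "G3", "X1", "X2", "X3"])
        assert filter_genesets([s], ["G1", "G2", "G3"]) == []
        kept = filter_genesets([s], ["G1", "G2", "G3"], min_size=3)
        assert kept[0].genes == ["G1", "G2", "G3"]


class TestFDR:
    def test_constant_pvalues_unchanged(self):
        np.testing.assert_allclose(bh_fdr([0.2, 0.2, 0.2]), [0.2, 0.2, 0.2])

    def test_hand_computed_stepup(self):
        np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04])

    def test_single_pvalue_unchanged(self):
        np.testing.assert_allclose(bh_fdr([0.37]), [0.37])

    def test_matches_loop_oracle_and_order_invariance(self, rng):
        p = rng.uniform(1e-4, 1.0, size=23)
        np.testing.assert_allclose(bh_fdr(p), bh_stepup_loop(p), atol=1e-12)
        perm = rng.permutation(23)
        np.testing.assert_allclose(bh_fdr(p[perm]), bh_fdr(p)[perm], atol=1e-12)

    def test_domain_validated(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 0.0])
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.2])

    def test_storey_no_larger_than_bh(self, rng):
        p = rng.uniform(1e-4, 1.0, size=40)
        assert np.all(storey_qvalues(p) <= bh_fdr(p) + 1e-12)


class TestRunGSA:
    @pytest.fixture
    def planted_study(self):
        return make_gsa_fixture(n=40, p=8, q=4, rho=0.3, mu=3.0, n_sets=8, seed=5)

    def test_planted_set_has_smallest_pvalue(self, planted_study):
        expr, pheno, sets, planted = planted_study
        table = run_gsa(expr, pheno, sets, n_perm=199, seed=1)
        assert table.loc[table["p_value"].idxmin(), "set"] == planted
        assert (table["status"] == "tested").all()

    def test_fdr_independent_of_set_order(self, planted_study):
        expr, pheno, sets, _ = planted_study
        fwd = run_gsa(expr, pheno, sets, n_perm=99, seed=2)
        rev = run_gsa(expr, pheno, sets[::-1], n_perm=99, seed=2)
        merged = fwd.merge(rev, on="set", suffixes=("_f", "_r"))
        np.testing.assert_allclose(merged["p_value_f"], merged["p_value_r"])
        np.testing.assert_allclose(merged["fdr_f"], merged["fdr_r"])

    def test_sample_order_alignment(self, planted_study):
        expr, pheno, sets, _ = planted_study
        base = run_gsa(expr, pheno, sets[:3], n_perm=50, seed=3)
        shuffled = pheno.sample(frac=1.0, random_state=0)  # realigned by id
        again = run_gsa(expr, shuffled, sets[:3], n_perm=50, seed=3)
        np.testing.assert_allclose(base["statistic"], again["statistic"])

    def test_univariate_phenotype_reduction(self, planted_study):
        expr, pheno, sets, _ = planted_study
        table = run_gsa(expr, pheno.iloc[:, :1], sets[:2], n_perm=50, seed=4)
        assert table["statistic"].notna().all()

    def test_untestable_set_flagged_and_excluded_from_fdr(self, planted_study):
        expr, pheno, sets, _ = planted_study
        expr = expr.copy()
        ghost = GeneSet("GHOST", genes=["NOPE1", "NOPE2", sets[0].genes[0]])
        table = run_gsa(expr, pheno, [ghost, sets[1]], n_perm=50, seed=5)
        row = table.set_index("set").loc["GHOST"]
        assert row["status"].startswith("untested")
        assert np.isnan(row["fdr"])
        assert table.set_index("set").loc[sets[1].name, "status"] == "tested"

    def test_zero_variance_gene_dropped_with_warning(self, planted_study, caplog):
        expr, pheno, sets, _ = planted_study
        expr = expr.copy()
        expr[sets[0].genes[0]] = 1.0  # constant gene
        with caplog.at_level("WARNING", logger="lctgsa.gsa"):
            table = run_gsa(expr, pheno, sets[:1], n_perm=50, seed=6)
        assert table.loc[0, "status"] == "tested"
        assert any("zero-variance" in r.message for r in caplog.records)

    def test_mismatched_samples_rejected(self, planted_study):
        expr, pheno, sets, _ = planted_study
        with pytest.raises(ValueError, match="same samples"):
            run_gsa(expr, pheno.iloc[:-1], sets[:1], n_perm=10, seed=0)

    def test_multivariate_can_find_what_univariate_misses(self):
        """A set associated with a *combination* of phenotypes: the joint test
        rejects while each single-phenotype analysis does not."""
        r = np.random.default_rng(8)
        n = 30
        s = r.normal(size=(n, 1))
        genes = s + 0.5 * r.normal(size=(n, 5))
        z = r.normal(size=(n, 1))
        pheno = pd.DataFrame(np.hstack([s + 5 * z, 5 * z]),
                             index=[f"S{i}" for i in range(n)],
                             columns=["y1", "y2"])
        expr = pd.DataFrame(genes, index=pheno.index,
                            columns=[f"G{i}" for i in range(5)])
        sets = [GeneSet("SET", genes=list(expr.columns))]
        multi = run_gsa(expr, pheno, sets, n_perm=199, seed=9)
        uni1 = run_gsa(expr, pheno[["y1"]], sets, n_perm=199, seed=9)
        uni2 = run_gsa(expr, pheno[["y2"]], sets, n_perm=199, seed=9)
        assert multi.loc[0, "p_value"] <= 0.05
        assert uni1.loc[0, "p_value"] > 0.05
        assert uni2.loc[0, "p_value"] > 0.05
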