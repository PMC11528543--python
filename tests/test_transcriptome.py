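"""RPKM, the NB differential test, DEG gates, cis pairs and reversal logic."""

import numpy as np
import pandas as pd
import pytest

import nomepipe as nm


class TestRPKM:
    def test_worked_example(self):
        counts = pd.DataFrame({"s1": [10]}, index=pd.Index(["g"], name="gene_id"))
        out = nm.rpkm(counts, pd.Series({"g": 2000}), library_size={"s1": 1_000_000})
        assert out.loc["g", "s1"] == pytest.approx(5.0)

    def test_zero_counts_give_zero(self):
        counts = pd.DataFrame({"s1": [0]}, index=pd.Index(["g"], name="gene_id"))
        out = nm.rpkm(counts, pd.Series({"g": 500}), library_size={"s1": 1e6})
        assert out.loc["g", "s1"] == 0.0

    def test_scale_invariance(self):
        counts = pd.DataFrame(
            {"s1": [10, 90]}, index=pd.Index(["a", "b"], name="gene_id")
        )
        lengths = pd.Series({"a": 1000, "b": 2000})
        np.testing.assert_allclose(
            nm.rpkm(counts, lengths).values, nm.rpkm(counts * 2, lengths).values
        )

    def test_zero_library_rejected(self):
        counts = pd.DataFrame({"s1": [0]}, index=pd.Index(["g"], name="gene_id"))
        with pytest.raises(ValueError):
            nm.rpkm(counts, pd.Series({"g": 500}), library_size={"s1": 0})


class TestDiffTest:
    def test_identical_groups_have_zero_log2fc(self):
        counts = pd.DataFrame(
            {f"s{i}": [100, 20, 5] for i in range(4)},
            index=pd.Index(["a", "b", "c"], name="gene_id"),
        )
        res = nm.diff_test(counts.iloc[:, :2], counts.iloc[:, 2:])
        np.testing.assert_allclose(res["log2fc"], 0.0, atol=1e-12)

    def test_all_zero_gene_is_null(self):
        rng = np.random.default_rng(1)
        counts = pd.DataFrame(
            rng.poisson(50, size=(3, 6)),
            index=pd.Index(["a", "b", "z"], name="gene_id"),
        )
        counts.loc["z"] = 0
        res = nm.diff_test(counts.iloc[:, :3], counts.iloc[:, 3:]).set_index("gene_id")
        assert res.loc["z", "p"] == 1.0 and res.loc["z", "log2fc"] == 0.0

    def test_single_sample_group_rejected(self):
        counts = pd.DataFrame(
            {"a": [1], "b": [2], "c": [3]}, index=pd.Index(["g"], name="gene_id")
        )
        with pytest.raises(ValueError):
            nm.diff_test(counts[["a"]], counts[["b", "c"]])

    def test_null_type_one_error_calibrated(self):
        rng = np.random.default_rng(42)
        a, b = nm.simulate_null_counts(2000, 6, 0.05, rng)
        res = nm.diff_test(a, b)
        frac = float((res["p"] <= 0.05).mean())
        assert 0.03 <= frac <= 0.07

    def test_planted_fourfold_genes_recover_log2fc(self, expr_sim):
        res = nm.diff_test(
            expr_sim["counts"][expr_sim["groups"]["disease"]],
            expr_sim["counts"][expr_sim["groups"]["control"]],
        ).set_index("gene_id")
        planted = res.loc[list(expr_sim["truth"].fold_changes)]
        assert planted["log2fc"].mean() == pytest.approx(2.0, abs=0.3)


class TestDEGGates:
    def _results(self, log2fc, p=1e-8):
        return pd.DataFrame({"gene_id": ["g"], "log2fc": [log2fc], "p": [p]})

    def test_coding_rpkm_gate(self):
        bt = pd.Series({"g": "coding"})
        out = nm.call_degs(self._results(0.6), bt, pd.Series({"g": 0.8}))
        assert out["status"].item() == "ns"
        out = nm.call_degs(self._results(0.6), bt, pd.Series({"g": 1.5}))
        assert out["status"].item() == "up"

    def test_lncrna_lower_rpkm_gate(self):
        bt = pd.Series({"g": "lncRNA"})
        out = nm.call_degs(self._results(0.6), bt, pd.Series({"g": 0.8}))
        assert out["status"].item() == "up"
        out = nm.call_degs(self._results(-0.6), bt, pd.Series({"g": 0.05}))
        assert out["status"].item() == "ns"

    def test_fold_change_boundary_is_strict(self):
        bt = pd.Series({"g": "coding"})
        out = nm.call_degs(self._results(0.5), bt, pd.Series({"g": 10.0}))
        assert out["status"].item() == "ns"

    def test_fdr_computed_over_all_tested_genes(self):
        res = pd.DataFrame(
            {
                "gene_id": [f"g{i}" for i in range(4)],
                "log2fc": [1.0, 1.0, 1.0, 1.0],
                "p": [0.01, 0.02, 0.03, 0.9],
            }
        )
        bt = pd.Series({f"g{i}": "coding" for i in range(4)})
        rpkm = pd.Series({f"g{i}": 5.0 for i in range(4)})
        out = nm.call_degs(res, bt, rpkm)
        np.testing.assert_allclose(out["q"], nm.bh_fdr(res["p"]))


class TestCisPairs:
    def _setup(self):
        genes = [
            nm.GeneRecord("lnc1", "lncRNA", "+", 0, 1000, "c", 1000),
            nm.GeneRecord("cod1", "coding", "+", 11_000, 12_000, "c", 1000),   # 10 kb away
            nm.GeneRecord("cod2", "coding", "+", 161_000, 162_000, "c", 1000),  # 160 kb away
        ]
        x = np.array([1.0, 2, 3, 4, 5, 6])
        rpkm = pd.DataFrame(
            {f"s{i}": [x[i], x[i] * 2, x[i] * 3] for i in range(6)},
            index=pd.Index(["lnc1", "cod1", "cod2"], name="gene_id"),
        )
        return genes, rpkm

    def _degs(self, status_map):
        return pd.DataFrame(
            {
                "gene_id": list(status_map),
                "status": list(status_map.values()),
            }
        )

    def test_perfectly_correlated_nearby_pair_kept(self):
        genes, rpkm = self._setup()
        pairs = nm.cis_pairs(
            self._degs({"lnc1": "up"}), self._degs({"cod1": "up"}), rpkm, genes
        )
        assert len(pairs) == 1
        row = pairs.iloc[0]
        assert row["r"] == pytest.approx(1.0)
        assert row["distance_bp"] == 10_000

    def test_distance_gate(self):
        genes, rpkm = self._setup()
        pairs = nm.cis_pairs(
            self._degs({"lnc1": "up"}), self._degs({"cod2": "up"}), rpkm, genes
        )
        assert len(pairs) == 0

    def test_opposite_directions_never_tested(self):
        genes, rpkm = self._setup()
        pairs = nm.cis_pairs(
            self._degs({"lnc1": "up"}), self._degs({"cod1": "down"}), rpkm, genes
        )
        assert len(pairs) == 0

    def test_gene_distance_conventions(self):
        a = nm.GeneRecord("a", "coding", "+", 0, 1000, "c", 1000)
        b = nm.GeneRecord("b", "coding", "+", 500, 1500, "c", 1000)  # overlaps a
        c = nm.GeneRecord("c", "coding", "+", 2000, 3000, "c", 1000)
        assert nm.gene_distance(a, b) == 0
        assert nm.gene_distance(a, c) == 1000
        d = nm.GeneRecord("d", "coding", "+", 0, 1000, "chr2", 1000)
        assert nm.gene_distance(a, d) > 1e12

    def test_planted_pairs_recovered(self, expr_sim):
        groups, counts = expr_sim["groups"], expr_sim["counts"]
        rpkm = expr_sim["rpkm"]
        bt, truth = expr_sim["biotype"], expr_sim["truth"]
        res = nm.diff_test(counts[groups["disease"]], counts[groups["control"]])
        mean_rpkm = rpkm[groups["disease"] + groups["control"]].mean(axis=1)
        degs = nm.call_degs(res, bt, mean_rpkm)
        deg_lnc = degs[degs["biotype"] == "lncRNA"]
        deg_cod = degs[degs["biotype"] == "coding"]
        pairs = nm.cis_pairs(
            deg_lnc, deg_cod, rpkm[groups["disease"] + groups["control"]],
            expr_sim["genes"],
        )
        found = set(zip(pairs["lnc_id"], pairs["coding_id"]))
        planted = set(expr_sim["truth"].cis_pairs)
        # every planted pair whose members both reach DEG status must be
        # recovered; pairs losing a member to test power cannot be paired
        status = degs.set_index("gene_id")["status"]
        eligible = {
            (l, c) for l, c in planted if status[l] == "up" and status[c] == "up"
        }
        assert len(eligible) >= 5  # enough pairs survive to make the check meaningful
        assert eligible <= found
        assert found - planted == set()  # no spurious pairs at this scale


class TestIsoformRatio:
    def test_examples(self):
        a = pd.Series({"s1": 100.0, "s2": 50.0, "s3": 10.0})
        b = pd.Series({"s1": 50.0, "s2": 50.0, "s3": 0.0})
        out = nm.isoform_ratio(a, b)
        assert out["s1"] == 2.0 and out["s2"] == 1.0
        assert np.isnan(out["s3"])  # zero denominator flagged

    def test_invariant_under_library_rescale(self):
        a = pd.Series({"s1": 100.0})
        b = pd.Series({"s1": 50.0})
        assert nm.isoform_ratio(a * 3, b * 3)["s1"] == nm.isoform_ratio(a, b)["s1"]

    def test_ratio_rises_in_disease(self, expr_sim):
        groups, rpkm = expr_sim["groups"], expr_sim["rpkm"]
        ratio = nm.isoform_ratio(rpkm.loc["MYH7"], rpkm.loc["MYH6"])
        assert ratio[groups["disease"]].mean() > 2 * ratio[groups["control"]].mean()


class TestFetalProgram:
    def _degs(self, up=(), down=()):
        rows = [{"gene_id": g, "status": "up"} for g in up]
        rows += [{"gene_id": g, "status": "down"} for g in down]
        rows += [{"gene_id": "nsgene", "status": "ns"}]
        return pd.DataFrame(rows)

    def test_disjoint_sets_give_empty_program(self):
        prog = nm.fetal_program(self._degs(up=["a"]), self._degs(up=["b"]))
        assert prog.size == 0

    def test_intersection_logic_and_conservation(self):
        prog = nm.fetal_program(
            self._degs(up=["a", "b"], down=["x", "y"]),
            self._degs(up=["b", "c"], down=["y", "z"]),
        )
        assert prog.co_up == {"b"} and prog.co_down == {"y"}
        assert prog.size == len(prog.co_up) + len(prog.co_down)

    def test_reversal_set_logic(self):
        prog = nm.FetalProgram(co_up={"a", "b", "c"}, co_down={"x", "y"})
        rev = nm.reversal_fraction(
            nm.FetalProgram(co_up=prog.co_up, co_down=prog.co_down),
            self._degs(down=["a", "b"], up=["x"]),
            self._degs(down=["a", "b", "c"], up=["x", "y"]),
        )
        # reversed_up = {a,b} (c missing from A), reversed_down = {x}
        assert rev["reversed_up"] == 2 and rev["reversed_down"] == 1
        assert rev["percent_up"] == 67  # 2/3 rounded half-up
        assert rev["percent_down"] == 50

    def test_no_treated_degs_means_zero_percent(self):
        prog = nm.FetalProgram(co_up={"a"}, co_down={"x"})
        rev = nm.reversal_fraction(prog, self._degs(), self._degs())
        assert rev["percent_up"] == 0 and rev["percent_down"] == 0

    def test_empty_program_side_flagged_undefined(self):
        prog = nm.FetalProgram(co_up=set(), co_down={"x"})
        rev = nm.reversal_fraction(prog, self._degs(up=["x"]), self._degs(up=["x"]))
        assert np.isnan(rev["percent_up"])
        assert rev["percent_down"] == 100

    def test_program_recovered_exactly_under_favourable_conditions(self):
        config = nm.SimulationConfig(
            seed=4, n_genes=800, n_lncrna=80, program_fold=6.0,
            nb_dispersion=0.02, n_expr_samples=8,
            program_up_size=30, program_down_size=50, n_cis_pairs=0,
            expr_base_log_sd=0.5, expr_base_log_mean=float(np.log(300)),
        )
        counts, groups, genes, truth = nm.simulate_expression(config)
        lengths = pd.Series({g.gene_id: g.length_bp for g in genes})
        bt = pd.Series({g.gene_id: g.biotype for g in genes})
        rpkm = nm.rpkm(counts, lengths)

        def degs(g1, g2):
            res = nm.diff_test(counts[groups[g1]], counts[groups[g2]])
            return nm.call_degs(res, bt, rpkm[groups[g1] + groups[g2]].mean(axis=1))

        prog = nm.fetal_program(degs("disease", "control"), degs("fetal", "control"))
        assert prog.co_up == set(truth.program_up)
        assert prog.co_down == set(truth.program_down)
        rev = nm.reversal_fraction(
            prog, degs("treated_A", "disease"), degs("treated_B", "disease")
        )
        assert rev["reversed_up"] == len(truth.reversed_up)
        assert rev["reversed_down"] == len(truth.reversed_down)
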