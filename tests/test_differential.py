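"""Differential splicing (plate and droplet), differential expression and
multiple-testing control."""

import numpy as np
import pandas as pd
import pytest

from marvelx import differential as diff
from marvelx import psi as psi_mod
from marvelx import simulate

METHODS = ["ks", "ad", "dts", "wilcoxon", "ttest", "perm_mean"]


class TestTwoSampleTest:
    def test_identical_samples(self):
        x = np.array([0.1, 0.4, 0.5, 0.9, 0.3])
        stat, p = diff.two_sample_test(x, x, "ks")
        assert stat == 0.0
        assert p == 1.0

    @pytest.mark.parametrize("method", METHODS)
    def test_strong_separation(self, method):
        rng = np.random.default_rng(1)
        x = 0.1 + 0.02 * rng.standard_normal(50)
        y = 0.9 + 0.02 * rng.standard_normal(50)
        _, p = diff.two_sample_test(x, y, method, n_perm=1000,
                                    rng=np.random.default_rng(2))
        if method in ("ks", "wilcoxon", "ttest"):
            assert p < 1e-6
        else:
            # AD p-values are clamped at 1e-3; permutation p is floored at
            # 1/(B+1) -- both hit their minimum under full separation
            assert p <= 1.1e-3

    @pytest.mark.parametrize("method", METHODS)
    def test_null_calibration(self, method):
        rng = np.random.default_rng(42)
        rejections = 0
        n_rep = 500
        for _ in range(n_rep):
            x = rng.beta(2, 2, 40)
            y = rng.beta(2, 2, 40)
            _, p = diff.two_sample_test(x, y, method, n_perm=199, rng=rng)
            rejections += p < 0.05
        assert 0.03 <= rejections / n_rep <= 0.07, method

    def test_insufficient_samples_return_missing(self):
        stat, p = diff.two_sample_test([0.5], [0.1, 0.2, 0.3], "ks")
        assert np.isnan(stat) and np.isnan(p)

    def test_permutation_reproducible_and_floored(self):
        x = np.linspace(0.0, 0.2, 30)
        y = np.linspace(0.8, 1.0, 30)
        r1 = diff.two_sample_test(x, y, "dts", n_perm=100,
                                  rng=np.random.default_rng(9))
        r2 = diff.two_sample_test(x, y, "dts", n_perm=100,
                                  rng=np.random.default_rng(9))
        assert r1 == r2
        assert r1[1] == pytest.approx(1 / 101)

    def test_dts_statistic_zero_for_identical(self):
        x = np.array([0.1, 0.2, 0.3, 0.4])
        assert diff.dts_statistic(x, x) == pytest.approx(0.0)

    def test_group_relabel_invariance(self):
        rng = np.random.default_rng(3)
        x = rng.beta(2, 2, 30)
        y = rng.beta(5, 1, 30)
        for method in ("ks", "ad", "wilcoxon"):
            _, p1 = diff.two_sample_test(x, y, method)
            _, p2 = diff.two_sample_test(np.random.default_rng(0).permutation(x),
                                         y, method)
            assert p1 == pytest.approx(p2)


class TestBhFdr:
    def test_matches_reference_step_up(self):
        rng = np.random.default_rng(0)

        def reference(p):
            m = len(p)
            order = np.argsort(p)
            adj = np.empty(m)
            running = 1.0
            for rank in range(m, 0, -1):
                i = order[rank - 1]
                running = min(running, p[i] * m / rank)
                adj[i] = running
            return adj

        for _ in range(200):
            p = rng.uniform(size=rng.integers(1, 50))
            assert np.allclose(diff.bh_fdr(p), reference(p))

    def test_fdr_at_least_p(self):
        p = np.array([0.001, 0.02, 0.5, 0.9])
        assert (diff.bh_fdr(p) >= p - 1e-15).all()


def _psi_matrix(data: dict[str, np.ndarray], cells) -> psi_mod.PsiMatrix:
    psi = pd.DataFrame(data, index=cells).T
    return psi_mod.PsiMatrix(psi=psi, support=psi.notna() * 10)


class TestOutlierRemoval:
    def _setup(self, interior_g1, interior_g2, n=30):
        cells = [f"a{i}" for i in range(n)] + [f"b{i}" for i in range(n)]
        groups = pd.Series(["g1"] * n + ["g2"] * n, index=cells)
        v1 = np.concatenate([np.full(interior_g1, 0.5),
                             np.ones(n - interior_g1)])
        v2 = np.concatenate([np.full(interior_g2, 0.5),
                             np.zeros(n - interior_g2)])
        mat = _psi_matrix({"E1": np.concatenate([v1, v2])}, cells)
        res = pd.DataFrame({"event_id": ["E1"], "significant": [True]})
        return res, mat, groups

    @pytest.mark.parametrize("i1,i2,kept", [
        (12, 0, True),   # one population suffices
        (5, 9, False),   # both below 10
        (0, 0, False),   # all extreme
        (10, 0, True),   # boundary: exactly 10 interior cells
    ])
    def test_interior_cell_rule(self, i1, i2, kept):
        res, mat, groups = self._setup(i1, i2)
        out = diff.remove_outlier_events(res, mat, groups, ("g1", "g2"))
        assert bool(out.iloc[0]["significant"]) is kept
        assert bool(out.iloc[0]["outlier_removed"]) is (not kept)

    def test_removal_never_adds(self):
        res, mat, groups = self._setup(0, 0)
        res["significant"] = [False]
        out = diff.remove_outlier_events(res, mat, groups, ("g1", "g2"))
        assert not out["significant"].any()


@pytest.fixture(scope="module")
def plate_diff_setup():
    cfg = simulate.PlateSimConfig(seed=21, n_events=120, n_differential=15)
    res = simulate.simulate_plate(cfg)
    from marvelx import events as evm
    validated = evm.validate_events(res.events, res.junction_counts)
    mat = psi_mod.compute_psi_plate(validated, res.junction_counts)
    return res, mat


class TestPlateDifferential:
    def test_planted_events_recovered(self, plate_diff_setup):
        res, mat = plate_diff_setup
        table = diff.differential_splicing_plate(
            mat, res.cell_metadata["group"], ("g1", "g2"), seed=5)
        truth = res.truth.set_index("event_id")["kind"]
        merged = table.set_index("event_id").join(truth)
        planted = merged[merged["kind"] == "differential"]
        null = merged[merged["kind"] == "null"]
        assert planted["significant"].mean() >= 0.9
        assert null["significant"].mean() <= 0.10

    def test_group_swap_antisymmetry(self, plate_diff_setup):
        res, mat = plate_diff_setup
        sub = psi_mod.PsiMatrix(psi=mat.psi.iloc[:40], support=mat.support.iloc[:40])
        t12 = diff.differential_splicing_plate(
            sub, res.cell_metadata["group"], ("g1", "g2"), method="ad", seed=5)
        t21 = diff.differential_splicing_plate(
            sub, res.cell_metadata["group"], ("g2", "g1"), method="ad", seed=5)
        m = t12.set_index("event_id").join(t21.set_index("event_id"),
                                           rsuffix="_swap")
        assert np.allclose(m["delta_psi"], -m["delta_psi_swap"])
        assert (m["significant"] == m["significant_swap"]).all()

    def test_default_is_union_of_ad_and_dts(self, plate_diff_setup):
        res, mat = plate_diff_setup
        table = diff.differential_splicing_plate(
            mat, res.cell_metadata["group"], ("g1", "g2"), seed=5)
        # before outlier removal, significance requires FDR < 0.1 in >= 1 test
        called = table["significant"] | table["outlier_removed"]
        union = (table["fdr_ad"] < 0.10) | (table["fdr_dts"] < 0.10)
        assert (called == union.fillna(False)).all()

    def test_single_method_mode(self, plate_diff_setup):
        res, mat = plate_diff_setup
        table = diff.differential_splicing_plate(
            mat, res.cell_metadata["group"], ("g1", "g2"), method="ks", seed=5)
        assert {"stat_ks", "p_ks", "fdr_ks"} <= set(table.columns)

    def test_small_group_skipped_with_reason(self):
        cells = [f"a{i}" for i in range(30)] + ["b0"]
        groups = pd.Series(["g1"] * 30 + ["g2"], index=cells)
        mat = _psi_matrix({"E1": np.linspace(0, 1, 31)}, cells)
        table = diff.differential_splicing_plate(mat, groups, ("g1", "g2"),
                                                 min_cells=25, seed=0)
        assert table.iloc[0]["skip_reason"] == "insufficient_cells_per_group"
        assert not table.iloc[0]["significant"]


class TestDifferentialGenes:
    def _expr(self, g1_vals, g2_vals):
        n1, n2 = len(g1_vals[0]), len(g2_vals[0])
        cells = [f"a{i}" for i in range(n1)] + [f"b{i}" for i in range(n2)]
        groups = pd.Series(["g1"] * n1 + ["g2"] * n2, index=cells)
        expr = pd.DataFrame(np.hstack([g1_vals, g2_vals]),
                            index=[f"G{i}" for i in range(len(g1_vals))],
                            columns=cells)
        return expr, groups

    def test_constructed_fold_change(self):
        rng = np.random.default_rng(0)
        base = rng.lognormal(3, 0.2, 50)
        expr, groups = self._expr([base], [2 * base])
        out = diff.differential_genes(expr, groups, ("g1", "g2"))
        row = out.iloc[0]
        assert 0.8 < row["log2_fc"] <= 1.0  # pseudocount attenuates below 1
        assert row["fdr"] < 0.10
        assert row["direction"] == "up"

    def test_identical_groups_ns(self):
        vals = np.full(30, 7.0)
        expr, groups = self._expr([vals], [vals])
        out = diff.differential_genes(expr, groups, ("g1", "g2"))
        assert out.iloc[0]["direction"] == "ns"
        assert out.iloc[0]["p_value"] == 1.0

    def test_threshold_plate_vs_droplet(self):
        rng = np.random.default_rng(1)
        base = rng.lognormal(3, 0.1, 60)
        expr, groups = self._expr([base], [(2 ** 0.7) * base + 0.9])
        plate = diff.differential_genes(expr, groups, ("g1", "g2"),
                                        log2fc_threshold=0.5)
        droplet = diff.differential_genes(expr, groups, ("g1", "g2"),
                                          log2fc_threshold=1.0)
        assert plate.iloc[0]["fdr"] < 0.10
        assert 0.5 < plate.iloc[0]["log2_fc"] < 1.0
        assert plate.iloc[0]["direction"] == "up"
        assert droplet.iloc[0]["direction"] == "ns"

    def test_min_cells_feature_filter(self):
        expr = pd.DataFrame(
            {"c0": [1.0, 0.0], "c1": [2.0, 1.0], "c2": [3.0, 0.0],
             "c3": [1.0, 0.0]},
            index=["G_expressed", "G_rare"])
        groups = pd.Series(["g1", "g1", "g2", "g2"], index=expr.columns)
        out = diff.differential_genes(expr, groups, ("g1", "g2"), min_cells=3)
        assert out["gene_id"].tolist() == ["G_expressed"]


class TestDropletFilters:
    def test_rate_rules(self):
        n = 100
        cells = [f"a{i}" for i in range(n)] + [f"b{i}" for i in range(n)]
        groups = pd.Series(["g1"] * n + ["g2"] * n, index=cells)

        def with_rate(r1, r2):
            row = np.zeros(2 * n)
            row[:int(r1 * n)] = 1.0
            row[n:n + int(r2 * n)] = 1.0
            return row

        expr = pd.DataFrame([with_rate(0.12, 0.11), with_rate(0.12, 0.08)],
                            index=["G_both", "G_one"], columns=cells)
        sj = pd.DataFrame([with_rate(0.15, 0.02), with_rate(0.05, 0.02),
                           with_rate(0.5, 0.5)],
                          index=["j_either", "j_neither", "j_dropped_gene"],
                          columns=cells)
        gmap = {"j_either": "G_both", "j_neither": "G_both",
                "j_dropped_gene": "G_one"}
        genes, junctions = diff.droplet_feature_filters(
            expr, sj, groups, ("g1", "g2"), gmap)
        assert genes == ["G_both"]
        assert junctions == ["j_either"]

    def test_matches_hand_enumeration_on_toy(self, droplet_sim):
        groups = droplet_sim.cell_metadata["group"]
        expr = droplet_sim.expression.iloc[:20]
        sj = droplet_sim.sj_counts.iloc[:20]
        genes, junctions = diff.droplet_feature_filters(
            expr, sj, groups, ("g1", "g2"), droplet_sim.gene_of_junction)
        cells1 = groups.index[groups == "g1"]
        cells2 = groups.index[groups == "g2"]
        expect_genes = [g for g in expr.index
                        if (expr.loc[g, cells1] > 0).mean() >= 0.10
                        and (expr.loc[g, cells2] > 0).mean() >= 0.10]
        assert genes == expect_genes
        for j in junctions:
            r1 = (sj.loc[j, cells1] > 0).mean()
            r2 = (sj.loc[j, cells2] > 0).mean()
            assert max(r1, r2) >= 0.10
            assert droplet_sim.gene_of_junction[j] in set(expect_genes)


class TestDropletDifferential:
    def test_planted_usage_shift_significant(self, droplet_sim):
        groups = droplet_sim.cell_metadata["group"]
        out = diff.differential_splicing_droplet(
            droplet_sim.sj_counts, droplet_sim.gene_counts,
            droplet_sim.expression, groups, ("g1", "g2"),
            droplet_sim.gene_of_junction, n_perm=100, seed=3)
        truth = droplet_sim.truth.set_index("junction")["differential"]
        merged = out.set_index("junction").join(truth)
        assert merged[merged["differential"]]["significant"].mean() >= 0.9
        assert (merged[~merged["differential"]]["p_value"] < 0.05).mean() <= 0.10

    def test_small_delta_not_significant_despite_low_p(self):
        cfg = simulate.DropletSimConfig(seed=9, n_junctions=10,
                                        n_differential=10, usage_g1=0.30,
                                        usage_g2=0.34, n_cells_per_group=400,
                                        dropout=0.0)
        d = simulate.simulate_droplet(cfg)
        out = diff.differential_splicing_droplet(
            d.sj_counts, d.gene_counts, d.expression,
            d.cell_metadata["group"], ("g1", "g2"), d.gene_of_junction,
            n_perm=100, seed=1)
        low_p = out[out["p_value"] < 0.05]
        assert len(low_p) > 0
        small = low_p[low_p["delta_psi"].abs() <= 5.0]
        assert not small["significant"].any()

    def test_seeded_reproducibility(self, droplet_sim):
        groups = droplet_sim.cell_metadata["group"]
        args = (droplet_sim.sj_counts.iloc[:10], droplet_sim.gene_counts,
                droplet_sim.expression, groups, ("g1", "g2"),
                droplet_sim.gene_of_junction)
        o1 = diff.differential_splicing_droplet(*args, n_perm=50, seed=11)
        o2 = diff.differential_splicing_droplet(*args, n_perm=50, seed=11)
        pd.testing.assert_frame_equal(o1, o2)

    def test_p_floor(self, droplet_sim):
        groups = droplet_sim.cell_metadata["group"]
        out = diff.differential_splicing_droplet(
            droplet_sim.sj_counts, droplet_sim.gene_counts,
            droplet_sim.expression, groups, ("g1", "g2"),
            droplet_sim.gene_of_junction, n_perm=100, seed=3)
        assert out["p_value"].min() >= 1 / 101 - 1e-12
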