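"""Pointwise statistics, clustering, CBnPP and TFCE permutation tests."""

import numpy as np
import pytest
from scipy import stats as sps

from ierp.adjacency import AdjacencyGraph, build_lattice_adjacency
from ierp.cluster_stats import (StatMap, TfceParams, cbnpp_test,
                                compact_mode_map, form_clusters,
                                pointwise_statistic, tfce_test,
                                tfce_transform)
from ierp.containers import ChannelLayout
from ierp.modes import make_mode_labels
from ierp.spectral import ModeRange


def grid_graph(n_rows, n_cols):
    """4-connected grid as an AdjacencyGraph (rows x cols)."""
    edges = []
    for r in range(n_rows):
        for c in range(n_cols):
            u = r * n_cols + c
            if c + 1 < n_cols:
                edges.append((u, u + 1))
            if r + 1 < n_rows:
                edges.append((u, u + n_cols))
    return AdjacencyGraph(shape=(n_rows, n_cols), dims=("mode", "time"),
                          edges=np.array(edges, dtype=np.intp))


def chain_graph(n):
    edges = np.stack([np.arange(n - 1), np.arange(1, n)], axis=1)
    return AdjacencyGraph(shape=(n,), dims=("time",), edges=edges)


def flood_fill_clusters(mask, n_rows, n_cols):
    """Independent component oracle on a 4-connected grid."""
    seen = np.zeros_like(mask, dtype=bool)
    comps = []
    for start in range(mask.size):
        if not mask.flat[start] or seen.flat[start]:
            continue
        stack, comp = [start], []
        seen.flat[start] = True
        while stack:
            u = stack.pop()
            comp.append(u)
            r, c = divmod(u, n_cols)
            for rr, cc in ((r - 1, c), (r + 1, c), (r, c - 1), (r, c + 1)):
                if 0 <= rr < n_rows and 0 <= cc < n_cols:
                    v = rr * n_cols + cc
                    if mask.flat[v] and not seen.flat[v]:
                        seen.flat[v] = True
                        stack.append(v)
        comps.append(frozenset(comp))
    return set(comps)


class TestPointwiseStatistic:
    def test_identical_conditions_give_zero_t(self, rng):
        a = rng.standard_normal((6, 20))
        data = np.stack([a, a], axis=1)
        stat = pointwise_statistic(data, "paired-t")
        np.testing.assert_array_equal(stat.values, 0.0)
        assert stat.zero_variance.all()

    def test_two_condition_f_is_t_squared(self, rng):
        data = rng.standard_normal((8, 2, 30))
        t = pointwise_statistic(data, "paired-t").values
        f = pointwise_statistic(data, "rm-anova-F").values
        np.testing.assert_allclose(f, t ** 2, rtol=1e-10)

    def test_paired_t_matches_textbook_formula(self):
        a = np.array([3.1, 2.8, 4.0, 3.5])
        b = np.array([2.9, 2.5, 3.1, 3.0])
        d = a - b
        expected = d.mean() / (d.std(ddof=1) / np.sqrt(4))
        data = np.stack([a, b], axis=1)[:, :, None]
        stat = pointwise_statistic(data, "paired-t")
        assert stat.values[0] == pytest.approx(expected)
        ref = sps.ttest_rel(a, b)
        assert stat.values[0] == pytest.approx(ref.statistic)

    def test_pearson_matches_scipy(self, rng):
        x = rng.standard_normal((10, 5))
        cov = rng.standard_normal(10)
        stat = pointwise_statistic(x, "pearson-r", covariate=cov)
        for j in range(5):
            assert stat.values[j] == pytest.approx(
                sps.pearsonr(cov, x[:, j]).statistic)

    def test_rm_anova_matches_scipy(self, rng):
        data = rng.standard_normal((7, 3, 4))
        stat = pointwise_statistic(data, "rm-anova-F")
        import pandas as pd
        from statsmodels.stats.anova import AnovaRM
        for j in range(4):
            df = pd.DataFrame({
                "subject": np.repeat(np.arange(7), 3),
                "cond": np.tile(np.arange(3), 7),
                "y": data[:, :, j].ravel()})
            ref = AnovaRM(df, "y", "subject", within=["cond"]).fit()
            f_ref = float(ref.anova_table["F Value"].iloc[0])
            assert stat.values[j] == pytest.approx(f_ref)

    def test_too_few_subjects_errors(self, rng):
        with pytest.raises(ValueError):
            pointwise_statistic(rng.standard_normal((2, 2, 5)), "paired-t")


class TestFormClusters:
    def test_no_suprathreshold_nodes(self):
        graph = chain_graph(10)
        stat = StatMap(values=np.zeros(10), kind="t", df=(9,), n_subjects=10)
        assert form_clusters(stat, graph, 2.0) == []

    def test_two_adjacent_nodes_one_cluster(self, standard_lattice):
        _, labels = standard_lattice
        graph = build_lattice_adjacency(labels, n_time=2,
                                        dims=("mode", "time"))
        values = np.zeros((15, 2))
        i_25 = [str(lab) for lab in labels].index("2:5")
        i_35 = [str(lab) for lab in labels].index("3:5")
        values[i_25, 0] = 3.0
        values[i_35, 0] = 2.5
        stat = StatMap(values=values, kind="t", df=(9,), n_subjects=10)
        clusters = form_clusters(stat, graph, 2.0)
        assert len(clusters) == 1
        assert clusters[0].mass == pytest.approx(5.5)

    def test_random_maps_match_flood_fill_oracle(self, rng):
        graph = grid_graph(5, 8)
        threshold = 1.0
        for _ in range(100):
            values = rng.standard_normal((5, 8)) * 1.5
            stat = StatMap(values=values, kind="t", df=(9,), n_subjects=10)
            clusters = form_clusters(stat, graph, threshold)
            got = {frozenset(c.nodes.tolist()) for c in clusters}
            expected = (flood_fill_clusters(values > threshold, 5, 8)
                        | flood_fill_clusters(values < -threshold, 5, 8))
            assert got == expected

    def test_mass_is_signed_sum(self, rng):
        graph = grid_graph(5, 8)
        values = rng.standard_normal((5, 8)) * 2
        stat = StatMap(values=values, kind="t", df=(9,), n_subjects=10)
        for c in form_clusters(stat, graph, 1.5):
            assert c.mass == pytest.approx(values.ravel()[c.nodes].sum())
            assert np.sign(c.mass) == c.sign


class TestCbnpp:
    def test_injected_effect_is_detected_at_its_scale(self, rng,
                                                      standard_lattice,
                                                      mode_time_graph):
        """An effect at pure mode 4:4 must surface in modes containing
        order 4 and nowhere else."""
        _, labels = standard_lattice
        contains4 = np.array([4 in lab.constituents() for lab in labels])
        n_subj, n_time = 16, 50
        data = rng.standard_normal((n_subj, 2, 15, n_time))
        # inject at the pure mode and propagate linearly to composites
        effect = np.zeros((15, n_time))
        effect[contains4, 20:30] = 1.2
        data[:, 0] += effect
        res = cbnpp_test(data, "paired-t", mode_time_graph, n_perm=500,
                         seed=0)
        win = res.significant()[0]
        modes_in_win = {np.unravel_index(n, res.shape)[0] for n in win.nodes}
        i44 = [str(lab) for lab in labels].index("4:4")
        assert i44 in modes_in_win
        excl = [c for c in res.significant()
                if {np.unravel_index(n, res.shape)[0]
                    for n in c.nodes} <= set(np.nonzero(~contains4)[0])]
        assert not excl

    def test_seeded_determinism(self, rng, mode_time_graph):
        data = rng.standard_normal((8, 2, 15, 50))
        r1 = cbnpp_test(data, "paired-t", mode_time_graph, n_perm=200, seed=7)
        r2 = cbnpp_test(data, "paired-t", mode_time_graph, n_perm=200, seed=7)
        np.testing.assert_array_equal(r1.null_max_mass, r2.null_max_mass)
        assert [c.p for c in r1.clusters] == [c.p for c in r2.clusters]

    def test_exhaustive_enumeration_for_small_n(self, rng):
        graph = chain_graph(6)
        data = rng.standard_normal((5, 2, 6))
        res = cbnpp_test(data, "paired-t", graph, n_perm=500, seed=1)
        assert res.exhaustive and res.n_perm == 32
        assert "exhaustive" in res.note

    def test_p_values_in_unit_interval(self, rng, mode_time_graph):
        data = rng.standard_normal((6, 2, 15, 50))
        res = cbnpp_test(data, "paired-t", mode_time_graph, n_perm=100,
                         seed=3)
        for c in res.clusters:
            assert 0 < c.p <= 1

    def test_correlation_design_runs(self, rng):
        graph = chain_graph(12)
        data = rng.standard_normal((10, 12))
        cov = rng.standard_normal(10)
        res = cbnpp_test(data, "pearson-r", graph, n_perm=200, seed=2,
                         covariate=cov)
        assert res.null_max_mass.shape == (200,)


class TestTfceTransform:
    def test_plateau_closed_form(self):
        """An isolated plateau of extent a and height h0 integrates to
        a^E * h0^(H+1) / (H+1)."""
        n, a, h0 = 64, 7, 2.0
        values = np.zeros(n)
        values[20:20 + a] = h0
        graph = chain_graph(n)
        E, H = 0.5, 2.0
        dh = h0 / 100
        out = tfce_transform(
            StatMap(values=values, kind="t", df=(9,), n_subjects=10),
            graph, TfceParams(E=E, H=H, dh=dh))
        expected = a ** E * h0 ** (H + 1) / (H + 1)
        got = out[25]
        assert abs(got - expected) / expected < 2 * dh

    def test_all_zero_map(self):
        graph = chain_graph(16)
        out = tfce_transform(
            StatMap(values=np.zeros(16), kind="t", df=(9,), n_subjects=10),
            graph, TfceParams())
        assert not out.any()

    def test_monotone_in_scale(self, rng):
        graph = grid_graph(5, 8)
        values = rng.standard_normal((5, 8))
        p = TfceParams(dh=0.01)
        lo = tfce_transform(
            StatMap(values=values, kind="t", df=(9,), n_subjects=10), graph, p)
        hi = tfce_transform(
            StatMap(values=2 * values, kind="t", df=(9,), n_subjects=10),
            graph, p)
        nz = values.ravel() != 0
        assert (np.abs(hi).ravel()[nz] > np.abs(lo).ravel()[nz]).all()

    def test_sign_antisymmetry(self, rng):
        graph = grid_graph(4, 6)
        values = rng.standard_normal((4, 6))
        p = TfceParams(dh=0.02)
        fwd = tfce_transform(
            StatMap(values=values, kind="t", df=(9,), n_subjects=10), graph, p)
        rev = tfce_transform(
            StatMap(values=-values, kind="t", df=(9,), n_subjects=10), graph, p)
        np.testing.assert_allclose(fwd, -rev, atol=1e-12)


class TestTfceTest:
    def test_null_data_rarely_significant(self, rng, mode_time_graph):
        rejections = 0
        for i in range(10):
            data = rng.standard_normal((8, 2, 15, 50))
            res = tfce_test(data, "paired-t", mode_time_graph, n_perm=200,
                            seed=i)
            rejections += res.min_p <= 0.05
        assert rejections <= 2

    def test_strong_effect_detected(self, rng, mode_time_graph):
        data = rng.standard_normal((12, 2, 15, 50))
        data[:, 0, 5:8, 10:20] += 2.0
        res = tfce_test(data, "paired-t", mode_time_graph, n_perm=300, seed=0)
        assert res.min_p <= 0.05
        sig = res.significant_nodes()
        rows = {np.unravel_index(n, res.shape)[0] for n in sig}
        assert rows & {5, 6, 7}

    def test_deterministic_under_seed(self, rng, mode_time_graph):
        data = rng.standard_normal((8, 2, 15, 50))
        a = tfce_test(data, "paired-t", mode_time_graph, n_perm=150, seed=9)
        b = tfce_test(data, "paired-t", mode_time_graph, n_perm=150, seed=9)
        np.testing.assert_array_equal(a.node_p, b.node_p)


class TestCompactModeMap:
    @pytest.fixture
    def three_d_setup(self, rng, standard_lattice):
        _, labels = standard_lattice
        layout = ChannelLayout([f"c{i}" for i in range(4)],
                               np.array([[0, 0, 0], [30, 0, 0],
                                         [60, 0, 0], [200, 0, 0.0]]))
        graph = build_lattice_adjacency(labels, layout=layout, n_time=6,
                                        dims=("channel", "mode", "time"))
        return labels, layout, graph

    def test_no_significant_clusters_fully_transparent(self, rng,
                                                       three_d_setup):
        labels, _, graph = three_d_setup
        data = rng.standard_normal((8, 2, 4, 15, 6)) * 0.1
        res = cbnpp_test(data, "paired-t", graph, n_perm=100, seed=0)
        cm = compact_mode_map(res, res.stat, labels, [0, 1])
        assert not cm.opaque.any()

    def test_single_node_effect_marks_one_cell(self, rng, three_d_setup):
        labels, _, graph = three_d_setup
        i45 = [str(lab) for lab in labels].index("4:5")
        data = rng.standard_normal((10, 2, 4, 15, 6)) * 0.3
        data[:, 0, 1, i45, 2] += 3.0
        res = cbnpp_test(data, "paired-t", graph, n_perm=300, seed=1)
        assert res.significant()
        cm = compact_mode_map(res, res.stat, labels, [0, 1])
        assert cm.opaque[i45, 2]
        assert cm.opaque.sum() <= 3  # effect cell (+ possible spillover)

    def test_mask_invariant_to_channel_order(self, rng, three_d_setup):
        labels, _, graph = three_d_setup
        data = rng.standard_normal((10, 2, 4, 15, 6))
        data[:, 0, :2, 4, 3] += 1.5
        res = cbnpp_test(data, "paired-t", graph, n_perm=200, seed=2)
        a = compact_mode_map(res, res.stat, labels, [0, 1, 2])
        b = compact_mode_map(res, res.stat, labels, [2, 0, 1])
        np.testing.assert_array_equal(a.opaque, b.opaque)
        np.testing.assert_allclose(a.mean_stat, b.mean_stat)

    def test_triangular_layout(self, rng, three_d_setup):
        labels, _, graph = three_d_setup
        data = rng.standard_normal((8, 2, 4, 15, 6))
        res = cbnpp_test(data, "paired-t", graph, n_perm=100, seed=3)
        cm = compact_mode_map(res, res.stat, labels, [0])
        tri = cm.triangular(0)
        assert tri.shape == (5, 5)
        assert np.isnan(tri[3, 0])  # p > q is off the lattice
        assert np.isfinite(np.diag(tri)).all()
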