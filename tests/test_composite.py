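import numpy as np
import pytest
from scipy import stats

from ptsdconn.atlas import make_atlas
from ptsdconn.composite import (
    baseline_group_tests,
    bh_fdr,
    composite_metric,
    group_by_time_anova,
    network_pair_means,
    partial_correlation_retest,
)
from ptsdconn.connectivity import Connectome
from ptsdconn.errors import FormatError, InputError


def brute_force_bh(p, q):
    """Literal step-up definition, independent of the implementation."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p)
    reject = np.zeros(m, bool)
    kmax = 0
    for rank, idx in enumerate(order, start=1):
        if p[idx] <= rank * q / m:
            kmax = rank
    reject[order[:kmax]] = True
    adj = np.empty(m)
    prev = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        prev = min(prev, p[idx] * m / rank)
        adj[idx] = prev
    return adj, reject


def random_connectomes(rng, n_sub, n_nodes):
    conns = []
    for s in range(n_sub):
        a = rng.normal(size=(n_nodes, n_nodes))
        z = (a + a.T) / 2
        np.fill_diagonal(z, 0)
        conns.append(Connectome(f"s{s}", "baseline", z, "test"))
    return conns


class TestBhFdr:
    def test_hand_executed_example(self):
        adj, rej = bh_fdr([0.001, 0.02, 0.03, 0.8], q=0.05)
        np.testing.assert_array_equal(rej, [True, True, True, False])

    def test_all_ones_no_rejections(self):
        _, rej = bh_fdr(np.ones(7))
        assert not rej.any()

    def test_single_p_reduces_to_raw_threshold(self):
        _, rej = bh_fdr([0.04], q=0.05)
        assert rej.all()

    def test_agrees_with_brute_force_on_random_vectors(self, rng):
        for _ in range(1000):
            m = rng.integers(1, 25)
            p = rng.random(m).clip(1e-12)
            q = rng.choice([0.01, 0.05, 0.1])
            adj, rej = bh_fdr(p, q)
            adj_o, rej_o = brute_force_bh(p, q)
            np.testing.assert_allclose(adj, adj_o, atol=1e-12)
            np.testing.assert_array_equal(rej, rej_o)

    def test_adjusted_monotone_in_rank(self, rng):
        p = rng.random(50)
        adj, _ = bh_fdr(p)
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-15).all()

    def test_rejects_out_of_range(self):
        with pytest.raises(InputError):
            bh_fdr([0.0, 0.5])


class TestCompositeMetric:
    def test_single_edge_equals_that_edge(self, rng):
        conns = random_connectomes(rng, 3, 6)
        comp = composite_metric(conns, {(1, 4)})
        np.testing.assert_allclose(comp, [c.z_matrix[1, 4] for c in conns])

    def test_linearity(self, rng):
        conns = random_connectomes(rng, 4, 6)
        edges = {(0, 1), (2, 3), (1, 5)}
        comp = composite_metric(conns, edges)
        doubled = [
            Connectome(c.subject_id, c.session, 2 * c.z_matrix, c.atlas_id)
            for c in conns
        ]
        np.testing.assert_allclose(composite_metric(doubled, edges), 2 * comp)

    def test_matches_direct_summation_oracle(self, rng):
        conns = random_connectomes(rng, 5, 12)
        edges = set()
        while len(edges) < 10:
            i, j = rng.integers(12, size=2)
            if i != j:
                edges.add((min(i, j), max(i, j)))
        comp = composite_metric(conns, edges)
        for k, c in enumerate(conns):
            manual = np.mean([c.z_matrix[i, j] for i, j in edges])
            assert comp[k] == pytest.approx(manual, abs=1e-14)

    def test_unknown_node_rejected(self, rng):
        with pytest.raises(FormatError):
            composite_metric(random_connectomes(rng, 2, 5), {(0, 7)})


class TestNetworkPairMeans:
    def test_single_within_network_pair(self, rng):
        atlas = make_atlas(6, [], ["A", "B"], seed=0)
        a_nodes = np.flatnonzero(atlas.networks == "A")
        edges = {(int(a_nodes[0]), int(a_nodes[1]))}
        pairs = network_pair_means(random_connectomes(rng, 3, 6), atlas, edges)
        assert len(pairs) == 1
        assert pairs[0].pair == ("A", "A")

    def test_pair_labels_unordered(self, rng):
        atlas = make_atlas(8, [], ["A", "B"], seed=1)
        a = int(np.flatnonzero(atlas.networks == "A")[0])
        b = int(np.flatnonzero(atlas.networks == "B")[0])
        b2 = int(np.flatnonzero(atlas.networks == "B")[1])
        conns = random_connectomes(rng, 2, 8)
        pairs = network_pair_means(conns, atlas, {(a, b), (b2, a)})
        assert len(pairs) == 1
        assert pairs[0].pair == ("A", "B")
        assert pairs[0].edge_count == 2

    def test_reconstruction_identity(self, rng):
        atlas = make_atlas(15, ["sub1"], ["A", "B", "C"], seed=3)
        conns = random_connectomes(rng, 6, 16)
        edges = set()
        while len(edges) < 20:
            i, j = rng.integers(16, size=2)
            if i != j:
                edges.add((min(i, j), max(i, j)))
        pairs = network_pair_means(conns, atlas, edges)
        assert sum(p.edge_count for p in pairs) == len(edges)
        weighted = sum(p.edge_count * p.mean_z for p in pairs) / len(edges)
        np.testing.assert_allclose(
            weighted, composite_metric(conns, edges), atol=1e-10
        )


class TestBaselineGroupTests:
    def test_identical_distributions_give_null_result(self):
        vals = np.tile(np.arange(10.0), 3)
        groups = np.repeat(["responder", "nonresponder", "control"], 10)
        table = baseline_group_tests(vals, groups)
        anova = table[table.kind == "anova_F"].iloc[0]
        assert anova.statistic == pytest.approx(0.0, abs=1e-12)
        assert anova.p == pytest.approx(1.0)

    def test_two_group_f_equals_squared_t(self, rng):
        vals = rng.normal(size=30)
        groups = np.array(["responder"] * 14 + ["control"] * 16)
        table = baseline_group_tests(vals, groups)
        f = table[table.kind == "anova_F"].iloc[0].statistic
        t, _ = stats.ttest_ind(vals[:14], vals[14:], equal_var=True)
        assert f == pytest.approx(t**2, abs=1e-8)

    def test_shifted_groups_detected_with_power(self):
        hits_r = hits_n = 0
        n_seeds = 100
        for seed in range(n_seeds):
            r = np.random.default_rng(seed)
            controls = r.normal(0, 1, 36)
            responders = r.normal(-1, 1, 25)
            nonresponders = r.normal(+1, 1, 11)
            vals = np.concatenate([responders, nonresponders, controls])
            groups = np.array(
                ["responder"] * 25 + ["nonresponder"] * 11 + ["control"] * 36
            )
            table = baseline_group_tests(vals, groups).set_index("contrast")
            hits_r += table.loc["responder_vs_control", "p"] < 0.05
            hits_n += table.loc["nonresponder_vs_control", "p"] < 0.05
        # Monte-Carlo power for Welch contrasts at d = 1 (20k-rep oracle):
        # responder (25 vs 36) ~ 0.96, nonresponder (11 vs 36) ~ 0.78;
        # assert within 3-sigma binomial bands of those powers
        assert hits_r >= 0.9 * n_seeds
        assert 0.65 * n_seeds <= hits_n <= 0.92 * n_seeds

    def test_small_group_contrast_skipped(self):
        vals = np.arange(11.0)
        groups = np.array(["responder"] * 6 + ["nonresponder"] * 1 + ["control"] * 4)
        table = baseline_group_tests(vals, groups)
        assert "nonresponder_vs_control" not in set(table.contrast)
        assert "responder_vs_control" in set(table.contrast)


class TestGroupByTimeAnova:
    def test_no_change_gives_null_interaction(self, rng):
        pre = rng.normal(size=20)
        groups = np.array(["responder"] * 10 + ["control"] * 10)
        res = group_by_time_anova(pre, pre.copy(), groups)
        assert res["interaction_p"] == pytest.approx(1.0)
        t_row = res["anova"].set_index("Source").loc["time"]
        assert t_row.p == pytest.approx(1.0)

    def test_crossover_detected_with_correct_directions(self, rng):
        n = 20
        groups = np.repeat(["responder", "nonresponder", "control"], n)
        pre = rng.normal(0, 1, 3 * n)
        post = pre.copy()
        post[:n] += 2.0  # responders increase
        post[n : 2 * n] -= 2.0  # nonresponders decrease
        post += rng.normal(0, 0.3, 3 * n)
        res = group_by_time_anova(pre, post, groups)
        assert res["interaction_p"] < 0.05
        ph = res["posthoc"].set_index("contrast")
        assert ph.loc["responder_post_vs_pre", "estimate"] > 0
        assert ph.loc["responder_post_vs_pre", "significant_fdr"]
        assert ph.loc["nonresponder_post_vs_pre", "estimate"] < 0
        assert ph.loc["nonresponder_post_vs_pre", "significant_fdr"]

    def test_single_group_reduces_to_paired_t(self, rng):
        pre = rng.normal(size=15)
        post = pre + rng.normal(0.5, 1, 15)
        res = group_by_time_anova(pre, post, ["responder"] * 15)
        _, p_ref = stats.ttest_rel(post, pre)
        p_got = res["anova"].set_index("Source").loc["time", "p"]
        assert p_got == pytest.approx(p_ref, abs=1e-6)

    def test_balanced_case_matches_hand_computed_sums_of_squares(self):
        # 6 subjects, 2 groups of 3, pre/post; classic split-plot ANOVA
        pre = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        post = np.array([2.0, 4.0, 3.5, 3.0, 4.0, 5.5])
        groups = np.array(["a", "a", "a", "b", "b", "b"])
        res = group_by_time_anova(pre, post, groups, alpha=1.1)
        a = res["anova"].set_index("Source")

        # hand computation of the between-within decomposition
        y = np.stack([pre, post])  # time x subject
        grand = y.mean()
        n_per, n_time = 3, 2
        subj_mean = y.mean(axis=0)
        group_mean = {g: y[:, groups == g].mean() for g in "ab"}
        cell_mean = {(g, t): y[t, groups == g].mean() for g in "ab" for t in (0, 1)}
        time_mean = y.mean(axis=1)
        ss_group = sum(
            n_per * n_time * (group_mean[g] - grand) ** 2 for g in "ab"
        )
        ss_subj_within = sum(
            n_time * (subj_mean[i] - group_mean[groups[i]]) ** 2 for i in range(6)
        )
        ss_time = sum(2 * n_per * (time_mean[t] - grand) ** 2 for t in (0, 1))
        ss_int = sum(
            n_per
            * (cell_mean[(g, t)] - group_mean[g] - time_mean[t] + grand) ** 2
            for g in "ab"
            for t in (0, 1)
        )
        ss_err = sum(
            (y[t, i] - cell_mean[(groups[i], t)] - subj_mean[i]
             + group_mean[groups[i]]) ** 2
            for i in range(6)
            for t in (0, 1)
        )
        f_int = (ss_int / 1) / (ss_err / 4)
        f_group = (ss_group / 1) / (ss_subj_within / 4)
        assert a.loc["Interaction", "F"] == pytest.approx(f_int, abs=1e-8)
        assert a.loc["group", "F"] == pytest.approx(f_group, abs=1e-8)

    def test_missing_post_excluded_listwise(self, rng):
        pre = rng.normal(size=12)
        post = pre + 1.0
        post[3] = np.nan
        res = group_by_time_anova(pre, post, ["responder"] * 6 + ["control"] * 6)
        assert res["n_included"] == 11


def test_partial_correlation_removes_shared_covariate(rng):
    n = 60
    conf = rng.normal(size=n)
    x = conf + 0.1 * rng.normal(size=n)
    y = conf + 0.1 * rng.normal(size=n)
    raw_r = np.corrcoef(x, y)[0, 1]
    res = partial_correlation_retest(x, y, conf)
    assert abs(res["r_partial"]) < 0.4 < raw_r
    assert res["df"] == n - 3
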