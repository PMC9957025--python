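import numpy as np
import pytest

from inteinscan.simgen import evolve_sequences, simulate_host_tree
from inteinscan.topotest import (SiteLikTable, au_test, kh_test,
                                 rell_replicates, sh_test)
from inteinscan.topotest import test_suite as run_topo_suite


@pytest.fixture()
def random_table(rng):
    vals = -np.abs(rng.normal(3.0, 1.0, size=(3, 120)))
    vals[1] -= rng.normal(0.02, 0.05, size=120)
    vals[2] -= rng.normal(0.05, 0.05, size=120)
    return SiteLikTable(["t0", "t1", "t2"], vals)


class TestRell:
    def test_replicate_mean_matches_total(self, random_table):
        reps = rell_replicates(random_table, n_reps=4000, scale=1.0, seed=1)
        totals = random_table.values.sum(axis=1)
        site_var = random_table.values.var(axis=1)
        n = random_table.n_sites
        for t in range(3):
            se = np.sqrt(n * site_var[t] / 4000)
            assert abs(reps[t].mean() - totals[t]) < 3 * se

    def test_identical_rows_have_zero_replicate_difference(self):
        row = -np.abs(np.random.default_rng(0).normal(2, 1, 50))
        table = SiteLikTable(["a", "b"], np.vstack([row, row]))
        reps = rell_replicates(table, 500, 1.0, seed=2)
        assert np.abs(reps[0] - reps[1]).max() == 0.0

    def test_scale_changes_draw_size(self, random_table):
        reps_half = rell_replicates(random_table, 2000, 0.5, seed=3)
        reps_full = rell_replicates(random_table, 2000, 1.0, seed=3)
        # half-scale sums are about half the magnitude
        assert abs(reps_half[0].mean() / reps_full[0].mean() - 0.5) < 0.05

    def test_bootstrap_variance_identity(self, random_table):
        diff = random_table.values[0] - random_table.values[1]
        n = random_table.n_sites
        reps = rell_replicates(random_table, 10_000, 1.0, seed=4)
        boot_var = np.var(reps[0] - reps[1])
        assert boot_var == pytest.approx(n * diff.var(), rel=0.10)

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            rell_replicates(SiteLikTable([], np.empty((0, 0))), 100, 1.0, 0)


class TestKH:
    def test_tree_against_itself_is_one(self, random_table):
        assert kh_test(random_table, "t0", "t0", 1000, seed=0) == 1.0

    def test_seed_independence_within_monte_carlo_error(self, random_table):
        ps = [kh_test(random_table, "t0", "t1", 20_000, seed=s) for s in (1, 2, 3)]
        se = np.sqrt(max(ps[0], 1e-4) * (1 - ps[0]) / 20_000)
        assert max(ps) - min(ps) < 6 * se + 1e-3

    def test_p_in_unit_interval(self, random_table):
        p = kh_test(random_table, "t0", "t2", 2000, seed=5)
        assert 0.0 <= p <= 1.0


class TestSH:
    def test_best_tree_p_is_maximal(self, random_table):
        ps = sh_test(random_table, 2000, seed=6)
        totals = {tid: random_table.row(tid).sum() for tid in random_table.tree_ids}
        best = max(totals, key=totals.get)
        assert ps[best] == max(ps.values())

    def test_identical_rows_give_all_ones(self):
        row = -np.abs(np.random.default_rng(1).normal(2, 1, 60))
        table = SiteLikTable(["a", "b", "c"], np.vstack([row] * 3))
        assert set(sh_test(table, 1000, seed=7).values()) == {1.0}

    def test_sh_is_conservative_relative_to_kh(self, rng):
        # SH >= KH for the same tree on two-tree tables (known dominance)
        worse = 0
        for k in range(10):
            base = -np.abs(rng.normal(3, 1, size=80))
            other = base - rng.normal(0.03, 0.08, size=80)
            table = SiteLikTable(["a", "b"], np.vstack([base, other]))
            totals = table.values.sum(axis=1)
            better, worse_id = ("a", "b") if totals[0] >= totals[1] else ("b", "a")
            p_kh = kh_test(table, better, worse_id, 3000, seed=k)
            p_sh = sh_test(table, 3000, seed=k)[worse_id]
            if p_sh < p_kh - 0.02:
                worse += 1
        assert worse == 0


class TestAU:
    def test_symmetric_two_tree_table_gives_half(self, rng):
        base = -np.abs(rng.normal(3, 1, size=200))
        delta = rng.normal(0, 0.3, size=200)
        delta -= delta.mean()    # exactly symmetric rows
        table = SiteLikTable(["a", "b"], np.vstack([base + delta, base - delta]))
        ps = au_test(table, n_reps_per_scale=4000, seed=8)
        assert ps["a"] == pytest.approx(0.5, abs=0.1)
        assert ps["b"] == pytest.approx(0.5, abs=0.1)

    def test_dominant_tree_hits_upper_clamp(self, rng):
        good = -np.abs(rng.normal(2, 0.5, size=100))
        bad = good - 1.0
        table = SiteLikTable(["good", "bad"], np.vstack([good, bad]))
        res = au_test(table, n_reps_per_scale=1000, seed=9, full=True)
        assert res["good"].degenerate and res["good"].p > 0.99
        assert res["bad"].p < 0.05

    def test_needs_scales_spanning_one(self, random_table):
        with pytest.raises(ValueError):
            au_test(random_table, scales=(0.5, 0.6, 0.7, 0.8, 0.9), n_reps_per_scale=500)

    def test_all_p_in_unit_interval_and_deterministic(self, random_table):
        p1 = au_test(random_table, n_reps_per_scale=1000, seed=10)
        p2 = au_test(random_table, n_reps_per_scale=1000, seed=10)
        assert p1 == p2
        assert all(0.0 <= p <= 1.0 for p in p1.values())


class TestSuite:
    def test_single_best_tree_not_rejected(self, wag_g4):
        host = simulate_host_tree(6, 1.0, 40, rooted=True)
        seqs = evolve_sequences(host, wag_g4, 150, seed=41)
        unrooted = host.clone(depth=1)
        unrooted.deroot()
        res = run_topo_suite(seqs, wag_g4, {"only": unrooted}, n_reps=1000, seed=0)
        row = res.row("only")
        assert row.delta_lnl == 0.0
        assert not row.rejected
        assert res.best_tree == "only"

    def test_wrong_tree_rejected_with_strong_signal(self, wag_g4):
        from inteinscan.phylocore.search import _apply_nni, _nni_edge_indices
        host = simulate_host_tree(8, 2.0, 42, rooted=True)
        true = host.clone(depth=1)
        true.deroot()
        # lengthen an internal edge to create unambiguous signal
        idxs = _nni_edge_indices(true)
        nodes = list(true.postorder_node_iter())
        nodes[idxs[0]].edge.length = 0.8
        seqs = evolve_sequences(true, wag_g4, 400, seed=43)
        wrong = true.clone(depth=1)
        _apply_nni(wrong, idxs[0], False)
        res = run_topo_suite(seqs, wag_g4, {"true": true, "wrong": wrong},
                         n_reps=2000, seed=1)
        assert res.best_tree == "true"
        assert res.row("wrong").rejected
        assert not res.row("true").rejected
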