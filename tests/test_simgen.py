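import numpy as np
import pytest

from inteinscan.phylocore import build_model, robinson_foulds
from inteinscan.simgen import (ElementSpec, ScenarioConfig, apply_element_history,
                               evolve_sequences, read_truth, simulate_host_tree,
                               simulate_scenario, write_scenario)


class TestHostTree:
    def test_two_taxa_single_positive_edge(self):
        tree = simulate_host_tree(2, 1.0, 7)
        lengths = [nd.edge.length for nd in tree.preorder_node_iter()
                   if nd is not tree.seed_node]
        assert len(lengths) == 2 and all(l > 0 for l in lengths)

    def test_seeded_determinism_byte_identical(self):
        a = simulate_host_tree(5, 1.0, 42).as_string(schema="newick")
        b = simulate_host_tree(5, 1.0, 42).as_string(schema="newick")
        assert a == b

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            simulate_host_tree(1, 1.0, 0)
        with pytest.raises(ValueError):
            simulate_host_tree(5, 0.0, 0)

    def test_yule_depth_matches_analytic_expectation(self):
        # pure birth from 2 lineages: E[depth] = sum_{k=2..n} 1/(rate*k)
        n, rate, reps = 8, 1.0, 1000
        depths = np.array([
            max(lf.sim_time for lf in
                simulate_host_tree(n, rate, s, rooted=True).leaf_node_iter())
            for s in range(reps)
        ])
        expected = sum(1.0 / (rate * k) for k in range(2, n + 1))
        se = depths.std(ddof=1) / np.sqrt(reps)
        assert abs(depths.mean() - expected) < 3 * se


class TestSequenceEvolution:
    def test_zero_branch_lengths_give_identical_leaves(self, wag):
        tree = simulate_host_tree(5, 1.0, 3)
        for nd in tree.preorder_node_iter():
            if nd is not tree.seed_node:
                nd.edge.length = 0.0
        seqs = evolve_sequences(tree, wag, 40, seed=1)
        assert len(set(seqs.values())) == 1

    def test_divergence_matches_matrix_exponential(self, wag):
        # two-taxon tree: P(differ) = 1 - sum_a pi_a P_aa(t)
        import dendropy
        t = 0.4
        tree = dendropy.Tree.get(data=f"(A:{t},B:0.0);", schema="newick")
        n = 10_000
        seqs = evolve_sequences(tree, wag, n, seed=5)
        observed = np.mean([a != b for a, b in zip(seqs["A"], seqs["B"])])
        P = wag.transition_matrices(t)[0]
        expected = 1.0 - float(wag.frequencies @ np.diag(P))
        se = np.sqrt(expected * (1 - expected) / n)
        assert abs(observed - expected) < 3 * se

    def test_equilibrium_frequencies_preserved(self, wag):
        import dendropy
        tree = dendropy.Tree.get(data="(A:0.5,B:0.5);", schema="newick")
        n = 100_000
        seqs = evolve_sequences(tree, wag, n, seed=9)
        from inteinscan.phylocore.models import AA_INDEX
        counts = np.zeros(20)
        for ch in seqs["A"]:
            counts[AA_INDEX[ch]] += 1
        freqs = counts / n
        se = np.sqrt(wag.frequencies * (1 - wag.frequencies) / n)
        assert (np.abs(freqs - wag.frequencies) < 4 * se + 1e-4).all()


class TestElementHistory:
    def test_vertical_only_carriers_are_a_host_subtree(self, wag):
        host = simulate_host_tree(12, 1.0, 21, rooted=True)
        spec = ElementSpec("el", 30, 10, hgt_rate=0.0, min_carriers=3)
        seqs, log, trees = apply_element_history(host, spec, wag,
                                                 np.random.default_rng(2))
        origins = log.of_kind("origin")
        assert len(origins) == 1
        assert set(seqs) == set(origins[0].recipient.split("|"))

    def test_vertical_element_tree_congruent_with_host(self, wag):
        for seed in range(4):
            host = simulate_host_tree(12, 1.0, seed, rooted=True)
            spec = ElementSpec("el", 30, 10, min_carriers=4)
            seqs, _, trees = apply_element_history(host, spec, wag,
                                                   np.random.default_rng(seed))
            if len(seqs) < 4:
                continue
            sub = host.clone(depth=1)
            sub.retain_taxa_with_labels(sorted(seqs))
            sub.deroot()
            et = trees[0].clone(depth=1)
            et.deroot()
            assert robinson_foulds(sub, et) == 0

    def test_homing_group_identical_elements_diverged_hosts(self, two_element_scenario):
        sc = two_element_scenario
        group = ["T01", "T06", "T11", "T16"]
        s, e = sc.truth.true_site_sets["mobile"]
        blocks = {t: sc.alignment.rows[t][s:e] for t in group}
        assert len(set(blocks.values())) == 1
        exteins = {t: sc.alignment.rows[t][:s] for t in group}
        assert len(set(exteins.values())) == len(group)

    def test_unknown_homing_taxon_rejected(self, wag):
        host = simulate_host_tree(6, 1.0, 1, rooted=True)
        spec = ElementSpec("el", 30, 10, homing_groups=[["nope"]])
        with pytest.raises(ValueError, match="nope"):
            apply_element_history(host, spec, wag, np.random.default_rng(0))

    def test_event_log_replay_reproduces_carriers(self, two_element_scenario):
        # independent oracle: a leaf carries the element iff some origin/hgt
        # event targets an edge on its root path, or a homing event names it,
        # and it was not dropped by gene loss
        sc = two_element_scenario
        host = sc.truth.host_tree
        lost = {e.recipient for e in sc.truth.event_log.of_kind("gene_loss")}
        for name, carriers in sc.truth.carrier_sets.items():
            events = [e for e in sc.truth.event_log.events if e.element == name]
            replay = set()
            for ev in events:
                if ev.kind in ("origin", "hgt"):
                    replay.update(ev.recipient.split("|"))
                elif ev.kind == "homing":
                    replay.add(ev.recipient)
                    replay.add(ev.donor)
            replay -= lost
            assert replay == carriers


class TestScenarioOutput:
    def test_conservation_non_carriers_untouched(self, two_element_scenario):
        sc = two_element_scenario
        for name, (s, e) in sc.truth.true_site_sets.items():
            for t in sc.alignment.ids:
                block = sc.alignment.rows[t][s:e]
                if t in sc.truth.carrier_sets[name]:
                    assert "-" not in block
                else:
                    assert block == "-" * (e - s)

    def test_write_read_roundtrip_and_gap_block_cross_check(self, two_element_scenario, tmp_path):
        sc = two_element_scenario
        paths = write_scenario(sc, tmp_path)
        truth = read_truth(paths["truth"])
        assert truth["carrier_sets"] == sc.truth.carrier_sets
        assert truth["site_sets"] == sc.truth.true_site_sets
        from inteinscan.alnio import read_fasta
        aln = read_fasta(paths["alignment"])
        for name, (s, e) in truth["site_sets"].items():
            for t in aln.ids:
                has_res = any(c != "-" for c in aln.rows[t][s:e])
                assert has_res == (t in truth["carrier_sets"][name])

    def test_empty_element_list_gives_pure_extein_family(self):
        cfg = ScenarioConfig(n_taxa=6, cluster_sizes=[6], extein_length=50, seed=4)
        sc = simulate_scenario(cfg)
        assert sc.alignment.n_columns == 50
        assert all("-" not in r for r in sc.alignment.rows.values())

    def test_scenario_determinism(self):
        cfg = ScenarioConfig(
            n_taxa=8, cluster_sizes=[4, 4], extein_length=80,
            element_specs=[ElementSpec("el", 30, 40, hgt_rate=0.5, min_carriers=3)],
            seed=99)
        a = simulate_scenario(cfg)
        b = simulate_scenario(cfg)
        assert a.alignment.rows == b.alignment.rows
        assert a.truth.event_log.to_records() == b.truth.event_log.to_records()

    def test_config_validation(self):
        with pytest.raises(ValueError):
            ScenarioConfig(n_taxa=2, cluster_sizes=[2], seed=0)
        with pytest.raises(ValueError):
            ScenarioConfig(n_taxa=6, cluster_sizes=[3], seed=0)
        with pytest.raises(ValueError):
            ScenarioConfig(n_taxa=6, cluster_sizes=[6], extein_length=100,
                           element_specs=[ElementSpec("a", 10, 50),
                                          ElementSpec("b", 10, 20)], seed=0)

    def test_yaml_roundtrip(self, tmp_path):
        cfg = ScenarioConfig(n_taxa=6, cluster_sizes=[6], extein_length=50,
                             element_specs=[ElementSpec("el", 20, 25)], seed=3)
        p = tmp_path / "cfg.yaml"
        cfg.to_yaml(p)
        assert ScenarioConfig.from_yaml(p) == cfg
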