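import numpy as np
import pytest

from inteinscan.phylocore import DistanceMatrix
from inteinscan.xferscan import (DegenerateDistancesError, InsufficientOverlapError,
                                 detect_recent_invasions, distance_r2,
                                 leave_one_out_r2, leave_one_out_table,
                                 mantel_pvalue, paired_distances, run_pipeline)


def dm_from(vals, taxa):
    return DistanceMatrix(taxa, np.asarray(vals, dtype=float))


@pytest.fixture()
def proportional_pair():
    taxa = list("abcd")
    rng = np.random.default_rng(5)
    base = np.zeros((4, 4))
    iu = np.triu_indices(4, 1)
    base[iu] = rng.uniform(0.2, 2.0, size=len(iu[0]))
    base += base.T
    return dm_from(3.0 * base, taxa), dm_from(base, taxa)


class TestPairedDistances:
    def test_pair_count_is_m_choose_2(self, proportional_pair):
        el, ex = proportional_pair
        pairs = paired_distances(el, ex)
        assert len(pairs.pairs) == 6

    def test_disjoint_taxa_error(self):
        a = dm_from(np.zeros((3, 3)), list("abc"))
        b = dm_from(np.zeros((3, 3)), list("xyz"))
        with pytest.raises(InsufficientOverlapError):
            paired_distances(a, b)

    def test_identical_matrices_give_equal_coordinates(self, proportional_pair):
        _, ex = proportional_pair
        pairs = paired_distances(ex, ex)
        assert np.allclose(pairs.element_d, pairs.extein_d)


class TestR2:
    def test_proportional_matrices_give_one(self, proportional_pair):
        el, ex = proportional_pair
        assert distance_r2(paired_distances(el, ex)) == pytest.approx(1.0, abs=1e-12)

    def test_rescaling_invariance(self, proportional_pair):
        el, ex = proportional_pair
        r2a = distance_r2(paired_distances(el, ex))
        el2 = DistanceMatrix(el.taxa, el.values * 7.5)
        r2b = distance_r2(paired_distances(el2, ex))
        assert r2a == pytest.approx(r2b, abs=1e-12)

    def test_zero_variance_is_error_not_zero(self):
        taxa = list("abc")
        const = np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0.0]])
        vary = np.array([[0, 1, 2], [1, 0, 3], [2, 3, 0.0]])
        with pytest.raises(DegenerateDistancesError):
            distance_r2(paired_distances(dm_from(const, taxa), dm_from(vary, taxa)))

    def test_independent_random_distances_have_low_r2(self, rng):
        low = 0
        for k in range(40):
            n = 12
            def rand_dm():
                m = np.zeros((n, n))
                iu = np.triu_indices(n, 1)
                m[iu] = rng.uniform(0.1, 3.0, size=len(iu[0]))
                return dm_from(m + m.T, [f"t{i}" for i in range(n)])
            r2 = distance_r2(paired_distances(rand_dm(), rand_dm()))
            low += (r2 < 0.1)
        assert low >= 36   # >= 90% of null draws

    def test_mantel_p_significant_for_proportional(self, proportional_pair):
        el, ex = proportional_pair
        p = mantel_pvalue(paired_distances(el, ex), n_perm=199, seed=0)
        assert p < 0.05


class TestLeaveOneOut:
    def test_exclusion_keeps_perfect_correlation(self, proportional_pair):
        el, ex = proportional_pair
        assert leave_one_out_r2(el, ex, "a") == pytest.approx(1.0, abs=1e-12)

    def test_outlier_exclusion_restores_correlation(self):
        taxa = list("abcde")
        rng = np.random.default_rng(1)
        base = np.zeros((5, 5))
        iu = np.triu_indices(5, 1)
        base[iu] = rng.uniform(0.5, 2.0, size=len(iu[0]))
        base += base.T
        noisy = base.copy()
        noisy[0, 1:] = noisy[1:, 0] = rng.uniform(4, 9, size=4)   # 'a' decoupled
        el, ex = dm_from(noisy, taxa), dm_from(base, taxa)
        r2_full = distance_r2(paired_distances(el, ex))
        table = leave_one_out_table(el, ex)
        assert table.idxmax() == "a"
        assert table["a"] > r2_full

    def test_exclusion_below_three_taxa_is_error(self, proportional_pair):
        el, ex = proportional_pair
        small_el = el.subset(["a", "b", "c"])
        small_ex = ex.subset(["a", "b", "c"])
        with pytest.raises(InsufficientOverlapError):
            leave_one_out_r2(small_el, small_ex, "a")


class TestInvasionDetection:
    def test_all_distinct_elements_yield_nothing(self):
        seqs = {"a": "MKVA", "b": "MRVA", "c": "MKLA"}
        dm = dm_from(np.array([[0, 5, 5], [5, 0, 5], [5, 5, 0.0]]), list("abc"))
        assert detect_recent_invasions(seqs, dm, identity_eps=0.0) == []

    def test_identical_elements_in_diverged_hosts_reported(self):
        seqs = {"a": "MKVA", "b": "MKVA", "c": "MKLA"}
        dm = dm_from(np.array([[0, 5, 5], [5, 0, 5], [5, 5, 0.0]]), list("abc"))
        groups = detect_recent_invasions(seqs, dm)
        assert len(groups) == 1
        g = groups[0]
        assert g.taxa == frozenset({"a", "b"})
        assert g.max_element_p_distance == 0.0
        assert g.mean_extein_distance == pytest.approx(5.0)

    def test_similar_hosts_not_reported(self):
        seqs = {"a": "MKVA", "b": "MKVA"}
        dm = dm_from(np.array([[0, 0.01], [0.01, 0.0]]), list("ab"))
        assert detect_recent_invasions(seqs, dm, min_extein_divergence=0.1) == []

    def test_raising_eps_never_shrinks_groups(self):
        seqs = {"a": "MKVA", "b": "MKVA", "c": "MKVT", "d": "XXXX"}
        dm = dm_from(np.full((4, 4), 5.0) - 5 * np.eye(4), list("abcd"))
        tight = detect_recent_invasions(seqs, dm, identity_eps=0.0)
        loose = detect_recent_invasions(seqs, dm, identity_eps=0.3)
        for g in tight:
            assert any(g.taxa <= h.taxa for h in loose)

    def test_simulated_homing_group_recovered(self, two_element_scenario, wag_g4):
        from inteinscan import xferscan
        from inteinscan.elementscan import scan_insertions
        sc = two_element_scenario
        els = scan_insertions(sc.alignment)
        mobile = next(e for e in els if e.block == sc.truth.true_site_sets["mobile"])
        res = xferscan.analyze_element(mobile, sc.alignment, wag_g4)
        group = frozenset(["T01", "T06", "T11", "T16"])
        assert any(group <= g.taxa for g in res["invasion_groups"])


class TestPipeline:
    def test_end_to_end_report_and_determinism(self, two_element_scenario, tmp_path):
        from inteinscan.simgen import write_scenario
        sc = two_element_scenario
        write_scenario(sc, tmp_path / "data")
        config = {
            "alignment": str(tmp_path / "data" / "true_alignment.fasta"),
            "metadata": str(tmp_path / "data" / "metadata.tsv"),
            "out_dir": str(tmp_path / "out"),
            "model": "WAG+G4",
            "seed": 1,
        }
        report = run_pipeline(config)
        assert report["n_sequences"] == 16
        assert len(report["elements"]) == 2
        assert (tmp_path / "out" / "report.json").exists()
        assert (tmp_path / "out" / "site_sets.tsv").exists()
        report2 = run_pipeline({**config, "out_dir": str(tmp_path / "out2")})
        assert report == report2

    def test_missing_config_key_is_named(self):
        with pytest.raises(ValueError, match="out_dir"):
            run_pipeline({"alignment": "x.fasta"})

    def test_missing_metadata_column_reported(self, two_element_scenario, tmp_path):
        from inteinscan.simgen import write_scenario
        sc = two_element_scenario
        write_scenario(sc, tmp_path / "data")
        bad = tmp_path / "bad.tsv"
        bad.write_text("phage\tcluster\nT01\tA\n")
        with pytest.raises((RuntimeError, ValueError), match="location"):
            run_pipeline({
                "alignment": str(tmp_path / "data" / "true_alignment.fasta"),
                "metadata": str(bad),
                "out_dir": str(tmp_path / "out"),
            })
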