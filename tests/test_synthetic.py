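import numpy as np
import pytest

from retbench.benchmarks import normalized_unique_curve
from retbench.data_io import load_paired_collection
from retbench.synthetic import (
    generate_community,
    packaged_collection,
    simulate_incidence,
    subsample_oracle_exact,
    subsample_oracle_mc,
    true_fraction_at_retention,
    true_retention,
    true_unique_curve,
    write_collection,
)

from conftest import random_small_paired


class TestGenerateCommunity:
    def test_deterministic_for_fixed_seed(self):
        m1 = generate_community(seed=42)
        m2 = generate_community(seed=42)
        assert m1.species_ids == m2.species_ids
        np.testing.assert_array_equal(m1.p_unlogged, m2.p_unlogged)
        np.testing.assert_array_equal(m1.p_logged, m2.p_logged)

    def test_unique_classes_have_single_habitat(self):
        m = generate_community(seed=1)
        uu, ul = m.class_mask("uu"), m.class_mask("ul")
        assert np.all(m.p_logged[uu] == 0) and np.all(m.p_unlogged[uu] > 0)
        assert np.all(m.p_unlogged[ul] == 0) and np.all(m.p_logged[ul] > 0)

    def test_rare_species_expected_under_defaults(self):
        # with a logit-normal median of 0.15 over T1=15 plots, a sizeable
        # share of species should have expected incidence frequency <= 2
        m = generate_community(seed=7)
        expected_freq = m.p_unlogged[m.p_unlogged > 0] * m.T1
        assert np.mean(expected_freq <= 2) > 0.2

    def test_invalid_sizes_rejected(self):
        with pytest.raises(ValueError):
            generate_community(n_unique_unlogged=0, n_unique_logged=0, n_shared=0)
        with pytest.raises(ValueError):
            generate_community(T1=1)


class TestSimulateIncidence:
    def test_sure_and_impossible_detections(self):
        m = generate_community(n_unique_unlogged=2, n_unique_logged=0, n_shared=1, seed=3)
        m.p_unlogged[0] = 1.0
        m.p_unlogged[1] = 0.0
        ds = simulate_incidence(m, seed=5)
        sp0, sp1 = m.species_ids[0], m.species_ids[1]
        assert ds.unlogged_freqs.Q[sp0] == m.T1
        assert sp1 not in ds.unlogged_freqs.Q

    def test_incidence_frequency_mean_matches_binomial(self):
        m = generate_community(n_unique_unlogged=5, n_unique_logged=0, n_shared=0, T1=10, seed=9)
        reps = 500
        freqs = np.zeros((reps, 5))
        for r in range(reps):
            ds = simulate_incidence(m, seed=1000 + r)
            freqs[r] = [ds.unlogged_freqs.Q.get(s, 0) for s in m.species_ids[:5]]
        expected = m.T1 * m.p_unlogged[:5]
        se = np.sqrt(m.T1 * m.p_unlogged[:5] * (1 - m.p_unlogged[:5]) / reps)
        assert np.all(np.abs(freqs.mean(axis=0) - expected) <= 3 * se + 1e-9)


class TestTrueCurve:
    def test_closed_form_values(self):
        m = generate_community(n_unique_unlogged=1, n_unique_logged=0, n_shared=1, seed=0)
        m.p_unlogged[0] = 0.5
        assert true_unique_curve(m, 0) == 0.0
        assert true_unique_curve(m, 2) == pytest.approx(0.75)
        m.p_unlogged[0] = 1.0
        assert true_unique_curve(m, 1) == pytest.approx(1.0)

    def test_retention_inverts_normalized_curve(self):
        m = generate_community(seed=4)
        p_star = true_retention(m, 0.9)
        assert true_fraction_at_retention(m, p_star) == pytest.approx(0.9, abs=1e-9)


class TestOracles:
    @pytest.mark.parametrize("seed", range(6))
    def test_exact_oracle_matches_analytic(self, seed, meta):
        rng = np.random.default_rng(seed + 50)
        paired = random_small_paired(rng, meta)
        t1 = int(rng.integers(0, paired.T1 + 1))
        t2 = int(rng.integers(0, paired.T2 + 1))
        from retbench.mixture import _components_at

        analytic = _components_at(paired, float(t1), float(t2), "reference")
        oracle = subsample_oracle_exact(paired, t1, t2)
        for name in ("unique_unlogged", "unique_logged", "shared", "total"):
            assert analytic[name] == pytest.approx(oracle[name], abs=1e-10)

    def test_full_unlogged_subset_recovers_sample(self, tiny_paired):
        oracle = subsample_oracle_exact(tiny_paired, tiny_paired.T1, 0)
        assert oracle["total"] == tiny_paired.unlogged_freqs.S_obs

    def test_mc_agrees_with_exact_within_3se(self, meta):
        rng = np.random.default_rng(11)
        paired = random_small_paired(rng, meta)
        t1, t2 = paired.T1 // 2, paired.T2 // 2
        exact = subsample_oracle_exact(paired, t1, t2)
        mc, se = subsample_oracle_mc(paired, t1, t2, reps=4000, seed=3)
        for name in exact:
            assert abs(mc[name] - exact[name]) <= 3 * se[name] + 1e-9

    def test_se_scaling_with_reps(self, collection):
        paired = collection[0].paired
        t1, t2 = paired.T1 // 2, min(paired.T1 - paired.T1 // 2, paired.T2)
        _, se1 = subsample_oracle_mc(paired, t1, t2, reps=500, seed=1)
        _, se4 = subsample_oracle_mc(paired, t1, t2, reps=8000, seed=2)
        ratio = se1["total"] / se4["total"]
        assert 4 * 0.7 <= ratio <= 4 * 1.3  # SE ~ 1/sqrt(reps)

    def test_degenerate_full_sample_has_zero_variance(self, tiny_paired):
        mc, se = subsample_oracle_mc(tiny_paired, tiny_paired.T1, tiny_paired.T2, reps=200, seed=0)
        assert se["total"] == 0.0

    def test_enumeration_budget_enforced(self, collection):
        paired = collection[0].paired  # T1=20: C(20,10)^... way over budget
        with pytest.raises(ValueError, match="budget"):
            subsample_oracle_exact(paired, paired.T1 // 2, paired.T2 // 2)


class TestCollection:
    def test_structure(self, collection):
        assert len(collection) == 24
        metas = [st.paired.meta for st in collection]
        assert len({m.dataset_id for m in metas}) == 24
        assert {m.disturbance_type for m in metas} == {"fire", "windstorm", "insect_outbreak"}
        assert sum(m.saproxylic for m in metas) == 12
        for st in collection:
            assert 5 <= st.paired.T1 <= 30 and 5 <= st.paired.T2 <= 30
            assert 10 <= len(st.paired.species_universe) <= 300

    def test_round_trips_through_files(self, collection, tmp_path):
        write_collection(collection[:3], tmp_path)
        datasets, excluded = load_paired_collection(tmp_path / "meta.csv", tmp_path)
        assert not excluded and len(datasets) == 3
        for orig, loaded in zip(collection[:3], datasets):
            assert loaded.unlogged_freqs.Q == orig.paired.unlogged_freqs.Q
            assert loaded.logged_freqs.Q == orig.paired.logged_freqs.Q
            assert loaded.meta == orig.paired.meta

    def test_estimator_consistency_in_T1(self):
        # the normalized estimated unique curve approaches the analytic truth
        # as the number of plots grows, model held fixed
        devs = []
        for T1 in (10, 40, 160):
            m = generate_community(
                n_unique_unlogged=30, n_unique_logged=15, n_shared=40, T1=T1, T2=T1, seed=21
            )
            max_dev = []
            for rep in range(4):
                ds = simulate_incidence(m, seed=500 + rep)
                ps = np.linspace(0.1, 0.9, 9)
                est = [normalized_unique_curve(ds, p) for p in ps]
                tru = [true_fraction_at_retention(m, p) for p in ps]
                max_dev.append(np.max(np.abs(np.array(est) - np.array(tru))))
            devs.append(np.mean(max_dev))
        assert devs[2] < devs[1] < devs[0]
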