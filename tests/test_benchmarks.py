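import math

import numpy as np
import pytest

from retbench.benchmarks import (
    PipelineConfig,
    compute_benchmark,
    normalized_unique_curve,
    retention_for_fraction,
    run_pipeline,
    summarize_benchmarks,
    unique_fraction_at_retention,
)
from retbench.data_io import SpeciesPlotMatrix, StudyMetadata, pair_datasets
from retbench.synthetic import subsample_oracle_exact


@pytest.fixture
def concave_paired(meta):
    """All unique species occur in every unlogged plot (Q_i = T1): the
    unique-richness curve saturates almost immediately."""
    T1 = 4
    counts_u = np.vstack([np.ones((2, T1), int), np.ones((1, T1), int)])
    u = SpeciesPlotMatrix(("x", "y", "shared"), tuple(f"u{i}" for i in range(T1)), counts_u, "unlogged")
    l = SpeciesPlotMatrix(("shared",), ("l1", "l2"), np.array([[1, 1]]), "logged")
    return pair_datasets(u, l, meta)


class TestNormalizedCurve:
    def test_linear_case_is_identity(self, linear_paired):
        for p in (0.0, 0.25, 0.5, 0.9, 1.0):
            assert normalized_unique_curve(linear_paired, p) == pytest.approx(p, abs=1e-9)

    def test_concave_case_above_diagonal(self, concave_paired):
        # enumeration oracle: unique richness at t1=2 of T1=4 is already 2/2
        oracle = subsample_oracle_exact(concave_paired, 2, 0)
        full = subsample_oracle_exact(concave_paired, 4, 0)
        assert normalized_unique_curve(concave_paired, 0.5) == pytest.approx(
            oracle["unique_unlogged"] / full["unique_unlogged"], abs=1e-10
        )
        assert unique_fraction_at_retention(concave_paired, 0.5) > 0.5


class TestRetentionInversion:
    def test_linear_case_returns_q(self, linear_paired):
        assert retention_for_fraction(linear_paired, 0.9) == pytest.approx(0.9, abs=1e-6)

    def test_residual_bound(self, collection):
        for st in collection[:6]:
            p_star = retention_for_fraction(st.paired, 0.9, tol=1e-6)
            assert abs(normalized_unique_curve(st.paired, p_star) - 0.9) <= 1e-6

    def test_concave_case_needs_less_than_q(self, concave_paired):
        p_star = retention_for_fraction(concave_paired, 0.9)
        # brute-force grid scan lower bound
        grid = np.linspace(0, 1, 2001)
        first = grid[
            next(i for i, p in enumerate(grid) if normalized_unique_curve(concave_paired, p) >= 0.9)
        ]
        assert p_star < 0.9
        assert p_star == pytest.approx(first, abs=1e-3)

    def test_monotone_in_q_and_consistency(self, collection):
        paired = collection[3].paired
        qs = [0.5, 0.7, 0.9, 0.95, 0.99]
        p_stars = [retention_for_fraction(paired, q) for q in qs]
        assert np.all(np.diff(p_stars) >= 0)
        for q, p_star in zip(qs, p_stars):
            assert unique_fraction_at_retention(paired, p_star) >= q - 1e-6

    def test_q_domain_error(self, linear_paired):
        with pytest.raises(ValueError):
            retention_for_fraction(linear_paired, 1.0)


class TestUndefinedStatus:
    def test_no_unique_species_yields_status_flag(self, meta):
        u = SpeciesPlotMatrix(("a",), ("u1",), np.array([[1]]), "unlogged")
        l = SpeciesPlotMatrix(("a",), ("l1",), np.array([[1]]), "logged")
        res = compute_benchmark(pair_datasets(u, l, meta))
        assert res.status == "undefined_no_unique_species"
        assert res.p_star is None and res.frac_at_half is None


def make_meta(i, **kw):
    base = dict(
        dataset_id=f"d{i}",
        study_id="s1",
        taxon_group="beetles",
        saproxylic=False,
        disturbance_type="fire",
        years_since_disturbance=float(i),
    )
    base.update(kw)
    return StudyMetadata(**base)


class TestSummaries:
    def make_results(self, values, **meta_kw):
        from retbench.benchmarks import BenchmarkResult

        results, metas = [], []
        for i, v in enumerate(values):
            results.append(
                BenchmarkResult(f"d{i}", v, v, 5, 10, 10, "ok" if v is not None else
                                "undefined_no_unique_species")
            )
            metas.append(make_meta(i, **meta_kw))
        return results, metas

    def test_two_point_group(self):
        results, metas = self.make_results([0.7, 0.8])
        (s,) = summarize_benchmarks(results, metas, "all")
        assert s.n == 2
        assert s.mean == pytest.approx(0.75)
        assert s.sd == pytest.approx(np.std([0.7, 0.8], ddof=1))

    def test_single_dataset_sd_missing(self):
        results, metas = self.make_results([0.6])
        (s,) = summarize_benchmarks(results, metas, "all")
        assert s.mean == 0.6 and s.sd is None

    def test_undefined_excluded(self):
        results, metas = self.make_results([0.7, None, 0.8])
        (s,) = summarize_benchmarks(results, metas, "all")
        assert s.n == 2

    def test_pooled_matches_independent_accumulation(self, collection):
        results = [compute_benchmark(st.paired) for st in collection]
        metas = [st.paired.meta for st in collection]
        (s,) = summarize_benchmarks(results, metas, "all")
        vals = sorted(r.p_star for r in results)  # different accumulation order
        mean = math.fsum(vals) / len(vals)
        sd = math.sqrt(math.fsum((v - mean) ** 2 for v in vals) / (len(vals) - 1))
        assert s.mean == pytest.approx(mean, abs=1e-12)
        assert s.sd == pytest.approx(sd, abs=1e-12)

    def test_group_levels(self):
        results, metas = self.make_results([0.6, 0.7, 0.8])
        metas[2] = make_meta(2, disturbance_type="windstorm")
        summaries = summarize_benchmarks(results, metas, "disturbance_type")
        by_level = {s.level: s for s in summaries}
        assert by_level["fire"].n == 2 and by_level["windstorm"].n == 1


class TestPipeline:
    def test_config_yaml_round_trip(self, tmp_path):
        p = tmp_path / "cfg.yaml"
        p.write_text("q_target: 0.8\nn_grid: 31\nseed: 7\n")
        cfg = PipelineConfig.from_yaml(p)
        assert cfg.q_target == 0.8 and cfg.n_grid == 31 and cfg.seed == 7
        p.write_text("not_a_key: 1\n")
        with pytest.raises(ValueError):
            PipelineConfig.from_yaml(p)

    def test_run_over_collection(self, collection, tmp_path):
        cfg = PipelineConfig(n_grid=21)
        out = run_pipeline([st.paired for st in collection], cfg, out_dir=tmp_path / "out")
        bench = out["benchmarks"]
        assert len(bench) == 24
        assert (bench["status"] == "ok").all()
        assert (tmp_path / "out" / "benchmarks.csv").exists()
        assert (tmp_path / "out" / "run.log").exists()

    def test_removing_one_dataset_changes_only_that_row(self, collection):
        cfg = PipelineConfig(n_grid=11)
        full = run_pipeline([st.paired for st in collection], cfg)["benchmarks"]
        reduced = run_pipeline([st.paired for st in collection[1:]], cfg)["benchmarks"]
        merged = full[full.dataset_id != full.dataset_id.iloc[0]].reset_index(drop=True)
        assert merged.equals(reduced.reset_index(drop=True))

    def test_all_undefined_aborts(self, meta):
        u = SpeciesPlotMatrix(("a",), ("u1",), np.array([[1]]), "unlogged")
        l = SpeciesPlotMatrix(("a",), ("l1",), np.array([[1]]), "logged")
        with pytest.raises(RuntimeError):
            run_pipeline([pair_datasets(u, l, meta)], PipelineConfig(n_grid=5))
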