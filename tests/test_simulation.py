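import math

import numpy as np
import pytest

from setenrich import (
    BenchmarkConfig,
    OverlapSpec,
    generate_overlapping_ontology,
    list_to_collection,
    make_noisy_target,
    pairwise_overlap_stats,
    run_benchmark,
)


class TestPairwiseOverlapStats:
    def test_single_shared_gene(self):
        col = list_to_collection({"A": ["a", "b"], "B": ["b", "c"]})
        assert pairwise_overlap_stats(col).mean == 1.0

    def test_disjoint(self):
        col = list_to_collection({"A": ["a"], "B": ["b"], "C": ["c"]})
        assert pairwise_overlap_stats(col).mean == 0.0

    def test_identical_entries(self):
        genes = [f"g{i}" for i in range(5)]
        col = list_to_collection({"A": genes, "B": genes, "C": genes})
        assert pairwise_overlap_stats(col).mean == 5.0

    def test_requires_two_entries(self):
        with pytest.raises(ValueError):
            pairwise_overlap_stats(list_to_collection({"A": ["a"]}))


class TestGenerator:
    def test_zero_overlap_exactly_disjoint(self):
        spec = OverlapSpec(n_entries=5, genes_per_entry=(3, 6),
                           mean_pairwise_overlap=0.0, universe_size=100)
        col = generate_overlapping_ontology(spec, seed=1)
        assert pairwise_overlap_stats(col).mean == 0.0

    @pytest.mark.parametrize("target", [16.0, 1.0])
    def test_mean_overlap_within_15_percent(self, target):
        col = generate_overlapping_ontology(
            OverlapSpec(mean_pairwise_overlap=target), seed=123
        )
        got = pairwise_overlap_stats(col).mean
        assert abs(got - target) / target < 0.15

    def test_seed_determinism(self):
        spec = OverlapSpec()
        a = generate_overlapping_ontology(spec, seed=9)
        b = generate_overlapping_ontology(spec, seed=9)
        assert [(s.ontology_id, s.members) for s in a] == [
            (s.ontology_id, s.members) for s in b
        ]

    def test_entry_sizes_within_range(self):
        spec = OverlapSpec(genes_per_entry=(5, 200))
        col = generate_overlapping_ontology(spec, seed=2)
        assert all(5 <= len(s) <= 200 for s in col)

    def test_unachievable_overlap_rejected(self):
        spec = OverlapSpec(genes_per_entry=(3, 8), mean_pairwise_overlap=16.0)
        with pytest.raises(ValueError, match="unachievable"):
            generate_overlapping_ontology(spec, seed=0)


class TestMakeNoisyTarget:
    @pytest.fixture
    def collection(self):
        return generate_overlapping_ontology(
            OverlapSpec(n_entries=10, genes_per_entry=(5, 30),
                        mean_pairwise_overlap=2.0, universe_size=2000),
            seed=4,
        )

    def test_zero_noise_target_is_core(self, collection):
        cfg = BenchmarkConfig(iterations=1, seed=0)
        rng = np.random.default_rng(1)
        target, sources = make_noisy_target(collection, cfg, 0.0, rng)
        union = set()
        for sid in sources:
            union |= set(collection[sid].members)
        assert target <= union
        assert len(target) == math.ceil(0.85 * len(union))

    def test_noise_count_is_ceiling_of_ratio(self, collection):
        cfg = BenchmarkConfig(iterations=1, seed=0)
        rng = np.random.default_rng(2)
        target, sources = make_noisy_target(collection, cfg, 0.3, rng)
        union = set()
        for sid in sources:
            union |= set(collection[sid].members)
        core = target & union
        noise = target - union
        assert len(noise) == math.ceil(0.3 * len(core))

    def test_source_count(self, collection):
        cfg = BenchmarkConfig(iterations=1, seed=0)
        _, sources = make_noisy_target(
            collection, cfg, 0.0, np.random.default_rng(3)
        )
        assert len(sources) == math.ceil(0.2 * len(collection))

    def test_disjoint_sources_core_size(self):
        col = list_to_collection(
            {f"S{j}": [f"g{j}_{i}" for i in range(10)] for j in range(5)}
        )
        cfg = BenchmarkConfig(source_fraction=0.4, iterations=1, seed=0)
        target, sources = make_noisy_target(col, cfg, 0.0, np.random.default_rng(0))
        assert len(sources) == 2
        assert len(target) == math.ceil(0.85 * 20)

    def test_noise_pool_exhaustion_errors(self):
        col = list_to_collection({"A": ["a", "b", "c"], "B": ["a", "b", "d"]})
        cfg = BenchmarkConfig(source_fraction=1.0, iterations=1, seed=0)
        with pytest.raises(ValueError, match="noise pool"):
            make_noisy_target(col, cfg, 0.5, np.random.default_rng(0))


@pytest.fixture(scope="module")
def small_run():
    spec = OverlapSpec(n_entries=12, genes_per_entry=(5, 40),
                       mean_pairwise_overlap=3.0, universe_size=2000)
    cfg = BenchmarkConfig(iterations=3, efdr_resamples=100,
                          noise_ratios=(0.0, 0.2), seed=21)
    return run_benchmark(spec, cfg), spec, cfg


class TestRunBenchmark:
    def test_result_shape(self, small_run):
        (results, summary), spec, cfg = small_run
        assert len(results) == 2 * 3 * 2  # ratios x iterations x methods
        assert set(results["method"]) == {"efdr", "bh"}
        assert ((results["tpr"] >= 0) & (results["tpr"] <= 1)).all()
        assert ((results["fpr"] >= 0) & (results["fpr"] <= 1)).all()
        assert list(summary["noise_ratio"]) == [0.0, 0.2]

    def test_rates_are_exact_ratios(self, small_run):
        """TPR/FPR denominators are |sources| and |non-sources|."""
        (results, _), spec, cfg = small_run
        n_src = math.ceil(cfg.source_fraction * spec.n_entries)
        n_non = spec.n_entries - n_src
        assert ((results["tpr"] * n_src) % 1 < 1e-9).all()
        assert ((results["fpr"] * n_non) % 1 < 1e-9).all()

    def test_seed_determinism(self, small_run):
        (results, _), spec, cfg = small_run
        results2, _ = run_benchmark(spec, cfg)
        assert results.equals(results2)

    def test_alpha_zero_gives_no_discoveries(self):
        spec = OverlapSpec(n_entries=8, genes_per_entry=(4, 12),
                           mean_pairwise_overlap=1.0, universe_size=1000)
        cfg = BenchmarkConfig(iterations=2, efdr_resamples=50, alpha=0.0,
                              noise_ratios=(0.0,), seed=5)
        results, _ = run_benchmark(spec, cfg)
        assert (results["tpr"] == 0).all()
        assert (results["fpr"] == 0).all()
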