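"""Unit tests for the hypergeometric overrepresentation core.

The ground truth is exact combinatorics: P(X >= k) computed as a Fraction
tail sum of C(K,x)C(N-K,n-x)/C(N,n), independently validated by literal
enumeration of subsets on small backgrounds.
"""

from fractions import Fraction
from itertools import combinations
from math import comb

import numpy as np
import pytest
from scipy.stats import fisher_exact

from setenrich import (
    EntryCounts,
    hypergeom_upper_tail,
    list_to_collection,
    run_ora,
    validate_query,
)


def exact_tail(k, K, n, N) -> Fraction:
    """Exact P(X >= k) via the combinatorial tail sum."""
    num = sum(comb(K, x) * comb(N - K, n - x) for x in range(k, min(K, n) + 1))
    return Fraction(num, comb(N, n))


def enumerated_tail(k, K, n, N) -> Fraction:
    """Exact P(X >= k) by enumerating every n-subset of the background."""
    hits = 0
    total = 0
    marked = set(range(K))
    for subset in combinations(range(N), n):
        total += 1
        if len(marked.intersection(subset)) >= k:
            hits += 1
    return Fraction(hits, total)


class TestHypergeomUpperTail:
    def test_printed_example(self):
        """N=20, K=5, n=5, k=4 has exact tail 76/15504."""
        c = EntryCounts(k=4, K=5, n=5, N=20)
        assert exact_tail(4, 5, 5, 20) == Fraction(76, 15504)
        assert hypergeom_upper_tail(c) == pytest.approx(76 / 15504, rel=1e-12)

    def test_zero_overlap_is_one(self):
        assert hypergeom_upper_tail(EntryCounts(k=0, K=5, n=5, N=20)) == 1.0

    def test_entry_covering_background(self):
        assert hypergeom_upper_tail(EntryCounts(k=5, K=20, n=5, N=20)) == 1.0

    def test_monotone_in_overlap(self):
        ps = [
            hypergeom_upper_tail(EntryCounts(k=k, K=8, n=6, N=30))
            for k in range(7)
        ]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_matches_subset_enumeration(self):
        """Spot-check the closed-form tail against literal enumeration."""
        for N, K, n in [(8, 3, 4), (10, 5, 5), (12, 4, 6)]:
            for k in range(min(K, n) + 1):
                assert exact_tail(k, K, n, N) == enumerated_tail(k, K, n, N)
                got = hypergeom_upper_tail(EntryCounts(k=k, K=K, n=n, N=N))
                assert got == pytest.approx(float(exact_tail(k, K, n, N)), rel=1e-12)

    def test_matches_one_tailed_fisher(self):
        for k, K, n, N in [(4, 5, 5, 20), (2, 6, 8, 25), (0, 3, 3, 10)]:
            table = [[k, n - k], [K - k, N - K - n + k]]
            fisher_p = fisher_exact(table, alternative="greater")[1]
            got = hypergeom_upper_tail(EntryCounts(k=k, K=K, n=n, N=N))
            assert got == pytest.approx(fisher_p, rel=1e-9)

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            EntryCounts(k=6, K=5, n=5, N=20)
        with pytest.raises(ValueError):
            EntryCounts(k=1, K=5, n=5, N=4)


class TestValidateQuery:
    def test_out_of_background_dropped_with_warning(self, tiny_collection):
        with pytest.warns(UserWarning, match="dropped"):
            q = validate_query(["g01", "g02", "zzz"], ["g01", "g02", "g03"],
                               tiny_collection)
        assert q.target == ("g01", "g02")
        assert q.n_dropped == 1

    def test_subset_target_unchanged(self, tiny_collection, tiny_background):
        q = validate_query(["g03", "g01"], tiny_background, tiny_collection)
        assert q.target == ("g01", "g03")
        assert q.n_dropped == 0

    def test_disjoint_target_errors(self, tiny_collection):
        with pytest.warns(UserWarning):
            with pytest.raises(ValueError, match="empty"):
                validate_query(["x"], ["g01"], tiny_collection)

    def test_empty_background_errors(self, tiny_collection):
        with pytest.raises(ValueError, match="background"):
            validate_query(["g01"], [], tiny_collection)


class TestRunOra:
    def test_entry_equal_to_background_gets_p_one(self):
        bg = [f"g{i}" for i in range(10)]
        col = list_to_collection({"ALL": bg})
        table = run_ora(validate_query(bg[:4], bg, col))
        assert table.loc[0, "p_raw"] == 1.0

    def test_embedded_printed_example(self):
        bg = [f"g{i}" for i in range(20)]
        col = list_to_collection({"E": bg[:5]})
        table = run_ora(validate_query(bg[:4] + [bg[10]], bg, col))
        assert table.loc[0, "k"] == 4
        assert table.loc[0, "p_raw"] == pytest.approx(76 / 15504, rel=1e-12)

    def test_identical_entries_identical_rows(self, tiny_background):
        col = list_to_collection(
            {"A": ["g01", "g02", "g03"], "B": ["g01", "g02", "g03"]}
        )
        table = run_ora(validate_query(["g01", "g02"], tiny_background, col))
        a, b = table.iloc[0], table.iloc[1]
        assert (a[["k", "K", "n", "N", "p_raw"]] == b[["k", "K", "n", "N", "p_raw"]]).all()

    def test_rows_follow_collection_order(self, tiny_collection, tiny_background):
        table = run_ora(validate_query(["g01", "g03"], tiny_background,
                                       tiny_collection))
        assert list(table["ontology_id"]) == tiny_collection.ids

    def test_zero_overlap_entry_retained(self, tiny_collection, tiny_background):
        table = run_ora(validate_query(["g01", "g02"], tiny_background,
                                       tiny_collection))
        row = table[table.ontology_id == "TF3"].iloc[0]
        assert row["k"] == 0 and row["p_raw"] == 1.0

    def test_brute_force_oracle_on_random_instances(self):
        """p_raw equals exhaustive subset enumeration on small universes."""
        rng = np.random.default_rng(7)
        for _ in range(5):
            N = int(rng.integers(6, 11))
            bg = [f"g{i}" for i in range(N)]
            K = int(rng.integers(1, N))
            n = int(rng.integers(1, N))
            col = list_to_collection({"E": bg[:K]})
            target = list(rng.choice(bg, size=n, replace=False))
            table = run_ora(validate_query(target, bg, col))
            k = int(table.loc[0, "k"])
            assert table.loc[0, "p_raw"] == pytest.approx(
                float(enumerated_tail(k, K, n, N)), rel=1e-12
            )
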