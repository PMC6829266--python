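"""Negative-pool expansion and mixed negative-set assembly."""

import itertools

import pytest
from hypothesis import given, settings, strategies as st

from neglog.homology import HomologyMap
from neglog.io_formats import PairList, canonical_pair
from neglog.sampling import (
    NeglogPool,
    SamplingConfig,
    build_negative_set,
    expand_neglog,
    sample_random_pairs,
)


def _map(d):
    sym = {}
    for a, hits in d.items():
        for b in hits:
            sym.setdefault(a, {})[b] = 1e-30
            sym.setdefault(b, {})[a] = 1e-30
    return HomologyMap(neighbors=sym)


def brute_force_pool(seeds, hmap):
    """Independent enumeration of the per-seed expansion sets, unioned."""
    out = set()
    for a, b in seeds:
        A = hmap.homologs_of(a)
        B = hmap.homologs_of(b)
        for x, y in itertools.product({a} | A, {b} | B):
            if x != y:
                out.add(canonical_pair(x, y))
    return out


class TestExpandNeglog:
    def test_seed_without_homologs_expands_to_itself(self):
        pool = expand_neglog(PairList(pairs=[("a", "b")]), _map({}))
        assert pool.pairs == {("a", "b")}

    def test_single_homolog_each_side_gives_four_pairs(self):
        hmap = _map({"a": {"a1"}, "b": {"b1"}})
        pool = expand_neglog(PairList(pairs=[("a", "b")]), hmap)
        assert pool.pairs == {
            ("a", "b"), ("a", "b1"), ("a1", "b"), ("a1", "b1"),
        }

    def test_cartesian_count_with_distinct_proteins(self):
        hmap = _map({"a": {"a1", "a2"}, "b": {"b1", "b2", "b3"}})
        pool = expand_neglog(PairList(pairs=[("a", "b")]), hmap)
        assert len(pool) == (2 + 1) * (3 + 1)

    def test_empty_seed_list_errors(self):
        with pytest.raises(ValueError, match="empty seed"):
            expand_neglog(PairList(pairs=[]), _map({}))

    def test_provenance_tracks_seed(self):
        hmap = _map({"a": {"a1"}})
        pool = expand_neglog(PairList(pairs=[("a", "b")]), hmap)
        assert pool.provenance[("a1", "b")] == {("a", "b")}

    @settings(max_examples=60, deadline=None)
    @given(
        seeds=st.lists(
            st.tuples(st.sampled_from("abcdefgh"), st.sampled_from("abcdefgh"))
            .filter(lambda t: t[0] != t[1]),
            min_size=1,
            max_size=5,
        ),
        edges=st.lists(
            st.tuples(st.sampled_from("abcdefgh"), st.sampled_from("nopqrstuv")),
            max_size=12,
        ),
    )
    def test_matches_brute_force_oracle(self, seeds, edges):
        hmap = _map({})
        d = {}
        for a, b in edges:
            d.setdefault(a, set()).add(b)
        hmap = _map(d)
        seed_list = PairList(pairs=seeds)
        pool = expand_neglog(seed_list, hmap)
        assert pool.pairs == brute_force_pool(seed_list, hmap)
        # pool contains every seed and only homolog-derived substitutions
        assert seed_list.pair_set <= pool.pairs

    def test_monotone_in_homolog_map(self):
        seeds = PairList(pairs=[("a", "b"), ("c", "d")])
        small = _map({"a": {"a1"}})
        large = _map({"a": {"a1", "a2"}, "d": {"d1"}})
        assert expand_neglog(seeds, small).pairs <= expand_neglog(seeds, large).pairs


class TestSampleRandomPairs:
    def test_only_admissible_pair(self):
        pl = sample_random_pairs({"A", "B"}, 1, rng_seed=0)
        assert pl.pairs == [("A", "B")]

    def test_exhausted_space_reports_shortfall(self):
        excl = {("A", "B"), ("A", "C"), ("B", "C")}
        with pytest.raises(ValueError, match="shortfall"):
            sample_random_pairs({"A", "B", "C"}, 1, exclusions=excl, rng_seed=0)

    def test_deterministic_for_fixed_seed(self):
        space = {f"P{i}" for i in range(30)}
        a = sample_random_pairs(space, 50, rng_seed=42)
        b = sample_random_pairs(space, 50, rng_seed=42)
        assert a.pairs == b.pairs

    def test_no_self_pairs_no_duplicates(self):
        space = {f"P{i}" for i in range(10)}
        pl = sample_random_pairs(space, 30, rng_seed=1)
        assert len(set(pl.pairs)) == 30
        assert all(a != b for a, b in pl)


class TestBuildNegativeSet:
    def _pool(self, n):
        pairs = {(f"n{i:03d}a", f"n{i:03d}b") for i in range(n)}
        return NeglogPool(pairs=pairs, provenance={p: set() for p in pairs})

    def test_seventy_thirty_composition(self):
        pool = self._pool(20)
        space = {f"R{i}" for i in range(20)}
        out = build_negative_set(
            pool, SamplingConfig(n_total=10, neglog_fraction=0.7, random_space=space, rng_seed=0)
        )
        n_pool = sum(1 for p in out if p in pool.pairs)
        assert len(out) == 10
        assert n_pool == 7

    def test_full_neglog_fraction(self):
        pool = self._pool(12)
        out = build_negative_set(
            pool, SamplingConfig(n_total=12, neglog_fraction=1.0, rng_seed=0)
        )
        assert out.pair_set <= pool.pairs and len(out) == 12

    def test_disjoint_from_exclusions(self):
        pool = self._pool(30)
        excluded = set(list(pool.pairs)[:10])
        space = {f"R{i}" for i in range(20)}
        out = build_negative_set(
            pool,
            SamplingConfig(
                n_total=14, neglog_fraction=0.5, random_space=space,
                exclusions=excluded, rng_seed=3,
            ),
        )
        assert not (out.pair_set & excluded)

    def test_pool_too_small_is_error_not_topped_up(self):
        pool = self._pool(3)
        with pytest.raises(ValueError, match="admissible"):
            build_negative_set(
                pool, SamplingConfig(n_total=10, neglog_fraction=0.7, rng_seed=0)
            )

    def test_empty_pool_with_positive_fraction_errors(self):
        with pytest.raises(ValueError, match="pool is empty"):
            build_negative_set(
                NeglogPool(), SamplingConfig(n_total=2, neglog_fraction=0.5, rng_seed=0)
            )

    def test_random_share_never_duplicates_pool_pairs(self):
        pool = NeglogPool(pairs={("R0", "R1")}, provenance={("R0", "R1"): set()})
        space = {"R0", "R1", "R2"}
        out = build_negative_set(
            pool,
            SamplingConfig(n_total=3, neglog_fraction=1 / 3, random_space=space, rng_seed=0),
        )
        assert len(set(out.pairs)) == 3

    def test_deterministic_for_fixed_seed(self):
        pool = self._pool(40)
        space = {f"R{i}" for i in range(30)}
        cfg = dict(n_total=20, neglog_fraction=0.7, random_space=space, rng_seed=9)
        a = build_negative_set(self._pool(40), SamplingConfig(**cfg))
        b = build_negative_set(pool, SamplingConfig(**cfg))
        assert a.pairs == b.pairs
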