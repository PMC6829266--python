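"""Negative-data construction: homology expansion of curated
non-interactions and assembly of the mixed negative training set.

The central assumption is the negative counterpart of the interolog idea:
if proteins ``a`` and ``b`` are known not to interact, their paralogs and
orthologs are unlikely to interact either, because the structural mismatch
that prevents binding is conserved within a homology family. Each curated
seed non-interaction ``(a, b)`` with homolog sets ``A = homologs(a)`` and
``B = homologs(b)`` therefore expands to the pool

    {(a, b)} u {(a, b') : b' in B} u {(a', b) : a' in A}
            u {(a', b') : a' in A, b' in B}

and the union of these pools over all seeds is the inferred negative
space. A pure homology-derived negative set covers few proteins and risks
a biased model, so the training negatives mix pool pairs with uniformly
random pairs (default 7:3 pool:random), the total matched to the number
of positives.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .homology import HomologyMap
from .io_formats import PairList, ProteinPair, canonical_pair

logger = logging.getLogger("neglog")

DEFAULT_NEGLOG_FRACTION = 0.7


@dataclass
class NeglogPool:
    """Expanded negative pool with per-pair provenance.

    ``provenance`` maps each pool pair to the seed pair(s) it derives
    from; seeds derive from themselves.
    """

    pairs: set[ProteinPair] = field(default_factory=set)
    provenance: dict[ProteinPair, set[ProteinPair]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.pairs)

    def __contains__(self, pair: ProteinPair) -> bool:
        return canonical_pair(*pair) in self.pairs


@dataclass
class SamplingConfig:
    """How to assemble the negative training set.

    Parameters
    ----------
    n_total:
        Number of negative pairs to produce (match the positive count).
    neglog_fraction:
        Fraction drawn from the homology-expanded pool; the remainder is
        uniform random. Default 0.7 (the 7:3 pool:random mix).
    random_space:
        Proteins eligible for random sampling (conventionally those with
        at least one molecular-function or biological-process GO term).
    exclusions:
        Pairs the output must avoid: positives, reserved test pairs.
    rng_seed:
        Seed for the single random generator all sampling flows through.
    """

    n_total: int
    neglog_fraction: float = DEFAULT_NEGLOG_FRACTION
    random_space: set[str] = field(default_factory=set)
    exclusions: set[ProteinPair] = field(default_factory=set)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_total < 0:
            raise ValueError("n_total must be >= 0")
        if not 0.0 <= self.neglog_fraction <= 1.0:
            raise ValueError("neglog_fraction must lie in [0, 1]")
        self.exclusions = {canonical_pair(*p) for p in self.exclusions}


def expand_neglog(seeds: PairList, hmap: HomologyMap) -> NeglogPool:
    """Expand seed non-interactions through the homology map.

    Every seed is retained; every derived pair replaces at least one seed
    coordinate with one of its homologs. Output is canonicalized,
    deduplicated, and free of self-pairs.
    """
    if len(seeds) == 0:
        raise ValueError("empty seed list: nothing to expand")
    pool = NeglogPool()
    for seed in seeds:
        a, b = seed
        firsts = [a, *sorted(hmap.homologs_of(a))]
        seconds = [b, *sorted(hmap.homologs_of(b))]
        for x, y in itertools.product(firsts, seconds):
            if x == y:
                continue
            p = canonical_pair(x, y)
            pool.pairs.add(p)
            pool.provenance.setdefault(p, set()).add(seed)
    return pool


def _all_pairs(space: set[str]) -> list[ProteinPair]:
    prots = sorted(space)
    return [(prots[i], prots[j]) for i in range(len(prots)) for j in range(i + 1, len(prots))]


def sample_random_pairs(
    space: set[str],
    n: int,
    exclusions: set[ProteinPair] | None = None,
    rng_seed: int = 0,
) -> PairList:
    """Sample ``n`` distinct canonical pairs uniformly from ``space``.

    Self-pairs and ``exclusions`` are inadmissible. Sampling is without
    replacement and reproducible for a fixed ``rng_seed``. Raises when
    fewer than ``n`` admissible pairs exist, reporting the shortfall.

    For large spaces rejection sampling is used; when the admissible set
    is small relative to ``n`` it is enumerated exactly.
    """
    exclusions = {canonical_pair(*p) for p in (exclusions or set())}
    m = len(space)
    total = m * (m - 1) // 2
    n_admissible_bound = total - sum(1 for p in exclusions if p[0] in space and p[1] in space)
    if n > n_admissible_bound:
        raise ValueError(
            f"requested {n} random pairs but only {n_admissible_bound} admissible "
            f"pairs exist (shortfall {n - n_admissible_bound})"
        )
    rng = np.random.default_rng(rng_seed)
    chosen: list[ProteinPair] = []
    if total <= max(100_000, 4 * n):
        admissible = [p for p in _all_pairs(space) if p not in exclusions]
        if n > len(admissible):
            raise ValueError(
                f"requested {n} random pairs but only {len(admissible)} admissible "
                f"pairs exist (shortfall {n - len(admissible)})"
            )
        idx = rng.choice(len(admissible), size=n, replace=False)
        chosen = [admissible[i] for i in idx]
    else:
        prots = sorted(space)
        seen: set[ProteinPair] = set()
        # Rejection sampling; admissible density is high at this scale.
        while len(chosen) < n:
            k = 2 * (n - len(chosen)) + 16
            ii = rng.integers(0, m, size=k)
            jj = rng.integers(0, m, size=k)
            for i, j in zip(ii, jj):
                if i == j:
                    continue
                p = canonical_pair(prots[i], prots[j])
                if p in seen or p in exclusions:
                    continue
                seen.add(p)
                chosen.append(p)
                if len(chosen) == n:
                    break
    return PairList(pairs=chosen, label=-1, source=f"random(n={n}, seed={rng_seed})")


def build_negative_set(pool: NeglogPool, config: SamplingConfig) -> PairList:
    """Assemble the mixed negative training set.

    Exactly ``round(n_total * neglog_fraction)`` pairs are drawn uniformly
    without replacement from the pool (after removing exclusions — a pair
    that is both in the pool and in the positive/exclusion list is dropped
    from the pool with a warning, since experimental positives outrank
    inferred negatives) and the remainder uniformly from the random space,
    disjoint from the exclusions and from the whole pool. A pool smaller
    than the requested share is an error, never silently topped up.
    """
    n_neglog = int(round(config.n_total * config.neglog_fraction))
    n_random = config.n_total - n_neglog
    if n_neglog > 0 and len(pool) == 0:
        raise ValueError("neglog_fraction > 0 but the pool is empty")

    conflicted = pool.pairs & config.exclusions
    if conflicted:
        logger.warning(
            "%d pool pair(s) conflict with exclusions/positives and were removed",
            len(conflicted),
        )
    admissible_pool = sorted(pool.pairs - config.exclusions)
    if n_neglog > len(admissible_pool):
        raise ValueError(
            f"pool has {len(admissible_pool)} admissible pairs, "
            f"{n_neglog} requested for the homology share"
        )
    rng = np.random.default_rng(config.rng_seed)
    idx = rng.choice(len(admissible_pool), size=n_neglog, replace=False) if n_neglog else []
    neglog_part = [admissible_pool[i] for i in idx]

    random_part: list[ProteinPair] = []
    if n_random > 0:
        random_part = list(
            sample_random_pairs(
                config.random_space,
                n_random,
                exclusions=config.exclusions | pool.pairs,
                rng_seed=int(rng.integers(0, 2**31 - 1)),
            )
        )
    out = PairList(
        pairs=neglog_part + random_part,
        label=-1,
        source=f"mixed(neglog={n_neglog}, random={n_random}, seed={config.rng_seed})",
    )
    assert len(out) == config.n_total, "negative set size mismatch"
    assert not (out.pair_set & config.exclusions), "negative set overlaps exclusions"
    return out


def expected_random_contamination(truth: set[ProteinPair], space: set[str]) -> float:
    """Fraction of uniformly random pairs over ``space`` that truly interact.

    Exact expectation: |truth restricted to space| / C(|space|, 2).
    """
    m = len(space)
    if m < 2:
        raise ValueError("space must contain at least two proteins")
    in_space = sum(1 for a, b in truth if a in space and b in space)
    return in_space / math.comb(m, 2)


def pool_contamination(pool: NeglogPool, truth: set[ProteinPair]) -> float:
    """Fraction of pool pairs that truly interact (false-negative rate)."""
    if len(pool) == 0:
        raise ValueError("empty pool")
    truth = {canonical_pair(*p) for p in truth}
    return sum(1 for p in pool.pairs if p in truth) / len(pool)
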