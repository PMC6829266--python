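"""Self-contained synthetic worlds for exercising every pipeline stage.

A world is a toy proteome organized into homology families (the paralog
analog: members of a family are mutual sequence-search hits), a flat GO
annotation layer, a planted ground-truth interaction rule, and a small
curated-style list of seed non-interactions consistent with that rule.

Annotations come in two layers. Shared GO *modules* (term blocks) are
drawn per family from a global set, and a latent subset of modules is
*adhesive* — the binding-competent functional classes. Each family
additionally carries a few *private* terms, the paralog-conserved,
family-specific annotations real protein families accumulate. The
planted rule is profile compatibility with a structural caveat: a pair
interacts with high probability when both families' profiles touch an
adhesive module AND neither family is *binding-deficient* — a latent
fraction of adhesive-looking families whose annotations promise binding
competence their structure does not deliver. All other pairs interact
with low probability.

This construction keeps GO features sufficient for the learning task
(mirroring their standing as the most discriminative PPI feature) and
keeps the rule expressible by term-level weights in a linear classifier
(positive weight on adhesive-module terms, negative weight on deficient
families' private terms). It also gives the homology expansion its
intended semantics: substituting a protein by a family member preserves
the profile and the deficiency, so pairs derived from non-binding seeds
stay non-binding — the structural-conservation argument in miniature.
Crucially, the deficient families make the curated seed list what it is
in reality: annotation-plausible pairs that nonetheless do not bind,
invisible to uniform random sampling.

Defaults are chosen as the package's standard study conditions: 30
families of 4 proteins; 12 shared GO modules of 6 terms, 4 adhesive,
with 2 modules plus 3 private terms per family; 40% of adhesive-looking
families binding-deficient; interaction rule strength 0.9; 5% annotation
noise; 300 seed non-interactions.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .features import AnnotationStore, build_homolog_terms
from .homology import HomologyMap
from .io_formats import PairList, ProteinPair, canonical_pair, write_pair_list
from .sampling import (
    NeglogPool,
    SamplingConfig,
    build_negative_set,
    expand_neglog,
    expected_random_contamination,
    pool_contamination,
)

#: Interaction probability of incompatible pairs is (1 - rule_strength)
#: scaled by this factor, so the noiseless limit rule_strength = 1
#: plants exactly the compatible pairs.
INCOMPATIBLE_SCALE = 0.25

_ASPECT_CYCLE = ("P", "F", "C")


@dataclass
class SyntheticWorld:
    proteins: list[str]
    families: list[list[str]]
    family_profiles: list[frozenset[int]]
    adhesive_modules: frozenset[int]
    deficient_families: frozenset[int]
    go: AnnotationStore
    go_aspects: dict[str, str]
    truth: set[ProteinPair]
    seeds: PairList
    homology: HomologyMap
    rng_seed: int

    def __post_init__(self) -> None:
        self._family_index = {
            p: k for k, members in enumerate(self.families) for p in members
        }
        if self.seeds.pair_set & self.truth:
            raise ValueError("seed non-interactions overlap the planted truth")

    def family_of(self, protein: str) -> int:
        return self._family_index[protein]

    def adhesive_looking(self, protein: str) -> bool:
        """Does the protein's family profile touch an adhesive module?"""
        return bool(self.family_profiles[self.family_of(protein)] & self.adhesive_modules)

    def binding_competent(self, protein: str) -> bool:
        return self.adhesive_looking(protein) and self.family_of(protein) not in self.deficient_families

    def compatible(self, a: str, b: str) -> bool:
        """Does the planted rule mark this pair as interaction-prone?"""
        return self.binding_competent(a) and self.binding_competent(b)

    def plausible_nonbinding_pairs(self) -> list[ProteinPair]:
        """Non-interacting pairs that look like interactions: both proteins
        adhesive-looking, at least one from a binding-deficient family.
        The curated seed list is sampled from this space."""
        out = []
        for a, b in itertools.combinations(self.proteins, 2):
            pair = canonical_pair(a, b)
            if pair in self.truth:
                continue
            if not (self.adhesive_looking(a) and self.adhesive_looking(b)):
                continue
            if (
                self.family_of(a) in self.deficient_families
                or self.family_of(b) in self.deficient_families
            ):
                out.append(pair)
        return out

    def random_space(self) -> set[str]:
        """Proteins carrying >=1 molecular-function or biological-process term."""
        return {
            p
            for p, terms in self.go.target_terms.items()
            if any(self.go_aspects[t] in ("F", "P") for t in terms)
        }


def _term_id(module: int, t: int) -> str:
    return f"GO:{1_000_000 + 100 * module + t:07d}"


def _private_term_id(family: int, t: int) -> str:
    return f"GO:{2_000_000 + 10 * family + t:07d}"


def generate_world(
    n_families: int = 30,
    family_size: int = 4,
    n_go_modules: int = 12,
    terms_per_module: int = 6,
    modules_per_family: int = 2,
    private_terms_per_family: int = 3,
    n_adhesive_modules: int | None = None,
    deficient_fraction: float = 0.4,
    interaction_rule_strength: float = 0.9,
    annotation_noise: float = 0.05,
    n_seeds: int = 300,
    rng_seed: int = 0,
) -> SyntheticWorld:
    """Generate a toy world with planted interactions and seed negatives.

    Each family draws ``modules_per_family`` shared GO modules and owns
    ``private_terms_per_family`` family-specific terms; within-family
    proteins share these up to annotation dropout at rate
    ``annotation_noise``, which also governs spurious foreign terms.
    ``n_adhesive_modules`` (default: a third of the modules) are marked
    adhesive and ``deficient_fraction`` of the adhesive-looking families
    are marked binding-deficient. Pairs of binding-competent proteins
    interact with probability ``interaction_rule_strength``, all others
    with probability ``(1 - rule_strength) * 0.25``. Seed non-interactions
    are drawn from the annotation-plausible non-binding space (both sides
    adhesive-looking, at least one deficient), so every seed — and, by
    profile conservation, nearly every homology-derived pair — is a
    genuine non-interaction that random sampling would rarely surface.
    """
    if min(n_families, family_size, n_go_modules, terms_per_module, modules_per_family) < 1:
        raise ValueError("all counts must be >= 1")
    if private_terms_per_family < 0:
        raise ValueError("private_terms_per_family must be >= 0")
    if modules_per_family > n_go_modules:
        raise ValueError("modules_per_family exceeds n_go_modules")
    for prob in (interaction_rule_strength, annotation_noise, deficient_fraction):
        if not 0.0 <= prob <= 1.0:
            raise ValueError("probabilities must lie in [0, 1]")
    rng = np.random.default_rng(rng_seed)

    families = [
        [f"P{fam:03d}{j:02d}" for j in range(family_size)] for fam in range(n_families)
    ]
    proteins = [p for fam in families for p in fam]

    shared_terms = [
        _term_id(m, t) for m in range(n_go_modules) for t in range(terms_per_module)
    ]
    go_aspects = {
        _term_id(m, t): _ASPECT_CYCLE[t % 3]
        for m in range(n_go_modules)
        for t in range(terms_per_module)
    }
    go_aspects.update(
        {
            _private_term_id(f, t): _ASPECT_CYCLE[t % 3]
            for f in range(n_families)
            for t in range(private_terms_per_family)
        }
    )
    family_profiles = [
        frozenset(int(m) for m in rng.choice(n_go_modules, size=modules_per_family, replace=False))
        for _ in range(n_families)
    ]
    if n_adhesive_modules is None:
        n_adhesive_modules = max(1, n_go_modules // 3)
    if not 1 <= n_adhesive_modules <= n_go_modules:
        raise ValueError("n_adhesive_modules out of range")
    adhesive = frozenset(
        int(m) for m in rng.choice(n_go_modules, size=n_adhesive_modules, replace=False)
    )
    looking = [f for f in range(n_families) if family_profiles[f] & adhesive]
    n_deficient = int(round(deficient_fraction * len(looking)))
    deficient = frozenset(
        int(looking[i]) for i in rng.choice(len(looking), size=n_deficient, replace=False)
    ) if n_deficient else frozenset()
    if len(looking) - len(deficient) < 2:
        raise ValueError("fewer than two binding-competent families; enlarge the world")

    target_terms: dict[str, set[str]] = {}
    for fam, members in enumerate(families):
        profile_terms = [
            _term_id(m, t)
            for m in sorted(family_profiles[fam])
            for t in range(terms_per_module)
        ] + [_private_term_id(fam, t) for t in range(private_terms_per_family)]
        foreign_terms = [t for t in shared_terms if t not in set(profile_terms)]
        for p in members:
            keep = rng.random(len(profile_terms)) >= annotation_noise
            terms = {t for t, k in zip(profile_terms, keep) if k}
            n_spurious = rng.binomial(len(profile_terms), annotation_noise)
            if n_spurious and foreign_terms:
                extra = rng.choice(
                    len(foreign_terms), size=min(n_spurious, len(foreign_terms)), replace=False
                )
                terms |= {foreign_terms[i] for i in extra}
            if not terms:  # every protein carries >=1 term
                terms = {profile_terms[int(rng.integers(len(profile_terms)))]}
            target_terms[p] = terms

    fam_index = {p: k for k, members in enumerate(families) for p in members}

    def competent(p: str) -> bool:
        f = fam_index[p]
        return bool(family_profiles[f] & adhesive) and f not in deficient

    p_incompatible = (1.0 - interaction_rule_strength) * INCOMPATIBLE_SCALE
    truth: set[ProteinPair] = set()
    for a, b in itertools.combinations(proteins, 2):
        prob = interaction_rule_strength if competent(a) and competent(b) else p_incompatible
        if rng.random() < prob:
            truth.add(canonical_pair(a, b))

    seed_candidates = []
    for a, b in itertools.combinations(proteins, 2):
        pair = canonical_pair(a, b)
        fa, fb = fam_index[a], fam_index[b]
        both_looking = bool(family_profiles[fa] & adhesive) and bool(family_profiles[fb] & adhesive)
        if pair not in truth and both_looking and (fa in deficient or fb in deficient):
            seed_candidates.append(pair)
    if not seed_candidates:
        raise ValueError("no plausible non-binding pairs to seed from")
    n_seeds = min(n_seeds, len(seed_candidates))
    seed_idx = rng.choice(len(seed_candidates), size=n_seeds, replace=False)
    seeds = PairList(
        pairs=[seed_candidates[i] for i in sorted(seed_idx)],
        label=-1,
        source=f"synthetic seeds (seed={rng_seed})",
    )

    neighbors: dict[str, dict[str, float]] = {p: {} for p in proteins}
    for members in families:
        for a, b in itertools.combinations(members, 2):
            evalue = 10.0 ** (-rng.uniform(21.0, 60.0))
            neighbors[a][b] = evalue
            neighbors[b][a] = evalue
    homology = HomologyMap(neighbors=neighbors, threshold=1e-20)

    return SyntheticWorld(
        proteins=proteins,
        families=families,
        family_profiles=family_profiles,
        adhesive_modules=adhesive,
        deficient_families=deficient,
        go=AnnotationStore(target_terms=target_terms),
        go_aspects=go_aspects,
        truth=truth,
        seeds=seeds,
        homology=homology,
        rng_seed=rng_seed,
    )


_GAF_QUALIFIER = {"P": "involved_in", "F": "enables", "C": "located_in"}


def world_to_files(world: SyntheticWorld, directory: str | Path) -> dict[str, Path]:
    """Write the world in the pipeline's external formats.

    Emits positives.tsv and seeds.tsv (pair TSV), annotations.gaf
    (GAF 2.2), homology.blast.tsv (12-column BLAST tabular, both hit
    directions per family edge) and proteins.tsv (one identifier per
    line), all re-readable by the format readers.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "positives": directory / "positives.tsv",
        "seeds": directory / "seeds.tsv",
        "gaf": directory / "annotations.gaf",
        "blast": directory / "homology.blast.tsv",
        "proteins": directory / "proteins.tsv",
    }
    write_pair_list(sorted(world.truth), paths["positives"])
    write_pair_list(world.seeds, paths["seeds"])
    with open(paths["gaf"], "wt") as fh:
        fh.write("!gaf-version: 2.2\n")
        for prot in sorted(world.go.target_terms):
            for term in sorted(world.go.target_terms[prot]):
                aspect = world.go_aspects[term]
                cols = [
                    "SYN", prot, prot, _GAF_QUALIFIER[aspect], term,
                    "SYN:0000001", "IEA", "", aspect, "", "", "protein",
                    "taxon:9606", "20190101", "SYN", "", "",
                ]
                fh.write("\t".join(cols) + "\n")
    with open(paths["blast"], "wt") as fh:
        for a in sorted(world.homology.neighbors):
            for b in sorted(world.homology.neighbors[a]):
                e = world.homology.neighbors[a][b]
                fh.write(
                    f"{a}\t{b}\t90.00\t100\t10\t0\t1\t100\t1\t100\t{e:.3e}\t250.0\n"
                )
    paths["proteins"].write_text("".join(p + "\n" for p in world.proteins))
    return paths


# ---------------------------------------------------------------------------
# Standard experiments on a world (the package's study conditions)
# ---------------------------------------------------------------------------

def training_data(
    world: SyntheticWorld,
    neglog_fraction: float = 0.7,
    rng_seed: int = 0,
    extra_exclusions: set[ProteinPair] | None = None,
) -> tuple[PairList, PairList, AnnotationStore, NeglogPool]:
    """Assemble positives, mixed negatives and the annotation store.

    Positives are the planted truth; negatives mix the homology-expanded
    pool with random pairs over the F/P-annotated space, excluding the
    positives (and any reserved pairs) and matching the positive count.
    """
    store = build_homolog_terms(world.go, world.homology)
    pool = expand_neglog(world.seeds, world.homology)
    positives = PairList(pairs=sorted(world.truth), label=1, source="synthetic truth")
    exclusions = set(world.truth) | (extra_exclusions or set())
    config = SamplingConfig(
        n_total=len(positives),
        neglog_fraction=neglog_fraction,
        random_space=world.random_space(),
        exclusions=exclusions,
        rng_seed=rng_seed,
    )
    negatives = build_negative_set(pool, config)
    return positives, negatives, store, pool


def contamination_comparison(world: SyntheticWorld) -> tuple[float, float]:
    """(pool contamination, expected uniform-random contamination).

    Contamination is the fraction of truly interacting pairs — the false
    negatives a sampling strategy would admit.
    """
    pool = expand_neglog(world.seeds, world.homology)
    return (
        pool_contamination(pool, world.truth),
        expected_random_contamination(world.truth, world.random_space()),
    )


def heldout_curated_negatives(
    world: SyntheticWorld, n: int, rng_seed: int = 0
) -> PairList:
    """Curated-style hold-out negatives: annotation-plausible non-binding
    pairs outside the seed list.

    Drawn from the same distribution as the seeds (both proteins
    adhesive-looking, at least one family binding-deficient), these are
    the pairs an experimentalist would bother to test and find negative.
    Pairs outside the homology-expanded pool are preferred — they are
    the more independent test — topping up from pool pairs only when
    the outside space is exhausted. Callers reserving them as a test
    set must exclude them from training
    (``training_data(extra_exclusions=...)``).
    """
    candidates = set(world.plausible_nonbinding_pairs()) - world.seeds.pair_set
    pool = expand_neglog(world.seeds, world.homology)
    outside = sorted(candidates - pool.pairs)
    inside = sorted(candidates & pool.pairs)
    if n > len(candidates):
        raise ValueError(f"only {len(candidates)} hold-out negatives available, {n} requested")
    rng = np.random.default_rng(rng_seed)
    chosen: list[ProteinPair] = []
    for tier in (outside, inside):
        take = min(n - len(chosen), len(tier))
        if take:
            idx = rng.choice(len(tier), size=take, replace=False)
            chosen.extend(tier[i] for i in idx)
        if len(chosen) == n:
            break
    return PairList(pairs=chosen, label=-1, source="synthetic curated hold-out")
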