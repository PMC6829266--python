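# Methods

## The sampling model

The package treats negative-data construction for PPI prediction as an
inference problem of its own. Curated non-interactions are scarce
(hundreds of pairs) but trustworthy; random pairs are plentiful but
carry false negatives at the background interaction rate. The Neglog
expansion interpolates: it assumes the structural mismatch that keeps
two proteins from binding is conserved across their paralogs and
orthologs, so substituting either member of a curated non-interacting
pair by one of its homologs yields another (probable) non-interaction.
Formally, a seed ¬(a, b) with homolog sets A and B expands to
{(a,b)} ∪ {(a,b′)} ∪ {(a′,b)} ∪ {(a′,b′)} over a′ ∈ A, b′ ∈ B; the pool
is the union over seeds, canonicalized, deduplicated, and stripped of
self-pairs. A pair found both in the pool and in the positive list is
removed from the pool with a warning: experimental positives outrank
inferred negatives.

Homology is taken from sequence-search hits at E ≤ 1e-20 (the default
cutoff, exposed as a parameter). Hit lists are directional; because
paralogy is symmetric the map is symmetrized by default, keeping the
more significant E-value per edge. Paralogs and orthologs are not
distinguished in the data model.

Training negatives are drawn without replacement: a fraction (default
0.7) uniformly from the admissible pool and the remainder uniformly
from pairs over the random space — proteins carrying at least one
molecular-function or biological-process GO term — excluding positives,
reserved test pairs, and the pool itself (so the mixture's composition
is what it claims to be). The total matches the positive count. A pool
smaller than its requested share is an error, never silently topped up
from the random space. All randomness flows through one seeded
generator, so a configuration replays byte-identically.

## Features

Each protein i has a target term set ST_i (its own GO annotations,
NOT-qualified rows excluded, all three aspects) and a homolog term set
SH_i (the union of its homologs' target sets — annotation transfer for
sparsely annotated proteins). The vocabulary S is the union of both
sets over the proteins in the *training* pairs only; terms seen only at
prediction time are discarded, exactly as they would be for genuinely
novel data. A pair maps to two vectors over S — one per instance kind —
with component 2 where both proteins carry the term, 1 where exactly
one does, 0 otherwise. The encoding is symmetric in the pair and kept
flat on purpose: no DAG ancestors or semantic similarity, which would
correlate features. Unannotated proteins encode as zero vectors rather
than errors, since independent-test pairs may involve unseen proteins.
Matrices are materialized sparsely; the {0,1,2} contract is dense in
meaning only.

## Classifier and decision rule

One L2-regularized logistic regression is trained per instance kind on
the same ±1 labels, minimizing ½ωᵀω + C Σ log(1 + e^(−y ωᵀx)) with an
unpenalized intercept (scikit-learn's LBFGS solver at tolerance 1e-8,
which is deterministic; its objective is exactly this primal). Default
C = 1.0. The ridge term damps the annotation noise homolog transfer
introduces.

Decision values use a signed-probability convention: with p the
positive-class posterior, the decision is +p when p ≥ 0.5 and −(1−p)
otherwise — i.e. the winning class's posterior, signed. The boundary
p = 0.5 maps to the weakest positive. This scale is chosen so the
acceptance rule reads identically on both branches: a prediction is
labeled only if its winning posterior exceeds 0.5 + δ; otherwise it is
*undetermined* and excluded from confusion matrices (δ defaults to 0,
where the rule reduces to the posterior-0.5 classifier). For a pair
scored under both instance kinds, the decision with the larger absolute
value wins; exact ties go to the homolog decision. Raising δ can only
move predictions to undetermined, never flip a label.

## Evaluation

Metrics come from an L×L confusion matrix M (row = true class): per
class, p_l = M_ll, q_l = Σ_{i≠l,j≠l} M_ij, r_l = Σ_{i≠l} M_il,
s_l = Σ_{j≠l} M_lj give PR_l = p_l/(p_l+r_l), SE_l = p_l/(p_l+s_l) and
MCC_l = (p_l q_l − r_l s_l)/√((p_l+r_l)(p_l+s_l)(q_l+r_l)(q_l+s_l));
accuracy and the overall MCC use the class sums; F1 is the harmonic
mean of the positive class's PR and SE. Zero denominators yield 0 by
convention (bounded, standard). Reporting the negative class alongside
the positive one is deliberate: the negative side is where a biased
model betrays itself.

ROC-AUC is the Mann–Whitney probability that a random positive
outscores a random negative, ties counted ½, computed on raw decision
values *before* δ-thresholding — AUC stays threshold-free while
PR/SE/MCC/Acc/F1 exclude undetermined predictions (counted separately).

Cross-validation is stratified k-fold (default 5) at the pair level
with a fixed seed; the vocabulary is rebuilt from each training fold
only, and per-fold predictions are pooled into one confusion matrix
before scoring. Protein-level splitting is available as an option
(proteins are partitioned; pairs straddling groups are dropped) because
proteins shared across folds inflate pair-level estimates. Independent
tests assert disjointness from the training pairs and fail loudly,
listing offenders, rather than returning an optimistic number.
Candidate-list validation filters by per-evidence-channel score
thresholds (every channel present must have a threshold — none are
hard-coded, since reasonable conventions differ), then reports the
positive rate positives/(positives+negatives) per channel with
undetermined counts alongside.

## The synthetic generator

Worlds are built from homology families (all-vs-all within-family hits
at E-values drawn log-uniformly between 1e-21 and 1e-60) and a modular
annotation layer: families draw 2 of 12 shared GO modules (6 terms
each) and own 3 private terms — the family-specific annotations real
paralog families accumulate. A latent third of the modules is
*adhesive* (binding-competent functional classes) and a latent 40% of
the adhesive-looking families are *binding-deficient*: their
annotations promise competence their structure does not deliver. Pairs
of binding-competent proteins interact with probability 0.9 (the rule
strength); all others with probability (1 − 0.9) × 0.25 = 0.025. Per
protein, profile terms drop out at the annotation-noise rate (5%) and
spurious foreign terms enter at the same rate; every protein keeps at
least one term. Seed non-interactions (300) are drawn from the
annotation-plausible non-binding space — both sides adhesive-looking,
at least one family deficient — which is precisely the kind of pair an
experimentalist would test and find negative, and the kind uniform
random sampling essentially never surfaces.

Design notes on these choices:

- *Linear learnability.* A planted rule of the form "profiles overlap"
  is invisible to a linear model over the {0,1,2} encoding: the
  component sum equals |T1| + |T2| regardless of overlap. The
  adhesive/deficient construction is instead expressible by term-level
  weights (positive on adhesive-module terms, negative on deficient
  families' private terms), matching the representational class of the
  classifier the pipeline actually uses.
- *Conservation.* Substituting a protein by a family member preserves
  the family profile and its deficiency, so homology-derived pairs
  inherit the seeds' non-binding status up to the background rate —
  the expansion premise holds by construction, with quantifiable
  contamination.
- *Scale.* Defaults (30 families × 4 proteins) give ≈ 700–1100
  positives and a pool comfortably exceeding its 70% share of the
  negatives across world seeds, mirroring the intended regime in which
  the expanded pool is much larger than the training share. The
  incompatible-pair scale factor 0.25 makes the noiseless limit (rule
  strength 1) plant exactly the compatible pairs.
- The generator emulates homology conservation, annotation sparsity
  and curated-negative plausibility; it does **not** emulate scale-free
  degree distributions, sequence content, aspect-specific annotation
  structure or inter-family homology. Passing tests therefore show the
  pipeline's logic and its qualitative sampling claims, not performance
  on real proteomes.

## Study conditions and problem sizes

The multi-seed study (tests and `scripts/acceptance.py`) runs 20 world
seeds at the generator defaults; per world it compares pool
contamination against the exact uniform-random expectation
|truth ∩ space²|/C(|space|,2), trains combined-setting classifiers on
mixed (7:3) versus random-only negatives, scores 100 curated-style
hold-out negatives reserved before training, and cross-validates both
the combined and target settings (5-fold). Aggregation follows the
claims' forms: a sign test across seeds for the contamination
direction, mean recall for the training contrast, and a 0.02 tolerance
on the mean AUC difference between settings. Compact worlds used in
unit tests raise the deficient fraction to 0.5 so the seed-candidate
space stays large relative to the (smaller) positive set.

## Known limitations

- Identifier mapping between accession schemes is out of scope;
  identifiers are opaque strings and must already be consistent across
  the pair lists, GAF and homology files.
- The signed-probability decision scale is this package's
  reconstruction of how a 0.5-centered acceptance margin can apply to
  both classes; margins from other classifier families would need
  re-calibration before the δ rule is meaningful.
- Pair-level cross-validation shares proteins across folds; the
  protein-level option is conservative but discards straddling pairs.
- The homology expansion inherits every weakness of the seed list:
  biases toward well-studied families propagate to the pool, which is
  why mixing in random pairs remains part of the method.
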