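# Methods

This note documents the models and procedures implemented in `enzrxn`, the
choices made where the design was genuinely open, and what the synthetic
experiments do and do not show.

## Reactions and reaction centers

A reaction is held as lists of RDKit molecules per side, an atom map (the
partial bijection encoded by atom-map numbers; 1-based per the reaction
SMILES convention, while atom indices are 0-based and global per side), and
the RC atom sets. Agents in `reactants>agents>products` input are parsed
and discarded with a warning; only reactants and products enter the model.

**Standardization** removes stereochemistry, applies RDKit's standard
normalization transforms, and neutralizes condition-dependent charges via
an explicit rule table (protonate O⁻/S⁻ acid sites, deprotonate N⁺–H;
permanently charged centers such as quaternary nitrogen are untouched).
The rule table is explicit configuration because "standard" neutralization
is not a single canonical list; the default reflects the common
physiological-charge cases. Standardization is idempotent and preserves
the atom map.

**RC from the atom map.** An atom is in the RC iff it is incident to a bond
formed, broken, or changed in order between the sides, or its total
hydrogen count changes. Hydrogen-count changes are included deliberately:
redox transformations with implicit hydride transfer would otherwise have
empty or truncated RCs. Hydrogens themselves are implicit and never RC
atoms. Identity reactions (no change at all) are flagged and rejected at
dataset load rather than passed silently.

**RC via operator templates.** A minimal reaction operator is a reaction
SMARTS pair. For each combination of one substructure match per template
component, all other matches are protected, the operator is applied, and
the generated products (plus spectator reactants) are compared to the
actual products as canonical SMILES multisets. Each validating match
yields one candidate RC. The candidate is the matched atoms *restricted to
the template atoms the operator changes* (computed from the template's own
bond/charge diff): operator patterns legitimately carry anchor atoms — the
carbonyl oxygen in an ester-hydrolysis template constrains matching but
never changes — and including them would make the operator route disagree
with the map route on the same reaction. Under this definition the two
routes coincide on fully mapped reactions, which the tests enforce.

**The RC as a reaction.** The induced subgraph on the RC atoms of both
sides is itself a balanced transformation (RC atoms correspond under the
map). Each extracted atom freezes its original total hydrogen count as
explicit hydrogens, so the fragment parses cleanly even where bonds were
cut; heavy-atom balance is exact, hydrogen counts reflect the parent
environments. Fragments cut out of aromatic rings fall back to kekulized
single/double orders when the aromatic system is no longer valid.

## Similarity metrics

**RCMCS** between two reactions is the atom count of the largest common
subgraph of their disjoint-union graphs — reactant atoms matched to
reactant atoms, product atoms to product atoms, with one joint
correspondence across both sides — constrained to contain a full bijection
between the two RCs, divided by the total atom count of the larger
reaction. Pairs whose RCs admit no compatible bijection score 0: the
constrained MCS is empty, and a total, conservative metric is preferable to
a partial one. The common subgraph need not be connected beyond the RC
(reactions are multi-molecule objects). Default atom-match criteria:
element (mandatory) + aromaticity + bond order; formal charge is ignored
because charges are neutralized upstream.

The search enumerates RC bijections by backtracking, then solves a maximum
clique on the modular product of the remaining atoms (branch and bound with
greedy coloring). The guard against pathological pairs is a deterministic
search-step budget (default 2·10⁶ expansions) rather than a wall-clock
timeout — a time-based cut would make similarity matrices
machine-dependent. On budget exhaustion the best correspondence found so
far is used and the pair is recorded in the matrix's fallback log, keeping
benchmark matrices auditable. An independent, purely exhaustive oracle
(`mcs_oracle`, refusing graphs above 16 atoms per side) validates the
production search on every pair of a 30-reaction synthetic corpus.

**GSI** locally aligns two sequences (BLOSUM62, gap open 11 / extend 1 —
the field's default parameters, as none are canonical for this metric) and
divides identically aligned residues by the *longer* sequence's length.
The longer-sequence denominator is what makes the quantity global: an
alignment-length denominator would reward short high-identity islands.
Alignments with non-positive score contribute 0.

## Stratified similarity split

Clusters at a similarity bound are connected components of the thresholded
similarity graph (single linkage), so the maximum similarity between items
in different clusters is strictly below the bound. The split iterates
bounds ascending (default grid 0.4 / 0.6 / 0.8 / 1.0, the 0.4 floor
reflecting where all-against-all protein datasets typically collapse into
one cluster): cluster the unassigned pool, sample whole clusters into the
test fold (probability proportional to cluster size, without replacement)
until the stratum quota is met, then relax the bound. A cluster is only
taken if it overshoots the remaining quota by at most half the stratum
quota; coarser clusters are left to a more permissive bound, where single
linkage breaks them up, and unfilled quota rolls forward the same way. If
the pool is a single cluster at some bound, a collapse error names that
bound — stratification below it is infeasible for that dataset.

The remaining pool is split into inner CV folds (default 3) by the same
procedure, re-stratified within the pool. Afterwards every test entity's
maximum similarity to the train/validation pool is *measured* and its
stratum recorded from the measurement; `verify_split` re-derives these
numbers and reports violations, so the guarantee is checked, never assumed.
Splits are entity-level (reactions for RCMCS tracks, proteins for GSI
tracks); pairs inherit their entity's fold and the counterpart entity is
uncontrolled, mirroring the two separate experiment tracks.

**Negative sampling** is global: per fold, uniform draws without
replacement from {fold entities} × {all counterparts} minus the entire
positive set — no similarity biasing in either direction. Ratios are 3:1
in training folds and 1:1 in validation and test. The probability that a
sampled negative is secretly positive is bounded by
`observed_density / assumed_coverage`; at the observed 0.03% density and a
conservative 10% knowledge coverage this is 0.3%.

## Encoders

Atom features: one-hot element (C/N/O/S/P/F/Cl/Br/I + other), total degree
0–5, formal charge −2..+2, total hydrogens 0–4, hybridization, an
aromaticity bit, atomic mass × 0.01, and — for the disjoint-union variants —
a reactant/product side bit. The side bit is load-bearing: without it the
union graph is direction-blind and hydrolysis would embed identically to
condensation. The CGR variant omits it because its per-node
(reactant ∥ product) feature concatenation is directional by construction.
Bond features: order one-hot, conjugation, ring membership, and a dedicated
virtual-edge bit that is set exactly when all other bits are zero.

The virtual node of the RC variants starts stateless (all-zero features)
and is wired by virtual edges to the RC atoms of *both* sides — the RC is
defined on both, and a reactant-only wiring would halve the mechanism
context. `rc_aggregated` reads out the virtual node's embedding alone;
`rc_connected` and `bag_of_molecules` average over real atom nodes only
(the virtual node is not an atom). The CGR builds one node per mapped atom
pair with concatenated before/after atom features and edges carrying
(before, after) bond states with an explicit "absent" state for
formed/broken bonds.

Message passing is bond-centric for all graph variants (node-centric
passing is deliberately not offered — it would break the exact
receptive-field semantics): edge states initialize from
relu(W_in·[source features ∥ bond features]), each of M−1 updates is
relu(h⁰ + W_msg·(incoming sums excluding the reverse edge)), and node
readout is relu(W_read·[node features ∥ incoming edge sums]) followed by a
learned linear projection to the embedding dimension. M counts the
initialization pass, so the receptive radius is M−1 bonds; with the default
M = 4 for `rc_aggregated`, the embedding is bit-identical under any
perturbation more than 3 bonds from every RC atom (a property test, not an
approximation — paths through the virtual node cannot shorten an atom's
distance to the RC set because they enter through RC atoms). Defaults
follow the two-tower setup: embedding dimension 300, M = 6 for the
non-RC-aggregated graph variants, Morgan radius 2 over 2048 count bits,
25 training epochs, m = p = 3.

The Morgan path sums per-molecule circular count fingerprints per side,
takes the elementwise absolute difference (hence side-swap invariant, and
exactly zero for identity reactions), and applies a learned linear
projection; it is linear in the count vector after the absolute-value step.

## Scoring, loss and training

Score = σ(⟨reaction embedding, W·protein embedding⟩). The protein tower is
a frozen precomputed embedding (1280-dim, as produced by a protein language
model) with a single learned linear map — no fine-tuning. The loss is
implemented verbatim with the positive-term weight m·p (equal to plain BCE
when m·p = 1), stabilized through softplus so large-magnitude logits
neither overflow nor produce NaN; the alternative reading in which m
weights the negative term instead is noted but not implemented. The m·p
weight compensates the 3:1 negative oversampling, so batches are plain
shuffled pairs without per-batch class balancing.

Optimization is Adam at learning rate 10⁻³ (standard defaults; no values
are canonical for this setup), single-threaded on CPU, fully deterministic
given the seed. The default minibatch of 256 reflects that each step
embeds the whole reaction bank as one batched sparse-graph pass — larger
batches amortize that pass with no measurable quality cost at package
scale. Training aborts on non-finite loss. The decision threshold is
selected per track by maximizing validation F1 over midpoints of
consecutive distinct scores (degenerate all-equal scores fall back to
midpoints with the 0/1 bounds; ties go to the smallest threshold).
Hyperparameter selection is a grid search with k-fold CV over the inner
folds, first-in-grid-order winning ties, returning the full mean ± sd table
for depth-sweep analyses.

Because no GPU framework is a dependency, all gradients come from a small
vectorized reverse-mode autodiff module purpose-built for this package
(tensors over numpy arrays; matmul, sparse-matrix products for
edge-message aggregation, gather/scatter, ReLU, BCE-with-logits). Every
operation's gradient, and the loss gradient at 100 random points, is
checked against central finite differences in the tests.

## Evaluation

Standard confusion-matrix metrics plus ROC (threshold sweep, trapezoid
area) with explicit `None` markers where a one-class input makes a metric
undefined. Binned performance assigns each test pair to a bin of its
*split entity's* measured max-train similarity (the controlled variable;
pair-level binning would mix the uncontrolled counterpart in), default
edges 0/0.2/0.4/0.6/0.8/1.0, with low-count bins flagged.

The RC-proximity analysis groups reactions by the canonical form of their
extracted RC reaction, embeds the bare RC like any reaction, and scores
σ(⟨mean member embedding, RC embedding⟩) — the same functional form as an
enzyme-reaction score, valid because all inputs share one embedding space.
The encoder-vs-encoder comparison ("whose family mean is closer to the
RC?") is decided on the raw dot product: the ordering is identical to the
sigmoid's, but immune to σ saturating to exactly 1.0 in floating point at
the dot-product magnitudes untrained or small models produce.

## Synthetic data

The generator emulates the statistical shape the method assumes, not real
corpus chemistry. Six hand-written, chemically valid template reactions
(ester and amide hydrolysis, ketone reduction, decarboxylation, alcohol
oxidation, alkene hydration; five used by default) are decorated with
random substituent trees (C/O/N vocabulary, carbon roots, heteroatoms
bonded only to carbon) grafted identically onto both sides at designated
attachment atoms, preserving the atom map — so every output is fully
mapped, standardizes idempotently, and carries the template core as its
RC. Proteins are drawn around cluster centroids (unit-scale, noise 0.25)
with sequences mutated from per-cluster ancestors at rate 0.15 over 120
residues, making sequence identity systematically higher within clusters.

Positives are planted as "protein cluster c catalyzes reaction family
c mod F", with 5% of positives drawn as cross-family promiscuous pairs and
counts sampled exactly to hit the target density (default 0.01 on the
default 200×200 corpus → 400 positives; the real-world 0.03% regime is
emulated at a density where desk-scale folds still contain usable positive
counts). The planted signal is RC-local by construction: labels depend
only on the template family, never on substituents.

Planted-recovery experiments train on observed positives plus globally
sampled negatives (exactly as the pipeline would, including the ~19% of
sampled training negatives that are secretly in-block) but evaluate
held-out positives against *known true negatives* of the generative world —
that is what "recovery of the planted relation" means; evaluating against
globally sampled negatives instead would cap the measurable ranking quality
at the misassignment rate, which is quantified separately by the analytic
bound. The label-permuted control uses the identical pipeline with
shuffled training labels and stays at chance.

What these experiments do **not** show: performance on a real curated
enzyme-reaction corpus (far more diverse cores, unbalanced families, real
language-model embeddings), robustness to atom-mapping errors (synthetic maps are exact by
construction), or absolute accuracy numbers comparable to a real corpus.
They show that the implementation can learn a mechanism-local bipartite
relation from its inputs, that the RC-aggregated encoder's locality and
proximity advantages hold directionally, and that every pipeline contract
(split guarantee, sampling ratios, determinism) is enforced.

## Problem sizes and numerical choices

The shipped experiments are sized for a single CPU: 200×200 planted corpus,
64-dim embeddings in the learnability tests, 30-reaction oracle corpus
(≤ 12 atoms per side), 3 seeds for stochastic claims (the label-permuted
chance control averages 5 permutation draws, since a single draw's AUC
fluctuates by about ±0.05 from block-level label imbalance alone). All arithmetic is
float64; weight initialization is seeded Glorot-uniform; RNG streams derive
from one configured seed (the CLI fans it out per stage by stable hashing,
so stages are independently reproducible and whole-pipeline reruns are
byte-identical). Degenerate inputs fail loudly: empty RCs, partial maps
for map-requiring encoders, one-class threshold selection, unreachable
planted densities, and exhausted negative pools all raise with specifics.

## Known limitations

- Operator RC assignment requires operators whose product patterns
  reconstruct the products exactly up to canonicalization; operators with
  under-specified valence contexts can fail to validate and yield no
  assignment (the caller decides how to proceed).
- Atoms whose only change is hydrogen count *and* whose incident template
  bonds are unchanged are invisible to the operator-template diff (they are
  still captured by the map route).
- The MCS step budget makes very large or highly symmetric reaction pairs
  fall back to bounded search; fallbacks are logged per pair.
- GSI treats `X` as a standard residue via the substitution matrix; other
  ambiguity codes are rejected.
- The synthetic promiscuity model is uniform cross-family noise, not
  mechanism-correlated promiscuity.
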