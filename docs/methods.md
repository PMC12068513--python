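# Methods

This note documents the models and procedures implemented in `symfrag`,
the parameter choices that matter, and what the bundled synthetic data can
and cannot show.

## Fragment decomposition

**Cleavable bonds.**  A bond is cleavable when it is single, acyclic, and
has an aromatic atom on at least one end (SMARTS `[a]-!@[*]`, wildcard
atoms excluded).  This matches aromatic–aliphatic bonds (ring to chain)
and aromatic–aromatic single bonds (ring to ring) and never cuts inside a
ring, so every ring system survives decomposition intact.

**Vocabulary.**  For one molecule, the vocabulary is the set of fragments
obtainable by deleting exactly one cleavable bond, each side keeping an
unlabelled wildcard at the cut.  Forms are canonicalized, deduplicated and
sorted before IDs [0, N) are assigned, so vocabularies are reproducible
across runs and machines.  For a corpus, the union of single-cut forms over
all molecules is collected first and then sorted, so IDs do not depend on
molecule order.

**Marks.**  Recursive decomposition cuts one bond at a time, forming a
binary tree whose leaves (fragments with no cleavable bonds) are the final
fragment set.  Each cut labels the fresh attachment point on either side
with the vocabulary ID of the fragment on the *other side of that bond in
the original molecule* — i.e. the complete branch that was attached there,
not whatever remains of it at the moment of the cut.  This choice has
three consequences that the package relies on:

* identical substituent branches at symmetric positions always receive
  identical marks, and distinct branches receive distinct marks — the
  symmetry information the generator preserves;
* every mark resolves in the single-cut vocabulary, so no IDs are minted
  during recursion;
* the leaf multiset and all marks are independent of the order in which
  bonds are cut (bonds are processed first-in-canonical-atom-index order,
  which fixes the tree shape only).

The alternative — labelling with the counterpart *at cut time* — was
implemented first and rejected: in chain-like molecules the second of two
identical branches is necessarily detached from an already-dismembered
remainder, so no cut order can give symmetric positions equal marks.

**Serialization dialect.**  Attachment points are wildcard atoms; a mark is
carried in the wildcard's atom-map number as `ID + 1`, because atom-map 0
means "unlabelled" in SMILES and is reserved for free attachment points
(fresh cuts, vocabulary forms).  Files round-trip bit-exactly through
canonical SMILES.  Aromaticity follows RDKit's default perception.

**Memoization.**  Repeated sub-fragments reuse their decomposition subtree.
The memo key is the canonical marked form *plus* the original-side
identities of the fragment's remaining cleavable bonds, which together
determine the leaf multiset exactly; memoization therefore never changes
the result (verified memo-on vs memo-off over the whole fixture corpus).

**Reassembly.**  `reassemble` inverts decomposition and serves as the
round-trip oracle.  A mark names a complete branch, so a piece may absorb a
partner exactly when that partner is finished: a single open attachment
point and a stripped form equal to the vocabulary form the mark names.
Since several pieces can share a stripped form while belonging to
different positions, the join order is found by depth-first backtracking
with failed sub-states memoized; fixture molecules (≤ ~12 leaves)
reassemble in milliseconds.

**Pool filters.**  Corpus pools keep fragments with r(f) ≤ 6 reactive
positions and n(f) ≤ 40 heavy atoms by default (both configurable); the
caps bound the cost of downstream property evaluation.  Roles partition
generation duty by r(f): end-groups cap one position (r = 1), π-bridges
extend through two (r = 2), and any fragment may serve as a core.

## Generation grammars

Both environments satisfy one contract (`initial_state`, `legal_actions`,
`step`, `is_terminal`, `trajectory_molecule`), so the search engine is
agnostic to the grammar.

**Focused (Y6-style) grammar.**  Stages: heteroatom choice (S/O/Se) at each
of four core positions, applied by token substitution into a core SMILES
template; an optional π-bridge; an end-group; a methyl side chain.  The
default core template is an illustrative four-ring conjugated scaffold
with end-group sites on the outer rings and alkyl sites on the inner ones;
it stands in for the real acceptor core, whose editable template and
fragment libraries users supply via YAML.  Alkyl chains are deliberately
restricted to methyl: side chains mainly tune solubility and packing, not
single-molecule optical gaps, and short chains keep conformer costs down in
a real scoring pipeline.  Every transition is deterministic, and a
fragment is attached at *all* positions sharing a mark, so both molecule
arms stay identical (the acceptor–donor–acceptor symmetry of the family).
Deterministic transitions are memoized inside the environment, which
speeds repeated tree traversals by ~6×.

**Open (patent-style) grammar.**  Builds from an empty state over a
decomposition pool: choose a core cluster, then a core fragment; up to two
optional π-bridge rounds (cluster choice then member choice); then
alternate end-group cluster/member choices until no reactive position
remains.  Cluster factorization trades tree breadth for depth: k-means
(k = 100 by default, clamped to the number of distinct fingerprints) over
Morgan fingerprints groups chemically similar fragments so UCT statistics
generalize within clusters.

The *reactive position* is not an action.  After a π-bridge or end-group
identity is chosen, one of the k_t distinct open marks is sampled uniformly
(probability 1/k_t) and the fragment is attached at every position bearing
it.  Removing position choice from the action space halves the tree depth
and pushes the search toward fragment combinations that are robust to
placement.  With k distinct marks the end phase needs at most 2k steps
(cluster and member alternate).

Constraints: generated molecules never exceed 100 heavy atoms — if an
attachment would overflow the cap, the remaining positions are
hydrogen-capped and the state terminates (capping keeps the molecule
valid; the grammar does not define a rejection path).  Differently marked
positions must receive different fragment identities, enforced by masking
already-used stripped forms out of the action set; when masking would
empty a cluster, the constraint is relaxed for that step and a warning
logged once per cluster (a hard mask could deadlock small pools).

## Search

Standard UCT: selection by `Q(a) + c·sqrt(ln N_p / N(a))` with unvisited
actions taken first (uniformly at random among themselves — taking one
*is* the expansion step) and ties broken uniformly; uniform-random
rollouts; the terminal reward backed up as a running mean (`Q = W/N`) along
the selection path.  Rewards are used unnormalized, so the exploration
coefficient is scale-sensitive; the default `c = 1/√2` suits rewards of
magnitude ~1 (bandgaps in eV) and is configurable.  Stochastic outcomes
are handled by keying an edge's children on the outcome state, so edge
statistics marginalize over position sampling.  Nodes are keyed on the
canonical state by default, merging transpositions; a config switch
restores strict-tree semantics.  Terminal rewards are cached by canonical
SMILES (the reward is a pure function of the molecule), which matters on
small grammars where the same terminal recurs thousands of times.  A
failing reward function logs the molecule and scores it at a configurable
floor (−100 by default) rather than aborting the run.

All randomness — tie-breaks, expansion, rollouts, environment sampling —
flows from a single seeded generator, so (config, seed) reproduces ledgers
byte for byte.

## Diversity-penalized iteration, EI, and active learning

The iteration-i reward is `R_i(x) = w_p·C(x) − w_s·agg_{y∈Y<i} S(x, y)`
with `C = −bandgap`, S the Tanimoto similarity of Morgan fingerprints
(radius 2, 2048 bits — the community defaults, configurable), and Y the
inventory of previous iteration winners (the best molecule of each run's
final 100 steps).  Defaults `w_p = w_s = 1`; aggregation defaults to the
maximum over the inventory (the strongest diversity pressure), with the
mean as an option.  An empty inventory contributes nothing, so iteration 1
is plain property optimization.

Expected improvement uses the closed form
`EI = (μ−f*)Φ(z) + σφ(z)`; the σ = 0 limit is `max(μ−f*, 0)`, so
single-model "ensembles" degrade gracefully.  `f*` is the best predicted
reward within the current candidate batch (a config switch allows a global
incumbent).  Batch acquisition samples 10 000 random rollouts, deduplicates
by canonical form, and keeps the top 100 by EI (both configurable).

The active-learning loop alternates two acquisition modes per round —
diverse iteration winners (exploitative) and top-EI rollouts (explorative,
favouring high-uncertainty candidates) — hands the union to a
user-supplied trainer callback, and stops when the callback's held-out
RMSE reaches 0.3 eV (default) or the round budget is exhausted.

## Bundled predictors

The **conjugation oracle** maps a molecule deterministically to a bandgap
in a plausible window (≈0.3–4 eV): a decaying exponential in the number of
conjugated atoms plus a small heteroatom term that breaks ties between
similar structures.  It reproduces the one structure–property trend the
search is meant to exploit — more extended conjugation, lower gap — while
being instant and exactly reproducible.  It has no quantum-chemical
meaning, and results obtained with it validate the *search machinery*, not
any chemistry.  The **fingerprint ridge ensemble** (bagged ridge
regressions on Morgan fingerprints) is a minimal trainable implementation
of the ensemble contract for exercising the AL loop; the
**perturbed-oracle ensemble** is a synthetic stand-in that jitters a base
predictor deterministically per molecule to produce a nonzero σ.

## Synthetic fixtures

The fixture generator assembles molecules from small libraries of aromatic
cores (7 scaffolds, 2–4 substituent sites), conjugated two-point bridges
(3) and one-point end-groups (10), grouping core sites so that
`symmetry_degree` sites share one substituent.  Every attachment is a
cleavable bond and no library member contains an internal cleavable bond,
so each molecule's exact fragment composition is known and decomposition
must recover it — the ground truth behind the round-trip and
symmetry-label tests.  What the fixtures do **not** emulate: the chemical
breadth of a mined patent corpus, fused-ring cores with many inequivalent
positions, substituents that are themselves deeply nested, charged or
exotic species, or any property signal.  Passing the fixture suite shows
the decomposition/generation machinery is exact on molecules within its
structural assumptions; it says nothing about performance on real NFA
chemistry, which enters only through user-supplied corpora and predictors.

## Problem sizes and numerical choices

The test and acceptance workloads use: 200 fixture molecules for
round-trip/symmetry/memoization checks; 1000 randomized tuples for the UCT
oracle; 20 independent 2000-step searches on the 120-terminal enumerable
grammar (2000 steps is where single-run training curves flatten on this
grammar); 10 000 draws for the χ² uniformity check of the 1/k_t law
(α = 0.01); a 5×5 (μ−f*, σ) grid against a 10⁶-draw stratified
(randomized quasi-Monte-Carlo) normal sample for EI, whose own error
(~10⁻⁶) is far below the 10⁻³ comparison band; 5 diversity iterations;
1000 random rollouts of the open grammar for constraint checks.  Exact
float equality is asserted only where determinism guarantees it (ledger
reproducibility); stochastic properties use sign tests or χ² at stated
levels.

Degenerate inputs: k-means k clamps to the number of distinct fingerprint
vectors (duplicates must share a cluster); selection k clamps to the
number of distinct candidates; an uncleavable molecule is its own
single-entry vocabulary and sole decomposition leaf; a core fragment with
no reactive positions terminates a trajectory immediately; `best_in_window`
with a window longer than the ledger scans the whole ledger.

## Known limitations

* Single-bond chemistry only: new bonds are always single, ring-forming
  and multi-bond attachments are out of scope, and stereochemistry is
  passed through untouched.
* The reassembly search is exponential in the worst case (highly repetitive
  mark structures); it is intended as a test oracle, not a production
  synthesis planner.
* Identity masking is relaxed (with a warning) when it would empty an
  action set, so the distinct-fragments-for-distinct-marks rule is a soft
  constraint on very small pools.
* The focused-grammar core template and fragment libraries are
  illustrative defaults, not a curated acceptor library; real campaigns
  should supply their own via config.
* Rewards are cached per canonical molecule; predictors whose output
  changes between calls (e.g. mid-loop retraining) must be wrapped to
  invalidate the cache, as `iterative_diverse_search` does by rebuilding
  the search per iteration.
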