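# Methods

## Model and assumptions

Glycans are modeled as rooted labeled trees: nodes are monosaccharides
(symbol from a configurable registry plus anomeric state α/β/unknown),
edges carry glycosidic linkage positions (1–9 or unknown), and the root is
the reducing-end residue. Cyclic structures are rejected — glycan
biosynthesis is hierarchical and acyclic, and every algorithm here relies
on that. Structural identity is decided by a canonical key: a recursive
serialization with children ordered by (symbol, anomer, parent position,
recursive key), so two trees share a key exactly when they are isomorphic
as rooted trees respecting labels and linkages. Unknown positions and
anomers compare equal only to themselves for identity; during *pattern
matching* (substructure queries, enzyme rule contexts) an unknown on the
pattern side is a wildcard while an unknown on the data side matches only
an explicit unknown. This asymmetry lets users query with under-specified
motifs without ever merging distinct measured structures.

A glycoprofile is one sample's map from glycans to relative abundance
(normalized to sum to 1 within 1e-9). Ambiguous topology annotations are
handled by enumeration: each of the *n* candidate structures receives
abundance *g*/*n*, conserving total abundance.

## Substructure decomposition

Substructures are all connected subtrees of a glycan — everything
obtainable by breaking any combination of linkages — each rooted at its
node nearest the reducing end. Enumeration is the rooted-subtree dynamic
program (for each node, the product over children of "excluded or any
rooted subtree"); the worst case is exponential in depth but practical
glycans (≤ ~25 residues) stay small, and results are deduplicated by
canonical key. An optional root constraint (single monosaccharide,
lactose, or the N-glycan core) keeps only subtrees containing the core at
their reducing-end side, which focuses decomposition on biosynthetic
intermediates rather than internal epitopes.

Presence is binary: a substructure counts once per glycan regardless of
how many times it embeds (the embedding count is available separately via
`contains`). The substructure abundance vector is the presence-weighted
sum of relative glycan abundances, which makes it (i) bounded by 1,
(ii) monotone under containment — a substructure is at least as abundant
as anything containing it — and (iii) linear in glycan abundances. These
three invariants are property-tested.

## Network, pruning and weights

The substructure network connects each substructure to every substructure
containing it with exactly one more monosaccharide. Roots sit at the
core (or monosaccharide) level; a deeper node with no parent is a closure
violation and an error. Edges are annotated by enzyme rules — added
residue, linkage, and an acceptor context pattern — shipped as YAML for
N-glycan and milk-oligosaccharide transferase families and extensible by
the user; a rule set in which two different enzymes match one edge is
rejected as ambiguous.

Motif selection prunes a parent whose abundance vector equals some
child's across **all** samples (relative tolerance 1e-9; exact equality is
only meaningful with a float tolerance). Processing is topological, root
to leaf, and the pruned node's weight (all nodes start at 1) is divided
equally among the children it matched; a merge trace records the
absorbing children. Consequences, all tested: total weight is conserved;
no surviving parent–child pair has identical vectors; and the full
substructure profile is recoverable exactly from the motif profile by
following merge traces, so the reduction is lossless. Equality with a
parent always prunes the parent, never the child.

## Downstream analyses

**Clustering** uses complete linkage on correlation distance (1 − Pearson
r), cut at a distance threshold (default 0.5) or with the number of
clusters chosen by the elbow rule — the k maximizing the second difference
of within-cluster distance sums over k = 1..min(10, n−1). Zero-variance
items have undefined correlation; they are assigned distance 1 to
everything and flagged rather than crashing. Note the max-second-difference
elbow favors the sharpest kink: on equally separated planted clusters it
returns the first large drop, which is the rule's defined behavior.

**Representative substructures** superimpose a cluster's member trees by
anchored alignment from the shared root (children matched greedily by
label and linkage in canonical order); each position accumulates the
weight share of the members containing it, positions above the 51%
threshold are retained, and retention is restricted to the component
connected to the root so the consensus is itself a valid tree. Thresholds
0 and 1−ε yield the union and intersection trees respectively. An
alternative reading — selecting whole member substructures whose summed
weight exceeds 51% of the cluster total — exists; the per-position reading
is implemented because it is the one that produces position-resolved
consensus structures.

**Differential testing** compares one sample's cluster-member abundances
to a reference sample's by one-sided one-sample Wilcoxon signed-rank on
the member-wise differences (≥5 members required). P-values are exact for
≤25 nonzero differences and normal-approximated above; the effect size
r = |z|/√N always uses the continuity-and-tie-corrected normal z so the
small- and large-sample regimes report on one scale. Bonferroni controls
the family-wise level (0.05 over 16 tests → per-test criterion 0.0031).

**Flux proxies.** Because substructure abundance measures total amount
synthesized, the child/parent ratio along an edge estimates the fraction
of the substrate pool converted by that reaction; defined ratios lie in
[0, 1] by monotonicity, ratios with parent abundance below a floor
(default 1e-12) are excluded rather than imputed, and multi-parent
children give one ratio per incoming edge since enzymes live on edges.
Per-enzyme ratio distributions are compared between samples with a
one-sided rank-sum test (exact for ≤30 pooled tie-free values), optionally
restricted to edges defined in every compared sample.

**Statistics.** Correlation-test power uses the Fisher-z approximation
with small-sample bias correction and a t-derived critical r — the
classic `pwr.r.test` formula. Regression effect sizes (marginal R²) are
passed directly as the effect size r; under that convention the median
motif-level effect size 0.45 gives 80% power at 36 samples. The same
formula reaches 90% power at n = 47. Partial correlations come from the
inverse covariance (ridge-regularizable); an identity with the
regress-out definition is tested. Group comparison uses Welch t with
Benjamini–Hochberg FDR. PQN divides each sample by the median feature-wise
quotient against the median reference profile; it removes known dilution
factors up to one common global factor (the reference itself rescales),
which is the sense in which it is scale-invariant.

## Synthetic data generator

The generator builds a biosynthetic universe as the enzyme closure of a
core (default: an HMO-like pathway on a lactose core with five
transferases at conversion fractions 0.40–0.80), propagates a unit input
to steady state — each enzyme converts fraction *f* of its substrate pool,
the remainder is secreted — and observes secreted pools under
multiplicative log-normal noise (default sd 0.1) renormalized to relative
abundance. Species below a detection limit (default 1% of secreted mass,
the usual HPLC reporting threshold) go unobserved, reproducing the
sparsity of real glycoprofiles that makes motif pruning effective.
Knockouts set *f* = 0 and zero exactly the structures whose every route
requires the enzyme. The lactose core's reducing-end glucose occurs
nowhere else in the universe, so core-anchored substructures embed
uniquely and pool abundances are identifiable from decomposition.

What the generator does *not* emulate: measurement-process artifacts
(isotope patterns, in-source fragmentation, annotation errors), ambiguous
topologies, abundance-dependent noise, and — in branched universes —
the inflation of substructure abundance over single-route pools when a
structure is reachable by several addition orders. Passing tests
therefore demonstrate correctness of the transformations under the stated
generative model, not robustness to annotation error. Parameter-recovery
claims (edge ratio MAE < 0.05 at noise sd 0.1, n = 20) use strictly
linear cascades where the pool/abundance identity is exact.

## Problem sizes and numerical choices

The test suite and acceptance script use: 200 random trees (≤8 nodes,
3-symbol alphabet) against the exhaustive enumeration oracle; 100 random
universes for lossless-pruning checks; 20-sample cascades at
f ∈ {0.25, 0.5, 0.8} for ratio recovery; a 16-condition knockout panel
with glycans up to 12 residues (271 substructures) for panel-scale runs,
which complete in a few seconds. Tolerances: profile normalization and
pruning equality 1e-9; ratio monotonicity guard 1e-9; partial-correlation
identity 1e-8. Ties in rank tests are handled by mid-ranks with tie
corrections in the normal approximations. Degenerate inputs (constant
features, zero-variance samples, all-zero differences) return defined
values with warnings or explicit flags rather than NaNs.

## Known limitations

- Substructure enumeration and matching are exact but exponential in the
  worst case; glycans beyond ~30 residues with heavy branching are out of
  intended scope.
- The GlycoCT dialect covers RES/LIN topology only; underdetermined (UND)
  sections must be pre-expanded into explicit candidates.
- Estimating-equation (GEE) modeling of phenotype associations is
  deliberately not implemented; `model_ready_table` exports long-format
  tables for external fitting.
- The compositional ≥-lattice aggregation is unconstrained; pathway-aware
  compositional networks are not implemented.
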