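# Methods

## Model

A panel of monokaryons from a tetrapolar basidiomycete is described by a
ground-truth mapping strain → (A-allele, B-allele). Observables are
derived from it mechanically:

* **compatibility**: a cross is compatible iff the two strains differ at
  both loci;
* **sibling constraint**: the two protoplast-derived monokaryons of one
  dikaryon differ at both loci (they coexisted in a fertile dikaryon), so
  sibling pairs are inherently compatible and are recorded without
  testing;
* **OWE-SOJ relations**: an incompatible pair's plate phenotype reveals
  which locus is shared — encoded as A=B≠ (`AeqBne`), A≠B= (`AneBeq`),
  or A=B= (`AeqBeq`). The third category does not arise in the classical
  two-phenotype reading but is logically required for strains sharing
  both loci, so the data model supports it.

An assignment is identified with one set partition of the strains per
locus; allele labels are arbitrary class identifiers. Canonical form is
the restricted-growth labelling: classes numbered by first appearance
over strains in sorted identifier order. All reported assignments are
canonical, so equivalent solutions are recognized and deduplicated.

## Score

Each observed pair contributes independently:

| observation                        | checks                          | range   | max |
|------------------------------------|---------------------------------|---------|-----|
| compatible                         | A differs; B differs            | −2…+2   | 2   |
| incompatible with OWE-SOJ record   | A matches record; B matches     | −2…+2   | 2   |
| incompatible, no record            | assignment predicts incompatible| −1/+1   | 1   |
| untested                           | —                               | 0       | 0   |

The total is compared with the maximum achievable score (the sum of the
per-pair maxima); for a complete fully informed panel this is 2·C(n, 2),
i.e. 870 at n = 30. A record-free incompatible pair carries only a single
compatibility-level check because no locus-level evidence exists for it.
Untested pairs score 0 rather than being penalized — missing crosses are
a statistic, not an error.

## Search

1. **Anchor.** A sibling starting pair (user-supplied or the
   lexicographically first two-strain dikaryon) is designated A₁B₁ and
   A₂B₂.
2. **Compatible sub-population.** Remaining strains are scanned in
   identifier order and added to a greedy clique if observed compatible
   with every current member. Members with no OWE-SOJ record touching
   them are *evidence-isolated*: no evidence-consistent assignment can
   ever merge them with anything, so they are fixed with fresh mutually
   distinct alleles at no loss of optima. (The sibling anchor can be
   fixed unconditionally: SAME evidence chains imply true allele
   equality, and siblings differ at both loci, so no valid assignment can
   ever merge them.)
3. **Branch-and-bound.** The remaining strains are traversed depth-first,
   ordered by descending number of incompatible observations (ties by
   identifier, so runs are deterministic). Each strain branches over
   candidate labels per locus: one fresh label, plus — under the default
   `EVIDENCE_REQUIRED` policy — the labels of already-assigned strains in
   the same per-locus SAME-evidence connected component. A branch is
   pruned when its partial score plus the per-pair maxima of all pairs
   touching unassigned strains falls below the best complete score found;
   ties are kept, so the full co-optimal set survives pruning.
4. **Leaf filter.** A complete assignment is accepted under
   `EVIDENCE_REQUIRED` only if every allele class of size ≥ 2 is
   connected *within itself* in the evidence graph.

The component-based candidate rule together with the leaf filter makes
the searched space exactly the evidence-consistent partition space. This
matters when records have been corrupted: deleting one record from an
evidence triangle leaves a class that is connected only through a third
strain, and a cheaper direct-record rule (or hard-fixing the whole
clique) would silently drop co-optimal solutions containing that class.
The brute-force reference (`mti.oracle`) applies the identical
connectivity criterion to exhaustively enumerated partition pairs, and
the two routes are asserted to agree — best score and full canonical
co-optimal set — on hundreds of randomly perturbed small panels.

Under the `FREE` policy every existing label is a candidate for every
strain and nothing is fixed up front: with corrupted observations even a
merged starting pair can tie for the optimum, so completeness requires
the full restricted-growth space. The policy exists for oracle
comparisons and is guarded to ≤ 12 strains (the space is Bell-number
sized). The brute-force oracle itself is guarded to 8 strains
(Bell(8) = 4140; ~17M scored partition pairs at the ceiling), since it is
a verification instrument, not a production path.

`n_enumerated` counts complete candidate assignments examined. With
pruning enabled and a good incumbent found on the leftmost path this is
typically 1 on clean data; with pruning disabled it measures the size of
the evidence-restricted combination space; the test suite computes its
median over 12-strain panels at compatibility rates from ~70% to 100%
and asserts it falls monotonically, reaching a single candidate on fully
compatible panels.

## Suspect-record detection

Pairs whose contribution is negative in *every* co-optimal assignment are
flagged: `possible_false_negative` when observed incompatible, otherwise
`inconsistent`. When the best score equals the maximum no pair can be
negative, so perfect-scoring datasets flag nothing — which is exactly why
false positives are undetectable (see below).

## Synthetic populations

`generate_population` draws each dikaryon's two monokaryons from allele
pools of configurable size, resampling the second sibling until it
differs at both loci. Defaults are 15 dikaryons (30 strains), matching
the panel size the method is routinely applied to. Pools smaller than
twice the dikaryon count produce cross-dikaryon allele sharing and hence
incompatible pairs; `distinct=True` gives every strain unique alleles
(fully compatible matrix, the cleanest analytic case: max score
2·C(n, 2), truth the unique optimum).

`paired_sharing_population` builds an all-distinct truth and then makes a
chosen number of disjoint non-sibling strain pairs share one allele
(defaults: 6 A-sharing + 4 B-sharing pairs on 30 strains → 10
incompatible pairs, 24 A and 26 B alleles). This mirrors the regime of
real panels, where most strains are mutually compatible and
incompatibilities occur in isolated pairs, and it is the preset used for
false-positive experiments — which need truly incompatible pairs to
flip, and whose published behaviour (perfect-scoring wrong optimum)
holds when sharing classes are isolated pairs. With larger sharing
classes a false positive can leave a contradictory evidence triangle and
becomes partially detectable; the generator makes the studied regime
explicit rather than leaving it to pool-sampling luck.

What the generator does **not** emulate: genuinely missing crosses,
mis-read OWE-SOJ phenotypes (records are always truth-consistent unless
deleted by a false positive), linkage or population structure in allele
frequencies, and uneven sibling recovery. Passing tests therefore show
correctness of the inference given the stated error model, not robustness
to every failure mode of a real bench experiment.

## Error injection

A false positive rewrites a uniformly chosen truly incompatible pair as
compatible and deletes its OWE-SOJ record (a pair scored compatible would
never enter the assay). A false negative rewrites a uniformly chosen
truly compatible, non-sibling pair as incompatible and adds no record
(the assay is only run after an apparently failed cross; sibling pairs
are excluded because they are recorded compatible without testing).
Selections are without replacement and reproducible from the seed; all
experiment randomness derives from one root seed via seed sequences.

Consequences, asserted in the test suite:

* each false negative lowers the maximum achievable score by 1 (a
  2-point pair becomes a 1-point record-free pair) and costs the truth 2
  points, so with k false negatives on an all-distinct truth the best
  score is 2·C(n, 2) − 3k (867 at n = 30, k = 1) while the truth remains
  the unique optimum and the flagged set equals the injected set exactly;
* a false positive never lowers the maximum; on isolated-pair panels the
  search reaches the (now wrong) maximum, the truth is strictly
  sub-optimal, and nothing is flagged.

## Numerical and design choices

* Integer scoring throughout; no floating point in the search.
* Deterministic everywhere: traversal order, candidate order (existing
  labels ascending, fresh last), canonical sorting of the result set.
  Identical inputs give byte-identical result documents; strain input
  order does not change canonical optima.
* Co-optimal assignments are capped at `max_optima` (default 100) with a
  truncation flag; the *count* of optima stays exact.
* Degenerate inputs: empty datasets and datasets with validation errors
  are rejected before search; a missing sibling pair in the matrix is
  auto-filled as compatible at load time.
* Problem sizes used in the shipped checks — 30-strain panels for the
  score identities and replicate sweeps (50 replicates per error
  condition), 4–6-strain panels for the 200-dataset oracle comparison,
  12-strain panels for the pruning curve — were chosen so each suite
  stays a desk-scale computation while exercising the full panel size
  the score identities refer to.

## Known limitations

* The exhaustive reference, and hence the strongest form of verification,
  stops at 8 strains; beyond that correctness rests on the search-space
  argument above.
* With two or more false negatives the truth still stands as the unique
  evidence-consistent optimum under the default policy, because injected
  records carry no SAME evidence that would license alternative merges;
  rival co-optimal combinations appear only under the permissive FREE
  policy. Both policies are provided; which one a given bench workflow
  should trust depends on how much it believes absent evidence.
* Wall-clock performance is not a tuned quantity; the implementation is
  pure Python plus numpy and is comfortable at panel sizes an order of
  magnitude beyond 30 strains only when the compatibility rate is high.
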