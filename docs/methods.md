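# Methods

## Ortholog-lineage delimitation

A *gene lineage* is an ortholog group of grass genes descending from a
single ancestral gene at the base of the grasses. Given a rooted
gene-family tree with bootstrap supports and a rooted species tree, a
clade qualifies as a lineage when

* each species' genes inside the clade are monophyletic (recent
  within-species duplicates are treated as members of one lineage, not
  separate lineages), and
* after collapsing each species to one tip, every clade-internal node
  with support ≥ τ corresponds to a clade of the species tree restricted
  to the species present. Conflicts with support < τ are treated as
  phylogenetic noise and do not disqualify the clade.

Lineages are the *maximal* qualifying clades whose own support is ≥ τ;
the root, the root's children, and single leaves are exempt from the
support requirement, which guarantees the output partitions the
reference genes. Because clades are nested-or-disjoint, maximal
qualifying clades never overlap and no tie-breaking is needed. Genes of
species absent from the species tree (e.g. eudicot outgroups) and query
transcripts are excluded before delimitation; collapsed unifurcations
keep the surviving child's support, since the removed node's support
described a clade that included pruned leaves.

The support threshold τ formalizes a judgement that was originally made
by manual tree inspection; it defaults to 70 (a conventional bootstrap
cut-off) and is configurable everywhere. Input trees are taken as
rooted; `root_on_outgroup` re-hangs a tree on a named outgroup clade
when needed, in preference to silent midpoint rooting.

Query transcripts are assigned to lineage L when the smallest clade
containing the query and at least one reference gene contains reference
genes of L only; queries basal to all lineages or bridging two lineages
are returned UNASSIGNED and their expression is dropped from lineage
totals (the dropped total is reported for transparency).

Correctness is checked against a brute-force oracle that enumerates
every clade of random ≤ 12-leaf trees, tests the predicate with naive
set operations, and keeps maximal clades.

## Expression

rpkm(count, length, depth) = count / ((length_bp/1000) · (depth/10⁶)).
The depth denominator is the sample's total mappable reads from the
sample sheet — it is not recomputed from the count table, where unmapped
reads are invisible. Lineage expression in a sample is the *sum* of
member-feature rpkm (exactly additive); per-condition values are
arithmetic means over biological replicates. Feature lengths are used
as given (contig/cDNA-level rpkm; no effective-length modelling).

## Recruitment rules

All inequalities are strict ("greater than"), with a switch to ≥ for
sensitivity analysis; the threshold is 300 rpkm.

* Diurnal design (C3/C4 accession pair, pooled light and dark
  libraries, one replicate each): a lineage passes iff
  rpkm(C4, light) > 300, > rpkm(C3, light), and > rpkm(C4, dark).
* Gradient design (leaf segments A–D from base to mature tip): a
  lineage passes iff rpkm(C) > 300, rpkm(D) > 300, and
  mean(C, D) > mean(A, B).

When several lineages pass in one species, the primary call is the
top-expressed one (by C4-light rpkm, or mean(C,D)); ties fall back to
lexicographic lineage-id order and are logged. A passing lineage whose
C3 relative also rises day-over-night is flagged `c3_shared_pattern`:
high C4 abundance with the same diurnal behaviour in the C3 is not
C4-specific evidence, and such families are excluded from the
convergence tally by default. This flag is our numeric formalization of
a distinction originally made case by case; the discriminator (C3
day-over-night increase) reproduces the published accept/reject calls
but is a design choice of this package.

The convergence tally counts only families with ≥ 2 lineages (with a
single lineage, identity across origins is forced) and with a primary
call in every C4 species; a family is convergent when all primaries
coincide. Ambiguous multi-pass calls are reported but the primary
decides, which reproduces the published treatment of the ambiguous
*Setaria* aspartate-aminotransferase call.

## The null model and its tails

Under the null, each of n_species = 3 independent C4 origins draws one
of a family's k lineages uniformly with replacement; the probability
all three agree is k·(1/k)³ = 1/k². The number of convergent families
is a sum of independent Bernoulli(1/k_i²) indicators — Poisson-binomial.

* Monte-Carlo: 100,000 replicates (the published protocol) on a single
  numpy PCG64 stream; the histogram over counts is returned with the
  seed and generator recorded, so it is reproducible cross-platform.
* p_mc is the plain tail proportion (#replicates ≥ observed)/n, matching
  how the original bound "< 0.00005" was obtained; because that
  proportion can be 0 at finite n, the conservative (r+1)/(n+1)
  estimator and a binomial standard error are reported alongside.
* p_exact is the dynamic-programming convolution of the per-family
  success probabilities (O(m²) adds; numerically stable for thousands
  of families), validated to 10⁻¹² against 2^m subset enumeration for
  m ≤ 15. For the surveyed sizes {5,4,3,4,4,7,2} and observed = 5,
  p_exact ≈ 3.6 × 10⁻⁵, confirming the published Monte-Carlo bound.

Single-lineage families are excluded from the null vectors by default
(`include_single=True` retains them as certain successes for
sensitivity analysis).

## Duplicates and time courses

Within a recruited lineage, ≥ 2 nonidentical genes of one species are a
recent duplicate group. Pairs with identical coding sequence cannot be
distinguished by read assignment and are merged by *averaging* their
profiles — deliberately different from the lineage-level summing rule,
mirroring the two distinct published procedures. Dominance is the ratio
of the top gene's maximum segment rpkm to the runner-up's (infinite when
the runner-up is undetected).

Diurnal signals are divided per time point and replicate by a
constitutive reference gene (polyubiquitin UBQ10 in the original
assays), then averaged over replicates (standard error with n−1
denominator). Peak/trough are taken at sampled points only (no
interpolation); amplitude is max − min of the replicate-mean series; the
peak is "in phase with light" when it falls strictly before lights-off
(12 h default). No rhythmicity statistics are fitted.

## Synthetic data

The generator emulates the study designs, not the sequences:

* species tree fixed to
  ((Brachypodium,Oryza),(Zea,(Setaria,Alloteropsis)));
* a k-lineage family is k species-tree copies joined by a basal
  duplication ladder (the duplications predate grass diversification, so
  all splits between lineages are placed below the species-tree root);
  supports drawn uniformly from `support_range` (default 80–100);
  optional per-species losses never touch the planted lineage;
* default family sizes are the surveyed ones {5,4,3,4,4,1,7,2}; the
  planted recruited lineage (default: lineage 1 of every family, shared
  by all origins) receives 500 rpkm in C4-day samples — comfortably
  above the 300 threshold — against a 50-rpkm baseline, a night/day
  ratio of 0.2, and a gradient profile (0.1, 0.2, 0.9, 1.0)×500 rising
  toward the mature segments, the shape expected of a C4-recruited gene;
* counts invert the rpkm formula at 10⁶ mapped reads per sample and
  ~1.5 kb genes (count = rpkm · length/10³ · depth/10⁶, rounded), with
  optional Poisson noise using that value as the mean; gradient designs
  get 2 replicates, pooled pair libraries 1, matching the original
  sampling;
* time courses are raised cosines at 4-h spacing over a 12:12 h
  light:dark day, three replicates, reference gene constant at 1.
* the original day/night libraries pooled RNA across time points; the
  generator's `day_mode` chooses whether the day target represents the
  pooled mean over light time points (default) or a single peak
  time point (scaled by the peak/mean ratio of the diurnal shape).

Seeding: one root seed; `numpy.random.SeedSequence(seed).spawn` derives
child streams in a fixed order (one per family, then counts, then time
courses), so regeneration is bit-identical and adding families does not
reshuffle earlier ones.

What the generator does *not* emulate: read-mapping ambiguity between
close duplicates (an optional cross-assignment rate was considered and
left out; profiles are exact), assembly fragmentation of 454 contigs,
overdispersion beyond Poisson, and gene-tree estimation error beyond
support values. Passing the recovery tests therefore shows the pipeline
is correct under its own assumptions, not that those assumptions hold
for any particular real data set.

## Problem sizes and numerical choices

Tests run the full 100,000-replicate null (sub-second) but reduced
Monte-Carlo sizes (4,000–50,000 replicates) where many seeds are
scanned; oracle equivalence uses ≤ 12-leaf trees (exhaustive clade
enumeration) and ≤ 15 families (2^m subset enumeration). Degenerate
inputs are errors, not silent defaults: nonpositive lengths/depths,
missing conditions or segments, empty histograms, k < 1, supports
outside [0, 100]. Floating-point comparisons in the rules are exact
strict inequalities; the 300 threshold is compared directly (a lineage
at exactly 300 rpkm fails).

## Known limitations

* The compatibility rule is a formalization of what was originally
  manual tree inspection; real borderline trees may have been judged
  differently.
* Lineage numbering is tree-order based; it matches the planted truth
  for ladder-simulated families but is arbitrary for real trees (only
  identity across species matters for the tally).
* The encoded published survey fixes lineage identities for families
  whose numbering is not printed; arbitrary shared labels are used
  there, which affects nothing downstream of identity.
* The null model is uniform over lineages; expression-weighted or
  compartment-aware nulls are out of scope.
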