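# Methods

This note records the models, conventions and numerical choices behind
`fepi`, and what the synthetic data do and do not establish about real
data.

## Fold changes and the undetermined convention

A fold change is the mean ± sample SD (ddof = 1) of the paired
per-replicate ratios treatment/control — not the ratio of means — because
the quantity being summarized across biological replicates is the fold
itself.  Replicates are paired by index; the data carry no explicit
pairing, so index pairing is the deterministic declared choice.

Zero controls are handled in three tiers:

* all control replicates zero with any positive treatment → the fold is
  **undetermined** (`-` in tables); no finite ratio exists;
* all replicates zero in both conditions → undetermined with an extra
  *silent* flag, distinguishing absent transcripts from induced ones;
* some but not all control replicates zero → those pairs are dropped and
  `n_reps` reduced, keeping the mean and SD finite instead of producing
  infinities.  With a single surviving pair the SD is undefined and
  omitted.

Undetermined folds count as *up-regulated* wherever a direction is
needed — they pass any up-cutoff in the fold filter and behave as "up" in
the type classifier — since a transcript that appears only under
treatment is an extreme induction.  A fold of exactly 1 leaves a gene
unclassified rather than silently assigned; exact ties are measure-zero
on real data and always indicate something worth inspecting.

Differential-expression significance is an attribute of the upstream
input lists; the package intersects and filters those lists, it does not
re-test them.

"Changed more than c-fold" is ambiguous for a two-contrast type (either
contrast, or both); `type_subcounts` reports both readings and the
package asserts neither as the canonical one.

qPCR relative expression uses per-replicate ΔCt = Ct(target) − mean Ct of
two reference genes, relative expression = 2^(mean ΔCt_control − mean
ΔCt_treatment), and a two-sample two-tailed Student t test on the
replicate ΔCt values; with fewer than two replicates per group the
p-value is NaN.

## Clustering

Rows are log2 fold changes per contrast, missing where undetermined.
Distance is pairwise-complete 1 − Pearson with average linkage by
default: correlation distance groups genes by profile shape, which is
the standard choice for expression heatmaps; Euclidean distance is a
config option (pairwise-complete, rescaled by the fraction of shared
cells).  With only two contrast columns correlation distance is
coarse — two complete profiles are either perfectly correlated or
anti-correlated — which is accepted and documented rather than hidden;
the Euclidean option is the finer-grained alternative.  Degenerate
cases: gene pairs sharing < 2 finite cells get the maximal distance
2.0; constant profiles get distance 0 to an equal constant profile and
1 otherwise.  Genes with no finite cell are excluded and reported.
Rows are sorted lexicographically before linkage so merge-distance ties
break by smallest gene id and the tree (and its depth-first leaf order)
is invariant to input order.  Dendrograms are exported as Newick with
branch lengths equal to merge-height differences.

## Co-expression networks

Edges require signed Pearson r ≥ threshold (default 0.7, inclusive);
only positive co-expression defines the network, with an absolute-value
mode behind a flag.  Whether the original tooling used signed or
absolute correlation, and ≥ versus >, is not documented anywhere
authoritative; signed/inclusive is declared as the default here.  The
network is built only among the supplied gene list, not against the full
compendium.  Zero-variance profiles (correlation undefined) are excluded
with a report.  Modules are exactly the connected components, listed
largest-first with lexicographic tie-breaks; exports (SIF, GraphML, edge
TSV) are lexicographically ordered and therefore byte-stable.

## GO enrichment

The per-term test is the one-sided hypergeometric upper tail
P(X ≥ k) via `scipy.stats.hypergeom.sf`.  Annotations are closed under
ancestry (true-path rule) before testing; `part_of` is treated
identically to `is_a` for ancestry, the simplest faithful closure
(configurable at parse time by which edge keys are retained).

The elim pass processes terms deepest-first, depth being the *longest*
path to the root (ties by term id), matching the published bottom-up
description of the algorithm.  A term whose current p-value falls below
the elim cutoff has its currently annotated genes removed from all
strict ancestors before those are tested.  The elim significance
threshold defaults to the reporting cutoff (0.01); they can be set
independently.  Universe and study sizes (N, n) stay global during
pruning; only per-term annotated sets shrink.  Classic p-values are
always computed on unpruned sets, and no multiple-testing correction is
applied, matching how elim results are conventionally reported.  Note
that p_elim ≥ p_classic does *not* hold in general for ancestors
(pruning can move the tail either way); for leaf terms the two always
coincide, which is asserted as a test.

## Promoter motif scanning

Promoters are stored 5'→3' with the final base adjacent to the
translation start.  Hits are reported as upstream distances: a window
starting at 1-based string position s in a promoter of length L with
pattern length m lies at distances d_near = L − s − m + 2 and
d_far = L − s + 1, with position 1 the base immediately 5' of the start
codon.  This origin/orientation convention is an inference from internal
consistency of the published hit coordinates (it is the only convention
under which "start ≤ 1000" reproduces the published count of proximal
genes) and is flagged as such.

Scanning is exact degenerate matching against position-wise IUPAC base
sets — no scoring, no mismatches.  Only the forward strand is scanned:
P1BS (`GNATATNC`) equals its own reverse complement at the degenerate
level, so a second-strand scan adds no information; this is proved by a
test rather than assumed.  A sequence letter `N` never matches any
pattern position (conservative handling of masked bases).  Duplicate
identical hit records are preserved in summaries — the published hit
table itself contains a duplicated record, and its printed totals are
only reproducible if duplicates are kept; both the raw record count and
the per-pattern tallies reflect input fidelity.

## Synthetic data: what it emulates, and what it does not

* **Contrasts** (`gen_contrast_experiment`): log-normal per-gene baselines
  (log-mean 3, log-sd 1, i.e. typical abundances of tens of RPKM spanning
  a few orders of magnitude), three replicates, gamma-distributed
  multiplicative noise with coefficient of variation 0.1 by default
  (tight technical+biological noise typical of RNA-seq abundance ratios),
  planted fold effects drawn lognormal(0, 1.5) so up- and
  down-regulation are exchangeable in log space and the right tail
  reaches the hundreds-fold inductions seen in real Fe-deficiency data.
  5 % of planted DEGs get all-zero controls with positive treatment to
  exercise the `-` convention.  Gamma noise makes expectations exact and
  values non-negative; cv = 0 reproduces means exactly, which is what
  makes noiseless planted-fold recovery an exact test.
* **Compendium** (`gen_compendium`): module genes share a standard-normal
  latent array profile scaled by weight w plus independent N(0, s²)
  noise; the expected within-module correlation is w²/(w² + s²), so
  w = 3, s = 1 plants r = 0.9 (comfortably above the 0.7 threshold) and
  the closed form lets tests plant modules on either side of it.
  Defaults use 200 arrays, comparable to a few-hundred-array root
  compendium; background genes are independent noise with essentially
  zero probability of crossing r = 0.7 at that sample size.
* **Ontology** (`gen_go_universe`): a single-rooted random DAG (each term
  takes 1–2 parents among shallower terms), direct annotations of 2
  terms/gene emitted *unpropagated*, one planted term (default: the
  deepest) carried by ~10 % of genes, and a study list drawn with
  weighted sampling at the stated odds (odds 1 = the hypergeometric
  null).
* **Promoters** (`gen_promoters`): i.i.d. background at a chosen GC
  content with concrete motifs written at exact upstream distances;
  `forbid_background_hits` rejection-resamples offending background
  windows until the scan output equals the planted truth exactly.

What passing these tests shows: the operations are algebraically correct
(oracle-equivalent), conventions are applied consistently, planted
structure at the stated effect sizes is recovered, and runs are
deterministic.  What they do not show: robustness to correlated noise,
batch effects, array curation artifacts, annotation-release differences,
non-i.i.d. promoter composition, or mapping/normalization upstream of
the abundance tables — none of which the generators model.

## Published-record fixtures

Two small fixtures ship with the package: the published fold-change
records (mean ± SD per contrast, `-` for zero-control genes) for the
Arabidopsis root genes responding more than twofold to either stress,
and the published 18 P1BS promoter-hit records over 12 genes.  The
packaged fold-change table carries the 110 records recoverable from the
printed source; its purely down-regulated block is not recoverable, so
tests assert properties of the available records (all pass the twofold
filter; directions classify as printed) rather than full-study totals.
Network statistics on the original 300-array compendium and
enrichment p-values against a specific annotation release are
compendium- and release-dependent; they are covered by the planted-truth
and oracle properties above instead of by value reproduction.

## Problem sizes and determinism

Default test and acceptance sizes — a few hundred genes, 200 arrays, 100
replicate seeds, 3-kb promoters — were chosen so each property is
measured with comfortable statistical margin while the whole suite runs
in seconds.  All randomness flows through `numpy.random.default_rng`
seeded per artifact stream from one integer seed, so every artifact,
report and test is bit-reproducible; adding an artifact to a run never
perturbs the streams of the others.
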