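# Methods

## Scope and data model

The pipeline starts from assembled transcript models and quantified
expression: GTF transcript/exon structures, an FPKM matrix over a small
factorial sample design (default 3 tissues × 4 age/condition groups = 12
samples), and tabular homology hits. Read trimming, mapping, assembly and
the execution of BLAST/CPC are upstream of this package and are consumed as
files. All in-memory genomic intervals are 1-based inclusive; conversion to
half-open coordinates happens only at format boundaries (BED6 export,
interval-tree indexing).

Homology hits use a 7-column extended tabular dialect carrying both query
and target coverage explicitly, because the retention rules are stated in
terms of "coverage of query and/or target" and standard 12-column tabular
BLAST output carries neither; `hits_with_computed_coverage` converts
12-column rows when sequence-length tables are available.

Strand "." is accepted on input and treated as unknown. Strand-dependent
operations (antisense calling, orientation matching) exclude unknown-strand
records with a warning instead of guessing, since a silent guess corrupts
classification downstream.

## Identification cascade

Filters run in a fixed order — length, coding potential, protein-domain
evidence, expression — with survivor counts recorded after each step; a
transcript failing step k is not evaluated at step k+1. The filters are
independent predicates, so reordering (a config option) changes the
per-step counts but never the final survivor set; a test asserts this.

Parameter choices:

- **Length ≥ 200 bp** is *total exonic length*, not genomic span: the rule
  defines the RNA molecule. Genomic span is reported separately in the
  class summary.
- **Coding potential: eliminate at score ≥ −1** on the CPC scale. This is
  deliberately stricter than the conventional CPC coding call (score > 0);
  the threshold is configurable and the default documents the discrepancy.
- **Domain evidence**: any Pfam or NR hit eliminates, at any E-value by
  default (`domain_evalue_max` adds a ceiling when wanted).
- **Expression: max FPKM over samples ≥ 0.3.** Max-over-samples is the most
  permissive reading of an unqualified FPKM cutoff; it is configurable.
- Transcripts absent from the expression matrix count as FPKM 0 (they fail
  the expression step) with a warning rather than an error, since
  assemblies and quantifications can legitimately diverge.

The built-in surrogate coding scorer maps ORF coverage to the CPC-like
scale: s = −2 + 4·(longest ATG→stop ORF)/(transcript length), searching 3
forward frames plus 3 reverse frames when the strand is unknown. ORFs
require an in-frame stop; the stop codon counts toward ORF length. ORF
coverage ≥ 25% therefore lands at s ≥ −1 (flagged coding). The scorer is a
transparent stand-in for an external coding-potential classifier, not a
reimplementation of one.

## Classification

Rules fire in precedence order antisense → intronic → sense-discard →
intergenic, mirroring assembly-comparison class-code semantics (x, i, o, u).
Overlap means ≥ 1 shared base; no fractional-overlap parameter exists
because none is defined for the method. Two consequences worth noting:

- A transcript antisense to one gene and intronic to another is antisense.
- An opposite-strand transcript contained in an intron with no exon overlap
  is *intronic*, not antisense — the antisense definition is exon-level.

Nearest-gene lookup uses span-edge distance with ties broken by
lexicographically smaller gene id (determinism). The relative position is
reported in the gene's 5′→3′ frame, with "overlapping" exactly when the
edge distance is 0.

## Differential expression

The 12-sample design has no within-condition replicates, so the package
uses tissues as groups and age/condition samples as replicates: Welch's
t-test on log2(FPKM+1), Benjamini–Hochberg FDR within each contrast, and
log2 fold change on pseudocounted means (+1, avoiding division by zero).
Significance requires |log2FC| > 1 (fold change strictly > 2) and
FDR < 0.05. This is a deliberate, documented methodological replacement for
assembly-era DE tooling; count-based models are out of scope because the
pipeline's unit is FPKM. "Expressed" for profiling reuses the 0.3 FPKM
cutoff — the single consistent choice given the identification threshold.

## Conservation

**Sequence.** Hits with coverage ≥ 50% (max of query/target coverage by
default; configurable to min) and E ≤ 1e−5 become edges weighted
−log₁₀E capped at 200 (E = 0 takes the cap), reciprocal hits merged by max.
This replaces OrthoMCL's full normalization machinery with a simple,
auditable scheme. MCL runs on the column-stochastic matrix with self-loops
at each node's max incident weight, alternating expansion (squaring) and
inflation (entrywise power 1.5 by default, then column renormalization)
until the largest entry change is < 1e−6 or 100 iterations; clusters are
the connected components of the converged matrix's nonzero structure, and
singletons are dropped (a group needs ≥ 2 members). Raising inflation never
decreases cluster count on a fixed graph (asserted over an inflation grid).

**Position.** Anchors (ortholog gene pairs with per-scaffold ordinal
indexes) are chained by quadratic DP into longest strictly monotone chains
— increasing = collinear, decreasing = inverted — with consecutive anchors
differing by ≤ 25 ordinals in both species; chains of ≥ 5 anchors are
emitted greedily by size, each anchor in ≤ 1 block. The 5/25 defaults follow
the common defaults of syntenic-block tools. The DP is verified against an
exhaustive subset-enumeration oracle for ≤ 12 anchors.

A lncRNA is *upstream* of a gene when it overlaps, or ends at/before, the
gene's 5′ end, *downstream* when it overlaps, or starts at/after, the 3′
end (gene strand defines the frame); a lncRNA strictly inside the gene body
is on neither side, one spanning the whole gene is on both. Two lncRNAs
match at an anchor pair when each lies within its species window
(defaults 815 kb and 894 kb, edge-to-edge distance), both on the same side,
with equal orientation relative to their anchor genes. "Same relative
orientation" is interpreted strand-relative to the anchor; a match needs
≥ 1 supporting anchor. Swapping the two species (and their windows) yields
the same match set with roles reversed, which a test asserts.

## Coexpression

cP is the standard two-sided t-distribution p-value for a correlation
coefficient — the conventional construction where the method itself leaves
"correlation P value" undefined — and is cross-checked against a
permutation p-value (10⁴ permutations) in the tests. At n = 12, |r| ≥ 0.8
already implies cP < 0.01, so the cP gate is non-binding at the default
thresholds and sample size; it binds for smaller designs. Exact linear
dependence can land at |r| = 1 − O(ε) in floating point; values within
1e−12 of 1 snap to ±1 with cP = 0.

Tier boundaries are inclusive: |r| = 0.8 with cP ≤ 0.01 is strong,
|r| = 0.9 intensive. The cancer-homology retention rule is strict
(coverage > 40%, E < 1e−5) whereas the ortholog-graph rule is inclusive
(≥ 50%, ≤ 1e−5) — both as stated for the respective analyses; the tests pin
the boundary behavior of each. The expressed-in-all-groups prefilter
requires FPKM ≥ 0.3 in ≥ 1 sample of every tissue × condition group (strict
reading; tissue-only grouping is a parameter), and the ≥ 4-developmental-
groups variant is provided for the small-gene-set analysis. No
multiple-testing correction is applied across the pair grid by default,
matching the fixed-cutoff design; `bh_correct=True` opts in. Constant
expression vectors are skipped, since r is undefined for them.

## Enrichment

P(X ≥ k) is computed from the hypergeometric survival function; Bonferroni
m counts only terms actually tested (K ≥ 1 annotated universe genes, k ≥ 1
list hits), which matches correction over performed tests without
penalizing untestable terms. The universe defaults to all genes with ≥ 1
annotation in the loaded map (configurable). No ontology-graph propagation
is applied: the map is tested as given.

## Synthetic data

The generator emulates the 12-transcriptome design: 3 tissues × 4
age/condition groups. Defaults chosen as study conditions:

- **Annotation**: 20 coding genes on one scaffold, exon counts drawn
  uniformly 2–14 (mean 8, echoing typical coding genes), exons 100–400 bp,
  introns 1.5–4 kb, 50 kb intergenic gaps; 5 planted lncRNAs per context
  class. Placement guarantees the class labels, so classifier agreement
  measures correctness, not noise.
- **Expression**: log-normal FPKM baselines, (μ, σ) = (1.0, 1.2) for
  lncRNAs and (2.5, 1.0) for coding genes — only the rank relation
  (lncRNA lower) is known, so these are conventions, not calibrations.
  Planted correlations blend the standardized partner row with independent
  standardized noise using weight w = r/(r + √(1−r²)), which makes the
  expected sample correlation equal the target; the blend is mapped to
  positive FPKM by a positive affine transform, which Pearson r is
  invariant to. |r| = 1 uses the zero-noise branch and is exact. Over 200+
  replicates at n = 12 the mean realized r sits within 0.05 of the target
  (asserted for r = 0.9).
- **Hits**: within-group pairs get coverage 60–95%, E = 10^−U(10,50);
  decoys either fail the retention rule outright ("filtered" mode) or pass
  it near threshold ("low_weight" mode, coverage 50–60%, E = 10^−U(5,6.5))
  to stress the clustering with weak cross edges.
- **Synteny**: anchor blocks spaced 1.5 Mb — wider than the positional
  windows — so a lncRNA planted within 100 kb of its anchor is in range of
  that anchor only, and each planted pair takes a distinct (side,
  orientation) combination; together these make the planted pairs exactly
  the rule-implied matches, so precision/recall against truth is
  well-defined at 100% under zero noise.
- **Enrichment**: one term's genes over-weighted 8-fold when drawing the
  gene list.

One RNG stream per sub-generator, keyed by CRC32 of the stream name from
the master seed, so adding features to one generator never shifts another's
output; identical configs give byte-identical files.

What the generator does *not* emulate: read-level noise, sequence content
(no hexamer/codon structure), alignment artifacts, assembly fragmentation,
or inter-feature correlation beyond the planted pairs. Passing
planted-truth tests therefore demonstrates algorithmic correctness of the
analysis stages under the stated statistical model, not robustness to
real-data pathologies.

## Problem sizes

The test suite and acceptance script run planted-recovery at the sizes the
design calls for: 5-per-class annotations, ortholog groups of (3, 3, 4, 5)
with 5% decoy edges, 6-anchor × 2-block synteny layouts with 4 planted
pairs, 200 replicates for the intensive-call rate, and 1000-feature DE
matrices with 20 planted 8-fold features (n = 4 per group, log-scale noise
sd 0.25). The full suite completes in seconds.

## Known limitations

- The MCL readout (connected components of the converged matrix) merges
  overlapping attractor systems; for the weakly-coupled graphs produced by
  the retention rule this is the standard behavior, but pathological
  near-tie graphs could differ from implementations that split overlapping
  attractors.
- Synteny chaining scores chains by anchor count only (no E-value weighted
  scoring, no tandem-array collapsing).
- The DE procedure is a replacement method; its operating characteristics
  are validated on the generator's log-normal noise model only.
- Enrichment treats the annotation map as flat; GO true-path propagation,
  if wanted, must happen upstream.
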