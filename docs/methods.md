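# Methods

## Problem setting

A pangenome study of a cultivar panel asks, for every gene, whether it is
present in all N sequenced accessions (*core*) or missing from at least one
(*auxiliary*, also called dispensable). Orthology clustering alone
(OrthoFinder-style orthogroups) over-calls presence: a paralog elsewhere in
the genome satisfies the orthogroup membership without the gene actually
being at its ancestral locus. This package implements the dual-evidence
remedy — require a whole-genome-alignment anchor near *both* genes of an
ortholog call — together with the downstream analyses that such labels feed:
exact accumulation (rarefaction) curves, core-vs-auxiliary structural and
expression contrasts, term enrichment, and cross-species intersection of
positionally conserved core sets.

## Dual-evidence classification

For an ortholog gene pair (g_a in accession A, g_b in accession B) the
anchor distance is

    d(g_a, g_b) = min over anchors z of max(gap(g_a, z_A), gap(g_b, z_B)),

where `gap` is the bp separation between the gene span and the anchor
interval on that accession's side (0 when they overlap; the anchor must lie
on the gene's chromosome). A call is retained when d ≤ W with W = 5,000 bp,
boundary inclusive. Requiring the *max* of the two per-side gaps to clear
the window expresses that both genes must flank the same alignment block.

Support is per accession: an accession counts as supported-present in an
orthogroup when at least one of its member genes has a retained call with a
member of any other accession, so one well-anchored gene rescues the
accession even if a second paralogous member fails the filter. An
orthogroup is core iff all N accessions are supported; occupancy-1 groups
(singletons included) can never be core.

A member gene with *no* retained call at all — in a group that does span
≥ 2 accessions, so the claim was testable — is demoted to an implicit
auxiliary singleton. This is what actually removes a mis-clustered paralog:
the family keeps its true occupancy, the stray member loses its false
presence call, and the post-filter occupancy structure remains a partition
of all genes. Degenerate windows behave as limits: W = ∞ retains every call
(pure orthogroup-occupancy classification, no demotion); W < 0 retains none
(every multi-accession group dissolves into auxiliary singletons).

The orthology-free alternative is reference projection: a reference gene is
called present in accession X when at least a fraction θ of its span is
covered by the union of reference↔X anchors. θ = 0.5 by default — no
published threshold exists for this step, and half-span coverage tolerates
fragmented alignment edges while rejecting incidental overlaps; it is
exposed as a parameter.

## Accumulation curves

The average number of core and pan orthogroups over *every* combination of
k of the N accessions depends on the presence structure only through the
occupancy histogram counts[m] (number of orthogroups present in exactly m
accessions). Writing C(a, b) for binomial coefficients with C(a, b) = 0
when a < b:

    E[core(k)] = Σ_m counts[m] · C(m, k) / C(N, k)
    E[pan(k)]  = Σ_m counts[m] · (1 − C(N − m, k) / C(N, k))

These are exact identities, not approximations: a group of occupancy m is
contained in a random k-subset with probability C(m,k)/C(N,k) and avoids it
entirely with probability C(N−m,k)/C(N,k). The implementation evaluates the
sums in exact rational arithmetic (`fractions.Fraction`) and converts to
float at the end; brute-force enumeration of all C(N, k) subsets is kept
behind a 10^5-subset cap as an independent oracle and agrees to better than
1e−12 on random matrices (exactly, as rationals, on small fixtures).
Marginal gain g(k) = pan(k) − pan(k−1) quantifies openness; the pangenome
is flagged "open" while g(N) exceeds a closedness threshold (default 0: any
new group still arriving with the last genome). Gene-level rather than
orthogroup-level curves can be produced by weighting each group in the
histogram by its mean member count.

## Feature and expression contrasts

Features are computed on one collapsed model per gene — the isoform with
the largest total CDS length, since per-gene statistics need a single
representative and isoform handling is otherwise unconstrained: gene length
(end − start + 1), CDS length and count, intron count = CDS count − 1, and
total intron length = CDS-span length − CDS length. TPM enters as an opaque
input column; genes without a value are excluded from the expression
contrast only (absent, never zero).

Published pangenome comparisons of these features are typically shown as
density plots without a named test. To make "auxiliary genes are shorter"
assertable, groups are compared with a two-sided Wilcoxon rank-sum test —
exact null distribution when both groups have ≤ 8 observations, normal
approximation with continuity correction otherwise. Medians and direction
are the primary output; the p-value is secondary.

## Term enrichment

Classic per-term one-sided hypergeometric over-representation of a
foreground class (default: auxiliary orthogroups, where each orthogroup
carries the union of its members' terms) against the labeled universe, with
Haldane-corrected odds ratios (0.5 added to each cell when any cell is
zero) and Benjamini–Hochberg q-values. Terms annotating fewer than
`min_count = 3` universe members are skipped as uninformative. No GO-graph
decorrelation (weight/elim-style algorithms) is attempted; ancestor
propagation of annotations under the true-path rule is available as an
explicit pre-processing step. Orthogroup-level testing avoids the
pseudo-replication that per-gene-copy testing would introduce, since every
copy of a family shares its annotation.

## Cross-species core intersection

Two species' positionally conserved core sets are intersected through
weighted cross-species gene links using greedy reciprocal-best 1:1
matching: links sorted by (score desc, lexicographic gene pair) and
accepted while both endpoints are unmatched. The ordering key treats the
two genes symmetrically, so swapping the species reproduces the same pair
set, and the tie-break makes the result invariant to input order. Matched
pairs are the cross-species core; unmatched core genes are reported as
species-specific. Conservation in an outgroup is the fraction of matched
genes present (by reference projection) in the outgroup genome, reported
half-up-rounded to one decimal.

Rounding everywhere follows the half-up convention of printed summary
tables (`percent()` in `vaccpav.util`), not Python's bankers rounding.

## Synthetic pangenome generator

The generator emulates the statistical structure the analysis assumes, on a
shared ancestral coordinate frame:

* **Panel**: N = 11 accessions and 20,000 orthogroups by default, matching
  a cranberry-style panel; `core_fraction = 0.53` of groups get occupancy
  N, the remainder draw occupancy from a spectrum — uniform on 1..N−1 by
  default (the real spectrum is unpublished), with a beta option for the
  U-shaped spectra seen in other crops.
* **Placement**: each orthogroup owns one slot on one of 12 chromosomes
  (60 Mb each by default); all copies of a group share the slot, ± optional
  positional jitter. Slots are sized so genes never overlap.
* **Features**: ancestral gene length is log-normal (arithmetic mean
  3,000 bp core vs 1,200 bp auxiliary, log-sd 0.5, truncated at 300 bp and
  30 kb); CDS count is 1 + Poisson (mean 5 core vs 2 auxiliary); roughly
  half the span is coding, split across alternating exons/introns. Length
  and structure are properties of the group, so zero jitter yields
  byte-identical coordinates across accessions.
* **Expression**: log-normal TPM per gene copy, natural-log mean 2.0 (core)
  vs 1.0 (auxiliary), log-sd 1.0 — core genes higher on average with heavy
  overlap, as observed in real panels.
* **Terms**: 20 GO-style terms assigned per orthogroup; one planted
  defense-response term at probability 0.20 in auxiliary vs 0.05 in core
  groups, the rest neutral at 0.05/0.05.
* **Anchors**: for every accession pair and every group present in both,
  one anchor spanning both copies (± 500 bp padding) survives with
  probability 1 − dropout; coordinates take optional Gaussian jitter.
* **Orthogroup errors**: with rate ε, an auxiliary singleton is absorbed
  into a random multi-accession family whose locus lies ≥ 50 kb away or on
  another chromosome — a false presence call with deliberately no syntenic
  support, which the 5 kb filter must remove.

All randomness flows from one seed through per-stage child generators, so
identical parameters give byte-identical outputs and stages can be re-run
independently. What the generator does *not* model: sequence content (no
FASTA), tetraploid fractionation and haplotype structure, segmental
duplications, nested/overlapping genes, alignment breakpoints uncorrelated
with genes, and annotation errors other than singleton mis-merges. Passing
recovery tests therefore demonstrates correctness of the pipeline's logic
under its own assumptions, not robustness to every artifact of real
assemblies.

## Problem sizes and numerical choices

The test suite and the acceptance script run the classifier end to end at
the full default panel scale (11 × 20,000, ≈ 1.5 M directed anchors);
calibration loops use reduced panels (2 accessions, 2,000–5,000 groups,
100–200 seeds) chosen so each simulation still has the sample sizes the
corresponding claim is about. Enrichment null calibration counts a seed as
a false positive when any term reaches BH q < 0.05 — the FDR-level
criterion that the procedure actually controls under the global null.
Closed-form curve values are exact rationals; float comparisons in tests
use 1e−12 absolute tolerance. Interval arithmetic is 1-based inclusive
throughout, and gene-to-anchor gaps are computed as `max(0, gs − ae,
as − ge)`, so "within 5 kb" includes the 5,000 bp boundary exactly.

## Known limitations

* The dual-evidence filter assumes anchors are gene-scale; very long
  alignment blocks would satisfy the proximity test for many genes at once
  and weaken its discriminative power.
* Reference projection reduces polyploid haplotype complexity to a single
  reference coordinate system; fractionation between haplotypes is not
  modeled.
* Enrichment reproduces the classic hypergeometric statistic only;
  published FDR values computed with graph-aware algorithms (topGO weight
  variants) are not comparable term by term.
* The matching step for cross-species cores is greedy reciprocal-best; it
  does not attempt maximum-weight bipartite matching, which could differ on
  dense many-to-many link sets.
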