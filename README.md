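# vaccpav

Core/auxiliary pangenome analysis for cultivar panels, built around the
*Vaccinium* (blueberry/cranberry) style of study: per-accession gene
annotations, an orthogroup table, and whole-genome-alignment anchors go in;
core/auxiliary gene labels, exact accumulation curves, feature and
expression contrasts, GO-term enrichment, and cross-species core
intersections come out. A ground-truthed synthetic pangenome generator
makes every stage testable at desk scale.

**Who it is for** — anyone classifying genes as core (present in every
accession of a panel) or auxiliary/dispensable (missing from at least one)
from orthology plus synteny evidence, and modeling how gene content
accumulates as genomes are added.

## The methods in brief

**Dual-evidence classification.** Orthology clustering over-calls presence:
a paralog elsewhere in the genome satisfies orthogroup membership without
the gene sitting at its ancestral locus. An ortholog call between genes
g_a and g_b is therefore retained only when some alignment anchor z lies
within W = 5,000 bp of **both** genes:

    d(g_a, g_b) = min_z max( gap(g_a, z_A), gap(g_b, z_B) ) ≤ W .

An accession is supported-present in an orthogroup when ≥ 1 of its member
genes has a retained call with any other accession; an orthogroup is core
iff all N accessions are supported. Genes whose every call the filter
rejects are demoted to auxiliary singletons. A purely positional mode
(reference projection: present where ≥ 50% of the gene span is covered by
anchors) is also provided.

**Exact accumulation curves.** The average core/pan counts over *every*
combination of k accessions collapse onto the occupancy histogram
counts[m] (#orthogroups in exactly m accessions):

    E[core(k)] = Σ_m counts[m] · C(m,k) / C(N,k)
    E[pan(k)]  = Σ_m counts[m] · (1 − C(N−m,k) / C(N,k))

computed in exact rational arithmetic, with brute-force subset enumeration
retained as an oracle. Marginal gain pan(k) − pan(k−1) flags an open vs
closed pangenome.

**Contrasts and enrichment.** Per-gene structural features (gene/CDS
length, CDS count, intron count/length) and TPM are contrasted between
core and auxiliary genes with a Wilcoxon rank-sum test; term enrichment is
the classic one-sided hypergeometric with Benjamini–Hochberg FDR. A greedy
reciprocal-best 1:1 matching intersects two species' core sets and scores
their conservation in outgroup genomes.

See `docs/methods.md` for assumptions, defaults, and limitations.

## Worked example

The one-command demo simulates an 11-accession panel (800 orthogroups, 53%
core), classifies it with the 5 kb filter, models the curve, contrasts
features and runs enrichment:

```bash
vpav run --out demo --seed 0
```

prints (abridged):

```json
{
  "classify": {"core_fraction": 0.53, "n_core_orthogroups": 424,
               "n_orthogroups": 800, "window": 5000.0},
  "model":    {"core_at_N": 424.0, "open_pangenome": true, "pan_at_N": 800.0},
  "enrich":   {"direction": "auxiliary", "top_term": "GO:0006952"},
  "simulate": {"n_genes": 6823, "true_core_fraction": 0.53}
}
```

The classifier recovers the generator's core fraction exactly (424/800 =
0.53): on clean anchors the dual-evidence labels equal the ground truth.
`demo/curve.tsv` holds the exact accumulation curve —

```
k   core_avg  pan_avg  aux_avg  gain
1   620.273   620.273  0        620.273
2   547.145   693.4    146.255  73.1273
...
11  424       800      376      3.81818
```

core content falls and pan content rises with every added genome, and the
last marginal gain (≈ 3.8 orthogroups for the 11th genome) is still
positive, so the run is flagged an *open* pangenome. `demo/enrichment.tsv`
shows the planted auxiliary defense-response term on top:

```
term_id     term_name         fg_with  bg_with  odds_ratio  p            fdr_q
GO:0006952  defense response  74       97       4.27        3.82e-10     7.65e-09
```

while the 19 neutral background terms stay non-significant after FDR.
Individual stages are available as `vpav
simulate|classify|model|features|enrich|bc-core|report`, and everything is
importable from Python (`vaccpav.classify`, `vaccpav.modeling`, ...).

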