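"""Ground-truthed synthetic pangenome generator.

Emulates the statistical structure of a cultivar-panel pangenome: a fixed
fraction of orthogroups present in every accession (core), the rest present
in a subset (auxiliary) drawn from a configurable occupancy spectrum;
auxiliary genes shorter, intron-poorer and lower-expressed than core genes;
whole-genome-alignment anchors covering syntenic ortholog pairs with
configurable dropout and coordinate jitter; and orthogroup-inference errors
that merge singletons into unrelated families at non-syntenic positions —
exactly the false presence calls an alignment-proximity filter must remove.

Everything is deterministic given ``SimulationParams.seed``; each emission
stage draws from its own child generator so stages can be re-run
independently without perturbing one another.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import NamedTuple

import numpy as np
import pandas as pd

from .io import (
    AnchorSet,
    ExpressionTable,
    GeneModel,
    GenomeAnnotation,
    OrthogroupTable,
    TermMap,
    qualify,
    write_anchors,
    write_gff3,
    write_table,
)

__all__ = [
    "FeatureClassParams",
    "ExprParams",
    "TermSpec",
    "SimulationParams",
    "SyntheticTruth",
    "generate_truth",
    "emit_annotations",
    "emit_orthogroups",
    "OrthogroupEmission",
    "emit_anchors",
    "emit_expression",
    "emit_terms",
    "write_outputs",
]

# minimum distance between a mis-merged singleton and its adoptive family's
# locus; guarantees the injected call is non-syntenic
MIN_MISMERGE_DISTANCE = 50_000


@dataclass(frozen=True)
class FeatureClassParams:
    """Structural gene-feature distributions for one class (core or auxiliary).

    Gene length is log-normal with the given arithmetic mean (bp); CDS count
    is 1 + Poisson(mean_cds_count - 1); roughly ``coding_fraction`` of the
    gene span is coding, split evenly-ish across CDS segments.
    """

    mean_gene_length: float
    gene_length_sigma: float = 0.5  # log-space sd
    mean_cds_count: float = 4.0
    coding_fraction: float = 0.5
    min_gene_length: int = 300


@dataclass(frozen=True)
class ExprParams:
    """Log-normal TPM parameters per class (natural-log scale)."""

    core_log_mean: float = 2.0
    aux_log_mean: float = 1.0
    log_sd: float = 1.0


class TermSpec(NamedTuple):
    term_id: str
    name: str
    p_core: float
    p_aux: float


def default_terms() -> list[TermSpec]:
    """One auxiliary-enriched defense term against a neutral background."""
    terms = [TermSpec("GO:0006952", "defense response", 0.05, 0.20)]
    for i in range(1, 20):
        terms.append(TermSpec(f"GO:{7000000 + i:07d}", f"background process {i}", 0.05, 0.05))
    return terms


@dataclass(frozen=True)
class SimulationParams:
    """Knobs of the synthetic pangenome; defaults mirror an 11-accession
    cranberry-like panel with ~53% core orthogroups."""

    n_accessions: int = 11
    n_orthogroups: int = 20_000
    core_fraction: float = 0.53
    occupancy_model: tuple = ("uniform",)  # or ("beta", alpha, beta)
    genes_per_group: int = 1
    chrom_count: int = 12
    chrom_length: int = 60_000_000
    anchor_dropout: float = 0.0
    anchor_jitter_sd: float = 0.0
    position_jitter_sd: float = 0.0
    og_error_rate: float = 0.0
    core_features: FeatureClassParams = field(
        default_factory=lambda: FeatureClassParams(mean_gene_length=3000.0, mean_cds_count=5.0)
    )
    aux_features: FeatureClassParams = field(
        default_factory=lambda: FeatureClassParams(mean_gene_length=1200.0, mean_cds_count=2.0)
    )
    expr_params: ExprParams = field(default_factory=ExprParams)
    enrich_params: tuple = field(default_factory=lambda: tuple(default_terms()))
    max_gene_length: int = 30_000
    slot_gap: int = 2_000
    anchor_pad: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_accessions < 2:
            raise ValueError("need at least 2 accessions")
        for name in ("core_fraction", "anchor_dropout", "og_error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for t in self.enrich_params:
            if not (0.0 <= t.p_core <= 1.0 and 0.0 <= t.p_aux <= 1.0):
                raise ValueError(f"term {t.term_id}: probabilities must be in [0, 1]")

    @property
    def accessions(self) -> list[str]:
        return [f"acc{i:02d}" for i in range(1, self.n_accessions + 1)]

    def with_(self, **kw) -> "SimulationParams":
        return replace(self, **kw)


@dataclass
class SyntheticTruth:
    """Ground truth: per-orthogroup occupancy/placement/features, per-gene
    copies with expression, and per-orthogroup term assignments."""

    params: SimulationParams
    groups: pd.DataFrame  # index og_id: occupancy, label, chrom, slot_start, ...
    genes: pd.DataFrame   # one row per gene copy
    og_terms: dict[str, set[str]]
    term_names: dict[str, str]

    @property
    def n_core(self) -> int:
        return int((self.groups["label"] == "core").sum())

    def true_labels(self) -> pd.Series:
        """Per-gene-uid core/auxiliary labels."""
        return pd.Series(self.genes["label"].values, index=self.genes["uid"].values)


def _rng(params: SimulationParams, stage: int) -> np.random.Generator:
    return np.random.default_rng([params.seed, stage])


def _draw_occupancy(params: SimulationParams, n: int, rng: np.random.Generator) -> np.ndarray:
    N = params.n_accessions
    model = params.occupancy_model
    if model[0] == "uniform":
        return rng.integers(1, N, size=n)  # 1..N-1 inclusive
    if model[0] == "beta":
        _, a, b = model
        x = rng.beta(a, b, size=n)
        return np.clip(1 + np.floor(x * (N - 1)).astype(np.int64), 1, N - 1)
    raise ValueError(f"unknown occupancy model {model!r}")


def _sample_structure(
    fp: FeatureClassParams, n: int, max_len: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Draw (gene_length, cds_count) for n ancestral genes."""
    mu = np.log(fp.mean_gene_length) - fp.gene_length_sigma**2 / 2.0
    lengths = rng.lognormal(mu, fp.gene_length_sigma, size=n)
    lengths = np.clip(np.round(lengths), fp.min_gene_length, max_len).astype(np.int64)
    counts = 1 + rng.poisson(max(fp.mean_cds_count - 1.0, 0.0), size=n)
    return lengths, counts


def _cds_layout(length: int, cds_count: int, coding_fraction: float) -> tuple[tuple[int, int], ...]:
    """Deterministic CDS layout: c exons and c-1 introns alternating,
    exon/intron lengths as even as integer arithmetic allows."""
    c = int(min(cds_count, max(1, length // 2)))  # each exon+intron needs ≥1 bp
    coding = max(c, int(round(length * coding_fraction)))
    coding = min(coding, length - (c - 1))  # leave ≥1 bp per intron
    exon_base, exon_extra = divmod(coding, c)
    segs = []
    pos = 1
    if c == 1:
        return ((1, length),)
    intron_total = length - coding
    intron_base, intron_extra = divmod(intron_total, c - 1)
    for i in range(c):
        elen = exon_base + (1 if i < exon_extra else 0)
        segs.append((pos, pos + elen - 1))
        pos += elen
        if i < c - 1:
            ilen = intron_base + (1 if i < intron_extra else 0)
            pos += ilen
    # force last exon to end at gene end (absorbs rounding)
    last_s, _ = segs[-1]
    segs[-1] = (last_s, length)
    return tuple(segs)


def generate_truth(params: SimulationParams) -> SyntheticTruth:
    """Draw the full ground truth for one synthetic pangenome."""
    N, G = params.n_accessions, params.n_orthogroups
    accs = np.asarray(params.accessions)
    rng = _rng(params, 0)

    n_core = int(np.floor(params.core_fraction * G))
    occupancy = np.empty(G, dtype=np.int64)
    occupancy[:n_core] = N
    occupancy[n_core:] = _draw_occupancy(params, G - n_core, rng)
    label = np.where(occupancy == N, "core", "auxiliary")

    # member accessions: first m of a per-group random permutation
    perm = np.argsort(rng.random((G, N)), axis=1)

    # ancestral loci: one slot per orthogroup on a shared coordinate frame
    jitter_margin = int(np.ceil(4 * params.position_jitter_sd))
    slot = (
        params.max_gene_length * params.genes_per_group
        + params.slot_gap
        + 2 * jitter_margin
    )
    slots_per_chrom = params.chrom_length // slot
    capacity = params.chrom_count * slots_per_chrom
    if G > capacity:
        raise ValueError(
            f"{G} orthogroups exceed genome capacity {capacity}; "
            "increase chrom_length or chrom_count"
        )
    slot_idx = rng.permutation(capacity)[:G]
    chrom = (slot_idx // slots_per_chrom).astype(np.int64)
    slot_start = (slot_idx % slots_per_chrom) * slot + 1 + jitter_margin

    # ancestral structural features, shared by every copy of the group
    lengths = np.empty(G, dtype=np.int64)
    cds_counts = np.empty(G, dtype=np.int64)
    for cls, fp in (("core", params.core_features), ("auxiliary", params.aux_features)):
        mask = label == cls
        lengths[mask], cds_counts[mask] = _sample_structure(
            fp, int(mask.sum()), params.max_gene_length, rng
        )
    strand = np.where(rng.random(G) < 0.5, "+", "-")

    og_ids = np.array([f"OG{i:07d}" for i in range(G)])
    groups = pd.DataFrame(
        {
            "occupancy": occupancy,
            "label": label,
            "chrom": np.array([f"chr{c + 1:02d}" for c in chrom]),
            "slot_start": slot_start,
            "gene_length": lengths,
            "cds_count": cds_counts,
            "strand": strand,
        },
        index=pd.Index(og_ids, name="orthogroup"),
    )

    # expand to gene copies (genes_per_group copies per present accession)
    reps = occupancy * params.genes_per_group
    g_idx = np.repeat(np.arange(G), reps)
    within = np.concatenate([np.arange(r) for r in reps]) if G else np.array([], int)
    acc_rank = within // params.genes_per_group
    copy_rank = within % params.genes_per_group
    acc_of_gene = accs[perm[g_idx, acc_rank]]

    if params.position_jitter_sd > 0:
        jit = np.clip(
            np.round(rng.normal(0.0, params.position_jitter_sd, size=len(g_idx))),
            -jitter_margin,
            jitter_margin,
        ).astype(np.int64)
    else:
        jit = np.zeros(len(g_idx), dtype=np.int64)

    start = slot_start[g_idx] + copy_rank * params.max_gene_length + jit
    end = start + lengths[g_idx] - 1
    gene_id = np.array(
        [
            f"g{gi:06d}" if params.genes_per_group == 1 else f"g{gi:06d}.{ci}"
            for gi, ci in zip(g_idx, copy_rank)
        ]
    )
    uid = np.array([qualify(a, g) for a, g in zip(acc_of_gene, gene_id)])

    # expression: log-normal with class-specific mean, independent per copy
    ep = params.expr_params
    log_mu = np.where(label[g_idx] == "core", ep.core_log_mean, ep.aux_log_mean)
    tpm = rng.lognormal(log_mu, ep.log_sd)

    genes = pd.DataFrame(
        {
            "orthogroup": og_ids[g_idx],
            "accession": acc_of_gene,
            "gene_id": gene_id,
            "uid": uid,
            "label": label[g_idx],
            "seq_id": groups["chrom"].values[g_idx],
            "start": start,
            "end": end,
            "strand": strand[g_idx],
            "gene_length": lengths[g_idx],
            "cds_count": cds_counts[g_idx],
            "tpm": tpm,
        }
    )

    # per-orthogroup functional terms with class-specific probabilities
    og_terms: dict[str, set[str]] = {og: set() for og in og_ids}
    term_names: dict[str, str] = {}
    is_core = label == "core"
    for t in params.enrich_params:
        term_names[t.term_id] = t.name
        p = np.where(is_core, t.p_core, t.p_aux)
        hit = rng.random(G) < p
        for og in og_ids[hit]:
            og_terms[og].add(t.term_id)

    return SyntheticTruth(
        params=params, groups=groups, genes=genes, og_terms=og_terms, term_names=term_names
    )


def emit_annotations(truth: SyntheticTruth) -> dict[str, GenomeAnnotation]:
    """One GenomeAnnotation per accession, consistent with the truth table."""
    params = truth.params
    out: dict[str, GenomeAnnotation] = {}
    cf = params.core_features.coding_fraction
    af = params.aux_features.coding_fraction
    layout_cache: dict[tuple[int, int, float], tuple[tuple[int, int], ...]] = {}
    for acc, sub in truth.genes.groupby("accession", sort=True):
        models = []
        for row in sub.itertuples(index=False):
            frac = cf if row.label == "core" else af
            key = (int(row.gene_length), int(row.cds_count), frac)
            rel = layout_cache.get(key)
            if rel is None:
                rel = _cds_layout(int(row.gene_length), int(row.cds_count), frac)
                layout_cache[key] = rel
            off = int(row.start) - 1
            models.append(
                GeneModel(
                    gene_id=row.gene_id,
                    seq_id=row.seq_id,
                    start=int(row.start),
                    end=int(row.end),
                    strand=row.strand,
                    cds_segments=tuple((s + off, e + off) for s, e in rel),
                )
            )
        out[acc] = GenomeAnnotation(accession_id=acc, genes=models)
    missing = set(params.accessions) - set(out)
    for acc in sorted(missing):  # accession with zero genes still gets a file
        out[acc] = GenomeAnnotation(accession_id=acc, genes=[])
    return out


class OrthogroupEmission(NamedTuple):
    table: OrthogroupTable
    injected: pd.DataFrame  # uid, source_og, target_og of each mis-merge


def emit_orthogroups(
    truth: SyntheticTruth, og_error_rate: float | None = None
) -> OrthogroupEmission:
    """Orthogroup table as an orthology-inference tool would report it.

    With error rate ε > 0, a Bernoulli(ε) fraction of auxiliary singletons is
    mis-merged into a random multi-accession family whose ancestral locus lies
    ≥ 50 kbp away (or on another chromosome) — a false presence call with no
    syntenic support.
    """
    params = truth.params
    eps = params.og_error_rate if og_error_rate is None else og_error_rate
    rng = _rng(params, 1)

    groups: dict[str, dict[str, list[str]]] = {}
    for row in truth.genes.itertuples(index=False):
        groups.setdefault(row.orthogroup, {}).setdefault(row.accession, []).append(
            row.gene_id
        )

    injected_rows = []
    if eps > 0:
        occ = truth.groups["occupancy"]
        sizes = truth.genes.groupby("orthogroup").size()
        singletons = [og for og in truth.groups.index if sizes.get(og, 0) == 1 and occ[og] == 1]
        families = [og for og in truth.groups.index if occ[og] >= 2]
        if families:
            fam_chrom = truth.groups.loc[families, "chrom"].values
            fam_pos = truth.groups.loc[families, "slot_start"].values
            hit = rng.random(len(singletons)) < eps
            for og, h in zip(singletons, hit):
                if not h:
                    continue
                s_chrom = truth.groups.at[og, "chrom"]
                s_pos = truth.groups.at[og, "slot_start"]
                for _ in range(100):
                    j = int(rng.integers(len(families)))
                    if fam_chrom[j] != s_chrom or abs(int(fam_pos[j]) - int(s_pos)) >= MIN_MISMERGE_DISTANCE:
                        break
                else:  # pragma: no cover - genome would have to be tiny
                    continue
                target = families[j]
                (acc, gids), = groups.pop(og).items()
                groups[target].setdefault(acc, []).extend(gids)
                injected_rows.append((qualify(acc, gids[0]), og, target))

    table = OrthogroupTable(accessions=params.accessions, groups=groups)
    injected = pd.DataFrame(injected_rows, columns=["uid", "source_og", "target_og"])
    return OrthogroupEmission(table=table, injected=injected)


def emit_anchors(
    truth: SyntheticTruth,
    dropout: float | None = None,
    jitter_sd: float | None = None,
) -> AnchorSet:
    """Alignment anchors: for every accession pair and every orthogroup
    present in both at its ancestral locus, one anchor spanning both gene
    copies (± jitter) survives with probability 1 - dropout."""
    params = truth.params
    dropout = params.anchor_dropout if dropout is None else dropout
    jitter_sd = params.anchor_jitter_sd if jitter_sd is None else jitter_sd
    rng = _rng(params, 2)

    cols = ["orthogroup", "accession", "seq_id", "start", "end"]
    g = truth.genes[cols]
    pairs = g.merge(g, on="orthogroup", suffixes=("_a", "_b"))
    pairs = pairs[pairs["accession_a"] < pairs["accession_b"]]
    if dropout > 0:
        pairs = pairs[rng.random(len(pairs)) >= dropout]
    n = len(pairs)
    pad = params.anchor_pad
    if jitter_sd > 0:
        jit = np.round(rng.normal(0.0, jitter_sd, size=(n, 4))).astype(np.int64)
    else:
        jit = np.zeros((n, 4), dtype=np.int64)
    sa = np.maximum(1, pairs["start_a"].to_numpy() - pad + jit[:, 0])
    ea = np.maximum(sa, pairs["end_a"].to_numpy() + pad + jit[:, 1])
    sb = np.maximum(1, pairs["start_b"].to_numpy() - pad + jit[:, 2])
    eb = np.maximum(sb, pairs["end_b"].to_numpy() + pad + jit[:, 3])
    records = pd.DataFrame(
        {
            "acc_a": pairs["accession_a"].to_numpy(),
            "seq_a": pairs["seq_id_a"].to_numpy(),
            "start_a": sa,
            "end_a": ea,
            "acc_b": pairs["accession_b"].to_numpy(),
            "seq_b": pairs["seq_id_b"].to_numpy(),
            "start_b": sb,
            "end_b": eb,
        }
    )
    return AnchorSet.from_records(records, params.accessions)


def emit_expression(truth: SyntheticTruth) -> ExpressionTable:
    return ExpressionTable(
        tpm=pd.Series(truth.genes["tpm"].values, index=truth.genes["uid"].values, name="tpm")
    )


def emit_terms(truth: SyntheticTruth) -> TermMap:
    """Per-gene term map; all copies of an orthogroup share its terms."""
    gene_terms: dict[str, set[str]] = {}
    for uid, og in zip(truth.genes["uid"], truth.genes["orthogroup"]):
        ts = truth.og_terms.get(og, set())
        if ts:
            gene_terms[uid] = set(ts)
    return TermMap(gene_terms=gene_terms, term_names=dict(truth.term_names))


def write_outputs(truth: SyntheticTruth, outdir: str | os.PathLike) -> dict[str, object]:
    """Emit every downstream input file into ``outdir``; returns the paths."""
    outdir = os.fspath(outdir)
    os.makedirs(outdir, exist_ok=True)
    paths: dict[str, object] = {}

    annotations = emit_annotations(truth)
    gff_paths = {}
    for acc, ann in annotations.items():
        p = os.path.join(outdir, f"{acc}.gff3")
        write_gff3(ann, p)
        gff_paths[acc] = p
    paths["gff3"] = gff_paths

    emission = emit_orthogroups(truth)
    table = emission.table
    accs = truth.params.accessions
    multi_rows, single_rows = [], []
    for og in sorted(table.groups):
        members = table.groups[og]
        cells = [", ".join(members.get(a, [])) for a in accs]
        row = [og] + cells
        (single_rows if table.singleton[og] else multi_rows).append(row)
    header = ["Orthogroup"] + accs
    og_path = os.path.join(outdir, "Orthogroups.tsv")
    un_path = os.path.join(outdir, "Orthogroups_UnassignedGenes.tsv")
    write_table(pd.DataFrame(multi_rows, columns=header), og_path)
    write_table(pd.DataFrame(single_rows, columns=header), un_path)
    paths["orthogroups"], paths["unassigned"] = og_path, un_path
    if len(emission.injected):
        inj_path = os.path.join(outdir, "injected_mismerges.tsv")
        write_table(emission.injected, inj_path)
        paths["injected"] = inj_path

    anchors = emit_anchors(truth)
    paths["anchors"] = os.path.join(outdir, "anchors.tsv")
    write_anchors(anchors, paths["anchors"])

    expr = truth.genes[["accession", "gene_id", "tpm"]]
    paths["expression"] = os.path.join(outdir, "expression.tsv")
    write_table(expr, paths["expression"])

    term_rows = [
        (uid, t, truth.term_names.get(t, ""))
        for uid, og in zip(truth.genes["uid"], truth.genes["orthogroup"])
        for t in sorted(truth.og_terms.get(og, ()))
    ]
    paths["terms"] = os.path.join(outdir, "terms.tsv")
    write_table(
        pd.DataFrame(term_rows, columns=["gene_id", "term_id", "term_name"]),
        paths["terms"],
    )

    labels = truth.genes[["uid", "label"]].rename(columns={"uid": "id"})
    labels.insert(0, "unit", "gene")
    paths["true_labels"] = os.path.join(outdir, "true_labels.tsv")
    write_table(labels, paths["true_labels"])
    return paths
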