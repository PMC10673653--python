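"""Dual-evidence core/auxiliary gene classification.

Orthology clustering alone will call a gene "present" in an accession even
when the matching member is a paralog elsewhere in the genome. The filter
here demands positional corroboration: an ortholog call between two genes is
retained only if some whole-genome-alignment anchor lies within ``W`` bp of
*both* genes (default W = 5000, boundary inclusive). An accession then counts
as supported-present in an orthogroup if at least one of its member genes has
a retained call with a member of any other accession; an orthogroup is core
when all N accessions are supported, auxiliary otherwise.

A second, orthology-free mode projects every reference gene onto each
accession through the anchors and calls it present when enough of its span is
covered (positionally conserved presence).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import AnchorSet, GeneModel, GenomeAnnotation, OrthogroupTable, qualify
from .util import percent

__all__ = [
    "DEFAULT_WINDOW",
    "FilteredCalls",
    "PavLabels",
    "PresenceMatrix",
    "genes_frame",
    "anchor_distance",
    "filter_ortholog_calls",
    "classify",
    "project_to_reference",
    "summarize",
]

DEFAULT_WINDOW = 5_000


def genes_frame(
    annotations: Mapping[str, GenomeAnnotation] | pd.DataFrame,
) -> pd.DataFrame:
    """Normalize annotations to a frame with columns
    uid, accession, gene_id, seq_id, start, end."""
    if isinstance(annotations, pd.DataFrame):
        required = {"uid", "accession", "gene_id", "seq_id", "start", "end"}
        missing = required - set(annotations.columns)
        if missing:
            raise ValueError(f"genes frame missing columns {sorted(missing)}")
        return annotations
    return pd.concat(
        [ann.to_frame() for ann in annotations.values()], ignore_index=True
    )


def _interval_gap(gs: int, ge: int, s: int, e: int) -> int:
    """bp separation of [gs, ge] and [s, e]; 0 when they overlap."""
    return max(0, gs - e, s - ge)


def anchor_distance(
    gene_a: GeneModel,
    acc_a: str,
    gene_b: GeneModel,
    acc_b: str,
    anchors: AnchorSet,
) -> float:
    """min over anchors of max(per-side gene↔anchor gaps); +inf when no
    anchor joins the two genes' chromosomes."""
    for acc in (acc_a, acc_b):
        if acc not in anchors.accessions:
            raise ValueError(f"accession {acc!r} not declared in the anchor set")
    recs = anchors.between(acc_a, acc_b)
    recs = recs[(recs["seq_a"] == gene_a.seq_id) & (recs["seq_b"] == gene_b.seq_id)]
    if not len(recs):
        return float("inf")
    da = np.maximum(
        0,
        np.maximum(
            gene_a.start - recs["end_a"].to_numpy(),
            recs["start_a"].to_numpy() - gene_a.end,
        ),
    )
    db = np.maximum(
        0,
        np.maximum(
            gene_b.start - recs["end_b"].to_numpy(),
            recs["start_b"].to_numpy() - gene_b.end,
        ),
    )
    return float(np.maximum(da, db).min())


@dataclass
class FilteredCalls:
    """Outcome of the alignment-proximity filter.

    ``calls`` holds one row per cross-accession ortholog gene pair:
    orthogroup, uid_a, uid_b, acc_a, acc_b, min_anchor_distance, retained.
    Distances are exact for retained pairs; unretained pairs are recorded as
    +inf (no anchor within the window). ``support`` holds one row per
    (orthogroup, accession) with a boolean ``supported``.
    """

    calls: pd.DataFrame
    support: pd.DataFrame
    window: float

    @property
    def n_retained(self) -> int:
        return int(self.calls["retained"].sum())


def _side_candidates(
    anchors_sub: pd.DataFrame,
    side: str,
    genes_by_loc: dict,
    W: float,
) -> pd.DataFrame:
    """(anchor_row, gene index, gap) for genes within W of the given side."""
    acc_col, seq_col = f"acc_{side}", f"seq_{side}"
    s_col, e_col = f"start_{side}", f"end_{side}"
    frames = []
    for (acc, seq), sub in anchors_sub.groupby([acc_col, seq_col], sort=False):
        loc = genes_by_loc.get((acc, seq))
        if loc is None:
            continue
        starts, ends, cummax_end, uids, idx0 = loc
        sa = sub[s_col].to_numpy()
        ea = sub[e_col].to_numpy()
        hi = np.searchsorted(starts, ea + W, side="right")
        lo = np.searchsorted(cummax_end, sa - W, side="left")
        counts = hi - lo
        keep = counts > 0
        if not keep.any():
            continue
        sa, ea, lo, counts = sa[keep], ea[keep], lo[keep], counts[keep]
        rows = sub.index.to_numpy()[keep]
        gene_idx = (
            np.repeat(lo, counts)
            + _ragged_arange(counts)
        )
        anchor_row = np.repeat(rows, counts)
        g_start = starts[gene_idx]
        g_end = ends[gene_idx]
        a_start = np.repeat(sa, counts)
        a_end = np.repeat(ea, counts)
        gap = np.maximum(0, np.maximum(g_start - a_end, a_start - g_end))
        ok = (gap <= W) & (g_end >= a_start - W)
        frames.append(
            pd.DataFrame(
                {
                    "anchor_row": anchor_row[ok],
                    "gene": uids[gene_idx[ok]],
                    "gap": gap[ok],
                }
            )
        )
    if not frames:
        return pd.DataFrame(columns=["anchor_row", "gene", "gap"])
    return pd.concat(frames, ignore_index=True)


def _ragged_arange(counts: np.ndarray) -> np.ndarray:
    """[0..c0-1, 0..c1-1, ...] for the run lengths in counts."""
    total = int(counts.sum())
    out = np.arange(total)
    offsets = np.repeat(np.cumsum(counts) - counts, counts)
    return out - offsets


def filter_ortholog_calls(
    table: OrthogroupTable,
    annotations: Mapping[str, GenomeAnnotation] | pd.DataFrame,
    anchors: AnchorSet | None,
    W: float = DEFAULT_WINDOW,
) -> FilteredCalls:
    """Apply the alignment-proximity filter to every cross-accession ortholog
    pair. ``W`` may be ``inf`` (all calls retained — pure orthogroup
    classification) or negative (no call retained)."""
    genes = genes_frame(annotations)
    long = table.to_long_frame()
    unresolved = set(long["uid"]) - set(genes["uid"])
    if unresolved:
        raise ValueError(
            f"orthogroup gene(s) absent from annotations, e.g. {sorted(unresolved)[0]!r}"
        )
    merged = long.merge(
        genes[["uid", "seq_id", "start", "end"]], on="uid", how="left"
    )

    cols = ["orthogroup", "accession", "uid", "seq_id", "start", "end"]
    m = merged[cols]
    pairs = m.merge(m, on="orthogroup", suffixes=("_a", "_b"))
    pairs = pairs[pairs["accession_a"] < pairs["accession_b"]].reset_index(drop=True)
    calls = pairs[["orthogroup", "uid_a", "uid_b", "accession_a", "accession_b"]].rename(
        columns={"accession_a": "acc_a", "accession_b": "acc_b"}
    )

    if np.isinf(W) and W > 0:
        calls["min_anchor_distance"] = np.inf
        calls["retained"] = True
    elif W < 0 or anchors is None or len(anchors) == 0 or len(pairs) == 0:
        calls["min_anchor_distance"] = np.inf
        calls["retained"] = False
    else:
        # index genes by (accession, seq) with start-sorted coordinate arrays
        genes_by_loc: dict = {}
        for (acc, seq), sub in genes.groupby(["accession", "seq_id"], sort=False):
            sub = sub.sort_values("start", kind="mergesort")
            starts = sub["start"].to_numpy(np.int64)
            ends = sub["end"].to_numpy(np.int64)
            genes_by_loc[(acc, seq)] = (
                starts,
                ends,
                np.maximum.accumulate(ends),
                sub["uid"].to_numpy(),
                sub.index.to_numpy(),
            )
        rec = anchors.records
        directed = rec[rec["acc_a"] < rec["acc_b"]].reset_index(drop=True)
        cand_a = _side_candidates(directed, "a", genes_by_loc, W)
        cand_b = _side_candidates(directed, "b", genes_by_loc, W)
        joined = cand_a.merge(cand_b, on="anchor_row", suffixes=("_a", "_b"))
        if len(joined):
            joined["dist"] = np.maximum(joined["gap_a"], joined["gap_b"])
            best = (
                joined.groupby(["gene_a", "gene_b"], sort=False)["dist"]
                .min()
                .reset_index()
                .rename(columns={"gene_a": "uid_a", "gene_b": "uid_b"})
            )
        else:
            best = pd.DataFrame(columns=["uid_a", "uid_b", "dist"])
        calls = calls.merge(best, on=["uid_a", "uid_b"], how="left")
        calls["min_anchor_distance"] = calls.pop("dist").astype(float).fillna(np.inf)
        calls["retained"] = calls["min_anchor_distance"] <= W

    ret = calls[calls["retained"]]
    sup_pairs = pd.concat(
        [
            ret[["orthogroup", "acc_a"]].rename(columns={"acc_a": "accession"}),
            ret[["orthogroup", "acc_b"]].rename(columns={"acc_b": "accession"}),
        ],
        ignore_index=True,
    ).drop_duplicates()
    sup_pairs["supported"] = True
    raw = long[["orthogroup", "accession"]].drop_duplicates()
    support = raw.merge(sup_pairs, on=["orthogroup", "accession"], how="left")
    support["supported"] = support["supported"].notna() & support["supported"].eq(True)
    return FilteredCalls(calls=calls, support=support, window=W)


@dataclass
class PavLabels:
    """Core/auxiliary designation per orthogroup and per gene.

    Genes whose every cross-accession ortholog call the proximity filter
    rejected are demoted out of their orthogroup into implicit singleton
    groups (always auxiliary); ``demoted`` lists their uids and
    ``occupancy`` includes one occupancy-1 entry per demoted gene, so the
    post-filter occupancy structure remains a partition of all genes.
    """

    og_labels: pd.Series    # index: orthogroup, values {"core", "auxiliary"}
    gene_labels: pd.Series  # index: gene uid
    occupancy: pd.Series    # filtered occupancy, incl. demoted singletons
    demoted: pd.Index       # gene uids split off as singletons by the filter
    n_accessions: int
    window: float

    @property
    def n_core_groups(self) -> int:
        return int((self.og_labels == "core").sum())

    @property
    def core_fraction(self) -> float:
        return self.n_core_groups / len(self.og_labels)

    def to_frame(self, unit: str = "gene") -> pd.DataFrame:
        if unit == "gene":
            s = self.gene_labels
        elif unit == "orthogroup":
            s = self.og_labels
        else:
            raise ValueError(f"unknown unit {unit!r}")
        return pd.DataFrame({"unit": unit, "id": s.index, "label": s.values})


def classify(
    table: OrthogroupTable,
    filtered: FilteredCalls,
    n_accessions: int | None = None,
) -> PavLabels:
    """Core iff supported-present in all N accessions.

    Occupancy-1 groups (singletons included) can never be core: a
    single-genome presence claim has no cross-accession evidence to test, so
    such groups keep occupancy 1. In a multi-accession group, a member gene
    with no retained call at all is demoted to an implicit auxiliary
    singleton — that is how a mis-clustered paralog at a non-syntenic locus
    loses its false presence call while a well-anchored sibling still rescues
    its accession's support.
    """
    N = table.n_accessions if n_accessions is None else n_accessions
    og_index = pd.Index(table.groups.keys(), name="orthogroup")
    n_supported = (
        filtered.support[filtered.support["supported"]]
        .groupby("orthogroup")
        .size()
        .reindex(og_index, fill_value=0)
    )
    raw_occ = table.occupancy().reindex(og_index)
    og_labels = pd.Series(
        np.where(n_supported.to_numpy() >= N, "core", "auxiliary"),
        index=og_index,
        name="label",
    )

    long = table.to_long_frame()
    ret = filtered.calls[filtered.calls["retained"]]
    supported_uids = set(ret["uid_a"]) | set(ret["uid_b"])
    testable = long["orthogroup"].map(raw_occ).to_numpy() >= 2
    demoted_mask = testable & ~long["uid"].isin(supported_uids).to_numpy()
    demoted = pd.Index(long.loc[demoted_mask, "uid"].to_numpy(), name="uid")

    gene_lab = og_labels.reindex(long["orthogroup"]).to_numpy(copy=True)
    gene_lab[demoted_mask] = "auxiliary"
    gene_labels = pd.Series(gene_lab, index=long["uid"].to_numpy(), name="label")

    group_occ = pd.Series(
        np.where(raw_occ.to_numpy() == 1, 1, n_supported.to_numpy()),
        index=og_index,
        name="occupancy",
    )
    group_occ = group_occ[group_occ > 0]  # groups emptied by the filter vanish
    occupancy = pd.concat(
        [group_occ, pd.Series(1, index=demoted, name="occupancy")]
    )
    return PavLabels(
        og_labels=og_labels,
        gene_labels=gene_labels,
        occupancy=occupancy,
        demoted=demoted,
        n_accessions=N,
        window=filtered.window,
    )


@dataclass
class PresenceMatrix:
    """Reference-projected presence/absence: reference gene × accession."""

    matrix: pd.DataFrame  # bool, rows = reference uids, cols = accessions
    provenance: str = "synteny"

    def core_genes(self) -> pd.Index:
        return self.matrix.index[self.matrix.all(axis=1)]

    def labels(self) -> pd.Series:
        return pd.Series(
            np.where(self.matrix.all(axis=1), "core", "auxiliary"),
            index=self.matrix.index,
            name="label",
        )

    def occupancy(self) -> pd.Series:
        return self.matrix.sum(axis=1)


def _merge_intervals(starts: np.ndarray, ends: np.ndarray):
    order = np.argsort(starts, kind="mergesort")
    starts, ends = starts[order], ends[order]
    merged_s, merged_e = [], []
    cs, ce = starts[0], ends[0]
    for s, e in zip(starts[1:], ends[1:]):
        if s <= ce + 1:
            ce = max(ce, e)
        else:
            merged_s.append(cs)
            merged_e.append(ce)
            cs, ce = s, e
    merged_s.append(cs)
    merged_e.append(ce)
    return np.asarray(merged_s), np.asarray(merged_e)


def project_to_reference(
    reference: GenomeAnnotation,
    anchors: AnchorSet,
    accessions: Sequence[str],
    coverage_threshold: float = 0.5,
) -> PresenceMatrix:
    """Mark a reference gene present in accession X when ≥ threshold of its
    span is covered by the union of reference↔X anchors."""
    ref_acc = reference.accession_id
    missing = [
        acc
        for acc in accessions
        if acc != ref_acc and not len(anchors.between(ref_acc, acc))
    ]
    if missing:
        raise ValueError(f"no anchors between reference and accession(s): {missing}")

    ref_genes = reference.to_frame()
    cols = {}
    for acc in accessions:
        if acc == ref_acc:
            cols[acc] = np.ones(len(ref_genes), dtype=bool)
            continue
        recs = anchors.between(ref_acc, acc)
        present = np.zeros(len(ref_genes), dtype=bool)
        for seq, gsub in ref_genes.groupby("seq_id", sort=False):
            rsub = recs[recs["seq_a"] == seq]
            if not len(rsub):
                continue
            ms, me = _merge_intervals(
                rsub["start_a"].to_numpy(np.int64), rsub["end_a"].to_numpy(np.int64)
            )
            lens = me - ms + 1
            prefix = np.concatenate([[0], np.cumsum(lens)])
            gs = gsub["start"].to_numpy(np.int64)
            ge = gsub["end"].to_numpy(np.int64)
            i0 = np.searchsorted(me, gs, side="left")
            i1 = np.searchsorted(ms, ge, side="right") - 1
            covered = np.zeros(len(gsub), dtype=np.int64)
            ok = i0 <= i1
            if ok.any():
                a, b = i0[ok], i1[ok]
                cov = prefix[b + 1] - prefix[a]
                cov -= np.maximum(0, gs[ok] - ms[a])
                cov -= np.maximum(0, me[b] - ge[ok])
                covered[ok] = cov
            frac = covered / (ge - gs + 1)
            present[gsub.index.to_numpy()] = frac >= coverage_threshold
        cols[acc] = present
    matrix = pd.DataFrame(cols, index=pd.Index(ref_genes["uid"], name="uid"))
    return PresenceMatrix(matrix=matrix, provenance="synteny")


def summarize(
    labels: PavLabels | PresenceMatrix,
    precision: int = 0,
) -> pd.DataFrame:
    """Per-accession and overall core/auxiliary counts and percentages
    (half-up rounding at the requested precision)."""
    rows = []
    if isinstance(labels, PresenceMatrix):
        lab = labels.labels()
        core_rows = lab == "core"
        for acc in labels.matrix.columns:
            present = labels.matrix[acc]
            total = int(present.sum())
            n_core = int((present & core_rows).sum())
            rows.append(("gene", acc, n_core, total - n_core, total))
        n_core = int(core_rows.sum())
        total = len(lab)
        rows.append(("gene", "reference_overall", n_core, total - n_core, total))
    else:
        gl = labels.gene_labels
        acc_of = pd.Index(gl.index).str.split("|").str[0]
        df = pd.DataFrame({"accession": acc_of, "label": gl.values})
        per_acc = (
            df.groupby("accession")["label"]
            .value_counts()
            .unstack(fill_value=0)
            .reindex(columns=["core", "auxiliary"], fill_value=0)
        )
        for acc, r in per_acc.iterrows():
            rows.append(
                ("gene", acc, int(r["core"]), int(r["auxiliary"]),
                 int(r["core"] + r["auxiliary"]))
            )
        mean_core = float(per_acc["core"].mean())
        mean_total = float((per_acc["core"] + per_acc["auxiliary"]).mean())
        rows.append(
            ("gene_mean_per_accession", "all", mean_core, mean_total - mean_core, mean_total)
        )
        n_core = labels.n_core_groups
        total = len(labels.og_labels)
        rows.append(("orthogroup", "all", n_core, total - n_core, total))
    out = pd.DataFrame(
        rows, columns=["unit", "accession", "n_core", "n_auxiliary", "n_total"]
    )
    out["pct_core"] = [
        percent(c, t, precision) if t else float("nan")
        for c, t in zip(out["n_core"], out["n_total"])
    ]
    out["pct_auxiliary"] = [
        percent(a, t, precision) if t else float("nan")
        for a, t in zip(out["n_auxiliary"], out["n_total"])
    ]
    return out
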