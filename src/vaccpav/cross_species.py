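"""Cross-species core-genome intersection and outgroup conservation.

Two species' positionally conserved core gene sets are intersected through
weighted cross-species gene links (orthology or synteny evidence) using a
greedy reciprocal-best 1:1 matching: links are visited in decreasing score
order (ties broken lexicographically on the gene pair) and accepted when
both endpoints are still unmatched. Unmatched core genes are reported as
species-specific. The matched set can then be scored for presence in an
outgroup genome.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Collection, Mapping, Sequence

import pandas as pd

from .util import round_half_up

__all__ = ["CrossCoreResult", "ConservationReport", "intersect_core", "conservation_in_outgroup"]


@dataclass
class CrossCoreResult:
    """1:1 matched cross-species core pairs plus the unmatched remainders."""

    pairs: pd.DataFrame  # gene_a, gene_b, score
    a_specific: list[str]
    b_specific: list[str]

    @property
    def size(self) -> int:
        return len(self.pairs)

    def summary(self) -> dict:
        return {
            "bc_core": self.size,
            "a_specific": len(self.a_specific),
            "b_specific": len(self.b_specific),
        }


def intersect_core(
    core_a: Collection[str],
    core_b: Collection[str],
    links: pd.DataFrame,
    universe_a: Collection[str] | None = None,
    universe_b: Collection[str] | None = None,
) -> CrossCoreResult:
    """Greedy reciprocal-best 1:1 matching of two core gene sets.

    ``links`` needs columns gene_a, gene_b and optionally score (default 1).
    Links touching genes outside the core sets are ignored; if gene universes
    are supplied, links referencing genes unknown to either species are an
    error. Symmetric: swapping the two species yields the same pair set.
    """
    core_a, core_b = set(core_a), set(core_b)
    df = links.copy()
    if "score" not in df.columns:
        df["score"] = 1.0
    if universe_a is not None:
        unknown = set(df["gene_a"]) - set(universe_a)
        if unknown:
            raise ValueError(f"link references unknown species-A gene(s): {sorted(unknown)[:3]}")
    if universe_b is not None:
        unknown = set(df["gene_b"]) - set(universe_b)
        if unknown:
            raise ValueError(f"link references unknown species-B gene(s): {sorted(unknown)[:3]}")

    df = df[df["gene_a"].isin(core_a) & df["gene_b"].isin(core_b)]
    # deterministic, direction-free order: score desc, then the gene pair
    key = [tuple(sorted((a, b))) for a, b in zip(df["gene_a"], df["gene_b"])]
    df = (
        df.assign(_key=key)
        .sort_values(["score", "_key"], ascending=[False, True], kind="mergesort")
        .drop(columns="_key")
    )
    matched_a: set[str] = set()
    matched_b: set[str] = set()
    keep = []
    for row in df.itertuples():
        if row.gene_a in matched_a or row.gene_b in matched_b:
            continue
        matched_a.add(row.gene_a)
        matched_b.add(row.gene_b)
        keep.append((row.gene_a, row.gene_b, float(row.score)))
    pairs = pd.DataFrame(keep, columns=["gene_a", "gene_b", "score"])
    return CrossCoreResult(
        pairs=pairs,
        a_specific=sorted(core_a - matched_a),
        b_specific=sorted(core_b - matched_b),
    )


@dataclass(frozen=True)
class ConservationReport:
    """Presence of the cross-species core in one outgroup genome."""

    outgroup_id: str
    found: int
    total: int

    @property
    def percent(self) -> float:
        return round_half_up(100.0 * self.found / self.total, 1)

    def as_dict(self) -> dict:
        return {
            "outgroup_id": self.outgroup_id,
            "found": self.found,
            "total": self.total,
            "percent": self.percent,
        }


def conservation_in_outgroup(
    cross_core: CrossCoreResult | int,
    outgroup_presence: Mapping[str, bool] | Sequence[bool],
    outgroup_id: str = "outgroup",
) -> ConservationReport:
    """Count cross-core genes positionally conserved in an outgroup.

    ``outgroup_presence`` is either a mapping from species-A gene to a
    presence boolean (must cover every matched gene) or a plain boolean
    vector aligned with the matched pairs.
    """
    total = cross_core if isinstance(cross_core, int) else cross_core.size
    if isinstance(outgroup_presence, Mapping):
        if isinstance(cross_core, int):
            raise TypeError("a mapping requires the full CrossCoreResult")
        genes = cross_core.pairs["gene_a"]
        missing = [g for g in genes if g not in outgroup_presence]
        if missing:
            raise ValueError(f"no presence call for gene(s) {missing[:3]}")
        found = int(sum(bool(outgroup_presence[g]) for g in genes))
    else:
        vec = list(outgroup_presence)
        if len(vec) != total:
            raise ValueError(
                f"presence vector length {len(vec)} != cross-core size {total}"
            )
        found = int(sum(bool(v) for v in vec))
    return ConservationReport(outgroup_id=outgroup_id, found=found, total=total)
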