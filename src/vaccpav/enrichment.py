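"""Term over-representation of one gene class against a universe.

Classic one-sided hypergeometric (Fisher upper-tail) enrichment of a
foreground set (e.g. auxiliary genes) against a background universe, with
Benjamini-Hochberg FDR control. No GO-graph decorrelation is attempted: the
test is the "classic" per-term statistic, and ancestor propagation of
annotations is available as an explicit option before testing.
"""

from __future__ import annotations

from typing import Collection, Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import TermMap

__all__ = ["term_enrichment", "bh_fdr", "propagate_terms"]


def bh_fdr(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, order-preserving."""
    p = np.asarray(list(pvals), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def term_enrichment(
    term_map: TermMap | Mapping[str, Collection[str]],
    foreground: Collection[str],
    universe: Collection[str],
    min_count: int = 3,
) -> pd.DataFrame:
    """Per-term over-representation of ``foreground`` within ``universe``.

    For every term annotating ≥ min_count universe genes: upper-tail
    hypergeometric p (P[X ≥ fg_with] drawing fg_total from the universe),
    odds ratio from the 2×2 table with a Haldane 0.5 correction when any
    cell is zero, and BH q-values. Rows sorted by ascending p.
    """
    gene_terms = term_map.gene_terms if isinstance(term_map, TermMap) else term_map
    term_names = term_map.term_names if isinstance(term_map, TermMap) else {}
    fg = set(foreground)
    uni = set(universe)
    if not fg <= uni:
        extra = sorted(fg - uni)[:3]
        raise ValueError(f"foreground not contained in universe, e.g. {extra}")

    bg_total = len(uni)
    fg_total = len(fg)
    term_bg: dict[str, int] = {}
    term_fg: dict[str, int] = {}
    for gene in uni:
        for t in gene_terms.get(gene, ()):
            term_bg[t] = term_bg.get(t, 0) + 1
            if gene in fg:
                term_fg[t] = term_fg.get(t, 0) + 1

    rows = []
    for term, bg_with in sorted(term_bg.items()):
        if bg_with < min_count:
            continue
        fg_with = term_fg.get(term, 0)
        # survival function is P[X > k], so shift by one for P[X >= fg_with]
        p = float(stats.hypergeom.sf(fg_with - 1, bg_total, bg_with, fg_total))
        p = min(p, 1.0)
        a = fg_with
        b = fg_total - fg_with
        c = bg_with - fg_with
        d = (bg_total - fg_total) - c
        if fg_total == bg_total:
            odds = 1.0  # foreground is the whole universe: no contrast
        else:
            if min(a, b, c, d) == 0:
                a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
            odds = (a * d) / (b * c)
        rows.append(
            {
                "term_id": term,
                "term_name": term_names.get(term, ""),
                "fg_with": fg_with,
                "fg_total": fg_total,
                "bg_with": bg_with,
                "bg_total": bg_total,
                "odds_ratio": float(odds),
                "p": p,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "term_id", "term_name", "fg_with", "fg_total",
            "bg_with", "bg_total", "odds_ratio", "p",
        ],
    )
    if len(df):
        df["fdr_q"] = bh_fdr(df["p"].to_numpy())
        df = df.sort_values(["p", "term_id"], kind="mergesort").reset_index(drop=True)
    else:
        df["fdr_q"] = pd.Series(dtype=float)
    return df


def propagate_terms(
    term_map: TermMap, parents: Mapping[str, Collection[str]]
) -> TermMap:
    """Annotate each gene with all ancestors of its terms (GO-DAG true-path
    rule). ``parents`` maps term → direct parents; cycles are rejected."""
    cache: dict[str, set[str]] = {}

    def ancestors(term: str, trail: tuple[str, ...] = ()) -> set[str]:
        if term in cache:
            return cache[term]
        if term in trail:
            raise ValueError(f"cycle in term graph at {term}")
        out: set[str] = set()
        for p in parents.get(term, ()):
            out.add(p)
            out |= ancestors(p, trail + (term,))
        cache[term] = out
        return out

    gene_terms = {
        gene: set().union(terms, *(ancestors(t) for t in terms))
        for gene, terms in term_map.gene_terms.items()
    }
    return TermMap(gene_terms=gene_terms, term_names=dict(term_map.term_names))
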