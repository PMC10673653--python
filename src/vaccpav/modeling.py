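"""Exact core/pan accumulation (rarefaction) curves.

The quantity of interest is the average, over every possible combination of
k accessions out of N, of the number of orthogroups present in all k chosen
accessions (core) or in at least one (pan). Both averages depend on the
presence structure only through the occupancy histogram counts[m]
(#orthogroups present in exactly m accessions) and admit exact hypergeometric
closed forms:

    E[core(k)] = sum_m counts[m] * C(m, k) / C(N, k)
    E[pan(k)]  = sum_m counts[m] * (1 - C(N - m, k) / C(N, k))

with C(a, b) = 0 for a < b. Brute-force subset enumeration is retained
(behind a combinatorial cap) as an independent oracle.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd

__all__ = [
    "OccupancyHistogram",
    "PangenomeCurve",
    "occupancy_histogram",
    "expected_core",
    "expected_pan",
    "expected_aux",
    "enumerate_curve",
    "model_curve",
]


@dataclass(frozen=True)
class OccupancyHistogram:
    """counts[m] = number of orthogroups present in exactly m of N accessions.

    ``weights[m]`` (optional) carries the summed per-group weight instead of
    the raw count — used for gene-level curves where each orthogroup counts
    as its mean number of member genes per present accession. An m=0 bin is
    tolerated (groups stripped of all supported presence by a degenerate
    filter); such groups never contribute to any curve point.
    """

    n_accessions: int
    counts: tuple[float, ...]  # index m = 0..N

    @classmethod
    def from_mapping(cls, n_accessions: int, mapping) -> "OccupancyHistogram":
        counts = [0.0] * (n_accessions + 1)
        for m, c in dict(mapping).items():
            m = int(m)
            if not 0 <= m <= n_accessions:
                raise ValueError(f"occupancy {m} outside 0..{n_accessions}")
            counts[m] += c
        return cls(n_accessions=n_accessions, counts=tuple(counts))

    @property
    def total(self) -> float:
        return sum(self.counts)

    def as_series(self) -> pd.Series:
        return pd.Series(
            self.counts, index=pd.RangeIndex(self.n_accessions + 1, name="occupancy"),
            name="n_orthogroups",
        )


def occupancy_histogram(source, n_accessions: int | None = None) -> OccupancyHistogram:
    """Build the histogram from PavLabels, a PresenceMatrix, a boolean
    presence frame (groups × accessions), or an occupancy Series."""
    from .classify import PavLabels, PresenceMatrix  # local import, no cycle at module load

    if isinstance(source, PavLabels):
        occ = source.occupancy
        N = source.n_accessions
    elif isinstance(source, PresenceMatrix):
        occ = source.occupancy()
        N = source.matrix.shape[1]
    elif isinstance(source, pd.DataFrame):
        occ = source.astype(bool).sum(axis=1)
        N = source.shape[1]
    elif isinstance(source, pd.Series):
        if n_accessions is None:
            raise ValueError("n_accessions required with a raw occupancy series")
        occ, N = source, n_accessions
    else:
        raise TypeError(f"cannot build an occupancy histogram from {type(source)!r}")
    vc = occ.value_counts()
    return OccupancyHistogram.from_mapping(N, vc.to_dict())


def _check_k(h: OccupancyHistogram, k: int) -> None:
    if not 1 <= k <= h.n_accessions:
        raise ValueError(f"k={k} outside 1..{h.n_accessions}")


def expected_core(h: OccupancyHistogram, k: int, exact: bool = False) -> float | Fraction:
    """Average number of orthogroups present in every one of k sampled
    accessions, exactly over all C(N, k) subsets."""
    _check_k(h, k)
    N = h.n_accessions
    denom = comb(N, k)
    total = Fraction(0)
    for m, c in enumerate(h.counts):
        if c and m >= k:
            total += Fraction(comb(m, k)) * Fraction(c) / denom
    return total if exact else float(total)


def expected_pan(h: OccupancyHistogram, k: int, exact: bool = False) -> float | Fraction:
    """Average number of orthogroups present in ≥1 of k sampled accessions."""
    _check_k(h, k)
    N = h.n_accessions
    denom = comb(N, k)
    total = Fraction(0)
    for m, c in enumerate(h.counts):
        if c and m > 0:
            total += Fraction(c) * (1 - Fraction(comb(N - m, k)) / denom)
    return total if exact else float(total)


def expected_aux(h: OccupancyHistogram, k: int, exact: bool = False) -> float | Fraction:
    return expected_pan(h, k, exact=exact) - expected_core(h, k, exact=exact)


ENUMERATION_CAP = 100_000


def enumerate_curve(
    presence: pd.DataFrame, k: int, cap: int = ENUMERATION_CAP
) -> tuple[float, float]:
    """Brute-force (core_avg, pan_avg) over all C(N, k) accession subsets of a
    boolean presence frame (orthogroups × accessions). Oracle for the closed
    form; refuses combinatorial explosions."""
    N = presence.shape[1]
    if not 1 <= k <= N:
        raise ValueError(f"k={k} outside 1..{N}")
    n_subsets = comb(N, k)
    if n_subsets > cap:
        raise ValueError(
            f"C({N},{k}) = {n_subsets} subsets exceeds cap {cap}; use the closed form"
        )
    mat = presence.astype(bool).to_numpy()
    core_sum = 0
    pan_sum = 0
    for cols in combinations(range(N), k):
        sub = mat[:, cols]
        core_sum += int(sub.all(axis=1).sum())
        pan_sum += int(sub.any(axis=1).sum())
    return core_sum / n_subsets, pan_sum / n_subsets


@dataclass
class PangenomeCurve:
    """Closed-form accumulation curve with marginal pan-gain per added genome."""

    points: pd.DataFrame  # k, core_avg, pan_avg, aux_avg, gain
    method: str
    open_pangenome: bool

    def as_frame(self) -> pd.DataFrame:
        return self.points.copy()


def model_curve(
    source,
    n_accessions: int | None = None,
    closedness_threshold: float = 0.0,
) -> PangenomeCurve:
    """Curve points for k = 1..N plus gain(k) = pan(k) - pan(k-1); the
    pangenome is flagged open while the last marginal gain still exceeds the
    closedness threshold (default: any new group at all)."""
    h = (
        source
        if isinstance(source, OccupancyHistogram)
        else occupancy_histogram(source, n_accessions)
    )
    N = h.n_accessions
    ks = list(range(1, N + 1))
    core = [expected_core(h, k) for k in ks]
    pan = [expected_pan(h, k) for k in ks]
    gain = [pan[0]] + [pan[i] - pan[i - 1] for i in range(1, len(ks))]
    points = pd.DataFrame(
        {
            "k": ks,
            "core_avg": core,
            "pan_avg": pan,
            "aux_avg": [p - c for p, c in zip(pan, core)],
            "gain": gain,
        }
    )
    return PangenomeCurve(
        points=points,
        method="closed_form",
        open_pangenome=bool(gain[-1] > closedness_threshold),
    )
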