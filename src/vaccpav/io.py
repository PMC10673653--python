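"""Readers, writers and validated in-memory containers for pangenome inputs.

All coordinates are 1-based inclusive base pairs (GFF3 convention). Gene IDs
are qualified internally as ``"accession|gene_id"`` because different
accessions of a cultivar panel routinely reuse annotation IDs.
"""

from __future__ import annotations

import io as _stdio
import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import gffutils
import numpy as np
import pandas as pd

__all__ = [
    "GeneModel",
    "GenomeAnnotation",
    "OrthogroupTable",
    "AnchorSet",
    "ExpressionTable",
    "TermMap",
    "qualify",
    "read_gff3",
    "write_gff3",
    "read_orthogroups",
    "read_anchors",
    "read_expression",
    "read_terms",
    "write_table",
    "read_table",
]


def qualify(accession_id: str, gene_id: str) -> str:
    """Globally unique gene identifier ``accession|gene_id``."""
    return f"{accession_id}|{gene_id}"


@dataclass(frozen=True)
class GeneModel:
    """A single protein-coding gene collapsed to one representative model.

    ``cds_segments`` are sorted, non-overlapping (start, end) pairs contained
    in ``[start, end]``; multi-isoform genes are collapsed upstream to the
    isoform with the largest total CDS length.
    """

    gene_id: str
    seq_id: str
    start: int
    end: int
    strand: str
    cds_segments: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"gene {self.gene_id}: start {self.start} > end {self.end}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: invalid strand {self.strand!r}")
        if not self.cds_segments:
            raise ValueError(f"gene {self.gene_id}: no CDS segments")
        prev_end = None
        for s, e in self.cds_segments:
            if s > e:
                raise ValueError(f"gene {self.gene_id}: CDS start {s} > end {e}")
            if s < self.start or e > self.end:
                raise ValueError(
                    f"gene {self.gene_id}: CDS ({s},{e}) outside gene span"
                )
            if prev_end is not None and s <= prev_end:
                raise ValueError(
                    f"gene {self.gene_id}: CDS segments overlap or are unsorted"
                )
            prev_end = e


@dataclass
class GenomeAnnotation:
    """All gene models of one accession."""

    accession_id: str
    genes: list[GeneModel]

    def __post_init__(self) -> None:
        ids = [g.gene_id for g in self.genes]
        if len(ids) != len(set(ids)):
            dup = pd.Series(ids).value_counts()
            dup = dup[dup > 1].index[0]
            raise ValueError(
                f"accession {self.accession_id}: duplicate gene ID {dup!r}"
            )

    def __len__(self) -> int:
        return len(self.genes)

    def to_frame(self) -> pd.DataFrame:
        """One row per gene: uid, gene_id, seq_id, start, end, strand."""
        return pd.DataFrame(
            {
                "uid": [qualify(self.accession_id, g.gene_id) for g in self.genes],
                "accession": self.accession_id,
                "gene_id": [g.gene_id for g in self.genes],
                "seq_id": [g.seq_id for g in self.genes],
                "start": np.asarray([g.start for g in self.genes], dtype=np.int64),
                "end": np.asarray([g.end for g in self.genes], dtype=np.int64),
                "strand": [g.strand for g in self.genes],
            }
        )


def _cds_total(segments: Iterable[tuple[int, int]]) -> int:
    return sum(e - s + 1 for s, e in segments)


def read_gff3(path: str | os.PathLike, accession_id: str | None = None) -> GenomeAnnotation:
    """Parse a GFF3 file with gene/mRNA/CDS features into a GenomeAnnotation.

    Multi-isoform genes are collapsed to the isoform with the largest total
    CDS length. Malformed coordinates are rejected with the offending line
    number; genes lacking any CDS are rejected.
    """
    path = os.fspath(path)
    if accession_id is None:
        accession_id = os.path.basename(path).removesuffix(".gff3").removesuffix(".gff")

    # pre-scan for coordinate sanity so errors can name a line number
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 9:
                raise ValueError(f"{path}:{lineno}: expected 9 GFF3 columns")
            try:
                start, end = int(cols[3]), int(cols[4])
            except ValueError as exc:
                raise ValueError(
                    f"{path}:{lineno}: non-integer coordinates {cols[3]!r}/{cols[4]!r}"
                ) from exc
            if end < start:
                raise ValueError(
                    f"{path}:{lineno}: end {end} < start {start}"
                )

    db = gffutils.create_db(
        path,
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    genes: list[GeneModel] = []
    for gene in db.features_of_type("gene"):
        best: tuple[int, list[tuple[int, int]]] | None = None
        mrnas = list(db.children(gene, featuretype="mRNA"))
        if mrnas:
            for mrna in mrnas:
                segs = sorted(
                    (c.start, c.end) for c in db.children(mrna, featuretype="CDS")
                )
                if not segs:
                    continue
                cand = (_cds_total(segs), segs)
                if best is None or cand[0] > best[0]:
                    best = cand
        else:  # tolerate CDS directly under gene
            segs = sorted((c.start, c.end) for c in db.children(gene, featuretype="CDS"))
            if segs:
                best = (_cds_total(segs), segs)
        if best is None:
            raise ValueError(f"{path}: gene {gene.id} has no CDS features")
        genes.append(
            GeneModel(
                gene_id=gene.id,
                seq_id=gene.seqid,
                start=gene.start,
                end=gene.end,
                strand=gene.strand,
                cds_segments=tuple(best[1]),
            )
        )
    return GenomeAnnotation(accession_id=accession_id, genes=genes)


def write_gff3(annotation: GenomeAnnotation, path: str | os.PathLike) -> None:
    """Write gene/mRNA/CDS features; inverse of :func:`read_gff3`."""
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(annotation.genes, key=lambda g: (g.seq_id, g.start, g.gene_id)):
            base = f"{g.seq_id}\tvaccpav\t"
            fh.write(
                base + f"gene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\tID={g.gene_id}\n"
            )
            mrna_id = f"{g.gene_id}.t1"
            fh.write(
                base
                + f"mRNA\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
                + f"ID={mrna_id};Parent={g.gene_id}\n"
            )
            for i, (s, e) in enumerate(g.cds_segments, start=1):
                fh.write(
                    base
                    + f"CDS\t{s}\t{e}\t.\t{g.strand}\t0\t"
                    + f"ID={mrna_id}.cds{i};Parent={mrna_id}\n"
                )


@dataclass
class OrthogroupTable:
    """Orthogroup membership across N accessions, singletons included.

    ``groups`` maps orthogroup ID to ``{accession: [gene_id, ...]}`` with raw
    (unqualified) gene IDs; ``singleton`` flags groups holding exactly one gene.
    Every gene belongs to exactly one orthogroup.
    """

    accessions: list[str]
    groups: dict[str, dict[str, list[str]]]
    singleton: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.accessions) < 2:
            raise ValueError("an orthogroup table needs at least 2 accessions")
        seen: dict[str, str] = {}
        for og, members in self.groups.items():
            n_genes = 0
            for acc, gene_ids in members.items():
                if acc not in self.accessions:
                    raise ValueError(f"orthogroup {og}: unknown accession {acc!r}")
                for gid in gene_ids:
                    uid = qualify(acc, gid)
                    if uid in seen:
                        raise ValueError(
                            f"gene {uid} listed in orthogroups {seen[uid]} and {og}"
                        )
                    seen[uid] = og
                    n_genes += 1
            if n_genes == 0:
                raise ValueError(f"orthogroup {og} is empty")
            self.singleton.setdefault(og, n_genes == 1)

    @property
    def n_accessions(self) -> int:
        return len(self.accessions)

    def __len__(self) -> int:
        return len(self.groups)

    def gene_uids(self) -> set[str]:
        return {
            qualify(acc, gid)
            for members in self.groups.values()
            for acc, gids in members.items()
            for gid in gids
        }

    def occupancy(self) -> pd.Series:
        """Raw occupancy m (accessions with ≥1 member) per orthogroup."""
        return pd.Series(
            {og: sum(1 for gids in m.values() if gids) for og, m in self.groups.items()},
            name="occupancy",
        )

    def to_long_frame(self) -> pd.DataFrame:
        """One row per member gene: orthogroup, accession, gene_id, uid."""
        rows = [
            (og, acc, gid, qualify(acc, gid))
            for og, members in self.groups.items()
            for acc, gids in members.items()
            for gid in gids
        ]
        return pd.DataFrame(rows, columns=["orthogroup", "accession", "gene_id", "uid"])


def _sniff_sep(path: str) -> str:
    with open(path, "rt", encoding="utf-8") as fh:
        first = fh.readline()
    return "\t" if "\t" in first else ","


def read_orthogroups(
    groups_path: str | os.PathLike,
    unassigned_path: str | os.PathLike | None,
    accessions: Sequence[str],
) -> OrthogroupTable:
    """Parse OrthoFinder-style ``Orthogroups`` and ``UnassignedGenes`` tables.

    Both ``.tsv`` (tab) and ``.csv`` (comma) dialects are accepted; gene lists
    within a cell are ``", "``-separated. Every unassigned gene becomes its own
    singleton orthogroup.
    """
    groups_path = os.fspath(groups_path)
    accessions = list(accessions)
    groups: dict[str, dict[str, list[str]]] = {}

    def _parse(path: str, singleton_rows: bool) -> None:
        sep = _sniff_sep(path)
        if sep == ",":
            # comma-dialect columns; ", " inside a cell is the gene-list
            # delimiter, so only split on commas not followed by a space
            df = pd.read_csv(
                path, sep=r",(?! )", engine="python",
                dtype=str, keep_default_na=False,
            )
        else:
            df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
        og_col = df.columns[0]
        acc_cols = [c for c in df.columns[1:]]
        unknown = sorted(set(acc_cols) - set(accessions))
        if unknown:
            raise ValueError(f"{path}: unknown accession column(s) {unknown}")
        for _, row in df.iterrows():
            og_id = row[og_col]
            members = {
                acc: [g for g in row[acc].split(", ") if g] for acc in acc_cols
            }
            members = {acc: gids for acc, gids in members.items() if gids}
            if not members:
                continue
            if singleton_rows:
                genes = [(acc, g) for acc, gids in members.items() for g in gids]
                if len(genes) == 1:
                    groups[og_id] = {genes[0][0]: [genes[0][1]]}
                else:
                    for i, (acc, g) in enumerate(genes):
                        groups[f"{og_id}.s{i}"] = {acc: [g]}
            else:
                if og_id in groups:
                    raise ValueError(f"{path}: duplicate orthogroup ID {og_id}")
                groups[og_id] = members

    _parse(groups_path, singleton_rows=False)
    if unassigned_path is not None:
        _parse(os.fspath(unassigned_path), singleton_rows=True)
    return OrthogroupTable(accessions=accessions, groups=groups)


_ANCHOR_COLS = [
    "acc_a", "seq_a", "start_a", "end_a", "acc_b", "seq_b", "start_b", "end_b",
]


@dataclass
class AnchorSet:
    """Pairwise aligned-interval records between accession genomes.

    Stored direction-free: every record also appears with its two sides
    swapped (symmetric closure), so ``between(A, B)`` always lists intervals
    with A on the left. Coordinates are 1-based inclusive bp.
    """

    records: pd.DataFrame
    accessions: list[str]

    @classmethod
    def from_records(
        cls, records: pd.DataFrame, accessions: Sequence[str]
    ) -> "AnchorSet":
        df = records.loc[:, _ANCHOR_COLS].copy()
        for c in ("start_a", "end_a", "start_b", "end_b"):
            vals = pd.to_numeric(df[c], errors="coerce")
            if vals.isna().any():
                bad = df.loc[vals.isna(), c].iloc[0]
                raise ValueError(f"non-integer anchor coordinate {bad!r} in {c}")
            df[c] = vals.astype(np.int64)
        if ((df["end_a"] < df["start_a"]) | (df["end_b"] < df["start_b"])).any():
            raise ValueError("anchor with end < start")
        accessions = list(accessions)
        unknown = sorted(
            (set(df["acc_a"]) | set(df["acc_b"])) - set(accessions)
        )
        if unknown:
            raise ValueError(f"anchor accession(s) not declared: {unknown}")
        swapped = df.rename(
            columns={
                "acc_a": "acc_b", "seq_a": "seq_b", "start_a": "start_b", "end_a": "end_b",
                "acc_b": "acc_a", "seq_b": "seq_a", "start_b": "start_a", "end_b": "end_a",
            }
        )[_ANCHOR_COLS]
        full = (
            pd.concat([df, swapped], ignore_index=True)
            .drop_duplicates()
            .sort_values(_ANCHOR_COLS, kind="mergesort")
            .reset_index(drop=True)
        )
        return cls(records=full, accessions=accessions)

    def __len__(self) -> int:
        return len(self.records)

    def between(self, acc_a: str, acc_b: str) -> pd.DataFrame:
        """Directed records with ``acc_a`` on the left side."""
        r = self.records
        return r[(r["acc_a"] == acc_a) & (r["acc_b"] == acc_b)]


def read_anchors(path: str | os.PathLike, accessions: Sequence[str]) -> AnchorSet:
    """Read the 8-column anchors TSV (header lines starting with '#' skipped)."""
    df = pd.read_csv(
        os.fspath(path), sep="\t", comment="#", header=None, names=_ANCHOR_COLS,
        dtype={c: str for c in _ANCHOR_COLS},
    )
    return AnchorSet.from_records(df, accessions)


def write_anchors(anchors: AnchorSet, path: str | os.PathLike) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("#" + "\t".join(_ANCHOR_COLS) + "\n")
        anchors.records.to_csv(fh, sep="\t", header=False, index=False)


@dataclass
class ExpressionTable:
    """Per-gene TPM values keyed by qualified gene uid."""

    tpm: pd.Series  # index: uid, values: float

    def __post_init__(self) -> None:
        if (self.tpm < 0).any():
            bad = self.tpm[self.tpm < 0].index[0]
            raise ValueError(f"negative TPM for gene {bad}")
        if self.tpm.index.has_duplicates:
            dup = self.tpm.index[self.tpm.index.duplicated()][0]
            raise ValueError(f"duplicate expression entry for gene {dup}")

    def get(self, uid: str) -> float | None:
        val = self.tpm.get(uid)
        return None if val is None else float(val)


def read_expression(path: str | os.PathLike) -> ExpressionTable:
    """Read TSV with columns accession, gene_id, tpm."""
    df = pd.read_csv(os.fspath(path), sep="\t", dtype={"accession": str, "gene_id": str})
    uid = df["accession"].str.cat(df["gene_id"], sep="|")
    return ExpressionTable(tpm=pd.Series(df["tpm"].astype(float).values, index=uid, name="tpm"))


_GO_PATTERN = r"^GO:\d{7}$"


@dataclass
class TermMap:
    """gene uid → set of functional term IDs, plus term names."""

    gene_terms: dict[str, set[str]]
    term_names: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        import re

        for terms in self.gene_terms.values():
            for t in terms:
                if t.startswith("GO:") and not re.match(_GO_PATTERN, t):
                    raise ValueError(f"malformed GO term ID {t!r}")

    def terms_for(self, uid: str) -> set[str]:
        return self.gene_terms.get(uid, set())

    def genes_with(self, term_id: str) -> set[str]:
        return {g for g, ts in self.gene_terms.items() if term_id in ts}

    def all_terms(self) -> set[str]:
        out: set[str] = set()
        for ts in self.gene_terms.values():
            out |= ts
        return out


def read_terms(path: str | os.PathLike) -> TermMap:
    """Read TSV with columns gene_id (qualified uid), term_id, term_name."""
    df = pd.read_csv(os.fspath(path), sep="\t", dtype=str, keep_default_na=False)
    gene_terms: dict[str, set[str]] = {}
    term_names: dict[str, str] = {}
    for gid, tid, name in zip(df["gene_id"], df["term_id"], df["term_name"]):
        gene_terms.setdefault(gid, set()).add(tid)
        if name:
            term_names[tid] = name
    return TermMap(gene_terms=gene_terms, term_names=term_names)


def write_table(rows: pd.DataFrame, path: str | os.PathLike | _stdio.TextIOBase) -> None:
    """Write a TSV with header; floats rendered at 6 significant digits."""
    if rows.columns.has_duplicates:
        raise ValueError("duplicate column names")
    rows.to_csv(path, sep="\t", index=False, float_format="%.6g", lineterminator="\n")


def read_table(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(os.fspath(path), sep="\t")
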