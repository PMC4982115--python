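"""Core in-memory containers for the olfactory transcriptome pipeline.

Expression is carried as FPKM (fragments per kilobase per million mapped
reads) in genes x samples tables; raw read counts live in a parallel integer
table used only by the count-based overexpression test.  Genomic intervals
are 0-based half-open everywhere inside the package; GTF I/O converts at the
boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

DEFAULT_FPKM_FLOOR = 0.003

OR_STATUSES = ("intact", "pseudogene", "non_OR")


class OlfscreenError(ValueError):
    """Raised on malformed inputs or violated contracts."""


@dataclass
class ExpressionMatrix:
    """Genes x samples FPKM table with tissue-group labels.

    ``floor`` is None until :func:`olfscreen.io.apply_fpkm_floor` has been
    applied; downstream log-scale operations require a floored matrix so that
    log10 is finite.
    """

    values: pd.DataFrame
    sample_groups: dict[str, str]
    floor: float | None = None

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique()
            raise OlfscreenError(f"duplicate gene ids: {list(dups[:5])}")
        missing = [s for s in self.values.columns if s not in self.sample_groups]
        if missing:
            raise OlfscreenError(f"samples without a group label: {missing}")
        if (self.values.values < 0).any():
            raise OlfscreenError("negative FPKM values")

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    def samples_in_group(self, group: str) -> list[str]:
        """Samples whose label equals ``group`` or starts with ``group:``."""
        return [
            s
            for s in self.values.columns
            if self.sample_groups[s] == group
            or self.sample_groups[s].startswith(group + ":")
        ]

    def require_floored(self) -> None:
        if self.floor is None:
            raise OlfscreenError("operation requires a floored expression matrix")

    def log10(self, genes: Sequence[str] | None = None,
              samples: Sequence[str] | None = None) -> pd.DataFrame:
        self.require_floored()
        sub = self.values
        if genes is not None:
            sub = sub.loc[list(genes)]
        if samples is not None:
            sub = sub[list(samples)]
        return np.log10(sub)

    def subset_genes(self, genes: Iterable[str]) -> "ExpressionMatrix":
        return replace(self, values=self.values.loc[list(genes)])


@dataclass
class CountMatrix:
    """Genes x samples uniquely-mapped read counts (non-negative integers)."""

    counts: pd.DataFrame
    sample_groups: dict[str, str]

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            raise OlfscreenError("duplicate gene ids in count matrix")
        vals = self.counts.values
        if not np.issubdtype(vals.dtype, np.integer):
            if not np.allclose(vals, np.round(vals)):
                raise OlfscreenError("counts must be integer-valued")
            self.counts = self.counts.astype(np.int64)
        if (self.counts.values < 0).any():
            raise OlfscreenError("negative counts")
        missing = [s for s in self.counts.columns if s not in self.sample_groups]
        if missing:
            raise OlfscreenError(f"samples without a group label: {missing}")

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    def samples_in_group(self, group: str) -> list[str]:
        return [
            s
            for s in self.counts.columns
            if self.sample_groups[s] == group
            or self.sample_groups[s].startswith(group + ":")
        ]


@dataclass
class GeneCatalog:
    """Per-gene annotation: OR status/class, segregating-pseudogene flag,
    ortholog id, literature-hit count and functionality (CORP-like) score."""

    table: pd.DataFrame  # indexed by gene_id

    REQUIRED = ("symbol", "or_status", "or_class", "segregating_pseudogene",
                "ortholog_id", "literature_hits", "functionality_score")

    def __post_init__(self) -> None:
        if self.table.index.has_duplicates:
            raise OlfscreenError("duplicate gene ids in catalog")
        for col in self.REQUIRED:
            if col not in self.table.columns:
                raise OlfscreenError(f"catalog missing column {col!r}")
        bad = ~self.table["or_status"].isin(OR_STATUSES)
        if bad.any():
            raise OlfscreenError(
                f"invalid or_status for {list(self.table.index[bad][:5])}")
        nonor = self.table["or_status"] == "non_OR"
        has_class = self.table["or_class"].notna() & (self.table["or_class"] != "NA")
        if (nonor & has_class).any():
            raise OlfscreenError("or_class set for non-OR gene")

    @property
    def gene_ids(self) -> pd.Index:
        return self.table.index

    def genes_with_status(self, *statuses: str) -> pd.Index:
        return self.table.index[self.table["or_status"].isin(statuses)]

    @property
    def or_genes(self) -> pd.Index:
        return self.genes_with_status("intact", "pseudogene")

    @property
    def non_or_genes(self) -> pd.Index:
        return self.genes_with_status("non_OR")

    def without_segregating(self) -> "GeneCatalog":
        keep = ~self.table["segregating_pseudogene"].astype(bool)
        return GeneCatalog(self.table[keep])


@dataclass
class OrthologMap:
    """Human -> mouse gene-id pairs; possibly partial, unique human keys."""

    pairs: dict[str, str]

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "OrthologMap":
        seen: dict[str, str] = {}
        for h, m in pairs:
            if h in seen:
                raise OlfscreenError(f"duplicate human gene in ortholog map: {h}")
            seen[h] = m
        return cls(seen)

    def get(self, human_gene: str) -> str | None:
        return self.pairs.get(human_gene)

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass
class TranscriptModel:
    """A stranded exon chain with (optionally) the gene's ORF interval.

    Exons and ``cds`` are 0-based half-open genomic intervals.  ``class_code``
    is the single-character assembler comparison code, when known.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    cds: tuple[int, int] | None = None
    fpkm: float = 0.0
    class_code: str | None = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise OlfscreenError(f"{self.transcript_id}: bad strand {self.strand!r}")
        if not self.exons:
            raise OlfscreenError(f"{self.transcript_id}: no exons")
        exons = sorted((int(a), int(b)) for a, b in self.exons)
        for (a, b) in exons:
            if b <= a:
                raise OlfscreenError(f"{self.transcript_id}: empty exon {(a, b)}")
        for (_, b1), (a2, _) in zip(exons, exons[1:]):
            if a2 < b1:
                raise OlfscreenError(f"{self.transcript_id}: overlapping exons")
        self.exons = exons
        if self.cds is not None:
            c0, c1 = int(self.cds[0]), int(self.cds[1])
            if not (exons[0][0] <= c0 < c1 <= exons[-1][1]):
                raise OlfscreenError(
                    f"{self.transcript_id}: cds {self.cds} outside exon span")
            self.cds = (c0, c1)
        if self.fpkm < 0:
            raise OlfscreenError(f"{self.transcript_id}: negative FPKM")

    @property
    def span(self) -> tuple[int, int]:
        return (self.exons[0][0], self.exons[-1][1])

    @property
    def length(self) -> int:
        return sum(b - a for a, b in self.exons)

    def cds_start_base(self) -> int | None:
        """Genomic coordinate of the initiating codon's first base
        (strand-aware: leftmost CDS base on +, rightmost on -)."""
        if self.cds is None:
            return None
        return self.cds[0] if self.strand == "+" else self.cds[1] - 1

    def contains_position(self, pos: int) -> bool:
        return any(a <= pos < b for a, b in self.exons)
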