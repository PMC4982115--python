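"""Readers/writers for the pipeline's tabular and annotation formats.

Expression and count tables are plain TSV with one header row of sample ids
and gene ids in the first column; missing values are not allowed.  Transcript
models travel as GTF (1-based closed intervals on disk, converted to the
package's 0-based half-open convention at this boundary).
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils
import numpy as np
import pandas as pd

from .types import (
    DEFAULT_FPKM_FLOOR,
    CountMatrix,
    ExpressionMatrix,
    GeneCatalog,
    OlfscreenError,
    OrthologMap,
    TranscriptModel,
)


# ---------------------------------------------------------------------------
# expression / count tables

def _read_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique()
        raise OlfscreenError(f"{path}: duplicated gene ids: {list(dups[:5])}")
    non_numeric = df.select_dtypes(exclude="number")
    if not non_numeric.empty:
        col = non_numeric.columns[0]
        coerced = pd.to_numeric(df[col], errors="coerce")
        row = df.index[coerced.isna()][0] if coerced.isna().any() else "?"
        raise OlfscreenError(
            f"{path}: non-numeric value at gene {row!r}, sample {col!r}")
    if df.isna().any().any():
        gene, sample = next(zip(*np.where(df.isna())))
        raise OlfscreenError(
            f"{path}: missing value at gene {df.index[gene]!r}, "
            f"sample {df.columns[sample]!r}")
    return df


def read_expression_table(path: str | Path,
                          group_map: Mapping[str, str]) -> ExpressionMatrix:
    """Read a genes x samples FPKM TSV.  The floor is NOT applied here."""
    df = _read_table(path)
    return ExpressionMatrix(df.astype(float), dict(group_map))


def write_expression_table(m: ExpressionMatrix, path: str | Path) -> None:
    m.values.to_csv(path, sep="\t", index_label="gene_id")


def read_count_table(path: str | Path,
                     group_map: Mapping[str, str]) -> CountMatrix:
    df = _read_table(path)
    return CountMatrix(df, dict(group_map))


def write_count_table(c: CountMatrix, path: str | Path) -> None:
    c.counts.to_csv(path, sep="\t", index_label="gene_id")


def apply_fpkm_floor(m: ExpressionMatrix,
                     floor: float = DEFAULT_FPKM_FLOOR) -> ExpressionMatrix:
    """Replace every value v by max(v, floor).

    Zero FPKM entries are otherwise fatal for the log-scale analyses; the
    conventional floor is 0.003 FPKM.  Idempotent.
    """
    if not floor > 0:
        raise OlfscreenError(f"floor must be positive, got {floor}")
    values = m.values.clip(lower=floor)
    return ExpressionMatrix(values, dict(m.sample_groups), floor=floor)


# ---------------------------------------------------------------------------
# gene catalog / ortholog map

def read_gene_catalog(path: str | Path) -> GeneCatalog:
    df = pd.read_csv(path, sep="\t", index_col=0,
                     dtype={"or_class": "object", "ortholog_id": "object"})
    df["segregating_pseudogene"] = df["segregating_pseudogene"].astype(bool)
    return GeneCatalog(df)


def write_gene_catalog(catalog: GeneCatalog, path: str | Path) -> None:
    catalog.table.to_csv(path, sep="\t", index_label="gene_id")


def read_ortholog_map(path: str | Path) -> OrthologMap:
    df = pd.read_csv(path, sep="\t")
    return OrthologMap.from_pairs(
        zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str)))


def write_ortholog_map(om: OrthologMap, path: str | Path) -> None:
    pd.DataFrame(
        sorted(om.pairs.items()), columns=["human_gene_id", "mouse_gene_id"]
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# transcript models (GTF)

def read_transcript_models(path: str | Path,
                           fpkm_attr: str = "FPKM") -> list[TranscriptModel]:
    """Parse a GTF into transcript models.

    Exon intervals are converted from GTF 1-based closed to 0-based
    half-open.  A transcript's CDS interval, when present, is the union span
    of its CDS features.  Inconsistent strands within a transcript are an
    error.
    """
    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True, disable_infer_transcripts=True)
    per_tx: dict[str, dict] = {}
    for feat in db.all_features():
        if feat.featuretype not in ("exon", "CDS"):
            continue
        tx_id = feat.attributes["transcript_id"][0]
        rec = per_tx.setdefault(tx_id, {
            "gene_id": feat.attributes.get("gene_id", [tx_id])[0],
            "chrom": feat.seqid, "strand": feat.strand,
            "exons": [], "cds": [], "fpkm": 0.0, "class_code": None,
        })
        if feat.strand != rec["strand"]:
            raise OlfscreenError(
                f"{tx_id}: inconsistent strand across features")
        interval = (feat.start - 1, feat.end)  # GTF is 1-based closed
        if feat.featuretype == "exon":
            rec["exons"].append(interval)
        else:
            rec["cds"].append(interval)
        if fpkm_attr in feat.attributes:
            rec["fpkm"] = float(feat.attributes[fpkm_attr][0])
        if "class_code" in feat.attributes:
            rec["class_code"] = feat.attributes["class_code"][0]
    models = []
    for tx_id, rec in per_tx.items():
        cds = None
        if rec["cds"]:
            cds = (min(a for a, _ in rec["cds"]), max(b for _, b in rec["cds"]))
        models.append(TranscriptModel(
            transcript_id=tx_id, gene_id=rec["gene_id"], chrom=rec["chrom"],
            strand=rec["strand"], exons=rec["exons"], cds=cds,
            fpkm=rec["fpkm"], class_code=rec["class_code"]))
    return models


def write_transcript_models(models: Sequence[TranscriptModel],
                            path: str | Path,
                            fpkm_attr: str = "FPKM") -> None:
    """Write models as GTF (exon + CDS features, 1-based closed on disk)."""
    with open(path, "w") as fh:
        for m in models:
            attrs = (f'gene_id "{m.gene_id}"; transcript_id "{m.transcript_id}"; '
                     f'{fpkm_attr} "{m.fpkm:.6g}";')
            if m.class_code is not None:
                attrs += f' class_code "{m.class_code}";'
            for a, b in m.exons:
                fh.write("\t".join([
                    m.chrom, "olfscreen", "exon", str(a + 1), str(b),
                    ".", m.strand, ".", attrs]) + "\n")
            if m.cds is not None:
                fh.write("\t".join([
                    m.chrom, "olfscreen", "CDS",
                    str(m.cds[0] + 1), str(m.cds[1]),
                    ".", m.strand, ".", attrs]) + "\n")


# ---------------------------------------------------------------------------
# FASTA / BED

def read_fasta(path: str | Path) -> dict[str, str]:
    from Bio import SeqIO
    return {rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: Mapping[str, str], path: str | Path,
                width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def write_bed(intervals: Iterable[tuple[str, int, int, str, float, str]],
              path: str | Path) -> None:
    """Write (chrom, start, end, name, score, strand) rows as BED6."""
    with open(path, "w") as fh:
        for chrom, start, end, name, score, strand in intervals:
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\t{score:.4g}\t{strand}\n")


def validate(path: str | Path) -> str:
    """Best-effort format sniffing used by the CLI's `io validate`."""
    p = Path(path)
    if p.suffix in (".gtf", ".gff"):
        models = read_transcript_models(p)
        return f"GTF with {len(models)} transcript models"
    if p.suffix in (".fa", ".fasta"):
        seqs = read_fasta(p)
        return f"FASTA with {len(seqs)} sequences"
    df = _read_table(p)
    return f"TSV table: {df.shape[0]} genes x {df.shape[1]} samples"
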