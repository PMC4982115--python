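"""OR transcript-model curation, structure statistics and aberrant calls.

Curation applies, in order: removal of antisense/run-on assembly artifacts
(class codes x, s, p), removal of transcripts under 1.0 FPKM, and removal of
isoforms under 0.15% of their gene's major isoform.  Structure statistics
split each functional transcript into 5'UTR / CDS / 3'UTR in transcript
orientation; a transcript is aberrant when its exon union excludes the
gene's initiating-codon base (splice-driven pseudogenization despite an
intact genomic ORF).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .types import OlfscreenError, TranscriptModel

logger = logging.getLogger(__name__)


@dataclass
class CurationConfig:
    min_transcript_fpkm: float = 1.0
    min_isoform_fraction: float = 0.0015   # 0.15% of the major isoform
    drop_class_codes: frozenset[str] = frozenset({"x", "s", "p"})

    def __post_init__(self) -> None:
        if not 0.0 <= self.min_isoform_fraction <= 1.0:
            raise OlfscreenError("min_isoform_fraction must be in [0, 1]")


@dataclass
class StructureRecord:
    transcript_id: str
    gene_id: str
    transcript_length: int
    genomic_span: int
    cds_length: int
    utr5_length: int
    utr3_length: int
    n_5prime_noncoding_exons: int
    n_exons: int
    functional: bool
    tss: int
    strand: str
    cds_incomplete: bool = False


def curate_transcripts(models: Sequence[TranscriptModel],
                       cfg: CurationConfig | None = None
                       ) -> tuple[list[TranscriptModel],
                                  list[tuple[TranscriptModel, str]]]:
    """Apply the curation filters; removed models carry their first
    triggering reason.  Output order is independent of input order
    (sorted by transcript id)."""
    cfg = cfg or CurationConfig()
    models = sorted(models, key=lambda t: t.transcript_id)
    removed: list[tuple[TranscriptModel, str]] = []
    stage1: list[TranscriptModel] = []
    for t in models:
        if t.class_code is not None and t.class_code in cfg.drop_class_codes:
            removed.append((t, f"class_code:{t.class_code}"))
        else:
            stage1.append(t)
    stage2: list[TranscriptModel] = []
    for t in stage1:
        if t.fpkm < cfg.min_transcript_fpkm:
            removed.append((t, "min_transcript_fpkm"))
        else:
            stage2.append(t)
    major: dict[str, float] = {}
    for t in stage2:
        major[t.gene_id] = max(major.get(t.gene_id, 0.0), t.fpkm)
    kept: list[TranscriptModel] = []
    for t in stage2:
        if t.fpkm < cfg.min_isoform_fraction * major[t.gene_id]:
            removed.append((t, "min_isoform_fraction"))
        else:
            kept.append(t)
    return kept, removed


def infer_tss(model: TranscriptModel) -> int:
    """The transcript's 5'-most transcribed base: smallest exon start on the
    plus strand, largest exon end - 1 on the minus strand."""
    if model.strand == "+":
        return model.exons[0][0]
    return model.exons[-1][1] - 1


def _exonic_positions_5to3(model: TranscriptModel) -> np.ndarray:
    parts = [np.arange(a, b) for a, b in model.exons]
    pos = np.concatenate(parts)
    return pos if model.strand == "+" else pos[::-1]


def structure_stats(model: TranscriptModel,
                    cds: tuple[int, int] | None = None) -> StructureRecord:
    """Length decomposition of one transcript.

    ``cds`` overrides the model's own ORF interval (used when the gene's ORF
    is supplied externally).  When the CDS is only partially covered by the
    exons the record is flagged ``cds_incomplete`` and cds_length counts the
    covered portion only.
    """
    cds = cds if cds is not None else model.cds
    transcript_length = model.length
    genomic_span = model.span[1] - model.span[0]
    n_exons = len(model.exons)
    tss = infer_tss(model)
    if cds is None:
        return StructureRecord(
            model.transcript_id, model.gene_id, transcript_length,
            genomic_span, 0, 0, 0, 0, n_exons, False, tss, model.strand)

    covered = sum(max(0, min(b, cds[1]) - max(a, cds[0]))
                  for a, b in model.exons)
    cds_len_genomic = cds[1] - cds[0]
    incomplete = covered < cds_len_genomic

    # transcript-orientation split around the CDS interval
    if model.strand == "+":
        utr5 = sum(max(0, min(b, cds[0]) - a) for a, b in model.exons)
        utr3 = sum(max(0, b - max(a, cds[1])) for a, b in model.exons)
        n5 = sum(1 for a, b in model.exons if b <= cds[0])
    else:
        utr5 = sum(max(0, b - max(a, cds[1])) for a, b in model.exons)
        utr3 = sum(max(0, min(b, cds[0]) - a) for a, b in model.exons)
        n5 = sum(1 for a, b in model.exons if a >= cds[1])
    start = model.cds_start_base() if model.cds is not None else (
        cds[0] if model.strand == "+" else cds[1] - 1)
    functional = model.contains_position(start) and not incomplete
    return StructureRecord(
        model.transcript_id, model.gene_id, transcript_length, genomic_span,
        covered, utr5, utr3, n5, n_exons, functional, tss, model.strand,
        cds_incomplete=incomplete)


def detect_aberrant(models: Sequence[TranscriptModel],
                    gene_cds: Mapping[str, tuple[int, int]]
                    ) -> tuple[dict[str, bool], dict[str, str]]:
    """Flag transcripts whose exon union excludes the initiating codon.

    Returns (per-transcript functional flag, per-gene class in
    {all_functional, mixed, all_aberrant}).  A transcript that contains the
    ORF start but splices out an internal CDS chunk is still counted
    functional here and flagged separately by ``structure_stats`` as
    cds_incomplete (internal disruption).  Genes without a known CDS are
    skipped with a warning.
    """
    functional: dict[str, bool] = {}
    per_gene: dict[str, list[bool]] = {}
    for t in models:
        cds = gene_cds.get(t.gene_id, t.cds)
        if cds is None:
            logger.warning("gene %s has no CDS; skipping %s",
                           t.gene_id, t.transcript_id)
            continue
        start = cds[0] if t.strand == "+" else cds[1] - 1
        ok = t.contains_position(start)
        functional[t.transcript_id] = ok
        per_gene.setdefault(t.gene_id, []).append(ok)
    gene_class = {}
    for g, flags in per_gene.items():
        if all(flags):
            gene_class[g] = "all_functional"
        elif any(flags):
            gene_class[g] = "mixed"
        else:
            gene_class[g] = "all_aberrant"
    return functional, gene_class


def structure_table(models: Sequence[TranscriptModel],
                    gene_cds: Mapping[str, tuple[int, int]] | None = None
                    ) -> pd.DataFrame:
    gene_cds = gene_cds or {}
    records = [structure_stats(t, cds=gene_cds.get(t.gene_id, t.cds))
               for t in models]
    return pd.DataFrame([r.__dict__ for r in records]).set_index("transcript_id")


def length_summary(table: pd.DataFrame) -> dict[str, tuple[float, float]]:
    """Mean +/- population SD of the structural lengths over functional
    transcripts (descriptive, matching the repertoire-wide reporting style)."""
    func = table[table["functional"]]
    out = {}
    for col in ("transcript_length", "genomic_span", "cds_length",
                "utr5_length", "utr3_length", "n_5prime_noncoding_exons"):
        vals = func[col].astype(float)
        out[col] = (float(vals.mean()), float(vals.std(ddof=0)))
    return out
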