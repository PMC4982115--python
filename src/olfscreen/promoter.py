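"""Promoter-window selection, PWM scanning and TSS-anchored motif profiles.

The motif model is a plain position weight matrix scored as log2 odds against
a background composition; enrichment of a motif in target promoter windows
versus background windows is a Fisher exact test on windows-with-a-hit
counts.  Offsets are counted in bp upstream of the TSS (TSS base = offset 0).
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .types import OlfscreenError

_ALPHABET = "ACGT"
_CODE = {c: i for i, c in enumerate(_ALPHABET)}
_COMPLEMENT = {0: 3, 1: 2, 2: 1, 3: 0}

DEFAULT_WINDOW = (-750, 250)      # bp relative to TSS
DEFAULT_DEDUP_OVERLAP = 500       # bp
DEFAULT_PROFILE_BP = 4000         # upstream profile extent
DEFAULT_THRESHOLD_FRACTION = 0.8  # of the maximal PWM log-odds score


@dataclass
class PWM:
    """Position probability matrix (4 x L, rows A,C,G,T) with background."""

    matrix: np.ndarray
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25))

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.matrix.shape[0] != 4:
            raise OlfscreenError("PWM matrix must have 4 rows (A,C,G,T)")
        if not np.allclose(self.matrix.sum(axis=0), 1.0, atol=1e-6):
            raise OlfscreenError("PWM columns must sum to 1")
        if not np.isclose(self.background.sum(), 1.0, atol=1e-6):
            raise OlfscreenError("PWM background must sum to 1")

    @classmethod
    def from_counts(cls, counts: np.ndarray, pseudocount: float = 0.5,
                    background: np.ndarray | None = None) -> "PWM":
        counts = np.asarray(counts, dtype=float) + pseudocount
        matrix = counts / counts.sum(axis=0, keepdims=True)
        if background is None:
            return cls(matrix)
        return cls(matrix, np.asarray(background, dtype=float))

    @classmethod
    def from_jaspar(cls, text_or_path: str, pseudocount: float = 0.5) -> "PWM":
        """Parse a JASPAR-style count matrix (via Bio.motifs)."""
        from Bio import motifs
        try:
            handle = open(text_or_path)
        except (OSError, ValueError):
            handle = _io.StringIO(text_or_path)
        with handle:
            motif = motifs.read(handle, "jaspar")
        counts = np.array([motif.counts[b] for b in _ALPHABET], dtype=float)
        return cls.from_counts(counts, pseudocount=pseudocount)

    @property
    def length(self) -> int:
        return self.matrix.shape[1]

    def log_odds(self) -> np.ndarray:
        """4 x L matrix of log2(p / background), one row per base."""
        with np.errstate(divide="ignore"):
            return np.log2(self.matrix / self.background[:, None])

    def max_score(self) -> float:
        return float(self.log_odds().max(axis=0).sum())

    def consensus(self) -> str:
        return "".join(_ALPHABET[i] for i in self.matrix.argmax(axis=0))

    def sample(self, rng: np.random.Generator) -> str:
        cols = [rng.choice(4, p=self.matrix[:, j]) for j in range(self.length)]
        return "".join(_ALPHABET[i] for i in cols)


def ebf_like_pwm(strength: float = 0.85) -> PWM:
    """A 10-bp early-B-cell-factor-like motif (consensus TCCCNNGGGA).

    Synthetic stand-in motif model for the Olf/EBF site family; ``strength``
    is the probability mass on the consensus base at informative positions.
    """
    consensus = "TCCCNNGGGA"
    rest = (1.0 - strength) / 3.0
    cols = []
    for c in consensus:
        if c == "N":
            cols.append(np.full(4, 0.25))
        else:
            col = np.full(4, rest)
            col[_CODE[c]] = strength
            cols.append(col)
    return PWM(np.column_stack(cols))


@dataclass
class MotifHit:
    """A PWM match; ``offset`` is in bp upstream of the anchoring TSS when a
    TSS index was supplied to the scan, otherwise the 0-based window start."""

    window_id: str | None
    offset: int
    score: float
    strand: str
    start: int = 0


@dataclass
class PromoterWindow:
    """A TSS-anchored promoter interval, default [-750, +250) around the TSS."""

    gene_id: str
    transcript_id: str
    tss: int
    strand: str
    fpkm: float = 0.0
    rel_interval: tuple[int, int] = DEFAULT_WINDOW
    sequence: str | None = None

    @property
    def genomic_interval(self) -> tuple[int, int]:
        lo, hi = self.rel_interval
        if self.strand == "+":
            return (self.tss + lo, self.tss + hi)
        # on the minus strand upstream extends to higher coordinates
        return (self.tss - hi + 1, self.tss - lo + 1)


def _encode(seq: str) -> np.ndarray:
    codes = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    table = np.full(256, 4, dtype=np.int8)  # 4 = N / unknown
    for c, i in _CODE.items():
        table[ord(c)] = i
    return table[codes]


def _window_scores(codes: np.ndarray, lo: np.ndarray) -> np.ndarray:
    """Score every length-L window; unknown bases contribute 0 log-odds."""
    L = lo.shape[1]
    lo5 = np.vstack([lo, np.zeros((1, L))])
    windows = np.lib.stride_tricks.sliding_window_view(codes, L)
    return lo5[windows, np.arange(L)].sum(axis=1)


def scan_pwm(seq: str, pwm: PWM, threshold: float,
             both_strands: bool = True,
             tss_index: int | None = None,
             window_id: str | None = None) -> list[MotifHit]:
    """All PWM matches with log2-odds score >= threshold.

    A hit is anchored at its 5'-most matching base in the scanned (promoter)
    orientation; with ``tss_index`` given, ``offset = tss_index - start`` is
    the distance upstream of the TSS.
    """
    L = pwm.length
    if len(seq) < L:
        return []
    codes = _encode(seq)
    lo = pwm.log_odds()
    hits: list[MotifHit] = []
    strands = {"+": lo}
    if both_strands:
        # reverse-complement match scored in place: complement rows, flip cols
        strands["-"] = lo[[3, 2, 1, 0], :][:, ::-1]
    for strand, mat in strands.items():
        scores = _window_scores(codes, mat)
        for start in np.flatnonzero(scores >= threshold):
            offset = (tss_index - int(start)) if tss_index is not None else int(start)
            hits.append(MotifHit(window_id, offset, float(scores[start]),
                                 strand, start=int(start)))
    hits.sort(key=lambda h: (h.start, h.strand))
    return hits


def default_threshold(pwm: PWM,
                      fraction: float = DEFAULT_THRESHOLD_FRACTION) -> float:
    return fraction * pwm.max_score()


def select_promoter_windows(candidates: Sequence[PromoterWindow],
                            dedup_overlap: int = DEFAULT_DEDUP_OVERLAP
                            ) -> list[PromoterWindow]:
    """Per-gene greedy dedup of TSS windows.

    Candidates are taken in descending transcript FPKM order (ties broken by
    transcript id); a window is dropped iff it overlaps an already-retained
    window of the same gene by >= ``dedup_overlap`` bp.
    """
    kept: list[PromoterWindow] = []
    by_gene: dict[str, list[PromoterWindow]] = {}
    for w in candidates:
        by_gene.setdefault(w.gene_id, []).append(w)
    for gene_id in sorted(by_gene):
        group = sorted(by_gene[gene_id],
                       key=lambda w: (-w.fpkm, w.transcript_id))
        retained: list[PromoterWindow] = []
        for w in group:
            a, b = w.genomic_interval
            overlap = max(
                (min(b, rb) - max(a, ra)
                 for ra, rb in (r.genomic_interval for r in retained)),
                default=0)
            if overlap < dedup_overlap:
                retained.append(w)
        kept.extend(retained)
    return kept


def positional_profile(hits: Iterable[MotifHit],
                       window_bp: int = DEFAULT_PROFILE_BP,
                       bin_bp: int = 100) -> np.ndarray:
    """Sum hit counts into upstream-distance bins over [0, window_bp).

    Bin i covers offsets [i*bin_bp, (i+1)*bin_bp); hits outside the window
    are excluded, so the bins sum to the number of in-window hits.
    """
    if window_bp % bin_bp != 0:
        raise OlfscreenError("window_bp must be divisible by bin_bp")
    counts = np.zeros(window_bp // bin_bp, dtype=int)
    for h in hits:
        if 0 <= h.offset < window_bp:
            counts[h.offset // bin_bp] += 1
    return counts


def motif_enrichment(target_seqs: Sequence[str],
                     background_seqs: Sequence[str],
                     pwm: PWM, threshold: float,
                     both_strands: bool = True) -> tuple[float, float]:
    """Fisher exact test on windows-with->=1-hit, target vs background.

    Returns (odds ratio, two-sided p).  A degenerate 2x2 table (a zero
    margin) yields an undefined odds ratio (nan) and p = 1.
    """
    if not len(target_seqs) or not len(background_seqs):
        raise OlfscreenError("both window sets must be non-empty")

    def n_with_hit(seqs: Sequence[str]) -> int:
        return sum(
            bool(scan_pwm(s, pwm, threshold, both_strands=both_strands))
            for s in seqs)

    a = n_with_hit(target_seqs)
    b = len(target_seqs) - a
    c = n_with_hit(background_seqs)
    d = len(background_seqs) - c
    table = np.array([[a, b], [c, d]])
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return (float("nan"), 1.0)
    odds, p = stats.fisher_exact(table, alternative="two-sided")
    return (float(odds), float(p))
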