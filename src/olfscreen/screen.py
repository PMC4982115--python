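"""The tissue-overexpression screen.

Counts are normalized with median-of-ratios size factors, per-gene
dispersions come from a within-group method-of-moments estimate, and
significance is an exact conditional negative-binomial test on the two group
totals (the testable core of the classical DESeq approach).  A gene is
called overexpressed when its FPKM fold change is >= 6 with p < 0.001 (or is
rescued by a significant mouse ortholog at human fold > 6), and is then
discarded if the respiratory-epithelium sample carries more than 0.1 of its
olfactory-epithelium expression (contamination filter).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats

from .types import (
    CountMatrix,
    ExpressionMatrix,
    GeneCatalog,
    OlfscreenError,
    OrthologMap,
)

logger = logging.getLogger(__name__)


@dataclass
class ScreenConfig:
    fold_cutoff: float = 6.0
    p_cutoff: float = 0.001
    respiratory_ratio_cutoff: float = 0.1
    rescue_requires_mouse_significant: bool = True
    rescue_human_fold_min: float = 6.0
    hit_threshold: int = 1          # literature hits for evidence class A
    bh_correct: bool = False        # optional FDR column, off by default

    def __post_init__(self) -> None:
        for name in ("fold_cutoff", "p_cutoff", "respiratory_ratio_cutoff",
                     "rescue_human_fold_min"):
            if getattr(self, name) <= 0:
                raise OlfscreenError(f"{name} must be positive")


@dataclass
class ScreenRecord:
    gene_id: str
    fold_change: float
    p_value: float
    respiratory_ratio: float
    status: str          # retained/failed_fold/failed_p/respiratory_filtered/rescued_by_mouse
    evidence_class: str = "NA"
    q_value: float = float("nan")

    @property
    def retained(self) -> bool:
        return self.status in ("retained", "rescued_by_mouse")


@dataclass
class DispersionModel:
    alpha: pd.Series          # per-gene dispersion, >= 0
    size_factors: pd.Series   # per-sample, geometric mean 1


# ---------------------------------------------------------------------------
# normalization and dispersion

def estimate_size_factors(c: CountMatrix) -> pd.Series:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    s_j = median over all-sample-positive genes of count_ij divided by the
    gene's geometric mean across samples.
    """
    counts = c.counts.values.astype(float)
    if counts.shape[1] == 1:
        return pd.Series([1.0], index=c.sample_ids)
    positive = (counts > 0).all(axis=1)
    if not positive.any():
        raise OlfscreenError(
            "no gene with nonzero counts in every sample")
    logc = np.log(counts[positive])
    log_ratios = logc - logc.mean(axis=1, keepdims=True)
    s = np.exp(np.median(log_ratios, axis=0))
    s /= np.exp(np.mean(np.log(s)))
    return pd.Series(s, index=c.sample_ids)


def estimate_dispersions(c: CountMatrix, s: pd.Series,
                         groups: Mapping[str, Sequence[str]],
                         sharing: str = "maximum") -> DispersionModel:
    """Per-gene method-of-moments dispersion pooled within groups.

    For each group with >= 2 samples, alpha = max(0, (var(q) - mean(q)) /
    mean(q)^2) on normalized counts q = k/s; group estimates are averaged.
    With ``sharing="maximum"`` (default) each gene's dispersion is floored
    at the across-gene median: at a handful of samples per group the raw
    moment estimate is noisy and its underestimates make the exact test
    anti-conservative, so the larger of the gene's own and the repertoire's
    typical dispersion is used.  ``sharing="none"`` returns the raw
    per-gene estimates.
    """
    eligible = {g: list(ss) for g, ss in groups.items() if len(ss) >= 2}
    if not eligible:
        raise OlfscreenError("need >=2 samples in at least one group")
    per_group = []
    df_total = 0
    for name, samples in eligible.items():
        q = c.counts[samples].values / s.loc[samples].values[None, :]
        mean = q.mean(axis=1)
        var = q.var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            a = (var - mean) / mean ** 2
        a = np.where(mean > 0, np.maximum(a, 0.0), 0.0)
        per_group.append(a)
        df_total += len(samples) - 1
    alpha = np.mean(per_group, axis=0)
    if sharing == "maximum":
        alpha = np.maximum(alpha, float(np.median(alpha)))
    elif sharing != "none":
        raise OlfscreenError(f"unknown sharing mode {sharing!r}")
    return DispersionModel(
        alpha=pd.Series(alpha, index=c.gene_ids),
        size_factors=s)


# ---------------------------------------------------------------------------
# exact conditional NB test

def _nb_logpmf(k: np.ndarray, mean: float, alpha: float) -> np.ndarray:
    if mean <= 0:
        return np.where(k == 0, 0.0, -np.inf)
    if alpha <= 1e-12:
        return stats.poisson.logpmf(k, mean)
    r = 1.0 / alpha
    p = r / (r + mean)
    return stats.nbinom.logpmf(k, r, p)


def nb_two_group_test(c: CountMatrix, s: pd.Series, d: DispersionModel,
                      group_a: Sequence[str], group_b: Sequence[str],
                      gene: str) -> float:
    """Two-sided exact conditional test on the split of the gene's total.

    Conditional on K = K_A + K_B, every split (a, K-a) with probability not
    exceeding the observed split's is summed, using NB probabilities for the
    group totals: K_A ~ NB(q0*S_A, alpha/n_A) where q0 is the pooled
    normalized mean and S_A the group's size-factor sum.  At alpha = 0 this
    is the exact Poisson-conditional (binomial) test.  Computed in log space.
    """
    if set(group_a) & set(group_b):
        raise OlfscreenError("groups must be disjoint")
    if gene not in c.gene_ids:
        raise OlfscreenError(f"gene {gene!r} not in count matrix")
    row = c.counts.loc[gene]
    k_a = int(row[list(group_a)].sum())
    k_b = int(row[list(group_b)].sum())
    total = k_a + k_b
    if total == 0:
        return 1.0
    S_a = float(s.loc[list(group_a)].sum())
    S_b = float(s.loc[list(group_b)].sum())
    q0 = total / (S_a + S_b)
    alpha = float(d.alpha.loc[gene])
    a = np.arange(total + 1)
    logp = (_nb_logpmf(a, q0 * S_a, alpha / len(group_a))
            + _nb_logpmf(total - a, q0 * S_b, alpha / len(group_b)))
    logz = special.logsumexp(logp)
    logp -= logz
    keep = logp <= logp[k_a] + 1e-8
    p = float(np.exp(special.logsumexp(logp[keep])))
    return min(max(p, np.exp(logp[k_a])), 1.0)


# ---------------------------------------------------------------------------
# fold changes

def fpkm_fold_change(m: ExpressionMatrix, gene: str,
                     group_a: Sequence[str],
                     group_b: Sequence[str]) -> float:
    """(mean FPKM over group_a samples) / (mean over group_b samples)."""
    m.require_floored()
    if not len(group_a) or not len(group_b):
        raise OlfscreenError("fold change needs non-empty groups")
    row = m.values.loc[gene]
    return float(row[list(group_a)].mean() / row[list(group_b)].mean())


def shared_tissue_fold_change(m_human: ExpressionMatrix,
                              m_mouse: ExpressionMatrix,
                              shared_tissues: Sequence[str],
                              gene: str,
                              ortholog_map: OrthologMap
                              ) -> tuple[float, float]:
    """Fold changes of a human gene and its mouse ortholog computed against
    only the control tissues present in both studies (the convention used
    for families, like the lipocalins, whose members mostly lack orthologs)."""
    def controls(m: ExpressionMatrix) -> list[str]:
        out: list[str] = []
        for t in shared_tissues:
            out.extend(m.samples_in_group(f"control:{t}"))
        return out

    h_ctrl = controls(m_human)
    m_ctrl = controls(m_mouse)
    if not h_ctrl or not m_ctrl:
        raise OlfscreenError("no shared control tissue present in both studies")
    h_fold = fpkm_fold_change(m_human, gene,
                              m_human.samples_in_group("OE"), h_ctrl)
    mg = ortholog_map.get(gene)
    if mg is None or mg not in m_mouse.gene_ids:
        return (h_fold, float("nan"))
    m_fold = fpkm_fold_change(m_mouse, mg,
                              m_mouse.samples_in_group("OE"), m_ctrl)
    return (h_fold, m_fold)


# ---------------------------------------------------------------------------
# the screen

def run_screen(m: ExpressionMatrix, c: CountMatrix, catalog: GeneCatalog,
               ortholog_map: OrthologMap,
               mouse_screen: Mapping[str, bool] | None = None,
               cfg: ScreenConfig | None = None) -> list[ScreenRecord]:
    """Full overexpression screen over the catalog's non-OR genes.

    Retained iff (fold >= fold_cutoff and p < p_cutoff) or (mouse ortholog
    significantly overexpressed and human fold > rescue_human_fold_min);
    afterwards a retained gene is relabelled respiratory_filtered iff
    FPKM_respiratory / FPKM_OE exceeds the contamination cutoff.
    """
    cfg = cfg or ScreenConfig()
    m.require_floored()
    oe = m.samples_in_group("OE")
    controls = [smp for smp in m.sample_ids
                if m.sample_groups[smp].startswith("control")]
    resp = m.samples_in_group("respiratory")
    if not oe or not controls:
        raise OlfscreenError("screen requires OE and control samples")
    if not resp:
        logger.warning("no respiratory sample: contamination filter disabled")

    s = estimate_size_factors(c)
    d = estimate_dispersions(c, s, {"OE": oe, "control": controls})
    mouse_screen = mouse_screen or {}

    records: list[ScreenRecord] = []
    for gene in catalog.non_or_genes:
        if gene not in m.gene_ids or gene not in c.gene_ids:
            continue
        fold = fpkm_fold_change(m, gene, oe, controls)
        p = nb_two_group_test(c, s, d, oe, controls, gene)
        if resp:
            ratio = float(m.values.loc[gene, resp[0]]
                          / m.values.loc[gene, oe].mean())
        else:
            ratio = float("nan")
        significant = fold >= cfg.fold_cutoff and p < cfg.p_cutoff
        ortholog = ortholog_map.get(gene)
        rescued = (not significant
                   and ortholog is not None
                   and bool(mouse_screen.get(ortholog, False))
                   and fold > cfg.rescue_human_fold_min)
        if significant or rescued:
            status = "rescued_by_mouse" if rescued else "retained"
            if resp and ratio > cfg.respiratory_ratio_cutoff:
                status = "respiratory_filtered"
        elif fold < cfg.fold_cutoff:
            status = "failed_fold"
        else:
            status = "failed_p"
        records.append(ScreenRecord(gene, fold, p, ratio, status))

    if cfg.bh_correct:
        ps = np.array([r.p_value for r in records])
        qs = stats.false_discovery_control(ps)
        for r, q in zip(records, qs):
            r.q_value = float(q)
    classify_evidence_class(records, catalog, cfg.hit_threshold)
    return records


def classify_evidence_class(records: Sequence[ScreenRecord],
                            catalog: GeneCatalog,
                            hit_threshold: int = 1) -> list[ScreenRecord]:
    """Label retained genes class A (literature_hits >= threshold) or B;
    genes without a hit count stay NA."""
    hits = catalog.table["literature_hits"]
    for r in records:
        if not r.retained:
            r.evidence_class = "NA"
            continue
        h = hits.get(r.gene_id, np.nan)
        if pd.isna(h):
            r.evidence_class = "NA"
        else:
            r.evidence_class = "A" if h >= hit_threshold else "B"
    return list(records)


def screen_table(records: Sequence[ScreenRecord]) -> pd.DataFrame:
    return pd.DataFrame([{
        "gene_id": r.gene_id, "fold_change": r.fold_change,
        "p_value": r.p_value, "respiratory_ratio": r.respiratory_ratio,
        "status": r.status, "evidence_class": r.evidence_class,
        "q_value": r.q_value,
    } for r in records]).set_index("gene_id")


def mouse_significance(records: Sequence[ScreenRecord]) -> dict[str, bool]:
    """Per-gene significance map from a (mouse) screen, as consumed by the
    rescue rule of a human screen."""
    return {r.gene_id: r.retained for r in records}
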