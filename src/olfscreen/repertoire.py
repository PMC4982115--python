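"""Olfactory-receptor repertoire expression statistics.

Covers expressed-fraction calls (FPKM >= 0.01 in at least one sample of the
tissue group), intact-versus-pseudogene distribution comparisons
(Kolmogorov-Smirnov on per-gene mean FPKM), the rank and normalized
cumulative expression curves with the half-fraction skew statistic (the
smallest fraction of top-ranked genes holding half the summed expression),
the class I/II contrast, the functionality-score association, and a
sensitivity rerun excluding segregating-pseudogene loci.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .types import ExpressionMatrix, GeneCatalog, OlfscreenError

EXPRESSED_FPKM_CUTOFF = 0.01


@dataclass
class RepertoireSummary:
    expressed_fraction_intact: float
    expressed_fraction_pseudo: float
    mean_fpkm_by_status: dict[str, tuple[float, float]]  # status -> (mean, sd)
    ks_p_intact_vs_pseudo: float
    half_fraction: float
    rank_curve: pd.DataFrame        # columns rank, fpkm
    cumulative_curve: pd.DataFrame  # columns rank_fraction, cumulative_fraction


def gene_mean_expression(m: ExpressionMatrix, genes: Sequence[str],
                         samples: Sequence[str]) -> pd.Series:
    """Per-gene mean FPKM across the listed samples (the repertoire-wide
    summaries average across the tissue group's samples)."""
    if len(genes) == 0:
        raise OlfscreenError("empty gene set")
    return m.values.loc[list(genes), list(samples)].mean(axis=1)


def expressed_fraction(m: ExpressionMatrix, genes: Sequence[str],
                       cutoff: float = EXPRESSED_FPKM_CUTOFF,
                       samples: Sequence[str] | None = None) -> float:
    """Fraction of genes at or above the cutoff in >= 1 listed sample."""
    if len(genes) == 0:
        raise OlfscreenError("empty gene set")
    samples = list(samples) if samples is not None else list(m.sample_ids)
    sub = m.values.loc[list(genes), samples]
    return float((sub >= cutoff).any(axis=1).mean())


def status_distribution_test(m: ExpressionMatrix, catalog: GeneCatalog,
                             samples: Sequence[str]
                             ) -> tuple[dict[str, tuple[float, float]],
                                        float, float]:
    """Mean +/- sd of per-gene mean FPKM by OR status, and the two-sample
    KS comparison of intact vs pseudogene distributions.

    Returns (stats_by_status, ks_statistic, ks_p).  SDs are population SDs
    (descriptive).
    """
    out: dict[str, tuple[float, float]] = {}
    per_status: dict[str, np.ndarray] = {}
    for status in ("intact", "pseudogene"):
        genes = [g for g in catalog.genes_with_status(status)
                 if g in m.gene_ids]
        if len(genes) < 2:
            raise OlfscreenError(f"<2 genes with status {status}")
        vals = gene_mean_expression(m, genes, samples).values
        per_status[status] = vals
        out[status] = (float(vals.mean()), float(vals.std(ddof=0)))
    ks = stats.ks_2samp(per_status["intact"], per_status["pseudogene"])
    return out, float(ks.statistic), float(ks.pvalue)


def half_fraction(values: np.ndarray) -> float:
    """Smallest k/n with the top-k sum >= half the total (no interpolation)."""
    values = np.asarray(values, dtype=float)
    total = values.sum()
    if total <= 0:
        raise OlfscreenError("total expression is zero")
    ordered = np.sort(values)[::-1]
    csum = np.cumsum(ordered)
    k = int(np.searchsorted(csum, 0.5 * total, side="left")) + 1
    return k / len(values)


def rank_and_cumulative(m: ExpressionMatrix, genes: Sequence[str],
                        samples: Sequence[str]
                        ) -> tuple[pd.DataFrame, pd.DataFrame, float]:
    """Rank curve, normalized cumulative curve and the half-fraction.

    Genes are sorted by mean FPKM descending (ties broken by gene id for
    determinism); the cumulative curve gives, at rank fraction k/n, the
    fraction of total expression held by the top k genes.
    """
    means = gene_mean_expression(m, genes, samples)
    order = sorted(means.index, key=lambda g: (-means[g], g))
    vals = means.loc[order].values
    total = vals.sum()
    if total <= 0:
        raise OlfscreenError("total expression is zero")
    n = len(vals)
    rank_curve = pd.DataFrame({
        "rank": np.arange(1, n + 1), "gene_id": order, "fpkm": vals})
    cumulative = pd.DataFrame({
        "rank_fraction": np.arange(1, n + 1) / n,
        "cumulative_fraction": np.cumsum(vals) / total})
    return rank_curve, cumulative, half_fraction(vals)


def repertoire_summary(m: ExpressionMatrix, catalog: GeneCatalog,
                       samples: Sequence[str],
                       cutoff: float = EXPRESSED_FPKM_CUTOFF
                       ) -> RepertoireSummary:
    intact = [g for g in catalog.genes_with_status("intact") if g in m.gene_ids]
    pseudo = [g for g in catalog.genes_with_status("pseudogene")
              if g in m.gene_ids]
    by_status, ks_stat, ks_p = status_distribution_test(m, catalog, samples)
    rank_curve, cumulative, hf = rank_and_cumulative(
        m, intact + pseudo, samples)
    return RepertoireSummary(
        expressed_fraction_intact=expressed_fraction(m, intact, cutoff, samples),
        expressed_fraction_pseudo=expressed_fraction(m, pseudo, cutoff, samples),
        mean_fpkm_by_status=by_status,
        ks_p_intact_vs_pseudo=ks_p,
        half_fraction=hf,
        rank_curve=rank_curve,
        cumulative_curve=cumulative)


def class_comparison(m: ExpressionMatrix, catalog: GeneCatalog,
                     samples: Sequence[str],
                     cutoff: float = EXPRESSED_FPKM_CUTOFF
                     ) -> dict[str, float]:
    """Class I vs class II ORs: a 2x2 chi-square on expressed counts and a
    KS test on expression levels (both reported; the underlying contrast can
    reasonably be framed either way)."""
    table = catalog.table
    cls = {}
    for label in ("I", "II"):
        genes = [g for g in table.index[(table["or_class"] == label)]
                 if g in m.gene_ids]
        if not genes:
            raise OlfscreenError(f"no class {label} OR genes present")
        cls[label] = genes
    counts = np.zeros((2, 2))
    levels = {}
    for i, label in enumerate(("I", "II")):
        sub = m.values.loc[cls[label], list(samples)]
        expressed = (sub >= cutoff).any(axis=1)
        counts[i] = [expressed.sum(), (~expressed).sum()]
        levels[label] = gene_mean_expression(m, cls[label], samples).values
    if (counts.sum(axis=0) == 0).any() or (counts.sum(axis=1) == 0).any():
        # degenerate table (e.g. everything expressed): no contrast to test
        chi2, chi_p, unreliable = 0.0, 1.0, True
    else:
        expected = stats.contingency.expected_freq(counts)
        unreliable = bool((expected < 1).any())
        chi2, chi_p = stats.chi2_contingency(counts, correction=False)[:2]
    ks = stats.ks_2samp(levels["I"], levels["II"])
    return {"chi2": float(chi2), "chi2_p": float(chi_p),
            "chi2_unreliable": unreliable,
            "ks_stat": float(ks.statistic), "ks_p": float(ks.pvalue)}


def score_expression_association(m: ExpressionMatrix, catalog: GeneCatalog,
                                 samples: Sequence[str]) -> float:
    """KS p for expression of high- vs low-functionality-score OR halves
    (median split of the functionality score)."""
    table = catalog.table
    has = table["functionality_score"].notna()
    genes = [g for g in table.index[has] if g in m.gene_ids]
    scores = table.loc[genes, "functionality_score"].astype(float)
    if scores.nunique() <= 1:
        raise OlfscreenError("all functionality scores equal")
    med = scores.median()
    order = scores.sort_values(kind="mergesort")
    n_low = int(np.ceil(len(order) / 2))
    low = list(order.index[:n_low])
    high = list(order.index[n_low:])
    if len(low) < 2 or len(high) < 2:
        raise OlfscreenError("too few genes on one side of the median split")
    expr_low = gene_mean_expression(m, low, samples).values
    expr_high = gene_mean_expression(m, high, samples).values
    return float(stats.ks_2samp(expr_low, expr_high).pvalue)


def rerun_excluding_segregating(operation: Callable[..., object],
                                catalog: GeneCatalog,
                                *args, **kwargs) -> tuple[object, object]:
    """Run a repertoire operation on the full catalog and again on the
    catalog stripped of segregating-pseudogene loci; returns (full, reduced).

    The operation must accept the catalog as its ``catalog`` keyword (or
    second positional argument by convention m, catalog, ...).
    """
    full = operation(*args, catalog=catalog, **kwargs)
    reduced = operation(*args, catalog=catalog.without_segregating(), **kwargs)
    return full, reduced
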