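"""Matched-distribution resampling test for inter-individual OR variability.

The question: is the between-individual Pearson correlation of OR expression
(log10 FPKM, one sample pair) lower than expected for genes of comparable
expression?  The null is built by repeatedly drawing control gene sets whose
reference-expression distribution matches the OR set's (two-sample KS
p > 0.05), computing each set's pair correlation, and locating the observed
OR correlation in that null (one-sided, add-one empirical p).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .types import ExpressionMatrix, OlfscreenError


@dataclass
class ResamplingConfig:
    n_iterations: int = 10_000
    match_ks_alpha: float = 0.05
    n_bins: int = 20
    max_proposals_per_iteration: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_iterations < 1:
            raise OlfscreenError("n_iterations must be >= 1")
        if not 0.0 < self.match_ks_alpha < 1.0:
            raise OlfscreenError("match_ks_alpha must be in (0, 1)")


@dataclass
class ResamplingOutcome:
    observed_r: float
    null_rs: np.ndarray
    empirical_p: float
    p_string: str
    n_matched_genes: int


def matched_control_sample(pool_values: pd.Series, target_values: pd.Series,
                           n: int, cfg: ResamplingConfig,
                           rng: np.random.Generator | None = None
                           ) -> list[str]:
    """Draw n control genes whose reference-expression distribution matches
    the target set's (accepted when two-sample KS p > match_ks_alpha).

    Proposals are stratified: the target distribution is cut into
    ``cfg.n_bins`` quantile bins, pool genes are assigned to the bins, and
    each proposal draws exactly the target's per-bin counts (scaled to n);
    an accept/reject KS step then guards the match.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    if len(pool_values) < n:
        raise OlfscreenError("control pool smaller than requested set size")
    overlap = set(pool_values.index) & set(target_values.index)
    if overlap:
        raise OlfscreenError("control pool must be disjoint from target set")

    target = target_values.values.astype(float)
    edges = np.quantile(target, np.linspace(0, 1, cfg.n_bins + 1))
    edges[0], edges[-1] = -np.inf, np.inf
    pool_bins = np.searchsorted(edges, pool_values.values, side="right") - 1
    pool_bins = np.clip(pool_bins, 0, cfg.n_bins - 1)
    target_bins = np.clip(
        np.searchsorted(edges, target, side="right") - 1, 0, cfg.n_bins - 1)
    target_counts = np.bincount(target_bins, minlength=cfg.n_bins)
    # deterministic per-bin quota proportional to the target's composition
    quota = np.floor(target_counts * n / len(target)).astype(int)
    shortfall = n - quota.sum()
    if shortfall > 0:
        frac = target_counts * n / len(target) - quota
        for b in np.argsort(-frac)[:shortfall]:
            quota[b] += 1
    pool_index = np.asarray(pool_values.index)
    by_bin = [np.flatnonzero(pool_bins == b) for b in range(cfg.n_bins)]

    bin_centers = np.array([
        np.median(target[target_bins == b]) if (target_bins == b).any()
        else 0.5 * (edges[b] if np.isfinite(edges[b]) else edges[b + 1])
        for b in range(cfg.n_bins)])

    for _ in range(cfg.max_proposals_per_iteration):
        chosen: list[int] = []
        deficits: list[int] = []  # bins still owed a gene
        for b in range(cfg.n_bins):
            have = by_bin[b]
            take = min(quota[b], len(have))
            if take:
                chosen.extend(rng.choice(have, size=take, replace=False))
            deficits.extend([b] * (quota[b] - take))
        if deficits:
            # fill shortfalls with the unchosen pool genes nearest in value
            # to the deficient bins, keeping the match as tight as possible
            free = np.setdiff1d(np.arange(len(pool_index)),
                                np.asarray(chosen, dtype=int))
            for b in deficits:
                j = int(np.argmin(np.abs(pool_values.values[free]
                                         - bin_centers[b])))
                chosen.append(int(free[j]))
                free = np.delete(free, j)
        sample_vals = pool_values.values[np.asarray(chosen, dtype=int)]
        if stats.ks_2samp(sample_vals, target).pvalue > cfg.match_ks_alpha:
            return [str(g) for g in pool_index[np.asarray(chosen, dtype=int)]]
    raise OlfscreenError(
        f"no matched control set accepted within "
        f"{cfg.max_proposals_per_iteration} proposals")


def pairwise_set_correlation(m: ExpressionMatrix, genes: Sequence[str],
                             sample_a: str, sample_b: str) -> float:
    """Pearson r of log10 FPKM between two samples over a gene set."""
    if len(genes) < 3:
        raise OlfscreenError("need >= 3 genes for a correlation")
    logv = m.log10(genes=genes, samples=[sample_a, sample_b])
    x, y = logv.values[:, 0], logv.values[:, 1]
    if x.std() == 0 or y.std() == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def reference_expression(m: ExpressionMatrix, genes: Sequence[str],
                         sample_a: str, sample_b: str) -> pd.Series:
    """Matching covariate: mean log10 FPKM over the two compared samples."""
    return m.log10(genes=genes, samples=[sample_a, sample_b]).mean(axis=1)


def resampling_test(m: ExpressionMatrix, or_genes: Sequence[str],
                    control_pool: Sequence[str],
                    sample_a: str, sample_b: str,
                    cfg: ResamplingConfig | None = None) -> ResamplingOutcome:
    """One-sided matched-resampling test: is the OR set's pair correlation
    lower than that of expression-matched control sets?

    empirical_p = (1 + #{null r <= observed r}) / (n_iterations + 1); with a
    zero count the p is additionally reported as the "< 1/(n+1)" string.
    """
    cfg = cfg or ResamplingConfig()
    m.require_floored()
    rng = np.random.default_rng(cfg.seed)
    or_genes = list(or_genes)
    observed_r = pairwise_set_correlation(m, or_genes, sample_a, sample_b)
    target_ref = reference_expression(m, or_genes, sample_a, sample_b)
    pool = [g for g in control_pool if g not in set(or_genes)]
    pool_ref = reference_expression(m, pool, sample_a, sample_b)

    null_rs = np.empty(cfg.n_iterations)
    for i in range(cfg.n_iterations):
        genes = matched_control_sample(
            pool_ref, target_ref, len(or_genes), cfg, rng=rng)
        null_rs[i] = pairwise_set_correlation(m, genes, sample_a, sample_b)
    n_below = int((null_rs <= observed_r).sum())
    p = (1 + n_below) / (cfg.n_iterations + 1)
    if n_below == 0:
        p_string = f"<{1.0 / (cfg.n_iterations + 1):.4g}"
    else:
        p_string = f"{p:.4g}"
    return ResamplingOutcome(
        observed_r=observed_r, null_rs=null_rs, empirical_p=p,
        p_string=p_string, n_matched_genes=len(or_genes))


def default_control_pool(m: ExpressionMatrix, or_genes: Sequence[str],
                         samples: Sequence[str],
                         cutoff: float = 0.01) -> list[str]:
    """Default pool: non-OR genes expressed (>= cutoff) in all compared
    samples."""
    m.require_floored()
    ors = set(or_genes)
    sub = m.values[list(samples)]
    keep = (sub >= cutoff).all(axis=1)
    return [g for g in m.gene_ids[keep] if g not in ors]
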