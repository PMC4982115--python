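"""Marker-based sample QC and tissue-by-tissue expression correlation.

Biopsies of olfactory epithelium are variably contaminated with respiratory
epithelium; a sample passes QC when olfactory markers (OMP, CNGA2, GNAL,
RTP1) dominate respiratory markers (KRT13, TMPRSS11D) on the log10-FPKM
scale.  The correlation analysis compares samples as vectors of log10 FPKM
over a shared gene subset.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .types import ExpressionMatrix, OlfscreenError


@dataclass
class MarkerPanel:
    olfactory_markers: tuple[str, ...] = ("OMP", "CNGA2", "GNAL", "RTP1")
    respiratory_markers: tuple[str, ...] = ("KRT13", "TMPRSS11D")

    def __post_init__(self) -> None:
        if not self.olfactory_markers or not self.respiratory_markers:
            raise OlfscreenError("marker panels must be non-empty")
        if set(self.olfactory_markers) & set(self.respiratory_markers):
            raise OlfscreenError("marker panels must be disjoint")


def _resolve_markers(m: ExpressionMatrix, markers: Sequence[str]) -> list[str]:
    missing = [g for g in markers if g not in m.gene_ids]
    if missing:
        raise OlfscreenError(f"marker genes absent from matrix: {missing}")
    return list(markers)


def marker_qc_score(m: ExpressionMatrix, panel: MarkerPanel,
                    sample: str) -> float:
    """Mean log10 FPKM over olfactory markers minus the respiratory mean."""
    m.require_floored()
    olf = _resolve_markers(m, panel.olfactory_markers)
    resp = _resolve_markers(m, panel.respiratory_markers)
    col = np.log10(m.values[sample])
    return float(col.loc[olf].mean() - col.loc[resp].mean())


def marker_qc_pass(m: ExpressionMatrix, panel: MarkerPanel, sample: str,
                   score_threshold: float = 0.0,
                   marker_fpkm_cutoff: float = 1.0) -> bool:
    """Pass iff the score clears the threshold and every olfactory marker is
    itself expressed at >= the cutoff."""
    score = marker_qc_score(m, panel, sample)
    olf = _resolve_markers(m, panel.olfactory_markers)
    expressed = (m.values.loc[olf, sample] >= marker_fpkm_cutoff).all()
    return bool(score > score_threshold and expressed)


def tissue_correlation_matrix(m: ExpressionMatrix,
                              gene_subset: Sequence[str] | None = None
                              ) -> pd.DataFrame:
    """Pairwise Pearson r between samples on log10 floored FPKM.

    Symmetric with unit diagonal; a sample with zero variance over the gene
    subset correlates as NaN (undefined) against every other sample.
    """
    m.require_floored()
    if len(m.sample_ids) < 2:
        raise OlfscreenError("need >=2 samples for a correlation matrix")
    if gene_subset is not None:
        if len(gene_subset) == 0:
            raise OlfscreenError("gene subset is empty")
        logv = m.log10(genes=gene_subset)
    else:
        logv = m.log10()
    X = logv.values
    sd = X.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(X, rowvar=False)
    corr[sd == 0, :] = np.nan
    corr[:, sd == 0] = np.nan
    np.fill_diagonal(corr, 1.0)
    return pd.DataFrame(corr, index=m.sample_ids, columns=m.sample_ids)


def genes_expressed_everywhere(m: ExpressionMatrix,
                               cutoff: float = 0.01) -> list[str]:
    """Default gene subset for the correlation analysis: genes at or above
    the expressed cutoff in every sample."""
    m.require_floored()
    keep = (m.values >= cutoff).all(axis=1)
    return list(m.gene_ids[keep])
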