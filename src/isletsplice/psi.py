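"""Percent-spliced-in (psi) quantification from junction counts, with QC filters.

The inclusion of a cassette exon is supported by two splice junctions while
skipping is supported by one, so inclusion reads are halved before
normalization:

    psi = (I/2) / (I/2 + S)

A cell/event entry is quantifiable only when its total junction coverage
``I + S`` reaches ``min_junction_coverage`` (default 20 reads); entries below
that are recorded as missing in the :class:`~isletsplice.io.PsiMatrix` mask.
Cells are kept when their detected-gene count (counts > 0) lies in
[2500, 10000] (boundaries inclusive: removal applies strictly below/above),
and events are retained when quantifiable in at least 10% of cells.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import JunctionCounts, PsiMatrix, ValidationError

__all__ = ["QcThresholds", "compute_psi", "quantify_matrix", "qc_cells",
           "filter_exons"]


@dataclass(frozen=True)
class QcThresholds:
    """Cell- and event-level quality-control thresholds."""

    min_genes_per_cell: int = 2500
    max_genes_per_cell: int = 10000
    min_junction_coverage: int = 20
    min_cell_fraction: float = 0.10

    def __post_init__(self):
        if not 0 < self.min_genes_per_cell < self.max_genes_per_cell:
            raise ValidationError("require 0 < min_genes < max_genes")
        if self.min_junction_coverage < 1:
            raise ValidationError("min_junction_coverage must be >= 1")
        if not 0 < self.min_cell_fraction <= 1:
            raise ValidationError("min_cell_fraction must be in (0, 1]")


def compute_psi(I, S, min_cov: int = 20):
    """Exon inclusion level from junction reads; NaN where coverage < min_cov.

    Accepts scalars or arrays.  ``I`` is the summed read count on the two
    inclusion junctions, ``S`` the skipping-junction count.
    """
    I = np.asarray(I, dtype=float)
    S = np.asarray(S, dtype=float)
    if (I < 0).any() or (S < 0).any():
        raise ValidationError("junction counts must be non-negative")
    half = I / 2.0
    with np.errstate(invalid="ignore", divide="ignore"):
        psi = half / (half + S)
    psi = np.where(I + S >= min_cov, psi, np.nan)
    if psi.ndim == 0:
        return float(psi)
    return psi


def quantify_matrix(counts: JunctionCounts,
                    thresholds: QcThresholds = QcThresholds()) -> PsiMatrix:
    """Elementwise psi for a whole cells x events junction-count matrix."""
    psi = compute_psi(counts.I, counts.S,
                      min_cov=thresholds.min_junction_coverage)
    observed = ~np.isnan(psi)
    return PsiMatrix(list(counts.cells), list(counts.events), psi, observed)


def qc_cells(expression: pd.DataFrame,
             thresholds: QcThresholds = QcThresholds()) -> list:
    """Cells passing the detected-gene QC window.

    ``expression`` is a cells x genes count matrix.  A gene is detected in a
    cell when its count is > 0; cells expressing fewer than
    ``min_genes_per_cell`` or more than ``max_genes_per_cell`` genes are
    removed (boundary values are kept).
    """
    detected = (expression.to_numpy() > 0).sum(axis=1)
    keep = ((detected >= thresholds.min_genes_per_cell)
            & (detected <= thresholds.max_genes_per_cell))
    return [c for c, k in zip(expression.index, keep) if k]


def filter_exons(psi: PsiMatrix,
                 thresholds: QcThresholds = QcThresholds()) -> PsiMatrix:
    """Restrict to events quantifiable in >= ``min_cell_fraction`` of cells."""
    frac = psi.observed.mean(axis=0)
    keep = frac >= thresholds.min_cell_fraction
    if not keep.any():
        warnings.warn("no events pass the quantifiability filter")
    events = [e for e, k in zip(psi.events, keep) if k]
    return PsiMatrix(list(psi.cells), events,
                     psi.psi[:, keep], psi.observed[:, keep])
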