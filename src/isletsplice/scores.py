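"""Expression normalization, gene-set module scores and KS comparisons.

Module scores follow the binned-control procedure used throughout
single-cell analysis: genes are binned by dataset-average normalized
expression, each gene-set gene draws ``n_ctrl`` control genes (with
replacement) from its bin, and a cell's score is the mean normalized
expression over the gene set minus the mean over the pooled controls.  The
expression-matched controls make the score robust to per-cell depth and
global shifts.  Group contrasts (e.g. maturity across splicing clusters in
ND vs T2D) are assessed with the two-sample Kolmogorov-Smirnov test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import ValidationError

__all__ = ["ModuleScoreResult", "KsResult", "log_normalize", "module_score",
           "ks_two_sample", "score_report"]


@dataclass
class ModuleScoreResult:
    """Per-cell module scores plus the parameters that produced them."""

    scores: pd.Series
    params: dict = field(default_factory=dict)


@dataclass(frozen=True)
class KsResult:
    statistic: float
    pvalue: float


def log_normalize(counts: pd.DataFrame, scale: float = 10000.0) -> pd.DataFrame:
    """Depth-normalize and log-transform a cells x genes count matrix.

    Per cell: divide by the cell total, multiply by ``scale``, then
    ``log(1 + x)``.  Zero-total cells are excluded with a warning.
    """
    arr = counts.to_numpy(dtype=float)
    if (arr < 0).any():
        raise ValidationError("expression counts must be non-negative")
    totals = arr.sum(axis=1)
    empty = totals == 0
    if empty.any():
        warnings.warn(f"excluding {int(empty.sum())} zero-total cell(s)")
        arr, totals = arr[~empty], totals[~empty]
        index = counts.index[~empty]
    else:
        index = counts.index
    norm = np.log1p(arr / totals[:, None] * scale)
    return pd.DataFrame(norm, index=index, columns=counts.columns)


def module_score(normexpr: pd.DataFrame, geneset: Sequence[str],
                 n_bins: int = 24, n_ctrl: int = 100,
                 seed: int = 0) -> ModuleScoreResult:
    """Expression-bin-matched control score of a gene set, per cell.

    Genes are cut into ``n_bins`` equal-size bins by their dataset-average
    normalized expression; each gene-set gene samples ``n_ctrl`` control
    genes with replacement from its bin.  Score = mean over gene-set genes
    minus mean over the pooled control draws.  Deterministic given ``seed``.
    """
    present = [g for g in geneset if g in normexpr.columns]
    if not present:
        raise ValidationError("gene set has no genes in the expression matrix")
    rng = np.random.default_rng(seed)
    avg = normexpr.mean(axis=0)
    order = avg.rank(method="first")
    bins = pd.cut(order, bins=n_bins, labels=False)
    genes_by_bin = {b: np.asarray(idx)
                    for b, idx in pd.Series(normexpr.columns,
                                            index=bins.values).groupby(level=0)}
    ctrl_genes = []
    for g in present:
        pool = genes_by_bin[bins[g]]
        ctrl_genes.extend(pool[rng.integers(len(pool), size=n_ctrl)])
    set_mean = normexpr[present].mean(axis=1)
    ctrl_mean = normexpr[ctrl_genes].mean(axis=1)
    scores = set_mean - ctrl_mean
    return ModuleScoreResult(scores, params={
        "geneset": list(present), "n_bins": n_bins, "n_ctrl": n_ctrl,
        "seed": seed})


def ks_two_sample(a, b) -> KsResult:
    """Two-sample Kolmogorov-Smirnov test (asymptotic p).

    D is the supremum distance between the empirical CDFs; D = 0 iff the
    empirical distributions coincide.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValidationError("each sample needs >= 2 values")
    res = stats.ks_2samp(a, b, method="asymp")
    return KsResult(float(res.statistic), float(min(res.pvalue, 1.0)))


def score_report(scores: pd.Series, cell_table: pd.DataFrame,
                 grouping: str) -> pd.DataFrame:
    """Per-group score summaries plus pairwise KS tests.

    ``grouping`` names a column of ``cell_table`` (indexed by cell id).
    Groups with fewer than 2 scored cells are dropped with a warning.
    Returns a table with one ``summary`` row per group (median and IQR) and
    one ``ks`` row per group pair (D and p).
    """
    if grouping not in cell_table.columns:
        raise ValidationError(f"grouping column {grouping!r} not in cell table")
    groups = {}
    for name, sub in cell_table.groupby(grouping, sort=True):
        vals = scores.reindex(sub.index).dropna().to_numpy()
        if vals.size < 2:
            warnings.warn(f"group {name!r} has {vals.size} scored cell(s); dropped")
            continue
        groups[name] = vals
    rows = []
    for name, vals in groups.items():
        q1, med, q3 = np.percentile(vals, [25, 50, 75])
        rows.append({"kind": "summary", "group_a": name, "group_b": "",
                     "n": vals.size, "median": med, "iqr": q3 - q1,
                     "D": np.nan, "p": np.nan})
    for ga, gb in combinations(groups, 2):
        ks = ks_two_sample(groups[ga], groups[gb])
        rows.append({"kind": "ks", "group_a": ga, "group_b": gb,
                     "n": groups[ga].size + groups[gb].size,
                     "median": np.nan, "iqr": np.nan,
                     "D": ks.statistic, "p": ks.pvalue})
    return pd.DataFrame(rows)
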