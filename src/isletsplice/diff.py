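"""Differential cassette-exon splicing and signature-gene expression testing.

Splicing is compared between two cell groups on pseudo-bulk junction counts:
reads are pooled within each group, inclusion reads are halved (two
supporting junctions) and rounded half-up, and the resulting 2x2 table

    [round(I_A/2), S_A; round(I_B/2), S_B]

is tested with a two-sided Fisher exact test.  Events enter the test family
only when quantifiable (per-cell coverage >= ``min_cov``) in at least
``min_frac`` of the cells of *both* groups and pooled coverage passes in
both; p-values are corrected by Benjamini-Hochberg over the tested family.
An event is called ``included`` when ``delta_psi > dpsi`` and ``q < alpha``,
``skipped`` when ``delta_psi < -dpsi`` and ``q < alpha``, else ``ns``.

Signature genes are tested per gene with a Wilcoxon rank-sum test on
log-normalized expression, Bonferroni-adjusted, and called at
``log2FC > 0.25`` and adjusted p < 0.05.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

from .io import JunctionCounts, ValidationError

__all__ = ["fisher_exact_two_sided", "pooled_group_psi", "diff_test",
           "one_vs_rest", "signature_genes", "splice_expression_overlap"]

# relative slack when collecting probability ties in the two-sided sum;
# hypergeometric pmfs computed in floating point can differ by ~1e-15 for
# exactly tied tables
_TIE_REL = 1e-10


def _log_binom(n, k):
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def fisher_exact_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the 2x2 table [[a, b], [c, d]].

    The p-value sums the hypergeometric probabilities of all tables with the
    observed margins whose probability does not exceed the observed table's
    (the standard "method of small p-values").
    """
    if min(a, b, c, d) < 0:
        raise ValidationError("table entries must be non-negative")
    n_total = a + b + c + d
    if n_total == 0:
        return 1.0
    row1 = a + b
    col1 = a + c
    lo = max(0, col1 - (n_total - row1))
    hi = min(row1, col1)
    support = np.arange(lo, hi + 1)
    # hypergeometric pmf over the full support via log-gamma (fast and
    # accurate enough for exact tie detection at _TIE_REL)
    logpmf = (_log_binom(row1, support) + _log_binom(n_total - row1,
                                                     col1 - support)
              - _log_binom(n_total, col1))
    pmf = np.exp(logpmf)
    p_obs = pmf[a - lo]
    return float(min(1.0, pmf[pmf <= p_obs * (1.0 + _TIE_REL)].sum()))


def _pool(counts: JunctionCounts, cell_ids: Sequence[str]):
    pos = {cid: i for i, cid in enumerate(counts.cells)}
    missing = [cid for cid in cell_ids if cid not in pos]
    if missing:
        raise ValidationError(f"unknown cells: {missing[:5]}")
    rows = [pos[cid] for cid in cell_ids]
    return counts.I[rows], counts.S[rows]


def pooled_group_psi(counts: JunctionCounts, cell_ids: Sequence[str],
                     min_cov: int = 20):
    """Group-pooled junction counts and psi per event.

    Returns ``(I_g, S_g, psi_g)`` arrays over events; ``psi_g`` is NaN where
    pooled coverage ``I_g + S_g`` falls below ``min_cov``.
    """
    if len(cell_ids) == 0:
        raise ValidationError("empty cell group")
    I, S = _pool(counts, cell_ids)
    I_g = I.sum(axis=0)
    S_g = S.sum(axis=0)
    half = I_g / 2.0
    with np.errstate(invalid="ignore", divide="ignore"):
        psi_g = np.where(I_g + S_g >= min_cov, half / (half + S_g), np.nan)
    return I_g, S_g, psi_g


def diff_test(counts: JunctionCounts, group_a: Sequence[str],
              group_b: Sequence[str], min_cov: int = 20,
              min_frac: float = 0.10, dpsi: float = 0.1,
              alpha: float = 0.05, per_cell_delta: bool = False) -> pd.DataFrame:
    """Differential splicing table for group B versus group A.

    ``delta_psi`` is reported as ``psi_B - psi_A`` on pooled counts (set
    ``per_cell_delta`` to additionally report the difference of per-cell mean
    psi).  Returns one row per event; untested events carry NaN p/q and call
    ``ns``.
    """
    set_a, set_b = set(group_a), set(group_b)
    if set_a & set_b:
        raise ValidationError("groups must be disjoint")
    if not group_a or not group_b:
        raise ValidationError("both groups must be non-empty")

    I_a, S_a = _pool(counts, list(group_a))
    I_b, S_b = _pool(counts, list(group_b))
    quant_a = ((I_a + S_a) >= min_cov).mean(axis=0)
    quant_b = ((I_b + S_b) >= min_cov).mean(axis=0)
    Ia, Sa = I_a.sum(axis=0), S_a.sum(axis=0)
    Ib, Sb = I_b.sum(axis=0), S_b.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        psi_a = (Ia / 2) / (Ia / 2 + Sa)
        psi_b = (Ib / 2) / (Ib / 2 + Sb)
    tested = ((quant_a >= min_frac) & (quant_b >= min_frac)
              & (Ia + Sa >= min_cov) & (Ib + Sb >= min_cov))

    n_events = len(counts.events)
    p = np.full(n_events, np.nan)
    for j in np.flatnonzero(tested):
        p[j] = fisher_exact_two_sided(
            int(np.floor(Ia[j] / 2 + 0.5)), int(Sa[j]),
            int(np.floor(Ib[j] / 2 + 0.5)), int(Sb[j]))
    q = np.full(n_events, np.nan)
    if tested.any():
        q[tested] = multipletests(p[tested], method="fdr_bh")[1]

    delta = psi_b - psi_a
    call = np.where(tested & (q < alpha) & (delta > dpsi), "included",
                    np.where(tested & (q < alpha) & (delta < -dpsi),
                             "skipped", "ns"))
    table = pd.DataFrame({
        "event_id": counts.events,
        "I_A": Ia, "S_A": Sa, "I_B": Ib, "S_B": Sb,
        "psi_A": psi_a, "psi_B": psi_b, "delta_psi": delta,
        "frac_quant_A": quant_a, "frac_quant_B": quant_b,
        "tested": tested, "p": p, "q": q, "call": call,
    }).set_index("event_id", drop=False)
    if per_cell_delta:
        with np.errstate(invalid="ignore", divide="ignore"):
            pa = np.where(I_a + S_a >= min_cov,
                          (I_a / 2) / (I_a / 2 + S_a), np.nan)
            pb = np.where(I_b + S_b >= min_cov,
                          (I_b / 2) / (I_b / 2 + S_b), np.nan)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            table["delta_psi_cellmean"] = (np.nanmean(pb, axis=0)
                                           - np.nanmean(pa, axis=0))
    return table


def one_vs_rest(counts: JunctionCounts, labels: Mapping[str, str],
                **kwargs) -> dict:
    """Per-label differential splicing of each label's cells against the rest.

    ``labels`` maps cell_id -> label.  Direction is label minus rest
    (``delta_psi = psi_label - psi_rest``).  Singleton label groups are
    skipped with a warning.
    """
    by_label = {}
    for cid, lab in labels.items():
        by_label.setdefault(lab, []).append(cid)
    if len(by_label) < 2:
        raise ValidationError("one-vs-rest needs at least two labels")
    out = {}
    for lab, members in by_label.items():
        if len(members) < 2:
            warnings.warn(f"label {lab!r} has {len(members)} cell(s); skipped")
            continue
        rest = [cid for cid in labels if labels[cid] != lab]
        out[lab] = diff_test(counts, rest, members, **kwargs)
    return out


def signature_genes(normexpr: pd.DataFrame, group: Sequence[str],
                    rest: Sequence[str], lfc_threshold: float = 0.25,
                    alpha: float = 0.05,
                    pseudocount: float = 1e-9) -> pd.DataFrame:
    """Signature genes of ``group`` versus ``rest`` on log-normalized expression.

    Per gene: two-sided Wilcoxon rank-sum p, Bonferroni adjustment over the
    tested genes, and ``log2fc`` of group means of normalized expression.
    A gene is called ``signature`` when ``log2fc > lfc_threshold`` and the
    adjusted p is below ``alpha``.
    """
    if not group or not rest:
        raise ValidationError("both groups must be non-empty")
    A = normexpr.loc[list(group)].to_numpy()
    B = normexpr.loc[list(rest)].to_numpy()
    mean_a, mean_b = A.mean(axis=0), B.mean(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        log2fc = np.log2((mean_a + pseudocount) / (mean_b + pseudocount))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = stats.mannwhitneyu(A, B, axis=0, alternative="two-sided",
                                 method="asymptotic")
    p = np.asarray(res.pvalue, dtype=float)
    p[~np.isfinite(p)] = 1.0    # zero-variance genes: no evidence
    p_adj = np.minimum(p * p.size, 1.0)
    call = np.where((log2fc > lfc_threshold) & (p_adj < alpha),
                    "signature", "ns")
    return pd.DataFrame({"gene": normexpr.columns, "log2fc": log2fc,
                         "p": p, "p_adj": p_adj, "call": call}
                        ).set_index("gene", drop=False)


def splice_expression_overlap(splice: pd.DataFrame, expr: pd.DataFrame,
                              gene_map: Mapping[str, str] | None = None) -> dict:
    """Overlap and rank correlation between splicing and expression changes.

    ``splice`` is a :func:`diff_test` table (a ``gene`` column may be present
    or supplied through ``gene_map`` event_id -> gene); ``expr`` is a
    :func:`signature_genes` table.  Reports Venn-style counts of called genes
    and the Spearman correlation between per-gene ``delta_psi`` (mean over a
    gene's tested events) and ``log2fc`` across all shared tested genes.
    """
    splice = splice.copy()
    if "gene" not in splice.columns:
        if gene_map is None:
            raise ValidationError("splice table lacks a gene column; "
                                  "provide gene_map")
        splice["gene"] = [gene_map[e] for e in splice["event_id"]]
    tested = splice[splice["tested"]]
    per_gene = tested.groupby("gene")["delta_psi"].mean()
    shared = per_gene.index.intersection(expr.index)
    if len(shared) == 0:
        warnings.warn("no genes shared between splicing and expression tables")
        return {"n_shared": 0, "n_splice_only": 0, "n_expr_only": 0,
                "n_both": 0, "spearman_rho": np.nan, "spearman_p": np.nan}
    rho, rho_p = stats.spearmanr(per_gene.loc[shared].to_numpy(),
                                 expr.loc[shared, "log2fc"].to_numpy())
    splice_called = set(tested.loc[tested["call"] != "ns", "gene"])
    expr_called = set(expr.loc[expr["call"] != "ns", "gene"])
    return {
        "n_shared": int(len(shared)),
        "n_splice_only": len(splice_called - expr_called),
        "n_expr_only": len(expr_called - splice_called),
        "n_both": len(splice_called & expr_called),
        "spearman_rho": float(rho),
        "spearman_p": float(rho_p),
    }
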