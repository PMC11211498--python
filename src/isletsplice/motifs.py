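"""Positional RBP-motif enrichment maps around cassette exons (RNA maps).

For each motif and each of the four regions around a cassette exon
(upstream intron, exon 5' end, exon 3' end, downstream intron) a positional
profile is computed: per sequence, a sliding window score equal to the
fraction of window bases covered by at least one motif match; per position,
the mean over sequences.  Target (regulated) and background (unregulated)
event sets are compared position-by-position with a two-sided Wilcoxon
rank-sum test (normal approximation with tie correction).  A motif is called
enriched when the minimum p over positions is < 0.05 in at least one region
and the maximum mean target score exceeds 0.01 in at least one region.

Position conventions: intron windows are indexed relative to the adjacent
exon boundary (upstream-intron positions are negative and right-aligned at
the 3' splice site; downstream-intron positions start at 0 at the 5' splice
site).  Truncated sequences are aligned at the exon-proximal edge; sequences
shorter than the window are skipped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import IUPAC_CODES, REGIONS, MotifDef, ValidationError

__all__ = ["MotifMap", "scan_motif", "positional_profile", "compare_profiles",
           "motif_map", "enriched_rbps"]

#: alignment of each region's windows at the exon-proximal edge
REGION_ALIGN = {"upstream_intron": "right", "exon5": "left",
                "exon3": "right", "downstream_intron": "left"}
DEFAULT_REGION_LENGTHS = {"upstream_intron": 250, "exon5": 50,
                          "exon3": 50, "downstream_intron": 250}


def _lookup_tables(pattern: str):
    """Per-pattern-position boolean lookup over ASCII codes."""
    tables = np.zeros((len(pattern), 128), dtype=bool)
    for i, letter in enumerate(pattern.upper()):
        if letter not in IUPAC_CODES:
            raise ValidationError(f"invalid IUPAC letter {letter!r} in pattern")
        for base in IUPAC_CODES[letter]:
            tables[i, ord(base)] = True
    return tables


def scan_motif(seq: str, pattern: str):
    """All (overlapping) matches of an IUPAC pattern on the given strand.

    Returns ``(starts, coverage)``: 0-based match start positions and a
    boolean per-base mask marking every base under at least one match.
    A sequence ``N`` matches only the pattern letter ``N``.
    """
    tables = _lookup_tables(pattern)
    m, L = len(pattern), len(seq)
    coverage = np.zeros(L, dtype=bool)
    if L < m:
        return np.empty(0, dtype=int), coverage
    codes = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    ok = np.ones(L - m + 1, dtype=bool)
    for j in range(m):
        ok &= tables[j][codes[j:j + L - m + 1]]
    starts = np.flatnonzero(ok)
    for s in starts:
        coverage[s:s + m] = True
    return starts, coverage


def _window_scores(seq: str, pattern: str, window: int, region_length: int,
                   align: str) -> np.ndarray:
    """Sliding-window coverage fractions, NaN-padded to the region grid."""
    n_pos = region_length - window + 1
    out = np.full(n_pos, np.nan)
    if len(seq) > region_length:
        # keep the exon-proximal end of an over-long sequence
        seq = seq[-region_length:] if align == "right" else seq[:region_length]
    L = len(seq)
    if L < window:
        return out
    _, cov = scan_motif(seq, pattern)
    csum = np.concatenate([[0], np.cumsum(cov)])
    scores = (csum[window:] - csum[:-window]) / window   # length L-window+1
    k = scores.size
    if align == "right":
        out[n_pos - k:] = scores
    else:
        out[:k] = scores
    return out


def positional_profile(regions: pd.DataFrame, pattern: str, window: int = 50,
                       region_lengths: Mapping[str, int] | None = None) -> dict:
    """Per-sequence positional window scores for each of the four regions.

    ``regions`` is the DataFrame produced by
    :func:`~isletsplice.io.extract_flanking_regions`.  Returns a dict
    region -> (n_sequences x n_positions) array; position axes are
    right-aligned at the exon boundary for ``upstream_intron``/``exon3`` and
    left-aligned for the other two, so truncated sequences stay anchored at
    the exon-proximal edge.  Sequences shorter than the window contribute
    NaN rows (skipped with a warning).
    """
    if len(regions) == 0:
        raise ValidationError("empty region set")
    lengths = dict(DEFAULT_REGION_LENGTHS)
    if region_lengths:
        lengths.update(region_lengths)
    out = {}
    n_short = 0
    for region in REGIONS:
        mats = []
        for seq in regions[region]:
            if len(seq) < window:
                n_short += 1
            mats.append(_window_scores(seq, pattern, window,
                                       lengths[region], REGION_ALIGN[region]))
        out[region] = np.vstack(mats)
    if n_short:
        warnings.warn(f"{n_short} region sequences shorter than the window "
                      "were skipped")
    return out


@dataclass
class MotifMap:
    """Positional enrichment map of one motif over the four regions."""

    motif: str
    rbp_gene: str = ""
    target_mean: dict = field(default_factory=dict)   # region -> positions
    background_mean: dict = field(default_factory=dict)
    p_values: dict = field(default_factory=dict)
    positions: dict = field(default_factory=dict)     # region -> int offsets

    def region_min_p(self) -> dict:
        out = {}
        for region, p in self.p_values.items():
            finite = p[np.isfinite(p)]
            out[region] = float(finite.min()) if finite.size else np.nan
        return out

    def region_max_score(self) -> dict:
        out = {}
        for region, s in self.target_mean.items():
            finite = s[np.isfinite(s)]
            out[region] = float(finite.max()) if finite.size else np.nan
        return out

    @property
    def min_p(self) -> float:
        vals = [v for v in self.region_min_p().values() if np.isfinite(v)]
        return float(min(vals)) if vals else np.nan

    @property
    def max_mean_score(self) -> float:
        vals = [v for v in self.region_max_score().values() if np.isfinite(v)]
        return float(max(vals)) if vals else np.nan


def _rank_sum_p(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided rank-sum p (normal approximation, tie-corrected)."""
    a = a[np.isfinite(a)]
    b = b[np.isfinite(b)]
    if a.size < 2 or b.size < 2:
        return np.nan
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        return 1.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        p = stats.mannwhitneyu(a, b, alternative="two-sided",
                               method="asymptotic").pvalue
    return 1.0 if not np.isfinite(p) else float(p)


def _position_axis(region: str, n_pos: int, window: int) -> np.ndarray:
    # window start offsets relative to the exon boundary of the region
    if REGION_ALIGN[region] == "right":
        return np.arange(-n_pos - window + 1, -window + 1)
    return np.arange(n_pos)


def compare_profiles(target: dict, background: dict, motif: str = "",
                     rbp_gene: str = "", window: int = 50,
                     min_sequences: int = 5) -> MotifMap:
    """Position-wise comparison of target vs background window scores.

    Both arguments are outputs of :func:`positional_profile`.  Requires at
    least ``min_sequences`` sequences on each side.
    """
    mm = MotifMap(motif=motif, rbp_gene=rbp_gene)
    for region in REGIONS:
        t, b = target[region], background[region]
        if t.shape[0] < min_sequences or b.shape[0] < min_sequences:
            raise ValidationError(
                f"need >= {min_sequences} sequences per set (region {region})")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            mm.target_mean[region] = np.nanmean(t, axis=0)
            mm.background_mean[region] = np.nanmean(b, axis=0)
        mm.p_values[region] = np.array(
            [_rank_sum_p(t[:, j], b[:, j]) for j in range(t.shape[1])])
        mm.positions[region] = _position_axis(region, t.shape[1], window)
    return mm


def motif_map(target_regions: pd.DataFrame, background_regions: pd.DataFrame,
              motif: MotifDef, window: int = 50) -> MotifMap:
    """Convenience wrapper: profiles plus comparison for one motif."""
    t = positional_profile(target_regions, motif.pattern, window=window)
    b = positional_profile(background_regions, motif.pattern, window=window)
    return compare_profiles(t, b, motif=motif.name, rbp_gene=motif.rbp_gene,
                            window=window)


def enriched_rbps(maps: Sequence[MotifMap], p_threshold: float = 0.05,
                  score_threshold: float = 0.01) -> pd.DataFrame:
    """Enrichment calls over a list of motif maps sharing one background.

    A motif is enriched when min p < ``p_threshold`` in at least one region
    and max mean target score > ``score_threshold`` in at least one region;
    the best region is the one with the smallest p.
    """
    rows = []
    for mm in maps:
        min_ps = mm.region_min_p()
        max_scores = mm.region_max_score()
        p_ok = any(np.isfinite(v) and v < p_threshold for v in min_ps.values())
        s_ok = any(np.isfinite(v) and v > score_threshold
                   for v in max_scores.values())
        finite = {r: v for r, v in min_ps.items() if np.isfinite(v)}
        best = min(finite, key=finite.get) if finite else ""
        rows.append({"motif": mm.motif, "rbp_gene": mm.rbp_gene,
                     "enriched": bool(p_ok and s_ok), "best_region": best,
                     "min_p": mm.min_p, "max_mean_score": mm.max_mean_score})
    return pd.DataFrame(rows)
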