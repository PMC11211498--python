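"""IUPAC motif scanning and positional enrichment maps."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from isletsplice import (MotifDef, scan_motif, positional_profile,
                         compare_profiles, motif_map, enriched_rbps)
from isletsplice.io import IUPAC_CODES, REGIONS, ValidationError
from isletsplice.motifs import MotifMap, _window_scores


def brute_force_scan(seq, pattern):
    """Oracle: explicit IUPAC expansion, position by position."""
    starts = []
    for s in range(len(seq) - len(pattern) + 1):
        if all(seq[s + j] in IUPAC_CODES[pattern[j]]
               for j in range(len(pattern))):
            starts.append(s)
    return starts


class TestScanMotif:
    def test_hnrnph2_motif_match_and_coverage(self):
        starts, cov = scan_motif("AAGGGAGGGAA", "GGGAGGG")
        assert list(starts) == [2]
        assert list(np.flatnonzero(cov)) == [2, 3, 4, 5, 6, 7, 8]

    def test_fxr1_motif_at_origin(self):
        starts, _ = scan_motif("ATGACA", "ATGACA")
        assert list(starts) == [0]

    def test_degenerate_letters(self):
        starts, _ = scan_motif("AT", "RY")   # A in R, T in Y
        assert list(starts) == [0]

    def test_sequence_n_only_matches_pattern_n(self):
        assert len(scan_motif("ANA", "AAA")[0]) == 0
        assert len(scan_motif("ANA", "ANA")[0]) == 1

    def test_overlapping_matches_reported(self):
        starts, cov = scan_motif("AAAA", "AA")
        assert list(starts) == [0, 1, 2]
        assert cov.all()

    def test_invalid_pattern_rejected(self):
        with pytest.raises(ValidationError, match="IUPAC"):
            scan_motif("ACGT", "AXG")

    @given(st.text(alphabet="ACGTN", min_size=0, max_size=40),
           st.text(alphabet="ACGTRYSWKMBDHVN", min_size=1, max_size=6))
    @settings(max_examples=300, derandomize=True, deadline=None)
    def test_matches_brute_force_oracle(self, seq, pattern):
        starts, cov = scan_motif(seq, pattern)
        expected = brute_force_scan(seq, pattern)
        assert list(starts) == expected
        oracle_cov = np.zeros(len(seq), bool)
        for s in expected:
            oracle_cov[s:s + len(pattern)] = True
        assert (cov == oracle_cov).all()


class TestPositionalProfile:
    def _regions(self, upstream_seqs):
        n = len(upstream_seqs)
        return pd.DataFrame({
            "upstream_intron": upstream_seqs,
            "exon5": ["A" * 50] * n, "exon3": ["A" * 50] * n,
            "downstream_intron": ["A" * 250] * n,
        }, index=[f"E{i}" for i in range(n)])

    def test_saturated_sequences_score_one(self):
        prof = positional_profile(self._regions(["G" * 250] * 3), "GG")
        assert np.nanmin(prof["upstream_intron"]) == 1.0

    def test_absent_motif_scores_zero(self):
        prof = positional_profile(self._regions(["A" * 250] * 3), "GGG")
        assert np.nanmax(prof["upstream_intron"]) == 0.0

    def test_window_coverage_arithmetic(self):
        # 60-nt sequence, one 6-nt match at bases 10-15, window 50:
        # left-aligned window starting at 0 covers all 6 bases -> 6/50
        seq = "A" * 10 + "CGCGCG" + "A" * 44
        scores = _window_scores(seq, "CGCGCG", window=50, region_length=250,
                                align="left")
        assert scores[0] == pytest.approx(6 / 50)
        assert np.isfinite(scores[:11]).all() and np.isnan(scores[11:]).all()

    def test_truncated_intron_aligns_at_exon_boundary(self):
        # a match placed at the exon-proximal end of a truncated upstream
        # intron must land in the rightmost (boundary) window
        short = "A" * 54 + "GGGAGG"       # 60 nt, motif at 3' edge
        prof = positional_profile(self._regions([short]), "GGGAGG")
        row = prof["upstream_intron"][0]
        assert row.size == 201            # 250 - 50 + 1 positions
        assert np.isnan(row[:190]).all()  # only 11 windows fit, right-aligned
        assert row[-1] == pytest.approx(6 / 50)

    def test_mean_profile_follows_incremental_update(self):
        seqs = ["A" * 100 + "GGGAGGG" + "A" * 143, "A" * 250, "G" * 250]
        base = positional_profile(self._regions(seqs[:2]), "GGGAGGG")
        ext = positional_profile(self._regions(seqs), "GGGAGGG")
        up_base = np.nanmean(base["upstream_intron"], axis=0)
        up_ext = np.nanmean(ext["upstream_intron"], axis=0)
        third = ext["upstream_intron"][2]
        np.testing.assert_allclose(up_ext, (2 * up_base + third) / 3,
                                   atol=1e-12)

    def test_short_sequences_warn(self):
        with pytest.warns(UserWarning, match="shorter than the window"):
            positional_profile(self._regions(["ACGT"]), "GG")

    def test_empty_set_rejected(self):
        with pytest.raises(ValidationError, match="empty"):
            positional_profile(self._regions([]), "GG")


class TestCompareProfiles:
    def test_identical_sets_never_significant(self):
        rng = np.random.default_rng(0)
        seqs = ["".join(np.array(list("ACGT"))[rng.integers(4, size=250)])
                for _ in range(8)]
        regions = pd.DataFrame({r: seqs if "intron" in r
                                else [s[:50] for s in seqs]
                                for r in REGIONS},
                               index=[f"E{i}" for i in range(8)])
        prof = positional_profile(regions, "GGG")
        mm = compare_profiles(prof, prof)
        for region in REGIONS:
            p = mm.p_values[region]
            assert np.nanmin(p) >= 0.05 or not np.isfinite(p).any()

    def test_undersized_sets_rejected(self):
        regions = pd.DataFrame({r: ["A" * 250] * 3 for r in REGIONS},
                               index=["a", "b", "c"])
        prof = positional_profile(regions, "GG")
        with pytest.raises(ValidationError, match=">= 5"):
            compare_profiles(prof, prof)

    def test_planting_more_instances_never_decreases_score(self):
        def regions_with(n_planted):
            seqs = []
            for i in range(10):
                if i < n_planted:
                    seqs.append("A" * 100 + "GGGAGGG" + "A" * 143)
                else:
                    seqs.append("A" * 250)
            return pd.DataFrame({r: seqs if "intron" in r
                                 else [s[:50] for s in seqs]
                                 for r in REGIONS},
                                index=[f"E{i}" for i in range(10)])
        scores = []
        bg = positional_profile(regions_with(0), "GGGAGGG")
        for k in (2, 5, 9):
            prof = positional_profile(regions_with(k), "GGGAGGG")
            mm = compare_profiles(prof, bg)
            scores.append(mm.max_mean_score)
        assert scores == sorted(scores)


class TestEnrichedRbps:
    def _map(self, min_p, max_score, region="upstream_intron"):
        mm = MotifMap(motif="m", rbp_gene="RBP")
        for r in REGIONS:
            n = 201 if "intron" in r else 1
            mm.p_values[r] = np.full(n, 0.5)
            mm.target_mean[r] = np.zeros(n)
            mm.positions[r] = np.arange(n)
        mm.p_values[region][10] = min_p
        mm.target_mean[region][10] = max_score
        return mm

    def test_score_criterion_blocks_low_coverage_motif(self):
        calls = enriched_rbps([self._map(0.01, 0.005)])
        assert not calls.enriched[0]

    def test_insignificant_p_blocks(self):
        calls = enriched_rbps([self._map(0.2, 0.05)])
        assert not calls.enriched[0]

    def test_both_criteria_met_reports_best_region(self):
        calls = enriched_rbps([self._map(0.001, 0.05)])
        assert calls.enriched[0]
        assert calls.best_region[0] == "upstream_intron"
        assert calls.min_p[0] == pytest.approx(0.001)


def test_motif_map_on_simulated_planting(default_dataset):
    """Planted upstream-intron motif is detected against null events."""
    regions = default_dataset.flanking_regions()
    truth = default_dataset.truth
    target = regions.loc[truth.event_id[truth.event_class != "null"]]
    background = regions.loc[truth.event_id[truth.event_class == "null"]]
    mm = motif_map(target, background,
                   MotifDef("GGGAGGG", "HNRNPH2", "GGGAGGG"))
    calls = enriched_rbps([mm])
    assert calls.enriched[0]
    assert calls.best_region[0] == "upstream_intron"
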