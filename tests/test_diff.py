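"""Differential splicing: exact test, BH correction, group contrasts."""

import numpy as np
import pandas as pd
import pytest
from fractions import Fraction
from math import comb

from isletsplice import (JunctionCounts, fisher_exact_two_sided,
                         pooled_group_psi, diff_test, one_vs_rest,
                         signature_genes, splice_expression_overlap,
                         SimConfig, simulate_dataset, log_normalize)
from isletsplice.io import ValidationError


def _exact_two_sided(a, b, c, d):
    """Rational-arithmetic oracle: sum hypergeometric probabilities of all
    tables with the observed margins that are no more probable."""
    r1, r2, col1 = a + b, c + d, a + c
    lo, hi = max(0, col1 - r2), min(r1, col1)
    weights = [comb(r1, x) * comb(r2, col1 - x) for x in range(lo, hi + 1)]
    w_obs = weights[a - lo]
    return float(Fraction(sum(w for w in weights if w <= w_obs), sum(weights)))


class TestFisherExact:
    def test_extreme_table(self):
        # [10,0;0,10]: the two extreme tables out of C(20,10) arrangements
        assert fisher_exact_two_sided(10, 0, 0, 10) == \
            pytest.approx(2 / comb(20, 10), rel=1e-9)

    def test_balanced_table_is_null(self):
        assert fisher_exact_two_sided(5, 5, 5, 5) == pytest.approx(1.0)

    def test_matches_exact_enumeration_small_margins(self):
        # full sweep of margins <= 12 here; margins <= 30 in the acceptance run
        for r1 in range(13):
            for r2 in range(13):
                for a in range(r1 + 1):
                    for c in range(r2 + 1):
                        p = fisher_exact_two_sided(a, r1 - a, c, r2 - c)
                        assert abs(p - _exact_two_sided(a, r1 - a, c, r2 - c)) \
                            < 1e-12

    def test_negative_entry_rejected(self):
        with pytest.raises(ValidationError):
            fisher_exact_two_sided(-1, 2, 3, 4)


class TestPooledGroupPsi:
    def test_pooling_follows_junction_normalization(self):
        # one pure-inclusion cell (20 reads over two junctions ~ 10
        # transcripts) plus one cell with 10 skipping reads -> psi 0.5
        counts = JunctionCounts(["a", "b"], ["E1"],
                                I=np.array([[20], [0]]), S=np.array([[0], [10]]))
        _, _, psi = pooled_group_psi(counts, ["a", "b"])
        assert psi[0] == pytest.approx(0.5)
        # with 20 skipping reads the skip side outweighs: (20/2)/(10+20)
        counts = JunctionCounts(["a", "b"], ["E1"],
                                I=np.array([[20], [0]]), S=np.array([[0], [20]]))
        _, _, psi = pooled_group_psi(counts, ["a", "b"])
        assert psi[0] == pytest.approx(1 / 3)

    def test_single_cell_formula(self):
        counts = JunctionCounts(["a"], ["E1"],
                                I=np.array([[40]]), S=np.array([[10]]))
        I_g, S_g, psi = pooled_group_psi(counts, ["a"])
        assert (I_g[0], S_g[0]) == (40, 10)
        assert psi[0] == pytest.approx(20 / 30)

    def test_low_coverage_undefined(self):
        counts = JunctionCounts(["a"], ["E1"],
                                I=np.array([[8]]), S=np.array([[4]]))
        _, _, psi = pooled_group_psi(counts, ["a"], min_cov=20)
        assert np.isnan(psi[0])

    def test_empty_group_rejected(self, small_counts):
        with pytest.raises(ValidationError, match="empty"):
            pooled_group_psi(small_counts, [])


def _two_group_counts(seed=0, n_per=40, n_events=30, reads=60, delta=0.0):
    rng = np.random.default_rng(seed)
    psi_a = rng.uniform(0.2, 0.7, size=n_events)
    psi_b = np.clip(psi_a + delta, 0.02, 0.98)
    cells, I, S = [], [], []
    for g, psis in (("A", psi_a), ("B", psi_b)):
        for i in range(n_per):
            cells.append(f"{g}{i}")
            T = rng.poisson(reads, size=n_events)
            p = 2 * psis / (1 + psis)
            Ii = rng.binomial(T, p)
            I.append(Ii)
            S.append(T - Ii)
    counts = JunctionCounts(cells, [f"E{j}" for j in range(n_events)],
                            np.array(I), np.array(S))
    groups = ([c for c in cells if c.startswith("A")],
              [c for c in cells if c.startswith("B")])
    return counts, groups


class TestDiffTest:
    def test_group_swap_flips_delta_and_keeps_p(self):
        counts, (ga, gb) = _two_group_counts(seed=1, delta=0.15)
        ab = diff_test(counts, ga, gb)
        ba = diff_test(counts, gb, ga)
        np.testing.assert_allclose(ab["delta_psi"], -ba["delta_psi"])
        np.testing.assert_allclose(ab["p"], ba["p"])

    def test_overlapping_groups_rejected(self):
        counts, (ga, gb) = _two_group_counts()
        with pytest.raises(ValidationError, match="disjoint"):
            diff_test(counts, ga, ga[:1] + gb)

    def test_bh_qvalues_match_step_up_definition(self):
        counts, (ga, gb) = _two_group_counts(seed=2, delta=0.1)
        tab = diff_test(counts, ga, gb)
        p = tab.loc[tab.tested, "p"].to_numpy()
        q = tab.loc[tab.tested, "q"].to_numpy()
        # direct step-up oracle
        m = p.size
        order = np.argsort(p)
        q_oracle = np.empty(m)
        running = 1.0
        for rank in range(m, 0, -1):
            idx = order[rank - 1]
            running = min(running, p[idx] * m / rank)
            q_oracle[idx] = running
        np.testing.assert_allclose(q, q_oracle, rtol=1e-12)
        assert (q >= p - 1e-15).all()

    def test_calls_are_function_of_delta_and_q(self):
        counts, (ga, gb) = _two_group_counts(seed=3, delta=0.2)
        tab = diff_test(counts, ga, gb)
        tested = tab[tab.tested]
        expect = np.where((tested.q < 0.05) & (tested.delta_psi > 0.1),
                          "included",
                          np.where((tested.q < 0.05) & (tested.delta_psi < -0.1),
                                   "skipped", "ns"))
        assert (tested.call.to_numpy() == expect).all()

    def test_untested_events_have_no_call(self):
        counts = JunctionCounts(["a", "b"], ["E1"],
                                I=np.array([[2], [2]]), S=np.array([[2], [2]]))
        tab = diff_test(counts, ["a"], ["b"])
        assert not tab.tested.iloc[0]
        assert np.isnan(tab.p.iloc[0]) and tab.call.iloc[0] == "ns"


class TestOneVsRest:
    def test_two_labels_are_antisymmetric(self):
        counts, (ga, gb) = _two_group_counts(seed=4, delta=0.15)
        labels = {c: ("A" if c.startswith("A") else "B") for c in counts.cells}
        tables = one_vs_rest(counts, labels)
        np.testing.assert_allclose(tables["A"]["delta_psi"],
                                   -tables["B"]["delta_psi"])

    def test_type_specific_events_called_only_for_target(self):
        # five equal types and a 0.2 shift so the dilution into the "rest"
        # group (delta/4 = 0.05) stays clear of the 0.1 delta-psi threshold
        cfg = SimConfig(seed=21, n_cells=300, n_events=60,
                        cell_types=("t1", "t2", "t3", "t4", "t5"),
                        cell_type_proportions=(0.2,) * 5,
                        mean_reads=100, dropout=0.1, delta_psi=0.2,
                        class_proportions={"null": 0.5, "type_specific": 0.5,
                                           "condition_specific": 0.0})
        ds = simulate_dataset(cfg)
        labels = dict(zip(ds.cells.index, ds.cells["cell_type"]))
        tables = one_vs_rest(ds.junctions, labels)
        truth = ds.truth
        spec = truth[truth.event_class == "type_specific"]
        hits = off_target = 0
        for _, ev in spec.iterrows():
            for t, tab in tables.items():
                called = tab.loc[ev.event_id, "call"] != "ns"
                if t == ev.target_type:
                    hits += called
                else:
                    off_target += called
        assert hits >= 0.8 * len(spec)
        # one-vs-rest contrasts of non-target types see a diluted opposite
        # shift; those must stay far rarer than target-type calls
        assert off_target <= 0.2 * hits

    def test_singleton_label_skipped_with_warning(self):
        counts, (ga, gb) = _two_group_counts(seed=5)
        labels = {c: "A" for c in ga} | {c: "B" for c in gb}
        labels[ga[0]] = "solo"
        labels = {c: l for c, l in labels.items()}
        with pytest.warns(UserWarning, match="solo"):
            tables = one_vs_rest(counts, labels)
        assert "solo" not in tables

    def test_single_label_rejected(self, small_counts):
        with pytest.raises(ValidationError, match="two labels"):
            one_vs_rest(small_counts, {c: "x" for c in small_counts.cells})


class TestSignatureGenes:
    def test_identical_groups_give_no_calls(self):
        rng = np.random.default_rng(0)
        expr = pd.DataFrame(rng.poisson(5, (10, 20)),
                            index=[f"c{i}" for i in range(10)],
                            columns=[f"G{j}" for j in range(20)])
        norm = log_normalize(pd.concat([expr, expr.set_axis(
            [f"d{i}" for i in range(10)])]))
        tab = signature_genes(norm, [f"c{i}" for i in range(10)],
                              [f"d{i}" for i in range(10)])
        assert np.allclose(tab["log2fc"], 0)
        assert (tab["call"] == "ns").all()

    def test_single_gene_bonferroni_is_identity(self):
        rng = np.random.default_rng(1)
        norm = pd.DataFrame(rng.normal(size=(40, 1)),
                            index=[f"c{i}" for i in range(40)], columns=["G"])
        tab = signature_genes(norm, [f"c{i}" for i in range(20)],
                              [f"c{i}" for i in range(20, 40)])
        assert tab["p_adj"].iloc[0] == pytest.approx(tab["p"].iloc[0])

    def test_planted_fold_change_detected(self):
        rng = np.random.default_rng(2)
        n = 100
        a = rng.negative_binomial(2, 2 / (2 + 40), size=(n, 1))   # mean 40
        b = rng.negative_binomial(2, 2 / (2 + 5), size=(n, 1))    # mean 5
        other = rng.poisson(10, size=(2 * n, 9))
        counts = pd.DataFrame(
            np.hstack([np.vstack([a, b]), other]),
            index=[f"c{i}" for i in range(2 * n)],
            columns=["target"] + [f"G{j}" for j in range(9)])
        norm = log_normalize(counts)
        tab = signature_genes(norm, [f"c{i}" for i in range(n)],
                              [f"c{i}" for i in range(n, 2 * n)])
        assert tab.loc["target", "call"] == "signature"
        assert tab.loc["target", "log2fc"] > 0.25

    def test_empty_group_rejected(self):
        norm = pd.DataFrame([[1.0]], index=["c"], columns=["G"])
        with pytest.raises(ValidationError):
            signature_genes(norm, [], ["c"])


class TestSpliceExpressionOverlap:
    def _splice_table(self, genes, deltas, calls):
        return pd.DataFrame({
            "event_id": [f"E{i}" for i in range(len(genes))],
            "gene": genes, "delta_psi": deltas, "tested": True,
            "call": calls}).set_index("event_id", drop=False)

    def _expr_table(self, genes, lfc, calls):
        return pd.DataFrame({"gene": genes, "log2fc": lfc,
                             "call": calls}).set_index("gene", drop=False)

    def test_identical_rankings_give_rho_one(self):
        genes = [f"G{i}" for i in range(30)]
        vals = np.linspace(-0.5, 0.5, 30)
        sp = self._splice_table(genes, vals, ["ns"] * 30)
        ex = self._expr_table(genes, vals, ["ns"] * 30)
        out = splice_expression_overlap(sp, ex)
        assert out["spearman_rho"] == pytest.approx(1.0)
        assert out["n_shared"] == 30

    def test_disjoint_gene_sets_warn(self):
        sp = self._splice_table(["A", "B"], [0.2, -0.2], ["included", "ns"])
        ex = self._expr_table(["C", "D"], [1.0, 0.0], ["signature", "ns"])
        with pytest.warns(UserWarning, match="no genes shared"):
            out = splice_expression_overlap(sp, ex)
        assert out["n_shared"] == 0 and out["n_both"] == 0

    def test_venn_counts(self):
        sp = self._splice_table(["A", "B", "C"], [0.2, -0.2, 0.0],
                                ["included", "skipped", "ns"])
        ex = self._expr_table(["A", "B", "C"], [1.0, 0.0, 0.6],
                              ["signature", "ns", "signature"])
        out = splice_expression_overlap(sp, ex)
        assert (out["n_both"], out["n_splice_only"], out["n_expr_only"]) \
            == (1, 1, 1)
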