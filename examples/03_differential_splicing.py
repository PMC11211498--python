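"""Differential splicing between conditions, and its independence from
expression changes.

Runs the pseudo-bulk Fisher test on ND-vs-T2D junction counts, compares the
calls with the planted truth, then tests signature genes on expression and
summarizes the overlap between the two regulatory layers.
"""

from isletsplice import (SimConfig, simulate_dataset, diff_test,
                         log_normalize, signature_genes,
                         splice_expression_overlap)

ds = simulate_dataset(SimConfig(seed=3))
cells = ds.cells
nd = list(cells.index[cells["condition"] == "ND"])
t2d = list(cells.index[cells["condition"] == "T2D"])

tab = diff_test(ds.junctions, nd, t2d, min_cov=20, min_frac=0.10)
truth = ds.truth
planted = set(truth.loc[truth["event_class"] == "condition_specific",
                        "event_id"])
called = set(tab.loc[tab["call"] != "ns", "event_id"])
print(f"events tested: {int(tab['tested'].sum())}   "
      f"called (q<0.05, |dpsi|>0.1): {len(called)}")
print(f"planted condition-specific events: {len(planted)}   "
      f"recovered: {len(called & planted)}   "
      f"false calls: {len(called - planted)}")

norm = log_normalize(ds.expression)
expr = signature_genes(norm, t2d, nd)
overlap = splice_expression_overlap(
    tab, expr, gene_map=dict(zip(truth["event_id"], truth["gene"])))
print(f"genes changing splicing only: {overlap['n_splice_only']}   "
      f"expression only: {overlap['n_expr_only']}   "
      f"both: {overlap['n_both']}")
print(f"Spearman rho(delta_psi, log2FC) over {overlap['n_shared']} genes: "
      f"{overlap['spearman_rho']:+.3f} (p={overlap['spearman_p']:.2f})")
print()
print("Splicing and expression effects were planted on disjoint gene sets,")
print("so the near-zero rank correlation and empty intersection show the")
print("pipeline keeps the two regulatory layers statistically separate.")
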