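"""Gene-set maturity scores across cells and KS contrasts between groups.

Log-normalizes expression, scores each cell on the maturity gene set with
expression-matched bin controls, and compares mature (top-quartile maturity)
cells against the rest with the two-sample KS test, overall and per cell
type.
"""

from isletsplice import (SimConfig, simulate_dataset, log_normalize,
                         module_score, ks_two_sample, score_report)

ds = simulate_dataset(SimConfig(seed=8))
norm = log_normalize(ds.expression)
res = module_score(norm, ds.gene_sets["maturity"], n_bins=24, n_ctrl=100,
                   seed=0)

cells = ds.cells.copy()
mature = (cells["maturity"] >= cells["maturity"].quantile(0.75)).to_numpy()
hi, lo = res.scores[mature], res.scores[~mature]
ks = ks_two_sample(hi, lo)
print(f"median maturity score, mature cells: {hi.median():+.3f}   "
      f"others: {lo.median():+.3f}")
print(f"two-sample KS: D={ks.statistic:.3f}, p={ks.pvalue:.2e}")

cells["state"] = ["mature" if m else "immature" for m in mature]
rep = score_report(res.scores, cells, "state")
print()
print(rep.to_string(index=False, float_format="{:.3g}".format))
print()
print("The planted maturity gradient scales a 20-gene set; the positive")
print("score gap and tiny KS p show the binned-control score recovers it,")
print("mirroring how maturity scoring separates functional beta-cell")
print("subsets.")
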