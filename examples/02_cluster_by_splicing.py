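"""Cluster cells by splicing profile alone and compare with true types.

Expression effects are switched off, so the three simulated cell types can
only be told apart through their exon-inclusion profiles: quantify psi,
impute missing entries with probabilistic PCA, embed with the top 10 PCs and
cluster the shared-nearest-neighbor graph with Leiden at resolution 1.2.
"""

from sklearn.metrics import adjusted_rand_score

from isletsplice import (SimConfig, simulate_dataset, quantify_matrix,
                         filter_exons, bpca_impute, pca_embed, snn_cluster)

cfg = SimConfig(seed=0, n_cells=300, n_events=200,
                cell_type_proportions=(1 / 3, 1 / 3, 1 / 3),
                class_proportions={"null": 0.4, "type_specific": 0.6,
                                   "condition_specific": 0.0},
                marker_fold=1.0, maturity_fold_range=1.0, condition_fold=1.0)
ds = simulate_dataset(cfg)

kept = filter_exons(quantify_matrix(ds.junctions))
filled = bpca_impute(kept, n_components=10, seed=0)
emb = pca_embed(filled, n_pcs=10)
res = snn_cluster(emb, k_neighbors=20, resolution=1.2, seed=0)

ari = adjusted_rand_score(ds.cells["cell_type"], res.labels)
print(f"missing psi entries imputed: {1 - kept.observed.mean():.1%}")
print(f"variance explained by PC1/PC2: "
      f"{emb.explained_variance_ratio[0]:.2f} / "
      f"{emb.explained_variance_ratio[1]:.2f}")
print(f"clusters found: {len(set(res.labels))}   "
      f"adjusted Rand index vs true types: {ari:.3f}")
print()
print("ARI 1.0 means the splicing-only profiles recover the cell types")
print("exactly -- the desk-scale analogue of splicing profiles separating")
print("endocrine cell types.")
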