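"""Visualize within- and between-population signature variability.

Samples two species' hyperspectrum populations, embeds them with PCA
and t-SNE, and scores the cluster separation by mean silhouette.
Run: python examples/03_population_embedding.py
"""

import crif
from crif.embedding import run_pca, run_tsne, separation_score

cfg = crif.SpectralConfig()
signatures = crif.example_signatures(cfg)

a = crif.sample_catalog(signatures["budding_yeast_like"], 200, cv=0.1, seed=3, config=cfg)
b = crif.sample_catalog(signatures["fission_yeast_like"], 200, cv=0.1, seed=4, config=cfg)

pca = run_pca([a, b])
print(f"PCA explained variance (PC1, PC2): "
      f"{pca.explained_variance_ratio[0]:.3f}, {pca.explained_variance_ratio[1]:.3f}")
print(f"PCA silhouette: {separation_score(pca.coords, pca.labels):.3f}")

tsne = run_tsne([a, b], perplexity=30, seed=0)
print(f"t-SNE silhouette: {separation_score(tsne.coords, tsne.labels):.3f}")
# Silhouette near 1 means the two populations form distinct clusters in
# the 2D view; near 0 would mean their signatures overlap.
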