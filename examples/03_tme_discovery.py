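"""Weakly supervised TME discovery: patches -> phenotypes -> neighborhoods.

Tiles synthetic cores into patches, trains the contrastive encoder,
builds the spatial patch graph, assigns the three TME levels
(8 phenotypes, 8 neighborhoods, 7 areas = 23 patterns), and evaluates
all 10 pairwise grade classifications from the per-image abundances.
"""

import warnings

warnings.filterwarnings("ignore")

from gliotme import pcl, synthetic, tissue_graph, tme

cohort = synthetic.generate_cohort(
    synthetic.strong_coupling_config(n_per_grade=8), seed=17
)
patches = []
for img, truth, iid in zip(cohort.images, cohort.truths, cohort.image_ids):
    patches.extend(pcl.tile_image(img, truth.tissue_mask, 16, 16, iid))
print(f"{len(cohort.images)} cores -> {len(patches)} patches of 16 px")

encoder = pcl.train_encoder(
    patches, pcl.PCLConfig(epochs=2, max_anchors_per_epoch=1500, seed=17)
)
embeddings = pcl.embed(encoder, patches)
print(f"embeddings: {embeddings.embeddings.shape} (unit-norm 256-d vectors)")

graph = tissue_graph.build_graph(embeddings, knn=8)
assignment = tme.assign_all(embeddings, graph, seed=17)
print(f"patch graph: {graph.number_of_edges()} edges; "
      f"TME patterns: {assignment.phenotypes.k} phenotypes + "
      f"{assignment.neighborhoods.k} neighborhoods + {assignment.areas.k} areas")

abundance = tme.abundance_matrix(
    assignment, dict(zip(cohort.image_ids, cohort.labels))
)
table = tme.evaluate_binary_pairs(abundance, seed=17)
print("\nheld-out binary grade classification (AUC):")
print(table["auc"].round(2).to_string())
# Extreme pairs (0 vs 4, 1 vs 4) separate almost perfectly; the
# deliberately overlapping grades 2 and 3 stay near chance — the same
# qualitative ordering the real cohort exhibits.
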