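# gliotme

Glioma grading and tumor-microenvironment (TME) quantification from
single-stain tissue-microarray (TMA) images.

Gliomas are graded (WHO grades 1–4, with normal brain tissue treated as
"grade 0") from stained histology. Immunostaining for HLA-DP/-DQ/-DR
highlights glioma-infiltrating myeloid cells, whose abundance and spatial
organisation shift with malignancy. This package implements, as a tested
and reusable library, the two complementary analysis tracks such a study
needs:

1. **Supervised grading benchmark** — 5-class classification over six CNN
   architectures (ResNet18/50, DenseNet121, VGG16, EfficientNet-B0,
   MobileNetV3-Small), each trained from scratch or in a transfer regime
   where only the final linear layer is updated, under stratified 10-fold
   cross-validation with cross-entropy, rotation augmentation of minority
   grades, and optional RGB→HSV preprocessing. Per-fold accuracies of two
   models are compared with the two-sided Mann–Whitney *U* test (exact
   enumerative null for *n* ≤ 10 without ties) after a Shapiro–Wilk
   normality check.
2. **Weakly supervised TME discovery** — core images are tiled into
   per-cell patches; a contrastive encoder maps each patch to a unit-norm
   256-d embedding by minimising the NT-Xent loss

   ℓ(a, p) = −log [ exp(cos(a,p)/τ) / Σₖ exp(cos(a,k)/τ) ],

   pulling together augmented views of nearby patches and pushing apart
   distant ones. A k-nearest-neighbour patch graph then supports a
   three-level prototype assignment — **8 phenotypes** (P1…P8) from the
   embeddings, **8 cellular neighborhoods** (N1…N8) from hop-limited
   phenotype compositions, **7 areas** (A1…A7) from wider-radius
   neighborhood distributions: 23 TME patterns in total. Per-image,
   block-normalised abundances feed a multinomial logistic patient
   classifier trained only with image-level grade labels, evaluated over
   all 10 pairwise grade comparisons (accuracy, sensitivity, specificity,
   AUC-ROC with the higher grade as positive class).

A **BioInsights** layer tests each TME element for differential abundance
between grade pairs (two-sided rank-sum; stars \* p<0.05, \*\* p<0.01,
\*\*\* p<0.001), aggregates significant elements into a grade graph whose
edges weigh stars ×1/×2/×3, computes per-patient predictive-influence
ratios, and orders abundance heatmaps by average-linkage hierarchical
clustering. UMAP projections visualise images and compositions.

Cohort-scale glioma TMA image datasets are rarely public, so the package
ships a **seeded synthetic TMA generator**: circular tissue cores rendered
by Beer–Lambert mixing of DAB-like (brown) and hematoxylin-like (blue)
absorbances, with planted phenotypes, Voronoi-grown neighborhood regions,
and grade-dependent Dirichlet abundance profiles matching the study
cohort's composition (206 images: 21/24/84/26/51 across grades 0–4).
Every planted truth map is returned alongside the pixels, so recovery can
be measured exactly.

## Worked example

`examples/03_tme_discovery.py` runs the discovery track end-to-end on a
synthetic cohort of 40 cores (8 per grade) with strongly grade-coupled
neighborhoods:

```
40 cores -> 7040 patches of 16 px
embeddings: (7040, 256) (unit-norm 256-d vectors)
patch graph: 30240 edges; TME patterns: 8 phenotypes + 8 neighborhoods + 7 areas

held-out binary grade classification (AUC):
pair
0,1    0.89
0,2    1.00
0,3    1.00
0,4    1.00
1,2    0.52
1,3    0.69
1,4    0.91
2,3    0.52
2,4    0.91
3,4    0.72
```

Extreme grade pairs (normal vs grade 4, grade 1 vs 4) separate almost
perfectly from the discovered abundances alone, while the deliberately
overlapping grades 2 and 3 stay near chance — the same qualitative
ordering real cohorts exhibit, where separating grades 2 and 3 is hard
even for pathologists. The other examples cover cohort simulation, the
grading benchmark with its exact parameter accounting (e.g. ResNet18:
11,179,077 trainable parameters from scratch, 2,565 in the transfer
regime), differential analysis with the shared-cluster graph, and UMAP
views.

A thin CLI wraps the most shell-worthy entry points:

```bash
gliotme simulate --out cohort/ --seed 17 --n-per-grade 4
gliotme params densenet121 --pretrained
gliotme run-all --out run/ --seed 17
```

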