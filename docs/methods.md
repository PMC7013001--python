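# Methods

## Model and procedure

`pathpass` scores the activation of each pathway in each individual disease
sample relative to a cohort of `n` healthy reference samples. Both scores are
rank-based enrichment AUCs, so they live on a common [0, 1] scale regardless
of platform or pathway size.

**Fully connected pathway networks.** Each pathway (a gene set with
undirected interaction edges) is first restricted to the genes present in the
expression matrix; edges incident to removed genes are dropped, and pathways
left with one edge or fewer are excluded (a single attention edge cannot
support a meaningful enrichment ranking). The retained genes are expanded
into the complete graph: real interactions form the *attention* edge set
(size `m`), artificially added pairs the *background* set (size `n_bg`).

**Edge view.** For each gene pair, the Pearson correlation over the reference
cohort (`PCC_n`) is compared with the correlation after appending the single
disease sample (`PCC_{n+1}`). The perturbation `ΔPCC_n = PCC_{n+1} − PCC_n`
is standardised as

    Z = ΔPCC_n / ((1 − PCC_n²) / (n − 1)),

the sample-specific-network statistic: one added observation can move a weak
correlation much further than a strong one, and the scale of the move shrinks
with cohort size. `n` is the number of *reference* samples. All edges of the
fully connected network are ranked by Z in ascending order and the attention
set's enrichment at the top of the ranking is the edge activation.

**Node view.** Every gene in the pathway universe (the union of all retained
pathways' genes present in the matrix — not all measured genes) gets a fold
change `FC = b/ā`, the disease sample's value over the reference mean. Genes
are ranked ascending by FC; the enrichment of the pathway's member genes at
the top is the node activation.

**AUCpath.** For a ranking of `m` attention among `m + n` total items,

    AUC = (Σ attention ranks − m(m+1)/2) / (m·n),

the normalised Mann–Whitney U: the fraction of (attention, background) pairs
in which the attention item ranks higher, ties counting one half. Ties are
resolved by midranks. The statistic is invariant under any strictly
increasing transform of the scores — which is why fold changes are used raw
rather than log-transformed: the log would change nothing.

Each pathway therefore contributes two features per disease sample,
`<id>|edge` and `<id>|node`. The framework does not prescribe how the two
views combine, so they are kept as separate features and the downstream
learner weighs them. Every column of the PASS matrix depends only on that
sample and the reference cohort, so samples are scored independently.

## Numerical choices and degenerate inputs

- **Zero-variance genes.** A gene constant across the reference (or
  augmented) cohort has no defined correlation; its edges get `PCC = 0` and
  `Z = 0` with a degenerate flag, so they fall mid-ranking instead of
  dominating either tail.
- **|PCC_n| = 1** is clamped to `1 − 1e-8` before the Z denominator:
  preserves sign and extremeness without infinities.
- **Signed vs absolute Z.** Edges are ranked by signed Z by default (the
  natural reading of "ascending order of Z"); `use_absolute_z=True` ranks by
  perturbation magnitude instead. Both modes are tested.
- **Complete pathways** (no background edges) have an undefined edge AUC; the
  feature is emitted as missing (NA) and dropped, with a log message, before
  classification and differential testing, rather than silently imputed.
- **Fold change** requires a nonzero reference mean; an exactly zero mean
  raises unless an explicit pseudocount is supplied. An optional
  `--input-log2` flag exponentiates log2 intensities first, since a ratio is
  only meaningful on the linear scale.
- **t-test degeneracy.** Two groups with zero variance get `p = 1` when their
  means agree and the machine-floor p otherwise. Welch's test is the default
  (no equal-variance assumption); the pooled Student variant is available.
  No multiple-testing correction is applied by default, matching the raw
  p < 0.05 / p < 0.01 usage the workflow is built around.
- **Reference ordering.** Reference sample ids are sorted internally so
  results are bit-identical regardless of how the caller orders the cohort.

## Classification protocol

Class A vs class B on PASS features, random forest (500 trees, √p feature
subsampling) under stratified 3-fold cross-validation repeated 500 times by
default (50 in the test studies below). Stratification matters because plain
3-fold splitting of cohorts with ~15 samples per class frequently produces
single-class folds. Per repeat, fold assignment and the forest are re-seeded
from `base_seed + repeat`; the per-repeat AUC is computed from the pooled
out-of-fold probabilities of that repeat (robust to tiny folds, unlike
averaging per-fold AUCs), and the aggregate ROC pools all repeats. The
positive class is a reporting orientation only: at fixed out-of-fold scores,
flipping it complements each AUC exactly.

## Enrichment

A pathway is *differential* when either of its two features passes the
significance threshold. The disease-associated-gene (DAG) enrichment is the
upper-tail hypergeometric probability of observing at least `m` DAGs among
the `n` genes of the differential pathways, drawn from `N` pathway-universe
genes of which `M` are DAGs; overlapping genes are counted once (union).
Reported as `−log10 p`, floored at the smallest positive double.

## Synthetic cohorts: what they emulate and what they do not

The generator produces a microarray-like study: a healthy reference cohort
and two disease classes, with disjoint random connected sparse pathway graphs
(a uniform random recursive spanning tree plus random extra edges; gene and
edge counts drawn from configured ranges), plus a block of pathway-free
background genes.

Within a pathway, genes follow a latent multivariate normal. A correlation
matrix with 0.7 on the edges and 0 elsewhere is generally not positive
semidefinite (a 4-gene path graph already fails), so the latent correlation
between two genes is `0.7^d` with `d` the graph geodesic distance — exact
for trees; when extra cycle edges push it slightly off PSD the matrix is
repaired by eigenvalue clipping (statsmodels `corr_clipped`). Background
correlations therefore decay geometrically with graph distance rather than
vanishing, which is also the more biologically plausible shape.

Perturbing a pathway in a disease class removes a `correlation_rewire`
fraction of its edges from the correlation model (breaking those
co-expression links, exercising the edge view) and shifts the latent mean of
all its genes by `mean_shift` (exercising the node view); the two channels
can be switched off independently (`correlation_rewire=0`, `mean_shift=0`).
Expression is `8.0 + latent + N(0, noise_sd²)`, floored at 0.05 — a typical
log2-intensity baseline keeping values strictly positive so fold changes are
always defined.

Parameter defaults (chosen once as the study conditions):

| parameter | default | meaning |
|---|---|---|
| n_reference / n_class_a / n_class_b | 20 / 20 / 20 | cohort sizes, comparable to the mid-sized real IBD cohorts |
| n_pathways | 30 | pathway count at test scale |
| genes_per_pathway / edges_per_pathway | 6–10 / 6–12 | sparse, connected graphs |
| perturbed per class | 5 + 5 (disjoint) | implanted ground truth |
| mean_shift | 2.0 | ~2 sd latent shift, a strong but realistic disease effect |
| correlation_rewire | 0.8 | fraction of edge correlations broken |
| noise_sd | 0.2 | measurement noise; attenuates the observed edge correlation to ≈ 0.7/(1+0.2²) ≈ 0.67 |

What the simulator does **not** emulate: probe-level artifacts, batch
effects, platform normalisation differences, overlapping pathway gene sets,
correlated perturbation across pathways, and label noise. Passing the
recovery studies therefore shows the statistics and the pipeline behave as
designed under their own model — not that the discrimination figures carry
over to real cross-platform cohorts.

## Study sizes used in tests and the acceptance script

The null-calibration and signal-recovery studies run at 20/20/20 samples,
30 pathways and 50 CV repeats (10 independent seeds for recovery); the
acceptance script runs one signal and one null study at the same size. These
sizes give stable statistics (per-repeat AUC standard errors well below the
decision margins) while keeping a full run in minutes.

## Known limitations

- KGML group entries are ignored rather than expanded into member genes;
  multi-gene KGML entries are expanded gene-by-gene with relations as cross
  products. Directed and typed KEGG relations collapse to simple undirected
  edges.
- The edge statistic assumes the reference correlations are estimated from
  the same population for every sample; cohort/batch structure inside the
  reference set is not modelled.
- Per-edge Z values are used only for ranking, never thresholded, so no
  multiple-testing machinery is applied at the edge level.
- Probe collapsing supports the discard-multimapper/median-per-gene policy
  only; platform annotation retrieval is out of scope.
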