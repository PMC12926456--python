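# Methods

## Problem and model

`cortexgnn` segments (parcellates) a cortical hemisphere surface into K
anatomical regions by treating the triangular pial-surface mesh as an
unweighted graph — vertices are nodes, unique triangle edges are edges — and
training a graph neural network to classify every vertex.  Three
architectures are implemented as explicit propagation rules over that graph:

* **GCN.**  Layer rule `H' = act(S H W + b)` with
  `S = D̂^{-1/2}(A + I)D̂^{-1/2}`; self-loops are added inside the
  propagation (the standard formulation of the cited convolutional rule).
* **GAT.**  Per head, edge logits
  `e_ij = LeakyReLU(a_src·Wh_j + a_dst·Wh_i)` over `j ∈ N(i) ∪ {i}`,
  normalized by a softmax over that neighborhood; hidden layers concatenate
  heads, the output layer averages them.  The LeakyReLU slope is 0.2.
* **Graph U-Net.**  A GCN embedding followed by `depth` top-k pooling
  stages (score `Hp/‖p‖`, keep `⌈ratio·V⌉` nodes, ties to the lower vertex
  index, retained features gated by `tanh(score)`, subgraph induced), then
  unpooling stages that scatter features back to their recorded indices
  (zeros elsewhere) with additive skip connections, and a GCN head.  The
  internal width is uniform because additive skips require matching widths.

All models emit raw per-vertex logits for a mean cross-entropy objective;
arg-max prediction breaks ties toward the lower class index.  The networks,
and the reverse-mode autodiff they run on (`cortexgnn.autodiff`), are
implemented in NumPy in float64; training is exactly reproducible on one
thread given the seeds.

Per-vertex features are, in fixed column order: (x, y, z) coordinates (3),
cortical thickness (1, mm), signed curvature (1, 1/mm; negative on gyri,
positive in sulci), and a 642-long structural-connectivity (conductance)
row, i.e. up to d = 647.  Features are min-max normalized per column over
all vertices of all subjects in the fitted set.  The default fits the
scaler over the *entire* cohort, reproducing the original protocol (which
normalizes across the whole dataset and therefore leaks test statistics
into training); `fit_scaler_on_train=True` gives the leakage-free variant.
Whether the original work normalized coordinates jointly or per axis is not
stated; per-column normalization is used here.

## Training protocol

Adam (β = 0.9/0.999), starting learning rate 0.01, 100 epochs, batch size 1
(one subject per gradient step, reshuffled each epoch), fresh i.i.d.
Gaussian noise of sd 0.01 added to the normalized features each step as
augmentation (the source protocol states noise augmentation but no sd), and
a reduce-on-plateau schedule monitoring validation loss (factor 0.5,
patience 5, floor 1e-5 — unstated in the source; these are common library
defaults).  The loss is mean per-vertex cross-entropy (the source does not
state its loss; cross-entropy is the standard choice for node
classification).  No early stopping: the final-epoch model is evaluated.
A non-finite loss aborts with the offending epoch named.

Evaluation follows the study protocol: a fixed holdout (default 8 subjects)
plus k-fold cross-validation (default 5) over the remainder; each fold's
model is applied to the holdout and the cell score is the mean ± std over
fold models of the holdout-mean macro Dice.  Dice is computed per region
(`2|P∩T|/(|P|+|T|)`), skipping regions absent from both sides, scoring 0
for regions present in exactly one, and averaging regions unweighted
("macro"); an UNKNOWN label can be excluded via `ignore_label`.  Whether
the source's reported std is across folds or subjects is ambiguous; both
are emitted (`std_dice`, `std_dice_subjects`).  Paired comparisons between
architectures use the two-sided paired t-test on per-subject holdout
scores, with p = 1 when all differences vanish and p floored at the
smallest positive double for zero-variance nonzero differences.

The architecture widths/depths of the original models are unknown and the
printed parameter counts cannot be uniquely inverted, so parameter counts
are configuration-dependent here, not a claimed reproduction; defaults are
hidden = (512, 256) for GCN/GAT (4 attention heads) and a narrower uniform
width for the Graph U-Net, matching the source's note that its U-Net had to
be kept narrower.  `count_parameters` agrees with the closed-form
shape sums by construction and is tested against them.

## Synthetic cohort

The real cohort (97 healthy young adults, restricted access) is replaced by
a generator that plants the statistical structure the pipeline assumes.
Defaults and what they emulate:

* **Geometry.** Order-3 icosphere (642 vertices — the fsaverage3 hemisphere
  resolution), radius 50 mm, with 24 smooth von-Mises–Fisher-shaped radial
  bumps (concentration 30, displacement ±8%) shared across the cohort as a
  common "folding" pattern; right hemispheres are mirrored in x.
* **Parcellation.** K = 35 regions per hemisphere (Desikan-Killiany-sized
  label space) by graph-Voronoi assignment from a cohort-level atlas of 35
  seed vertices; hop distance, ties to the lower seed index (which makes
  every region connected).  Each subject's seeds are jittered by one random
  hop with probability 0.5, emulating inter-subject anatomical variability
  while keeping labels learnable across subjects.  Hop distance rather than
  weighted geodesics keeps this cheap; parcel geometry is not a target.
* **Thickness.** `base(region) + β(age − 28.5) + subject offset + vertex
  noise`, floored at 0.1 mm.  Region baselines are drawn once per cohort
  from 1.5–4.5 mm.  β = −0.01 mm/year (within the range reported for
  healthy adults), vertex noise sd 0.3 mm, subject intercept sd 0.0992 mm.
  The intercept term is deliberate: with vertex noise alone the cohort-mean
  residual would be σ/√642 and any age effect would be recovered with
  r ≈ −1.  Calibration: the downstream statistic (equal-weighted
  across-region mean thickness) has measured non-intercept residual sd
  0.0155 mm, and with ages uniform on 22–35 (σ_age = 3.753),
  total residual 0.1004 mm yields population correlation exactly
  `βσ_age/√(β²σ_age² + σ²) = −0.35`, the value the pipeline is meant to
  recover.
* **Curvature.** `−0.3 · g/‖g‖_∞` (1/mm) where g is the bump field, so
  outward-displaced vertices (gyral crowns) get negative curvature and
  inward ones (sulcal pits) positive, with FreeSurfer-like magnitudes.
* **Connectivity.** Region-block structure on a fixed 642-column template
  grid: a symmetric K×K template with within-region conductance 1.0 and
  between-region conductances uniform on 0.1–0.3, plus vertex-level
  Gaussian noise (sd 0.05) truncated at 0.  Diffusion physics is not
  simulated; the block structure reproduces the *informativeness* of
  conductance features (a nearest-centroid readout of raw rows recovers
  ≥ 90% of labels), which is what makes the feature-ablation ordering
  meaningful.
* **Demographics.** Age uniform on 22–35 years; MMSE near ceiling (28–30),
  education 12–20 years from a fixed discrete distribution — both therefore
  uncorrelated with imaging by construction, mirroring the null results of
  the source cohort.  Hemisphere records of one individual share
  demographics.  The real cohort's demographic distributions are not
  public; these defaults are plausible, not claimed matches.

Per-subject randomness comes from `SeedSequence(master).spawn`: child 0 is
the cohort stream, child i+1 drives subject i, so cohorts are bit-identical
across runs and subjects are independent.

What the generator does **not** emulate: realistic folding geometry and
region shapes, spatially correlated measurement noise, distance-dependent
connectivity fall-off, hemispheric asymmetries, and any region-specific
aging profile (the planted age effect is global).  Tests passing on this
cohort demonstrate that the pipeline recovers planted structure of the
stated kind and size; they say nothing about absolute Dice levels on real
cortical data.

## Benchmark scale

The qualitative feature-ablation benchmark uses 20 subjects (8 holdout,
3 folds over the remaining 12), 642 vertices, K = 35, hidden widths
(64, 32) for the GCN and 4×16/4×8 for the GAT, 30 epochs — a desk-scale
configuration chosen so the full grid (3 feature sets × 2 architectures ×
3 folds) trains in minutes while the planted signal ordering
(coords < coords+thickness+curvature < all-647) is comfortably resolved.
The planted-correlation recovery check uses 100 cohorts of 97 subjects
(single hemisphere, no connectivity, which the statistic does not use).

## Downstream analyses

Region means are computed over the vertices of each region under either
label source (reference or model predictions — only the label source is
swapped, attributes held fixed); empty regions are recorded as absent, not
zero.  Pearson r with two-sided p (t-transform, n−2 df) is computed per
region and for the cohort-level across-region average (equal region
weights; size-weighted averaging would change the statistic slightly and is
not what "average of within-region means" describes).  Multiple testing is
Bonferroni at α/m (0.05/35 = 0.0014).  Two label sources are compared by a
paired Wilcoxon signed-rank test on region-wise p-values (zero differences
dropped; exact null for ≤ 25 untied pairs, normal approximation with
continuity correction otherwise).  Age prediction uses out-of-fold RMSE
from 5-fold CV over the length-70 cross-hemisphere region-mean vector, with
a regressor menu (ridge, decision tree, k-NN, small MLP) replacing the
original commercial toolbox's seven models — the analysis surface is the
RMSE-versus-σ_age comparison, not any specific regressor — and the
mean-age baseline reported alongside as the σ_age reference.  Absent
regions are imputed with the training-fold mean.

## Numerical choices and edge cases

* Midpoint deduplication during icosphere subdivision keys on exact vertex
  index pairs, never on floating-point coordinates.
* Vertex indexing is 0-based everywhere; 1-based file dialects are
  converted at the I/O boundary.  FreeSurfer binary payloads are float32,
  so file round trips are exact at float32 resolution.
* Top-k pooling breaks score ties toward the lower vertex index (stable
  argsort), making the U-Net deterministic; permutation equivariance of the
  U-Net holds for tie-free scores.
* Constant feature columns normalize to 0 rather than dividing by zero;
  unseen out-of-range values are clipped to [0, 1].
* Degenerate statistics: all-zero paired differences → p = 1 (t-test and
  Wilcoxon); constant nonzero differences → p floored at the smallest
  positive double; zero-variance correlation inputs are skipped with a
  warning.

## Known limitations

Training is CPU-only, single-threaded NumPy; the harness is sized for
hundreds of vertices per mesh, not native-resolution (100k+) surfaces.
Absolute Dice values on the synthetic cohort are not comparable to scores
on real data — the synthetic task is easier where connectivity is concerned
(clean block structure) and harder where geometry is concerned (labels
move between subjects only through seed jitter).  MMSE/education analyses
are null by construction and only exercise the machinery.
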