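# Methods

## Model

A drug–cell-line pair is featurized through four channels and fused into a
single normalized response prediction.

**Drug structure extractor (DSE).** The SMILES string is parsed (RDKit) into
a heavy-atom graph. Each atom carries a 78-dimensional binary feature vector:
a 44-wide atom-symbol one-hot (43 named elements plus an "other" bucket),
degree one-hot over 0–10, total-hydrogen one-hot over 0–10, implicit-valence
one-hot over 0–10, and an aromaticity flag (44 + 11 + 11 + 11 + 1 = 78).
Values above 10 are bucketed at 10. Three graph-convolution layers
`H' = relu(D̃^{-1/2}(A + I)D̃^{-1/2} H W)` widen the node features
78 → 78 → 156 → 312 (f, 2f, 4f with f = 78); the layers carry no bias,
matching the plain normalized-adjacency propagation rule. Global max pooling
over atoms yields a 312-vector, mapped by one linear layer to 128. Hydrogens
are implicit (heavy-atom graph only). Self-loops are added inside the
normalization, so isolated atoms are well defined (degree ≥ 1). Graphs are
batched by zero-padding to the largest molecule; padded rows are excluded
from the max by an additive −10⁹ mask (safe because post-ReLU features are
non-negative).

**Molecular fingerprint extractor (MFE) and miRNA expression extractor
(mEE).** Both are the same 1-D CNN: three blocks of valid cross-correlation
(kernel size 8, stride 1, no padding; 4, 8 and 16 kernels) with ReLU and
non-overlapping max pooling (window = stride = 3, trailing remainder
dropped), then flatten and one linear map to 128. For an 881-bit fingerprint
the stage lengths are 881 → 874 → 291 → 284 → 94 → 87 → 29 (flatten
16 × 29 = 464). The architecture requires input length ≥ ~110; shorter
vectors raise an error naming the failing stage.

**Copy number extractor (CNE).** A stacked autoencoder with hidden sizes
1024, 512, 256, 256, 512, 1024 (ReLU between linear layers, linear bottleneck
and output) is pretrained to reconstruct the standardized copy-number vector
under mean squared error. The 256-wide bottleneck is the channel embedding.
After pretraining, the encoder is fine-tuned end-to-end with the supervised
loss by default (a frozen-encoder mode is available); the decoder takes no
part in the supervised phase.

**Fusion head.** The active channel embeddings are concatenated (640-wide
for all four channels) and passed through linear layers of sizes
1024 → 512 → 128, each followed by batch normalization *before* the ReLU
activation and dropout (rate 0.1, disabled in evaluation). A final linear
layer and sigmoid produce a prediction in (0, 1). Evaluation mode uses
running batch-norm statistics, so single-pair predictions are defined and
batch-size invariant. Channel ablation removes an embedding from the
concatenation; the fusion input width shrinks accordingly and a fresh model
is trained per subset.

## Labels and preprocessing

Raw IC50 values are positive concentrations. The pipeline (in order):
non-positive entries are dropped with a logged count; the natural logarithm
is applied (any base is equivalent up to the subsequent rescale); box-plot
outliers are removed using quartiles of **all** responses jointly — fences at
Q1 − 1.5·IQR and Q3 + 1.5·IQR with linearly interpolated order statistics
(the common "type 7" quantile; the filter acts on the log scale, after the
log transform); surviving log values are min-max scaled to [0, 1]. The
scaling is exactly invertible (round-trip error < 1e-9), so predictions map
back to concentrations. When a split is supplied, the min-max bounds come
from the training portion only; held-out values outside the training range
are reported as-is, unclipped. Record conservation holds exactly:
`n_in = n_retained + n_outliers + n_nonpositive`.

Omics blocks are z-scored per feature with training-row statistics
(population standard deviation); features constant over the training rows are
mapped to zero everywhere. Fingerprints and graphs enter unscaled (binary).

## Fingerprint key dictionary

No installed toolkit computes the 881-key PubChem substructure set, so the
package defines its own deterministic 881-key dictionary in the same style
(`nerd/_fingerprint_keys.py`): hierarchical element counts, ring keys
(size × composition × aromaticity/saturation × count), bonded element pairs,
atom-neighborhood patterns, curated functional groups, and element-environment
keys padding the layout to exactly 881. Keys are evaluated by RDKit
substructure matching; the layout is frozen by construction order and
asserted at import. The model consumes only the *format* (a fixed 881-bit
binary substructure vector); the key identities are this package's own and
fingerprints are not interchangeable with PubChem-derived ones. Precomputed
881-bit fingerprints from any source can be supplied via
`load_fingerprint_table` instead.

## Training

Supervised loss is the mean squared error of normalized labels. Defaults
(all config-overridable): Adam with learning rate 1e-3, batch size 256,
30 epochs, CNE pretraining 20 epochs at 1e-3, float32 arithmetic. These are
desk-scale defaults chosen so the standard synthetic scenario trains to
convergence in well under a minute on one CPU; on the synthetic benchmark the
validation RMSE plateaus after roughly 20–25 epochs and the best-validation
checkpoint (selected by validation RMSE every epoch) is returned. Training is
fully deterministic given the seed: initialization, shuffling and dropout
each draw from generators derived from it.

## Splits and evaluation

* **mixed** — pairs are shuffled and split 8:1:1 (train/validation/test).
* **drug-blind** — 10% of drugs form the test set with all their pairs; the
  remaining drugs are split 8:1 into training and validation drugs.
* **cell-blind** — likewise on cell lines; the validation cells are carved
  from the 90% training side (8:1), keeping the 10% test side untouched.
* **similarity bins** — entities are scored by mean similarity to all others
  (drugs: Tanimoto on fingerprints; cells: Pearson on concatenated
  standardized omics), sorted ascending and cut into near-equal groups; each
  group serves as a blind test set in turn (group 1 = least similar).
* **five-fold cross-validation** — the pair set is cut once (per seed) into
  ten equal pieces; fold k uses pieces 2k and 2k+1 as validation and test and
  the other eight for training, so every piece is held out exactly once
  across the five folds. The reported spread is the population (divisor-n)
  standard deviation.

Metrics: Pearson correlation, Spearman correlation (average ranks on ties),
R² = 1 − SS_res/SS_tot, RMSE. A constant truth vector raises an error rather
than returning NaN.

The data-reduction experiment subsamples the training partition uniformly
without replacement to a given fraction (validation and test untouched) and
retrains from scratch.

## Channel attribution

The value of a channel subset S is the test metric of a model trained with
exactly those channels; the empty coalition is the constant train-mean
predictor, whose correlations are defined as 0 (no association). Games are
normalized so v(∅) = 0, and RMSE is recast as improvement
(rmse(∅) − rmse(S)) so every game is higher-is-better. Shapley values are
exact (enumeration over the 4! orderings; the weighted-subset closed form is
kept as an independent cross-check) and reported per metric as percentage
shares normalized within the metric. Retraining per subset (rather than
masking inputs of a fixed model) is the default, matching the ablation
framing; the grid, split and seed are recorded alongside the output.

Stage embeddings for segment verification are taken at three points: the
initial feature concatenation (fingerprint ⊕ flattened padded graph block ⊕
miRNA ⊕ copy number; the widths are returned in a manifest), the
post-extractor concatenation (128 + 128 + 128 + 256 = 640), and the last
fusion hidden layer. The 2-D projection for visualization is plain t-SNE
(scikit-learn) and is plumbing, not part of the model.

## Synthetic data generator

The generator emulates the statistical shape the method assumes — it makes
no attempt at pharmacological realism beyond sparsity and heavy tails.

* **Drugs**: SMILES assembled from a concatenation-safe fragment grammar
  (alkyl chains, aromatic and saturated rings, carbonyl/amide/halogen
  substituents); every molecule parses and has 3–30 heavy atoms.
* **Cells**: a rank-r latent factor matrix drives the copy-number block
  (plus 10% noise), and a mixture of the same shared factors (weight 0.6)
  and miRNA-private factors (weight 0.8) drives the miRNA block — so the
  CNE compression is meaningful and the two omics blocks are correlated but
  not redundant.
* **Responses**: log IC50 = 0.5·z_d + 0.5·z_c + 0.15·z_d·z_c + ε with
  ε ~ N(0, noise_sd); z_d is a standardized random linear score of the
  fingerprint, z_c of the cell latents. With `cell_signal="shared"` the
  response uses the factors that drive copy number; with
  `cell_signal="mirna_private"` it uses the miRNA-private factors, making
  copy number provably uninformative — the variant used to test planted
  channel importance. The coefficients give the log response a spread of
  ≈ 0.73, large against the default noise (0.05), so near-perfect recovery
  is attainable and failures indicate implementation defects rather than
  noise. All generating weights are returned for oracle checks.
* **Outliers**: 1% of observed entries (exact count, sampled without
  replacement) are multiplied by 50. On the log scale this is a +log 50 ≈ 3.9
  shift, far outside the box-plot fences of the bulk (≈ ±2.0), so the IQR
  filter should recover essentially all of them; recall ≥ 0.9 is asserted.
* **Standard scenario**: 60 drugs × 40 cell lines, miRNA width 200,
  copy-number width 2000, 45% label density, noise 0.05, latent rank 5.
  This mirrors a large repurposing panel's *shape* (sparse, heavy-tailed,
  low-rank omics) at a size a single CPU trains in ~20 s.

What passing synthetic tests shows: the implementation learns a planted
signal delivered through all four channels, respects cold-start protocol
(held-out entities are genuinely unseen), and its preprocessing removes
planted contamination. What it does not show: performance on real screening
panels, where responses are noisier, batch-structured, and not low-rank;
absolute metric values here are not comparable to real-data benchmarks.

## Numerical choices

* All arithmetic in float32 by default (float64 available per module); the
  autograd engine's gradients are verified against central finite differences
  at 1e-4 relative tolerance.
* Max operations break ties toward the first index; Spearman uses average
  ranks; quantiles use linear interpolation.
* Batch normalization uses biased batch variance and momentum-0.1 running
  estimates; training mode requires batch size ≥ 2.
* Degenerate inputs raise informative errors: non-positive IC50s before the
  log, fewer than 4 values for the IQR filter, equal min-max bounds, constant
  truth in correlations, empty graphs, too-short CNN inputs.

## Known limitations

* The 881-key dictionary is format-compatible but not key-compatible with
  PubChem fingerprints (see above).
* The NumPy implementation is single-core and intended for datasets up to a
  few thousand entities; it has no sparse-graph batching, so very large
  molecules pad the whole graph batch.
* Correlations of constant predictors are defined as 0 in the attribution
  game; other conventions would shift the empty-coalition baseline but not
  the Shapley differences.
* The five-fold piece partition is fixed per seed and not re-randomized
  between experiments.
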