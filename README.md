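# nerd — multichannel drug-response prediction

`nerd` predicts the response of cancer cell lines to drugs — the IC50, the
concentration inhibiting 50% of cell activity — by integrating four
heterogeneous inputs with channel-specific neural feature extractors:

| channel | input | extractor | output |
|---|---|---|---|
| DSE | molecular graph (from SMILES, 78-dim binary atom features) | 3 graph-convolution layers + global max pooling | 128 |
| MFE | 881-bit substructure fingerprint | 3 × (1-D conv, ReLU, max-pool) | 128 |
| mEE | miRNA expression vector | 3 × (1-D conv, ReLU, max-pool) | 128 |
| CNE | DNA copy-number vector | stacked-autoencoder bottleneck | 256 |

The drug representation (DSE ⊕ MFE, 256-dim) and cell-line representation
(mEE ⊕ CNE, 384-dim) are concatenated and passed through fully connected
layers with batch normalization before each activation; a sigmoid maps the
output to (0, 1), the min-max-normalized log IC50. Each graph-convolution
layer computes

    H^(l+1) = σ( D̃^(-1/2) Ã D̃^(-1/2) H^(l) W^(l) ),   Ã = A + I,

with widths f → 2f → 4f (f = 78); each 1-D convolution follows the valid
cross-correlation length rule L' = (L + 2p − f)/s + 1 with p = 0, s = 1 and
kernel size 8, followed by non-overlapping max pooling with window 3. Training
minimizes the mean squared error of the normalized labels; the checkpoint with
the best validation RMSE is kept.

The package targets sparse screening panels (for example drug-repurposing
resources with ~40–45% of the drug × cell-line matrix labeled). It is aimed at
computational biologists who want a reproducible, CPU-only reference
implementation of multichannel response prediction with honest cold-start
(drug-blind / cell-line-blind) evaluation and exact Shapley attribution of
performance to the four input channels. The whole network, including a small
reverse-mode autograd engine, is implemented on NumPy — no GPU framework is
required.

Besides the model it provides:

* preprocessing: natural-log transform of IC50 with exact invertibility,
  joint box-plot outlier removal (fences Q1 − 1.5·IQR, Q3 + 1.5·IQR,
  interpolated quartiles), train-statistics z-scoring of omics blocks;
* splits: mixed 8:1:1, drug-blind, cell-blind, similarity-binned, five-fold
  cross-validation over ten fixed pieces; Pearson/Spearman/R²/RMSE metrics;
* a feature-ablation grid over all 16 channel subsets and exact 4-channel
  Shapley values (enumeration over the 4! orderings);
* a synthetic-data generator that plants a known response surface, correlated
  omics and box-plot outliers, so every pipeline stage is testable offline;
* a CLI: `nerd synth | train | evaluate | cv | blind | reduce | attribute | embed`.

## Worked example

```python
from nerd import DrugResponseModel, SyntheticScenario

model = DrugResponseModel.from_synthetic(SyntheticScenario(seed=7))
results = model.fit(split="mixed", seed=7)
print(results.summary())
```

```
Multichannel drug-response network
======================================================
channels:        dse, mfe, mee, cne
parameters:      6,839,861
split mode:      mixed (seed 7)
pairs:           845 train / 105 val / 107 test
epochs:          30 (best validation at epoch 24)
------------------------------------------------------
partition         CCp      CCs       R2     RMSE     n
train           0.983    0.985    0.958    0.042   845
val             0.979    0.977    0.948    0.045   105
test            0.976    0.977    0.949    0.046   107
======================================================
```

The synthetic scenario (60 drugs × 40 cell lines, 45% labeled) plants a
log-linear response in the drug's fingerprint and the cell's latent factors;
a test Pearson correlation (CCp) of 0.976 on held-out pairs means the network
recovered that planted signal almost completely (the residual RMSE of 0.046
on the [0, 1] label scale is close to the injected noise). Predictions map
back to concentrations exactly:

```python
df = results.predictions_frame("test").head(3)
print(results.predict_ic50(df.drug_id, df.cell_id))
# [0.96863655 1.39488994 0.8929762 ]   (raw IC50 units)
```

The same pipeline runs from the shell:

```bash
nerd synth --out data/ --seed 7
nerd train --manifest data/manifest.yaml --out runs/mixed --seed 7
nerd blind --axis drug --manifest data/manifest.yaml --out runs/drug_blind
nerd attribute --manifest data/manifest.yaml --out runs/shapley
```

## Layout

```
src/nerd/
  core_data.py    response/omics loading, log + IQR + min-max preprocessing
  featurize.py    SMILES -> molecular graph; 881-bit substructure fingerprint
  network.py      DSE / MFE / mEE / CNE extractors and the fusion head
  train_eval.py   splits, metrics, training loop, cross-validation
  attribution.py  ablation grid, exact Shapley values, stage embeddings
  synthetic.py    synthetic scenario generator (planted ground truth)
  model.py        DrugResponseModel / DrugResponseResults facade
  cli.py          command-line interface
  nn.py, _autograd.py   NumPy neural-network layers and reverse-mode autograd
docs/methods.md   model assumptions, defaults, numerical choices, limitations
```
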