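# grnvae

Prior-guided variational inference of per-cell transcription-factor (TF)
activities and weighted gene regulatory networks (GRNs) from single-cell
RNA-seq data.

The model is a variational autoencoder whose decoder ends in an
interpretable linear layer: a TF × gene weight matrix mapping an inferred TF
activity embedding to reconstructed expression. Training proceeds in three
phases:

1. **Prior initialization** — the GRN layer starts at a signed TF→target
   prior network, and TF activities are anchored to univariate-linear-model
   (ULM) estimates computed against that prior.
2. **Dynamic inference** — a scheduled coefficient α shifts the activity
   embedding from the ULM anchor toward the decoder's data-driven estimate,
   while a decreasing logistic mask m(t) relaxes the blend of the GRN layer
   with the prior, and an L1 penalty (linearly scheduled γ) sparsifies the
   learned weights.
3. **Cell-type fine-tuning** — the global model is cloned per cell type and
   trained further at reduced learning rate, yielding cell-type-specific
   GRNs and activities.

Downstream tooling covers differential TF activity (Wilcoxon one-vs-rest +
BH), TF–TF co-regulation via cosine similarity of GRN rows, cross-cell-type
GRN correlation with hierarchical clustering, and top-target
over-representation against user gene sets. A benchmarking module provides
Leiden clustering sweeps (ARI/NMI/macro-F1/AUC), dropout-mask robustness,
GRN edge-recovery AUROC/AUPRC, proportional stratified subsetting, and
knockdown log-fold-change evaluation. A seeded synthetic generator with
known activities and a known sparse signed GRN serves as ground truth for
all of it.

The network runs on HIPS `autograd` (pure numpy autodiff), so a plain CPU
scientific Python stack is sufficient — no GPU or deep-learning framework
required.

## CLI

```bash
# synthetic data with ground truth (writes MTX-free plain text)
grnvae simulate --out data/ --seed 42

# filter + log-normalize an expression matrix against a prior network
grnvae preprocess --expr counts.csv --prior prior.tsv --out prep/

# ULM activities, global training, inference, GRN export
grnvae activities-ulm --expr prep/ --out ulm.csv
grnvae train --expr prep/ --out model.npz --config train.yaml --seed 42
grnvae activities --model model.npz --expr prep/ --out acts.csv
grnvae grn --model model.npz --out grn.tsv

# cell-type fine-tuning and downstream analyses
grnvae finetune --model model.npz --expr prep/ --labels labels.tsv --out ct/
grnvae da --activities acts.csv --labels labels.tsv --out da.tsv
grnvae coreg --grns ct/ --da-table da.tsv --out edges.tsv
grnvae enrich --grn-file grn.tsv --tf PAX5 --gmt sets.gmt --out enr.tsv

# benchmarking
grnvae bench cluster --activities acts.csv --labels labels.tsv --out report.tsv
grnvae bench dropout --expr prep/ --p 0.3 --out dropped/
grnvae bench grn --pred grn.tsv --gold gold_edges.tsv
grnvae bench subsets --expr prep/ --k 5 --out subsets.tsv
grnvae bench knockdown --activities acts.csv --groups groups.tsv --tf ELK1
```

Expression input formats: dense CSV/TSV (cells × genes, header = genes),
Matrix Market `.mtx` with `barcodes.tsv`/`features.tsv` sidecars, or
`.h5ad`. Priors are 3-column tables `tf, target, sign` with sign ∈ {+1, −1}
(textual aliases such as "activation"/"repression" accepted).

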