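# phoskan

Residue-level phosphorylation-site prediction from **bimodal sequence
embeddings**: an amino-acid-aware track fused with a codon-aware track,
classified by a convolution + bidirectional-GRU feature extractor with a
**wavelet Kolmogorov–Arnold network (Wav-KAN)** head.

## Who this is for

Computational biologists who want a fully inspectable, CPU-only
implementation of the codon-aware phosphosite-prediction pipeline: the
reverse-translation/CDS-verification step, the early-fusion window
representation, the ConvBiGRU + Wav-KAN classifier, the training and
evaluation protocol, and a synthetic-data harness that exercises all of
it end to end without pretrained language-model weights.

## The method in brief

1. **Reverse translation.** For each protein, candidate coding sequences
   are read from local GenBank records, translated under the standard
   genetic code, and globally aligned to the protein
   (Needleman–Wunsch).  Only 100%-identity pairs are kept; the terminal
   stop codon is stripped, leaving a CDS of length exactly 3N.
2. **Embedding fusion.** Two frozen encoders produce per-residue
   matrices: amino-acid track `E_aa ∈ R^{N×1024}` and codon track
   `E_codon ∈ R^{N×768}`.  Early fusion concatenates them to
   `E = (E_aa | E_codon) ∈ R^{N×1792}`.  A deterministic synthetic
   encoder (with a plantable class signal) ships with the package; real
   encoder adapters plug in behind the same shape contract.
3. **Window framing.** Each candidate S/T/Y site becomes one sample: the
   W = 9 rows centered on it (`9 × 1792`; zero-padded at termini), local
   in position but global in context.
4. **Classifier.** 16 valid 5×5 conv kernels + ReLU (`→ 16 × 5 × 1788`),
   a bidirectional GRU with 8 units over the 5-row axis (`→ 5 × 16`),
   flatten (`→ 80`), then batch-normalized Kolmogorov–Arnold layers
   whose edges apply learnable wavelets `ω·ψ((x−τ)/s)` (DoG
   `ψ(t) = t·e^{−t²/2}` by default; Mexican Hat, Morlet, Shannon and
   Meyer are registered) — hidden layout [128, 32] for the S+T model,
   [24] for the Y model — and a sigmoid output unit.
5. **Training/evaluation.** BCE-with-logits, Adam (9e-4, β = 0.9/0.999),
   early stopping on validation loss, protein-grouped stratified CV,
   and an imbalance-aware metric suite (MCC, precision, recall,
   specificity, F1, weighted F1, AUPR, AUROC).

The numeric core is a small reverse-mode autograd engine over numpy,
verified by finite-difference checks; no GPU framework is required.

## Worked example

Generate a toy study, verify its coding sequences, featurize, train the
S+T model and evaluate — all from the shell:

```bash
phoskan toydata   --out toy --n-proteins 40 --seed 5
phoskan revtrans  --proteins toy/proteins.fasta --genbank-dir toy/genbank --out toy/verified
phoskan featurize --proteins toy/verified.proteins.fasta \
                  --cds toy/verified.cds.fasta \
                  --sites toy/sites.tsv --out toy/features.npz --seed 5
phoskan train     --features toy/features.npz --out toy/model --seed 5
phoskan predict   --checkpoint toy/model \
                  --proteins toy/verified.proteins.fasta \
                  --cds toy/verified.cds.fasta \
                  --sites toy/sites.tsv --out toy/preds.tsv --seed 5
phoskan evaluate  --predictions toy/preds.tsv --truth toy/sites.tsv --out toy/metrics.tsv
```

Output of the run above:

```
wrote 40 proteins, 578 sites (83 P) to toy
accepted 40/40 proteins (0 rejected)
featurized 578 sites -> toy/features.npz
best epoch 9 (val loss 0.0597) -> toy/model
wrote 578 predictions -> toy/preds.tsv
MCC 0.9525  AUPR 0.9965842594471358
```

Reading the numbers: all 40 toy proteins pass the 100%-identity CDS
filter (the generator builds coding sequences by forward translation, so
none are lost); 578 candidate S/T/Y sites are framed into 9 × 1792
windows; training selects the epoch with the lowest validation loss on
a held-out protein split; and on the full site table the trained model
separates planted positives from negatives almost perfectly
(AUPR ≈ 0.997, MCC ≈ 0.95) — expected on training proteins, since the
toy study plants a strong, localized embedding signal.
Held-out-protein performance is what `scripts/acceptance.py` measures.

The same workflow is available as a library; see
`phoskan.protocol.run_planted_benchmark` for the programmatic
train-on-split/evaluate-held-out version, and `docs/methods.md` for the
model, its assumptions and the synthetic-data design.

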