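# m6amstack

Stacking-ensemble deep learning for predicting m6Am
(N6,2′-O-dimethyladenosine) sites in fixed-length RNA windows.

A 41-nt window centered on a candidate adenosine is one-hot encoded and
scored by three heterogeneous base classifiers:

* **densenet_senet** — squeeze-and-excitation attention on the input, six
  densely connected convolutional blocks each followed by a residual SE
  gate;
* **dcnn_bilstm** — three parallel dilated-convolution branches (rates
  1, 2, 3) whose feature maps are spliced and read by a BiLSTM;
* **msrn_bigru** — six cascaded multi-scale residual blocks (3 conv layers,
  64 kernels each), hierarchical fusion through a 192-filter convolution,
  then a BiGRU.

Their out-of-fold probabilities, concatenated with the flattened one-hot
features (3 + 41·4 = 167 meta-features), train a logistic-regression
meta-learner. The package also ships the alternative encodings
(nucleotide chemical property + nucleotide density), an evaluation harness
(Sn/Sp/ACC/MCC, AUROC, AUPR, repeated stratified CV, negative-resampling
stability), a positional-enrichment motif analysis, and a synthetic-data
generator that plants a position-specific motif at controllable effect
size so the entire pipeline is testable offline.

The neural networks run on a small numpy reverse-mode autodiff engine
bundled in `m6amstack.nn` (no GPU or deep-learning framework required);
gradients are verified against finite differences in the test suite.

## CLI

```bash
m6amstack simulate --n-pos 200 --n-neg 200 --effect 0.8 --seed 1 --out sim/
m6amstack encode sim/windows.tsv --encoding onehot --out sim/onehot.tsv
m6amstack train sim/windows.tsv --folds 5 --seed 1 --out model/
m6amstack predict model/ sim/windows.fasta --out preds.tsv
m6amstack evaluate preds.tsv sim/windows.tsv --out metrics.json
m6amstack cv sim/windows.tsv --folds 5 --seed 1 --out cv/
m6amstack motif sim/windows.tsv --out enrichment.tsv --plot logo.png
```

Training hyperparameters (epochs, batch size, learning rate, dropout,
early-stopping patience) can be overridden with `--config file.ini`
(flat `key = value` lines). Every artifact-producing run writes a
`manifest.json` so it can be reproduced bit-for-bit. Labeled datasets are
accepted either as TSV/CSV (`sequence`,`label` columns) or as FASTA with a
`pos`/`neg` token in the header.

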