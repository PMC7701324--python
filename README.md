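# psgkmer

Prediction of RNA 5-hydroxymethylcytosine (5hmC) sites from sequence
alone, using **position-specific gapped k-mer** binary descriptors,
mode-wise impurity-based feature selection, and a logistic-regression
classifier.

5hmC is a cytosine modification whose transcriptome-wide distribution is
expensive to map experimentally. Given a fixed-length window (41 nt by
default) centred on a candidate cytosine, this package predicts whether
the central C carries the mark. It is aimed at epitranscriptomics
researchers who want a transparent, sequence-only baseline predictor
whose features are directly interpretable as "pattern *p* matched at
window positions *i..j*".

## Model

A window `s` of length *L* over {A,C,G,U} is encoded into binary
indicators

```
f_ij = 1  if pattern j matches the window of s starting at position i,
       0  otherwise
```

where the patterns come from ten families (feature types FT1–FT10):
ungapped k-mers for k = 1, 2, 3 (FT1–FT3); a monomer and a dimer
separated by g ∈ {1,2,3} "don't care" gaps, e.g. `A--CG` (FT4–FT6); the
mirrored dimer-gap-monomer shape (FT7–FT9); and three monomers with
single gaps, `A-C-G` (FT10). Each family enumerates all 4^3 (or 4^k)
fixed-nucleotide combinations, so per window position exactly one
pattern of each family matches. With the GC-content percentage
(FT11) appended, *L* = 41 yields 19,876 binary columns + 1 = **19,877
features**, of which each row has exactly 379 ones.

Because descriptors within one generation mode are strongly correlated,
feature reduction is done **per mode**: an independent random forest
(Gini mean-decrease-in-impurity importance) ranks each of the four mode
groups, the top *k* = 100 of each are kept, and GC-content is added
unconditionally — 4k + 1 = **401 features**. An L2-regularized logistic
regression (L-BFGS, unit regularization strength) is fitted on the
reduced matrix. Evaluation uses accuracy / precision / sensitivity /
specificity (percent), F1 and MCC, auROC / auPR, under repeated
stratified 5-fold cross-validation in which **selection is re-run inside
every training fold** so held-out folds never leak into feature choice.

## Worked example

```python
from psgkmer import benchmark_like, generate, encode_dataset, groupwise_select

spec = benchmark_like(seed=7)          # 662 + 662 windows, 4 planted motifs
dataset = generate(spec)
matrix = encode_dataset(dataset)       # 1324 x 19877
result = groupwise_select(matrix, k=100, seed=7)
print(len(result.selected_names))      # 401
```

Running `python examples/simulate_and_select.py` prints:

```
dataset: 1324 windows (662 positive / 662 negative)
encoded matrix: 1324 x 19877
selected 401 features (top 100 per mode group + GC)
planted motif descriptors recovered: 4/4
  FT7:GG-A@11-14
  FT7:CA-C@24-27
  FT9:AC---G@28-33
  FT5:U--AG@34-38
```

i.e. all four motifs planted by the generator are recovered among the
401 selected descriptors; a name like `FT9:AC---G@28-33` reads "the
gapped pattern AC---G matched at window 28–33". The companion scripts
`examples/train_and_predict.py` (90/10 stratified holdout; prints a
confusion matrix and holdout accuracy 73.5% for seed 11) and
`examples/cross_validate.py` (repeated 5-fold CV with per-metric
mean ± std) show the remaining stages; accuracies on the synthetic
benchmark-shaped data depend on the planted signal strength, not on any
real transcriptome.

## Command line

```sh
psgkmer simulate --benchmark-like --seed 1 --out-prefix data/sim
psgkmer encode data/sim.fasta --labels data/sim.labels.tsv --out data/sim.triplets
psgkmer train data/sim.fasta data/sim.labels.tsv --model-out run/model.json
psgkmer cv data/sim.fasta data/sim.labels.tsv --report-out run/cv.json
psgkmer predict data/sim.fasta --model run/model.json --out run/preds.tsv
psgkmer stable-features data/sim.fasta data/sim.labels.tsv --out run/stable.json
```

Every command writes a resolved `.config` file next to its outputs from
which the run can be reproduced exactly.

## Documentation

See `docs/methods.md` for the model assumptions, parameter defaults,
what the synthetic generator does and does not emulate, and known
limitations.
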