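"""Repeated stratified 5-fold cross-validation with in-fold selection.

Feature selection is re-run inside every training fold, so the held-out
fold never influences which descriptors the model sees — the same
leakage guard the full-size protocol uses.  Two repeats keep the example
quick; the protocol default is ten.
"""

from psgkmer import benchmark_like, cross_validate, generate

dataset = generate(benchmark_like(seed=5))
report = cross_validate(dataset, folds=5, repeats=2, k=100, seed=5)

print(f"{'metric':<12}{'mean':>8}{'std':>8}")
for metric, value in report.mean.items():
    print(f"{metric:<12}{value:>8.3f}{report.std[metric]:>8.3f}")
# Percent metrics (accuracy .. specificity) are on 0-100; F1, MCC,
# auROC and auPR are fractions.  The std is across repeat-level means.
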