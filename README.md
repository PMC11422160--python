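# hapnn

Reference-free genotype imputation with neural sequence models, plus a
two-stage strategy that makes it robust to markers lost during SNP-array
quality control.

## The problem

Genotype imputation infers genotypes at untyped variant sites from the
linkage disequilibrium (LD) between typed array markers and their
neighbours. The widely used methods condition on a phased haplotype
reference panel at run time — so the panel must be shared in identifiable
form, which privacy and consent rules often forbid. An alternative is to
train neural networks on the panel once and distribute only the model
parameters: *reference-free* imputation. The catch: such models are
ordinary supervised learners. When array QC removes markers (deviation
from Hardy–Weinberg equilibrium, low call rate — typically up to 20% of
markers), the model receives inputs unlike anything it was trained on and
its accuracy collapses, while classical hidden-Markov methods simply skip
the missing markers.

`hapnn` implements both the imputer and the cure:

* **Stage 1 — RCDA**: a per-region *residual convolution denoising
  autoencoder* (3-state one-hot input: missing / a0 / a1; residual conv
  blocks with batch-norm; two pool/upsample pairs; 2-class softmax
  output) trained to reconstruct clean marker alleles from randomly
  masked haplotypes. At run time it fills QC-removed markers with hard
  allele calls.
* **Stage 2 — recurrent imputer**: per region, 4 bidirectional GRU
  layers (hidden size 40) read the array-marker sequence (with 50-marker
  flanks at full scale); each untyped target site has a small head over
  the hidden states of its two bracketing markers and outputs allele
  probabilities. Haplotype pairs combine under independence into
  genotype probabilities and the a1 dosage `P(het) + 2·P(hom-a1)`.

Accuracy is measured per site as **R²** — the squared Pearson correlation
between true a1 genotype counts and imputed dosages across individuals —
stratified by minor allele frequency (MAF).

The package also ships a mosaic-of-founders haplotype simulator (tunable
LD, no external data needed), VCF/BED/site-list I/O, and an evaluation
harness, so the entire pipeline is trainable and testable on a laptop.
The neural networks run on a compact NumPy autodiff core included in the
package; there is no deep-learning-framework dependency.

## Worked example

```python
import numpy as np
from hapnn import (
    ExperimentConfig, end_to_end_experiment,
)

result = end_to_end_experiment(ExperimentConfig(seed=1))
for (strategy, rate), r2 in sorted(result.mean_r2.items()):
    print(f"{strategy:>9} fill, missing rate {rate:4.2f}: mean R2 = {r2:.3f}")
print(f"gap recovered by two-stage: {result.gap_recovery:.2f}")
print(f"fill accuracy {result.rcda_fill_accuracy:.3f} "
      f"vs major-allele baseline {result.baseline_fill_accuracy:.3f}")
```

Output (about six minutes on one CPU):

```
frequency fill, missing rate 0.01: mean R2 = 0.720
frequency fill, missing rate 0.05: mean R2 = 0.672
frequency fill, missing rate 0.10: mean R2 = 0.634
frequency fill, missing rate 0.20: mean R2 = 0.480
     none fill, missing rate 0.00: mean R2 = 0.728
     rcda fill, missing rate 0.01: mean R2 = 0.728
     rcda fill, missing rate 0.05: mean R2 = 0.714
     rcda fill, missing rate 0.10: mean R2 = 0.701
     rcda fill, missing rate 0.20: mean R2 = 0.661
gap recovered by two-stage: 0.73
fill accuracy 0.928 vs major-allele baseline 0.755
```

Reading it: with complete marker input the imputer reaches mean R² 0.728
at common target sites. Replacing 20% of markers by their frequency
vector (what the bare model must do when QC removes them) drops accuracy
to 0.480; letting the denoising autoencoder fill those markers first
(it calls 92.8% of the masked genotypes correctly, far above the 75.5%
major-allele baseline) restores accuracy to 0.661 — 73% of the loss
recovered.

The `examples/` directory has one short script per capability:
simulating panels with LD, training and using the denoiser, imputing and
writing dosage VCFs, and the strategy comparison above at reduced size.
A thin CLI is included: `hapnn simulate` writes reference/test VCFs and a
marker list; `hapnn train` fits both model sets on a reference VCF and
saves per-region checkpoints; `hapnn impute` loads the checkpoints and
writes a GT/DS/GP dosage VCF for array-genotyped individuals (markers
absent from the input are treated as QC-removed and filled by the chosen
strategy); `hapnn run-experiment` drives the benchmark from a YAML
config.

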