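# Methods

## Problem setting

SNP arrays genotype a fixed set of marker positions; genotype imputation
infers the genotypes at the remaining segregating sites from linkage
disequilibrium (LD) between markers and their untyped neighbours.
Classical imputation methods condition on a phased haplotype reference
panel at run time, which requires distributing the panel in identifiable
form. The models in this package instead absorb the panel into trained
network parameters — reference-free imputation — at the price of being
ordinary supervised models: they expect the marker input they were trained
on, and markers removed during array quality control (QC) leave holes the
models were never taught to handle.

The package implements a two-stage answer to that fragility:

1. **Stage 1 (RCDA).** A residual convolution denoising autoencoder per
   region reconstructs clean marker alleles from corrupted input and is
   used to fill QC-removed markers with hard allele calls.
2. **Stage 2 (recurrent imputer).** A stack of bidirectional gated
   recurrent layers per region maps the (filled) marker sequence of one
   haplotype to 2-class allele probabilities at every untyped target site.

The stages are trained independently, on different region grids, and
nothing backpropagates between them.

## Data model and conventions

All sites are biallelic; the two alleles are labelled a0 (VCF REF
orientation) and a1, and a haplotype panel is a {0,1} matrix of a1
indicators, sites × haplotypes, with each diploid sample owning two
adjacent columns. VCF positions are 1-based, BED intervals half-open
0-based; all region arithmetic happens in site-index space so the file
conventions only matter at the boundary. Chromosome labels are
normalised by stripping a `chr` prefix. Ploidy is fixed at two.

Per-site allele frequency `f_a1` is the row mean of the allele matrix;
MAF is `min(f_a1, 1 − f_a1)`.

## Region segmentation

LD blocks (an input, e.g. a published block map in BED) are subdivided so
no region exceeds a marker budget: a block with `m` markers becomes
`ceil(m / budget)` sub-regions with marker counts differing by at most one
(a greedy cut-every-`budget`-markers mode exists behind a flag), split
boundaries at the bp midpoint between adjacent markers. Blocks with no
markers merge into their left neighbour (leftmost merges right). The
recurrent imputer uses a budget of about 200 markers with up to 50 flank
markers attached on each side; the denoiser uses about 500 markers and no
flanks. Target sites belong to the region whose core span contains their
position (the outermost spans are extended to the chromosome ends), which
makes target assignment a partition. Targets with reference-panel
MAF < 0.005 are dropped before training: rare variants dominate training
cost and are poorly learnable at panel scale. Segmentation is a pure
function of its inputs; region manifests serialise to JSON with a content
hash, and trained models refuse to impute against a different manifest.

## Stage 1: residual convolution denoising autoencoder

Input markers are 3-state one-hots (missing, a0, a1), shape
(haplotypes, 3, markers). The layer stack, with output channel sizes:

    ResBlock 32 → ReLU → MaxPool/2 → ResBlock 64 → ReLU → MaxPool/2
    → ResBlock 128 → ReLU → ResBlock 64 → ReLU → Upsample×2
    → ResBlock 32 → ReLU → Upsample×2 → Conv 2 → Softmax 2

Each residual block is conv–batchnorm–ReLU–conv–batchnorm on the main
path, an identity skip (1×1 convolution when channel counts change), and
an elementwise sum; the outer ReLU follows the sum, so a zero-initialised
block with identity skip is exactly the identity map. Batch
normalisation inside the blocks is the regulariser; there is no dropout
and no kernel sparsity penalty. Convolutions use same padding with an
odd kernel (default 5). The output head has only the two allele classes:
the model never needs to predict "missing". The two pool/upsample pairs
need the length divisible by four, so input is right-padded with the
missing one-hot and the output trimmed.

Training is denoising: each epoch, each training haplotype gets a mask
rate drawn uniformly from [0.01, 0.2] (the range of marker loss array QC
typically produces; a fixed-rate mode exists) and sites are masked i.i.d.
at that rate. The loss is mean cross-entropy against the uncorrupted
alleles at **all** sites, not only masked ones. Optimisation is Adam
(lr 0.001, batch 32); a validation set of individuals (both haplotypes,
held out at the individual level to avoid leakage) is masked once with a
fixed mask so its loss is comparable across epochs, and the parameters
with the best validation loss are returned. At fill time, missing
entries get the argmax allele — an exact 0.5 tie falls to the
region-major allele — and observed entries pass through verbatim.

## Stage 2: bidirectional recurrent imputer

Markers are encoded as 2-vectors: observed a0 → (1,0), observed a1 →
(0,1), missing → (1 − f_a1, f_a1) with frequencies from the reference
panel (test-set frequencies would leak and be unstable at typical test
sizes). Four bidirectional GRU layers of hidden size 40 read the
region's marker sequence (flanks + core); layer l consumes the
concatenated forward/backward states of layer l − 1. Each target site
has its own linear head over the concatenated forward/backward hidden
states of the two markers bracketing its position (4 × 40 features; the
nearest marker is duplicated when a target falls outside the marker
range), followed by a 2-class softmax. Gate order is (reset, update,
candidate) with the reset gate applied to the recurrent contribution of
the candidate state.

Training is supervised on clean inputs: reference haplotypes restricted
to the region markers in, reference alleles at target sites out, mean
cross-entropy over targets, Adam (lr 0.001), validation-individual
holdout with best-loss selection and early stopping (patience 20 by
default). Clean-input training is deliberate: the point of the pipeline
is that this model does *not* see missing values during training, and
stage 1 exists to protect it. A masking-augmentation flag is out of the
default path.

Imputation is per haplotype; an individual's two haplotype probabilities
p and q combine under independence: P(hom-a1) = pq, P(het) =
p(1 − q) + q(1 − p), dosage = p + q. Per-region results concatenate into
a genome-wide table (a partition by construction) and can be written as a
VCF with GT/DS/GP fields.

## Evaluation

Per target site, R² is the squared Pearson correlation between true a1
genotype counts (0/1/2) and imputed dosages across individuals. Sites
where either vector is constant have no defined correlation; they are
flagged and excluded from means (their count is reported), not scored
zero. Binned summaries use logarithmic-style MAF edges
{0.005, 0.01, 0.02, 0.05, 0.1, 0.2, 0.35, 0.5} by default; headline
means use common sites (MAF ≥ 0.05). The MAF used for binning comes from
the combined (reference + test) panel; the reference-only alternative is
available.

## Synthetic data

The simulator is a mosaic-of-founders model: founder haplotypes drawn
site-wise Bernoulli(p_s) with p_s ~ Beta(0.4, 0.4) (a U-shaped frequency
spectrum), 12 founders by default; each haplotype copies a founder and
switches to a uniformly chosen founder with per-site probability 0.01,
giving geometric segment lengths that approximate uniform recombination;
each emitted allele flips with probability 0.002. Positions are 1 kb
apart. This produces the block-correlated structure the models need with
no external data or coalescent machinery. What it does **not** emulate:
realistic site-frequency spectra, recombination hotspots, gene
conversion, population structure, genotyping error correlated with allele
frequency. Passing benchmarks here therefore demonstrate that the
machinery learns and exploits LD, not that real-chromosome accuracy
numbers transfer.

Marker selection mimics array design by sampling uniformly among sites
with MAF ≥ 0.05; missingness is whole-marker (QC semantics: a removed
marker is missing for every sample) at rates {0.01, 0.05, 0.1, 0.2},
with the per-genotype variant reserved for denoiser training.

## Desk-scale benchmark

`end_to_end_experiment` runs the full contrast on one CPU in a few
minutes: 600 sites × 150 samples, 120 markers, 25 test individuals, 20
validation individuals, 4 LD blocks; recurrent regions at a 60-marker
budget with 15-marker flanks (4 regions), denoiser regions at the
500-marker budget (one per block); recurrent training ≤100 epochs
(batch 64, patience 15), denoiser 200 epochs. These sizes are the
package's desk defaults chosen so the whole simulate–train–impute–
evaluate loop stays in the minutes range; every architectural constant
(4 layers, hidden 40, channel stack, kernel 5, Adam lr 0.001, denoiser
batch 32, mask range [0.01, 0.2]) is kept at its full-scale value. At
production scale one would raise the budgets to 200/500 markers, flanks
to 50, validation to 100 individuals and epochs into the hundreds to
thousands; all of these are plain configuration.

The benchmark reports, per missing rate and fill strategy, the mean
common-variant R², the denoiser's masked-entry fill accuracy against a
major-allele baseline, and the fraction of the R² gap (clean minus
frequency-filled) that the two-stage strategy recovers.

## Numerical choices

The networks run on a small reverse-mode autodiff engine over NumPy
(float32 parameters), sized to the models' needs: im2col convolution,
fused softmax/cross-entropy, and a fused GRU-sequence op whose
backward-through-time loop is hand-derived so the recurrent inner loop
runs at raw-NumPy cost. All gradients are verified against central
finite differences in the test suite. Every stochastic component
(simulation, marker choice, splits, masks, parameter init, batch order)
derives its generator from an explicit integer seed via seed sequences,
so runs are bit-reproducible at a fixed BLAS thread count. Adam uses
the standard bias-corrected update (β = 0.9/0.999, ε = 1e-8).
Degenerate inputs are handled explicitly: monomorphic evaluation sites →
flagged undefined rather than 0; argmax ties at 0.5 → region-major
allele; empty LD blocks → merged; haploid or non-{0,1} panels →
rejected.

## Known limitations

* The recurrent architecture beyond what is fixed above (cell type,
  head wiring, target-to-marker attachment) is one reasonable design
  among several; it is documented here precisely because alternatives
  (per-target models, attention over markers, dosage-regression heads)
  would also fit the same interface.
* Stage-1 fills are hard calls; a soft-probability interface between the
  stages is future work.
* Rare variants (MAF < 0.005) are excluded as targets; the denoiser is
  also weakest for rare markers, so recovery is smallest exactly where
  accuracy is hardest to earn.
* Single chromosome per call; no BCF/tabix indexing; diploid only.
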