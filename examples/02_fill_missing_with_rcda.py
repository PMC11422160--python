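"""Train the denoising autoencoder and fill markers lost to array QC.

A fraction of array markers is removed for every sample (whole-marker
missingness, as when markers fail quality control).  The residual
convolution denoising autoencoder learns from the reference haplotypes to
reconstruct each marker from its LD neighbourhood, and beats the
guess-the-major-allele baseline.
"""

import numpy as np

from hapnn import (
    RcdaTrainConfig,
    SimConfig,
    apply_marker_missingness,
    compute_freqs,
    fill_missing,
    select_markers,
    simulate_panel,
    split_samples,
    train_rcda,
)
from hapnn.rcda import MISSING
from hapnn.regions import build_regions, subdivide_blocks, uniform_blocks

panel = simulate_panel(SimConfig(n_sites=300, n_samples=120, seed=5))
assignment = select_markers(panel, 60, maf_min=0.05, seed=5)
reference, test = split_samples(panel, n_test=20, seed=5)

blocks = uniform_blocks("22", int(panel.positions[-1]) + 1, 1)
spans = subdivide_blocks(blocks, panel.positions[assignment.marker_idx], 500)
region = build_regions(spans, assignment, panel.sites, n_flank=0)[0]

trained = train_rcda(
    reference, region, RcdaTrainConfig(epochs=60, n_validation=15, seed=5)
)
print(f"trained {len(trained.log['val_loss'])} epochs; best validation "
      f"cross-entropy {min(trained.log['val_loss']):.4f} "
      f"at epoch {trained.log['best_epoch']}")

mask = apply_marker_missingness(assignment.marker_idx, rate=0.2, seed=9)
states = test.alleles[assignment.marker_idx, :].astype(np.int8)
truth = states.copy()
rows = np.searchsorted(assignment.marker_idx, mask.removed_marker_idx)
states[rows, :] = MISSING

filled, confidence = fill_missing(trained, states)
missing = states == MISSING
accuracy = (filled[missing] == truth[missing]).mean()
major = (compute_freqs(reference).f_a1[assignment.marker_idx] > 0.5).astype(np.int8)
baseline = (np.broadcast_to(major[:, None], truth.shape)[missing] == truth[missing]).mean()

print(f"masked {rows.size} of {assignment.marker_idx.size} markers for all "
      f"{test.n_haplotypes} test haplotypes")
print(f"fill accuracy at masked entries: {accuracy:.3f} "
      f"(major-allele baseline {baseline:.3f})")
print("accuracy above the baseline means the model is using LD context, "
      "not just allele frequencies.")
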