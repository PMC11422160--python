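"""Run a reduced two-stage benchmark: degradation and recovery.

Compares three ways of handling array markers lost to quality control
before recurrent imputation: complete input ("none"), frequency-vector
fill ("frequency"), and denoiser fill ("rcda").  The headline effect is
that missingness degrades imputation accuracy and stage-1 denoising
recovers most of the loss.  (Sizes here are reduced further than the
package defaults so the script finishes in a couple of minutes; run
scripts/acceptance.py for the full desk-scale numbers.)
"""

from hapnn import ExperimentConfig, end_to_end_experiment

config = ExperimentConfig(
    n_sites=300,
    n_samples=100,
    n_markers=60,
    n_test=15,
    n_blocks=2,
    rnn_region_budget=30,
    rnn_max_epochs=40,
    rcda_epochs=60,
    n_validation=12,
    rates=(0.2,),
    seed=11,
)
result = end_to_end_experiment(config)

print("mean R^2 at common target sites (MAF >= 0.05):")
for (strategy, rate), value in sorted(result.mean_r2.items()):
    print(f"  {strategy:>9} fill, missing rate {rate:0.2f}: {value:.3f}")
print(f"denoiser fill accuracy {result.rcda_fill_accuracy:.3f} vs "
      f"major-allele baseline {result.baseline_fill_accuracy:.3f}")
print(f"fraction of the R^2 gap recovered by the two-stage strategy: "
      f"{result.gap_recovery:.2f}")
print("'none' is the ceiling (no markers lost); 'frequency' shows the cost "
      "of missingness; 'rcda' shows how much stage-1 denoising wins back.")
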