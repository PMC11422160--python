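"""Two-stage imputation pipeline and the self-contained benchmark.

Stage 1 (optional): a per-region residual-convolution denoising
autoencoder fills missing array-marker genotypes with hard allele calls.
Stage 2: per-region bidirectional recurrent imputers estimate a1 dosages
at untyped target sites from the (filled) marker sequence.  Three fill
strategies are supported for the stage-2 input:

* ``none`` — inputs must be complete (errors otherwise);
* ``frequency`` — missing markers are encoded as [1 - f_a1, f_a1];
* ``rcda`` — missing markers are filled by the stage-1 denoiser first.

The stages use independent region grids (the denoiser trains on larger
regions than the recurrent model); stage-1 output is flattened back to
the global marker vector before stage-2 encoding, so the grids never need
to align.  Nothing backpropagates across stages.

``end_to_end_experiment`` is the desk-scale benchmark: it simulates a
panel, trains both model sets, imputes the held-out individuals under
every strategy and missing rate, and reports R² tables plus the
denoiser's fill accuracy against a major-allele baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .io import FreqTable, HaplotypePanel, SiteMeta, compute_freqs
from .metrics import EvalTable, build_eval_table
from .rcda import (
    MISSING,
    RcdaTrainConfig,
    TrainedRcda,
    fill_missing,
    train_rcda,
)
from .regions import (
    RegionSpec,
    build_regions,
    filter_targets_by_maf,
    subdivide_blocks,
    uniform_blocks,
)
from .rnn import (
    DosageResult,
    RnnConfig,
    RnnTrainConfig,
    TrainedRnn,
    combine_haplotypes_to_genotypes,
    encode_marker_inputs,
    impute_region,
    merge_regions,
    train_rnn,
)
from .sim import (
    MarkerAssignment,
    MissingMask,
    SimConfig,
    apply_marker_missingness,
    select_markers,
    simulate_panel,
    split_samples,
)

__all__ = [
    "PipelineConfig",
    "TrainedModels",
    "train_models",
    "run_two_stage",
    "ExperimentConfig",
    "ExperimentResult",
    "end_to_end_experiment",
]

STRATEGIES = ("none", "frequency", "rcda")


@dataclass(frozen=True)
class PipelineConfig:
    """Segmentation and filtering parameters shared by both stages."""

    fill_strategy: str = "rcda"
    rcda_region_budget: int = 500
    rnn_region_budget: int = 200
    n_flank: int = 50
    maf_min_targets: float = 0.005
    seed: int = 0

    def __post_init__(self):
        if self.fill_strategy not in STRATEGIES:
            raise ValueError(f"fill_strategy must be one of {STRATEGIES}")
        if self.rcda_region_budget < 1 or self.rnn_region_budget < 1:
            raise ValueError("region budgets must be >= 1")


@dataclass
class TrainedModels:
    """Both trained model sets plus the shared experiment context."""

    sites: list[SiteMeta]
    assignment: MarkerAssignment
    freqs_ref: FreqTable
    rnn_regions: list[RegionSpec]
    rcda_regions: list[RegionSpec]
    rnn: list[TrainedRnn]
    rcda: list[TrainedRcda]

    @property
    def target_sites(self) -> np.ndarray:
        return np.concatenate([r.target_idx for r in self.rnn_regions])


def _marker_rows(assignment: MarkerAssignment, global_idx: np.ndarray) -> np.ndarray:
    rows = np.searchsorted(assignment.marker_idx, global_idx)
    if not np.array_equal(assignment.marker_idx[rows], global_idx):
        raise ValueError("indices are not all array markers")
    return rows


def train_models(
    reference: HaplotypePanel,
    assignment: MarkerAssignment,
    blocks,
    pipeline_cfg: PipelineConfig,
    rnn_arch: RnnConfig = RnnConfig(),
    rnn_train: RnnTrainConfig = RnnTrainConfig(),
    rcda_train: RcdaTrainConfig = RcdaTrainConfig(),
) -> TrainedModels:
    """Segment the chromosome on both grids and train every region model."""
    freqs_ref = compute_freqs(reference)
    positions = reference.positions
    marker_pos = positions[assignment.marker_idx]

    rnn_spans = subdivide_blocks(blocks, marker_pos, pipeline_cfg.rnn_region_budget)
    rnn_regions = build_regions(rnn_spans, assignment, reference.sites, rnn_arch.n_flank)
    rnn_regions = [
        replace_targets(r, filter_targets_by_maf(r.target_idx, freqs_ref,
                                                 pipeline_cfg.maf_min_targets))
        for r in rnn_regions
    ]

    rcda_spans = subdivide_blocks(blocks, marker_pos, pipeline_cfg.rcda_region_budget)
    rcda_regions = build_regions(rcda_spans, assignment, reference.sites, n_flank=0)

    rnn_models = [
        train_rnn(reference, region, rnn_arch,
                  replace(rnn_train, seed=rnn_train.seed + region.region_id))
        for region in rnn_regions
        if region.target_idx.size
    ]
    rnn_regions = [r for r in rnn_regions if r.target_idx.size]
    rcda_models = [
        train_rcda(reference, region,
                   replace(rcda_train, seed=rcda_train.seed + region.region_id))
        for region in rcda_regions
    ]
    return TrainedModels(
        sites=list(reference.sites),
        assignment=assignment,
        freqs_ref=freqs_ref,
        rnn_regions=rnn_regions,
        rcda_regions=rcda_regions,
        rnn=rnn_models,
        rcda=rcda_models,
    )


def replace_targets(region: RegionSpec, targets: np.ndarray) -> RegionSpec:
    return RegionSpec(
        region_id=region.region_id,
        core_marker_idx=region.core_marker_idx,
        flank_left_idx=region.flank_left_idx,
        flank_right_idx=region.flank_right_idx,
        target_idx=targets,
        span=region.span,
    )


def apply_mask_to_markers(
    marker_alleles: np.ndarray,
    assignment: MarkerAssignment,
    mask: MissingMask | None,
) -> np.ndarray:
    """Marker-state matrix (markers x haplotypes) with masked markers set
    to MISSING for every haplotype."""
    states = np.asarray(marker_alleles, dtype=np.int8).copy()
    if mask is not None and mask.removed_marker_idx.size:
        states[_marker_rows(assignment, mask.removed_marker_idx), :] = MISSING
    return states


def run_two_stage(
    marker_states: np.ndarray,
    sample_ids: list[str],
    models: TrainedModels,
    fill_strategy: str,
) -> DosageResult:
    """Impute target-site dosages from (possibly missing) marker states.

    ``marker_states``: (n_markers, n_haplotypes) over {MISSING, 0, 1},
    rows ordered as ``models.assignment.marker_idx``.
    """
    if fill_strategy not in STRATEGIES:
        raise ValueError(f"fill_strategy must be one of {STRATEGIES}")
    states = np.asarray(marker_states, dtype=np.int8)
    if fill_strategy == "none" and (states == MISSING).any():
        raise ValueError("fill_strategy='none' requires complete marker input")

    if fill_strategy == "rcda":
        states = states.copy()
        for trained, region in zip(models.rcda, models.rcda_regions):
            if region.manifest_hash() != trained.region_hash:
                raise ValueError("stage-1 model does not match its region manifest")
            rows = _marker_rows(models.assignment, trained.marker_rows)
            filled, _ = fill_missing(trained, states[rows, :])
            states[rows, :] = filled

    per_region: list[DosageResult] = []
    for trained, region in zip(models.rnn, models.rnn_regions):
        rows = _marker_rows(models.assignment, region.marker_sequence)
        x = encode_marker_inputs(
            states[rows, :], models.freqs_ref.f_a1[region.marker_sequence]
        )
        hap_p = impute_region(trained, region, x)
        per_region.append(
            combine_haplotypes_to_genotypes(
                hap_p, [models.sites[i] for i in region.target_idx], sample_ids
            )
        )
    return merge_regions(per_region)


# ---------------------------------------------------------------------------
# Checkpointing: one directory per trained bundle
# ---------------------------------------------------------------------------


def save_models(models: TrainedModels, out_dir) -> None:
    """Persist a trained bundle: region manifests and shared context as
    JSON, per-region parameters as .npz with the region hash embedded."""
    import json
    from dataclasses import asdict
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    context = {
        "sites": [
            {"chrom": s.chrom, "pos": s.pos, "id": s.id, "a0": s.a0, "a1": s.a1}
            for s in models.sites
        ],
        "marker_idx": models.assignment.marker_idx.tolist(),
        "target_idx": models.assignment.target_idx.tolist(),
        "f_a1": models.freqs_ref.f_a1.tolist(),
        "rnn_regions": [r.to_dict() for r in models.rnn_regions],
        "rcda_regions": [r.to_dict() for r in models.rcda_regions],
    }
    (out / "bundle.json").write_text(json.dumps(context))
    for i, trained in enumerate(models.rnn):
        arch = trained.model.config
        np.savez(
            out / f"rnn_{i:04d}.npz",
            *[p.data for p in trained.model.params()],
            region_hash=trained.region_hash,
            target_idx=trained.target_idx,
            left_bracket=trained.model.left_bracket,
            right_bracket=trained.model.right_bracket,
            n_markers=trained.model.n_markers,
            arch=json.dumps(asdict(arch)),
            train_config=json.dumps(asdict(trained.config)),
        )
    for i, trained in enumerate(models.rcda):
        params, states = trained.model.snapshot()
        np.savez(
            out / f"rcda_{i:04d}.npz",
            *params,
            *states,
            n_params=len(params),
            region_hash=trained.region_hash,
            marker_rows=trained.marker_rows,
            major_allele=trained.major_allele,
            kernel_size=trained.model.kernel_size,
            train_config=json.dumps(asdict(trained.config)),
        )


def load_models(in_dir) -> TrainedModels:
    """Load a bundle written by :func:`save_models`."""
    import json
    from pathlib import Path

    from .rcda import RcdaModel, RcdaTrainConfig, TrainedRcda
    from .rnn import RnnModel, TrainedRnn

    src = Path(in_dir)
    context = json.loads((src / "bundle.json").read_text())
    sites = [SiteMeta(**d) for d in context["sites"]]
    assignment = MarkerAssignment(
        marker_idx=np.array(context["marker_idx"], dtype=np.int64),
        target_idx=np.array(context["target_idx"], dtype=np.int64),
    )
    freqs = FreqTable(f_a1=np.array(context["f_a1"]))
    rnn_regions = [RegionSpec.from_dict(d) for d in context["rnn_regions"]]
    rcda_regions = [RegionSpec.from_dict(d) for d in context["rcda_regions"]]

    rnn_models: list[TrainedRnn] = []
    for i in range(len(rnn_regions)):
        with np.load(src / f"rnn_{i:04d}.npz", allow_pickle=False) as z:
            arch = RnnConfig(**json.loads(str(z["arch"])))
            cfg = RnnTrainConfig(**json.loads(str(z["train_config"])))
            model = RnnModel(
                arch,
                z["left_bracket"],
                z["right_bracket"],
                n_markers=int(z["n_markers"]),
                seed=cfg.seed,
            )
            for p, key in zip(model.params(), (f"arr_{j}" for j in range(10**6))):
                p.data = z[key]
            rnn_models.append(
                TrainedRnn(
                    model=model,
                    region_hash=str(z["region_hash"]),
                    target_idx=z["target_idx"],
                    log={},
                    config=cfg,
                )
            )
    rcda_models: list[TrainedRcda] = []
    for i in range(len(rcda_regions)):
        with np.load(src / f"rcda_{i:04d}.npz", allow_pickle=False) as z:
            cfg = RcdaTrainConfig(**_as_rcda_kwargs(json.loads(str(z["train_config"]))))
            model = RcdaModel(kernel_size=int(z["kernel_size"]), seed=cfg.seed)
            n_params = int(z["n_params"])
            arrays = [z[f"arr_{j}"] for j in range(n_params + len(model.bn_state()))]
            model.load_snapshot((arrays[:n_params], arrays[n_params:]))
            rcda_models.append(
                TrainedRcda(
                    model=model,
                    region_hash=str(z["region_hash"]),
                    marker_rows=z["marker_rows"],
                    major_allele=z["major_allele"],
                    log={},
                    config=cfg,
                )
            )
    return TrainedModels(
        sites=sites,
        assignment=assignment,
        freqs_ref=freqs,
        rnn_regions=rnn_regions,
        rcda_regions=rcda_regions,
        rnn=rnn_models,
        rcda=rcda_models,
    )


def _as_rcda_kwargs(d: dict) -> dict:
    d = dict(d)
    if d.get("mask_rate_range") is not None:
        d["mask_rate_range"] = tuple(d["mask_rate_range"])
    return d


# ---------------------------------------------------------------------------
# Desk-scale end-to-end benchmark
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ExperimentConfig:
    """Self-contained benchmark configuration.

    The defaults are desk-scale: small enough that the whole experiment
    (simulation, training of both model sets, imputation at four missing
    rates under three strategies, evaluation) runs in minutes on one CPU
    while still exhibiting the LD structure the models rely on.
    """

    n_sites: int = 600
    n_samples: int = 150
    n_markers: int = 120
    n_test: int = 25
    n_blocks: int = 4
    marker_maf_min: float = 0.05
    rates: tuple[float, ...] = (0.01, 0.05, 0.1, 0.2)
    rnn_region_budget: int = 60
    rcda_region_budget: int = 500
    n_flank: int = 15
    maf_min_targets: float = 0.005
    eval_maf_min: float = 0.05  # common-variant cut for headline means
    n_validation: int = 20
    rnn_max_epochs: int = 100
    rnn_patience: int = 15
    rnn_batch_size: int | None = 64
    rcda_epochs: int = 200
    seed: int = 0

    def sim_config(self, seed: int) -> SimConfig:
        return SimConfig(n_sites=self.n_sites, n_samples=self.n_samples, seed=seed)


@dataclass
class ExperimentResult:
    """Everything the benchmark measures, machine-readable."""

    tables: dict[tuple[str, float], EvalTable]
    mean_r2: dict[tuple[str, float], float]  # over MAF >= eval_maf_min sites
    rcda_fill_accuracy: float  # at the largest missing rate
    baseline_fill_accuracy: float  # major-allele baseline, same mask
    gap_recovery: float  # fraction of the R² gap recovered at the largest rate
    config: ExperimentConfig
    seeds: dict[str, int]

    def summary(self) -> dict:
        out = {
            "mean_r2": {f"{s}@{r}": v for (s, r), v in self.mean_r2.items()},
            "rcda_fill_accuracy": self.rcda_fill_accuracy,
            "baseline_fill_accuracy": self.baseline_fill_accuracy,
            "gap_recovery": self.gap_recovery,
            "seeds": self.seeds,
        }
        return out


def end_to_end_experiment(config: ExperimentConfig) -> ExperimentResult:
    """Run the full benchmark: simulate, train, impute, evaluate."""
    ss = np.random.SeedSequence(config.seed)
    child = [int(s) for s in ss.generate_state(6) % (2**31)]
    seeds = {
        "simulate": child[0],
        "markers": child[1],
        "split": child[2],
        "mask": child[3],
        "rnn_train": child[4],
        "rcda_train": child[5],
    }

    panel = simulate_panel(config.sim_config(seeds["simulate"]))
    assignment = select_markers(
        panel, config.n_markers, config.marker_maf_min, seeds["markers"]
    )
    reference, test = split_samples(panel, config.n_test, seeds["split"])
    blocks = uniform_blocks(
        panel.sites[0].chrom, int(panel.positions[-1]) + 1, config.n_blocks
    )
    pipe_cfg = PipelineConfig(
        rcda_region_budget=config.rcda_region_budget,
        rnn_region_budget=config.rnn_region_budget,
        n_flank=config.n_flank,
        maf_min_targets=config.maf_min_targets,
        seed=config.seed,
    )
    models = train_models(
        reference,
        assignment,
        blocks,
        pipe_cfg,
        rnn_arch=RnnConfig(n_flank=config.n_flank),
        rnn_train=RnnTrainConfig(
            max_epochs=config.rnn_max_epochs,
            patience=config.rnn_patience,
            batch_size=config.rnn_batch_size,
            n_validation=config.n_validation,
            seed=seeds["rnn_train"],
        ),
        rcda_train=RcdaTrainConfig(
            epochs=config.rcda_epochs,
            n_validation=config.n_validation,
            seed=seeds["rcda_train"],
        ),
    )

    marker_alleles = test.alleles[assignment.marker_idx, :]
    target_idx = models.target_sites
    order = np.argsort(target_idx)
    target_idx = target_idx[order]
    true_counts = test.genotype_counts()[target_idx, :]
    maf_combined = compute_freqs(panel).maf[target_idx]
    positions = panel.positions[target_idx]

    def evaluate(dosages: DosageResult) -> EvalTable:
        assert len(dosages.sites) == target_idx.size
        return build_eval_table(
            target_idx, positions, maf_combined, true_counts, dosages.dosage
        )

    tables: dict[tuple[str, float], EvalTable] = {}
    clean = apply_mask_to_markers(marker_alleles, assignment, None)
    tables[("none", 0.0)] = evaluate(
        run_two_stage(clean, test.sample_ids, models, "none")
    )
    for rate in config.rates:
        mask = apply_marker_missingness(assignment.marker_idx, rate, seeds["mask"])
        masked = apply_mask_to_markers(marker_alleles, assignment, mask)
        for strategy in ("frequency", "rcda"):
            tables[(strategy, rate)] = evaluate(
                run_two_stage(masked, test.sample_ids, models, strategy)
            )

    mean_r2 = {
        key: table.mean_r2(config.eval_maf_min) for key, table in tables.items()
    }
    top_rate = max(config.rates)
    r2_none = mean_r2[("none", 0.0)]
    r2_freq = mean_r2[("frequency", top_rate)]
    r2_rcda = mean_r2[("rcda", top_rate)]
    gap = r2_none - r2_freq
    gap_recovery = float((r2_rcda - r2_freq) / gap) if gap > 0 else float("nan")

    # Stage-1 denoising skill at the largest rate, against the
    # reference-major-allele baseline at the same masked entries.
    mask = apply_marker_missingness(assignment.marker_idx, top_rate, seeds["mask"])
    masked = apply_mask_to_markers(marker_alleles, assignment, mask)
    filled = masked.copy()
    for trained, region in zip(models.rcda, models.rcda_regions):
        rows = _marker_rows(models.assignment, trained.marker_rows)
        filled[rows, :] = fill_missing(trained, masked[rows, :])[0]
    missing_entries = masked == MISSING
    truth = marker_alleles
    rcda_acc = float((filled[missing_entries] == truth[missing_entries]).mean())
    major = (models.freqs_ref.f_a1[assignment.marker_idx] > 0.5).astype(np.int8)
    baseline = np.broadcast_to(major[:, None], truth.shape)
    base_acc = float((baseline[missing_entries] == truth[missing_entries]).mean())

    return ExperimentResult(
        tables=tables,
        mean_r2=mean_r2,
        rcda_fill_accuracy=rcda_acc,
        baseline_fill_accuracy=base_acc,
        gap_recovery=gap_recovery,
        config=config,
        seeds=seeds,
    )
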