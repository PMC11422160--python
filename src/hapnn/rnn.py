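"""Region-wise bidirectional recurrent imputer (stage 2).

Per region, a stack of bidirectional gated recurrent layers reads the
sequence of array-marker input vectors (flanks + core, in genomic order).
Each untyped target site has its own small output head that looks at the
concatenated forward/backward hidden states of the two markers bracketing
the target's position (the nearest marker is duplicated when the target
lies outside the marker range) and emits 2-class allele probabilities.

Marker inputs are 2-vectors: an observed a0 allele is (1, 0), an observed
a1 allele is (0, 1), and a missing marker is (1 - f_a1, f_a1) where f_a1
is the a1 frequency in the reference panel — the expectation of the
one-hot under the panel's allele distribution.  Training uses clean
(fully observed) inputs only; robustness to missing markers is delegated
to the stage-1 denoiser, which is exactly the fragility/recovery contrast
the pipeline exists to measure.

Imputation is per haplotype; the two haplotypes of an individual are
combined under independence into genotype probabilities and the a1 dosage
P(het) + 2 P(hom-a1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .io import HaplotypePanel, SiteMeta
from .layers import BiGRUStack, glorot
from .rcda import MISSING
from .regions import RegionSpec

__all__ = [
    "RnnConfig",
    "RnnTrainConfig",
    "DosageResult",
    "encode_marker_inputs",
    "build_rnn",
    "train_rnn",
    "impute_region",
    "combine_haplotypes_to_genotypes",
    "merge_regions",
]


@dataclass(frozen=True)
class RnnConfig:
    """Recurrent-imputer architecture parameters."""

    n_layers: int = 4
    hidden_size: int = 40
    n_flank: int = 50
    input_size: int = 2

    def __post_init__(self):
        if self.n_layers < 1 or self.hidden_size < 1:
            raise ValueError("n_layers and hidden_size must be >= 1")


@dataclass(frozen=True)
class RnnTrainConfig:
    """Training hyperparameters for the recurrent imputer."""

    max_epochs: int = 300
    learning_rate: float = 0.001
    batch_size: int | None = None  # None = full batch
    n_validation: int = 100
    patience: int = 20  # early stop after this many epochs without val improvement
    mask_augment_rate: float = 0.0  # experimental: mask-and-frequency-fill inputs
    seed: int = 0


@dataclass
class DosageResult:
    """Imputed genotypes at target sites.

    ``dosage[s, i]`` is the expected a1-allele count of sample ``i`` at
    site ``s``; ``gp[s, i]`` the (hom-a0, het, hom-a1) probabilities.
    """

    sites: list[SiteMeta]
    sample_ids: list[str]
    dosage: np.ndarray  # (n_sites, n_samples)
    gp: np.ndarray  # (n_sites, n_samples, 3)

    def __post_init__(self):
        self.dosage = np.asarray(self.dosage, dtype=np.float64)
        self.gp = np.asarray(self.gp, dtype=np.float64)
        if self.gp.size and np.abs(self.gp.sum(axis=-1) - 1.0).max() > 1e-6:
            raise ValueError("genotype probabilities must sum to 1")
        if self.dosage.size and (
            self.dosage.min() < -1e-9 or self.dosage.max() > 2 + 1e-9
        ):
            raise ValueError("dosages must lie in [0, 2]")


def encode_marker_inputs(states: np.ndarray, f_a1: np.ndarray) -> np.ndarray:
    """Encode marker states into the imputer's 2-vector inputs.

    ``states``: (n_markers, n_haplotypes) over {MISSING, 0, 1}; ``f_a1``:
    reference-panel a1 frequency per marker.  Returns (n_haplotypes,
    n_markers, 2) float32: observed a0 -> (1,0), observed a1 -> (0,1),
    missing -> (1 - f_a1, f_a1).
    """
    states = np.asarray(states)
    f_a1 = np.asarray(f_a1, dtype=np.float64)
    if f_a1.shape[0] != states.shape[0]:
        raise ValueError("need one reference frequency per marker")
    if np.isnan(f_a1[np.any(states == MISSING, axis=1)]).any():
        raise ValueError("missing marker without a reference frequency")
    s = states.T  # (hap, markers)
    x = np.empty((s.shape[0], s.shape[1], 2), dtype=np.float32)
    x[:, :, 1] = np.where(s == MISSING, f_a1[None, :], s)
    x[:, :, 0] = 1.0 - x[:, :, 1]
    return x


class RnnModel:
    """Bidirectional GRU stack plus per-target bracketing-marker heads."""

    def __init__(
        self,
        config: RnnConfig,
        left_bracket: np.ndarray,
        right_bracket: np.ndarray,
        n_markers: int,
        seed: int = 0,
    ):
        if n_markers < 1:
            raise ValueError("a region must contain at least one marker")
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), 47]))
        self.config = config
        self.n_markers = n_markers
        self.left_bracket = np.asarray(left_bracket, dtype=np.int64)
        self.right_bracket = np.asarray(right_bracket, dtype=np.int64)
        n_targets = self.left_bracket.size
        self.stack = BiGRUStack(config.input_size, config.hidden_size, config.n_layers, rng)
        feat = 4 * config.hidden_size  # fwd+bwd states of two bracket markers
        self.head_w = glorot(rng, (n_targets, feat, 2), feat, 2)
        self.head_b = ad.tensor(np.zeros((n_targets, 1, 2)))

    @property
    def n_targets(self) -> int:
        return self.left_bracket.size

    def params(self) -> list[Tensor]:
        return self.stack.params() + [self.head_w, self.head_b]

    def n_params(self) -> int:
        return int(sum(p.data.size for p in self.params()))

    def snapshot(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.params()]

    def load_snapshot(self, snap: list[np.ndarray]) -> None:
        for p, d in zip(self.params(), snap):
            p.data = d.copy()

    def forward(self, x: np.ndarray) -> Tensor:
        """Logits per target, shape (n_targets, n_haplotypes, 2); ``x`` is
        the encoded marker sequence (n_haplotypes, n_markers, 2)."""
        if x.shape[1] != self.n_markers:
            raise ValueError(
                f"input has {x.shape[1]} markers, model expects {self.n_markers}"
            )
        states = self.stack.forward(ad.tensor(x))  # (hap, n_markers, 2H)
        feats = ad.concat(
            [ad.gather_steps(states, self.left_bracket),
             ad.gather_steps(states, self.right_bracket)],
            axis=2,
        )  # (hap, n_targets, 4H)
        feats = ad.transpose(feats, (1, 0, 2))  # (n_targets, hap, 4H)
        return ad.add(ad.matmul(feats, self.head_w), self.head_b)

    def predict_p_a1(self, x: np.ndarray) -> np.ndarray:
        """Per-target a1 probability per haplotype, (n_targets, n_hap)."""
        return ad.softmax(self.forward(x).data, axis=-1)[:, :, 1]


def _bracket_indices(
    marker_pos: np.ndarray, target_pos: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Positions of the two markers bracketing each target within the
    region's marker sequence; nearest marker duplicated at the ends."""
    right = np.searchsorted(marker_pos, target_pos)
    left = right - 1
    left = np.clip(left, 0, len(marker_pos) - 1)
    right = np.clip(right, 0, len(marker_pos) - 1)
    return left, right


def build_rnn(
    region: RegionSpec,
    panel_sites: list[SiteMeta],
    config: RnnConfig = RnnConfig(),
    seed: int = 0,
) -> RnnModel:
    """Instantiate the region's model; heads are wired to the markers
    bracketing each target's bp position."""
    if region.target_idx.size < 1:
        raise ValueError("region has no target sites")
    positions = np.array([s.pos for s in panel_sites], dtype=np.int64)
    marker_pos = positions[region.marker_sequence]
    target_pos = positions[region.target_idx]
    left, right = _bracket_indices(marker_pos, target_pos)
    return RnnModel(config, left, right, n_markers=marker_pos.size, seed=seed)


@dataclass
class TrainedRnn:
    """A trained per-region recurrent imputer with its provenance."""

    model: RnnModel
    region_hash: str
    target_idx: np.ndarray
    log: dict
    config: RnnTrainConfig


def train_rnn(
    reference: HaplotypePanel,
    region: RegionSpec,
    arch: RnnConfig = RnnConfig(),
    config: RnnTrainConfig = RnnTrainConfig(),
) -> TrainedRnn:
    """Supervised training: clean marker inputs -> reference alleles at the
    region's target sites, mean cross-entropy over targets, Adam, with
    validation-individual holdout and best-validation parameter selection.
    Stops early when validation loss has not improved for ``patience``
    epochs.
    """
    if reference.n_samples <= config.n_validation:
        raise ValueError(
            f"reference panel has {reference.n_samples} samples; "
            f"needs more than n_validation = {config.n_validation}"
        )
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 29]))
    markers = region.marker_sequence
    marker_states = reference.alleles[markers, :]  # (L, hap), no missing
    f_a1 = marker_states.mean(axis=1)
    x_all = encode_marker_inputs(marker_states, f_a1)
    y_all = reference.alleles[region.target_idx, :].astype(np.int64)  # (T, hap)

    val_individuals = rng.choice(reference.n_samples, size=config.n_validation, replace=False)
    val_cols = np.sort(np.concatenate([2 * val_individuals, 2 * val_individuals + 1]))
    train_cols = np.setdiff1d(np.arange(reference.n_haplotypes), val_cols)

    model = build_rnn(region, reference.sites, arch, seed=config.seed)
    optimizer = ad.Adam(model.params(), lr=config.learning_rate)
    log: dict = {"train_loss": [], "val_loss": [], "best_epoch": -1}
    best_loss, best_snap, stale = np.inf, None, 0
    batch_size = config.batch_size or len(train_cols)
    for epoch in range(config.max_epochs):
        order = rng.permutation(train_cols)
        epoch_loss = 0.0
        for start in range(0, len(order), batch_size):
            cols = order[start : start + batch_size]
            x_batch = x_all[cols]
            if config.mask_augment_rate > 0:
                # Experimental robustness augmentation: replace a random
                # subset of markers by their frequency encoding.  Off by
                # default — the pipeline's premise is that this model
                # trains on clean inputs and stage 1 handles missingness.
                hit = rng.random((len(cols), x_batch.shape[1])) < config.mask_augment_rate
                x_batch = x_batch.copy()
                x_batch[hit, 1] = f_a1[np.nonzero(hit)[1]].astype(np.float32)
                x_batch[hit, 0] = 1.0 - x_batch[hit, 1]
            logits = model.forward(x_batch)
            loss = ad.softmax_cross_entropy(logits, y_all[:, cols])
            optimizer.zero_grad()
            loss.backward()
            optimizer.step()
            epoch_loss += float(loss.data) * len(cols)
        log["train_loss"].append(epoch_loss / len(order))

        val_logits = model.forward(x_all[val_cols])
        val_loss = float(ad.softmax_cross_entropy(val_logits, y_all[:, val_cols]).data)
        log["val_loss"].append(val_loss)
        if val_loss < best_loss - 1e-6:
            best_loss, best_snap, stale = val_loss, model.snapshot(), 0
            log["best_epoch"] = epoch
        else:
            stale += 1
            if stale >= config.patience:
                break
    if best_snap is not None:
        model.load_snapshot(best_snap)
    return TrainedRnn(
        model=model,
        region_hash=region.manifest_hash(),
        target_idx=region.target_idx.copy(),
        log=log,
        config=config,
    )


def impute_region(
    trained: TrainedRnn, region: RegionSpec, x: np.ndarray
) -> np.ndarray:
    """Per-haplotype a1 probabilities at the region's target sites,
    shape (n_targets, n_haplotypes).  Refuses to run against a region
    manifest other than the one the model was trained on."""
    if region.manifest_hash() != trained.region_hash:
        raise ValueError(
            "region manifest does not match the trained model "
            f"({region.manifest_hash()} != {trained.region_hash})"
        )
    return trained.model.predict_p_a1(x)


def combine_haplotypes_to_genotypes(
    hap_p: np.ndarray,
    sites: list[SiteMeta],
    sample_ids: list[str],
) -> DosageResult:
    """Combine per-haplotype a1 probabilities into diploid genotypes.

    Haplotypes are treated as independent: with per-haplotype a1
    probabilities p and q, P(hom-a1) = pq, P(het) = p(1-q) + q(1-p),
    P(hom-a0) = (1-p)(1-q), and the dosage is p + q.
    """
    hap_p = np.asarray(hap_p, dtype=np.float64)
    if hap_p.shape[1] != 2 * len(sample_ids):
        raise ValueError("need exactly two haplotype columns per sample")
    p, q = hap_p[:, 0::2], hap_p[:, 1::2]
    gp = np.stack(
        [(1 - p) * (1 - q), p * (1 - q) + q * (1 - p), p * q], axis=-1
    )
    return DosageResult(
        sites=list(sites), sample_ids=list(sample_ids), dosage=p + q, gp=gp
    )


def merge_regions(results: list[DosageResult]) -> DosageResult:
    """Concatenate per-region dosage results into one site-ordered result;
    every target site must appear exactly once."""
    if not results:
        raise ValueError("no regions to merge")
    sample_ids = results[0].sample_ids
    for r in results[1:]:
        if r.sample_ids != sample_ids:
            raise ValueError("regions carry different sample sets")
    sites = [s for r in results for s in r.sites]
    keys = [(s.chrom, s.pos) for s in sites]
    if len(set(keys)) != len(keys):
        raise ValueError("duplicate target site across regions")
    order = np.argsort([s.pos for s in sites], kind="stable")
    dosage = np.concatenate([r.dosage for r in results], axis=0)[order]
    gp = np.concatenate([r.gp for r in results], axis=0)[order]
    return DosageResult(
        sites=[sites[i] for i in order],
        sample_ids=list(sample_ids),
        dosage=dosage,
        gp=gp,
    )
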