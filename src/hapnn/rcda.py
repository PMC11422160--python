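"""Residual convolution denoising autoencoder (RCDA) for filling missing
array-marker genotypes (stage 1 of the two-stage pipeline).

Each region gets its own small encoder-decoder over the marker sequence:
residual 1-D convolution blocks with two max-pooling steps down and two
nearest-neighbour upsampling steps back, ending in a 2-class softmax per
marker.  Input markers are encoded as 3-state one-hots (missing / a0 / a1);
the output drops the missing state because the model's sole job is to
decide which allele a missing marker should carry.  Batch normalisation
inside the residual blocks regularises training, so no dropout or kernel
sparsity penalty is used.

Training is denoising: haplotypes are corrupted by masking a random
fraction of sites (the fraction itself drawn per example from the range of
missingness array quality control typically produces, up to 0.2) and the
model is fit by cross-entropy against the uncorrupted alleles at all
sites.  The parameters with the best loss on a held-out validation set of
individuals are kept.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .io import HaplotypePanel
from .layers import Conv1d, ResidualBlock1d
from .regions import RegionSpec

__all__ = [
    "MISSING",
    "A0",
    "A1",
    "RcdaTrainConfig",
    "RcdaModel",
    "TrainedRcda",
    "encode_rcda_input",
    "train_rcda",
    "fill_missing",
]

# Marker states in a MaskedMarkerMatrix (sites x haplotypes, int8).
MISSING: int = -1
A0: int = 0
A1: int = 1

#: Output-channel size after every layer of the architecture, in order:
#: ResBlock, ReLU, MaxPool, ResBlock, ReLU, MaxPool, ResBlock, ReLU,
#: ResBlock, ReLU, Upsample, ResBlock, ReLU, Upsample, Conv, Softmax.
CHANNEL_SEQUENCE: tuple[int, ...] = (
    32, 32, 32, 64, 64, 64, 128, 128, 64, 64, 64, 32, 32, 32, 2, 2,
)


@dataclass(frozen=True)
class RcdaTrainConfig:
    """Denoising-autoencoder training hyperparameters."""

    epochs: int = 1000
    learning_rate: float = 0.001
    batch_size: int = 32
    n_validation: int = 100  # individuals held out for model selection
    mask_rate_range: tuple[float, float] = (0.01, 0.2)
    fixed_mask_rate: float | None = None  # overrides the range when set
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.mask_rate_range
        if not 0.0 <= lo <= hi < 1.0:
            raise ValueError("mask_rate_range must satisfy 0 <= low <= high < 1")


def encode_rcda_input(states: np.ndarray) -> np.ndarray:
    """One-hot encode marker states into the model's 3-channel input.

    ``states``: (n_markers, n_haplotypes) over {MISSING, A0, A1}.  Returns
    (n_haplotypes, 3, n_markers) float32 with channel order
    (missing, a0, a1); each site's channel vector sums to one.
    """
    states = np.asarray(states)
    if not np.isin(states, (MISSING, A0, A1)).all():
        raise ValueError("states must be MISSING (-1), A0 (0) or A1 (1)")
    s = states.T  # (haplotypes, markers)
    x = np.zeros((s.shape[0], 3, s.shape[1]), dtype=np.float32)
    x[:, 0, :] = s == MISSING
    x[:, 1, :] = s == A0
    x[:, 2, :] = s == A1
    return x


class RcdaModel:
    """The per-region residual convolution denoising autoencoder."""

    def __init__(self, kernel_size: int = 5, seed: int = 0):
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), 91]))
        k = kernel_size
        self.kernel_size = k
        self.rb1 = ResidualBlock1d(3, 32, k, rng)
        self.rb2 = ResidualBlock1d(32, 64, k, rng)
        self.rb3 = ResidualBlock1d(64, 128, k, rng)
        self.rb4 = ResidualBlock1d(128, 64, k, rng)
        self.rb5 = ResidualBlock1d(64, 32, k, rng)
        self.conv_out = Conv1d(32, 2, k, rng)

    # --- parameter plumbing -------------------------------------------------
    def params(self) -> list[Tensor]:
        blocks = [self.rb1, self.rb2, self.rb3, self.rb4, self.rb5]
        out: list[Tensor] = []
        for b in blocks:
            out += b.params()
        return out + self.conv_out.params()

    def bn_state(self) -> list[np.ndarray]:
        out: list[np.ndarray] = []
        for b in (self.rb1, self.rb2, self.rb3, self.rb4, self.rb5):
            out += b.state()
        return out

    def snapshot(self) -> tuple[list[np.ndarray], list[np.ndarray]]:
        return ([p.data.copy() for p in self.params()],
                [s.copy() for s in self.bn_state()])

    def load_snapshot(self, snap: tuple[list[np.ndarray], list[np.ndarray]]) -> None:
        params, states = snap
        for p, d in zip(self.params(), params):
            p.data = d.copy()
        for s, d in zip(self.bn_state(), states):
            s[...] = d

    def channel_sequence(self) -> tuple[int, ...]:
        """Output-channel size after every layer, for auditing."""
        seq = []
        for b in (self.rb1, self.rb2, self.rb3):
            seq += [b.out_channels] * (3 if b is not self.rb3 else 2)
        seq += [self.rb4.out_channels] * 3  # ResBlock, ReLU, Upsample
        seq += [self.rb5.out_channels] * 3
        seq += [self.conv_out.out_channels] * 2  # Conv, Softmax
        return tuple(seq)

    # --- forward ------------------------------------------------------------
    def forward(self, x: np.ndarray, training: bool = False) -> Tensor:
        """Logits over (a0, a1) per marker; shape (batch, 2, length).

        The two pool/upsample pairs need the length divisible by 4, so the
        input is right-padded with the missing-state one-hot and the
        output trimmed back.
        """
        batch, channels, length = x.shape
        if channels != 3:
            raise ValueError(f"expected 3 input channels, got {channels}")
        padded_len = -(-length // 4) * 4
        if padded_len != length:
            pad = np.zeros((batch, 3, padded_len - length), dtype=x.dtype)
            pad[:, 0, :] = 1.0  # missing state
            x = np.concatenate([x, pad], axis=2)
        t = ad.tensor(x)
        t = ad.relu(self.rb1.forward(t, training))
        t = ad.max_pool1d_2(t)
        t = ad.relu(self.rb2.forward(t, training))
        t = ad.max_pool1d_2(t)
        t = ad.relu(self.rb3.forward(t, training))
        t = ad.relu(self.rb4.forward(t, training))
        t = ad.upsample1d_2(t)
        t = ad.relu(self.rb5.forward(t, training))
        t = ad.upsample1d_2(t)
        t = self.conv_out.forward(t, training)
        if padded_len != length:
            t = ad.narrow(t, 2, 0, length)
        return t

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        """Per-marker (a0, a1) probabilities, shape (batch, 2, length)."""
        logits = self.forward(x, training=False)
        return ad.softmax(logits.data, axis=1)


@dataclass
class TrainedRcda:
    """A trained per-region RCDA with its provenance."""

    model: RcdaModel
    region_hash: str
    marker_rows: np.ndarray  # rows of the region's markers in the marker matrix
    major_allele: np.ndarray  # per-marker argmax-tie-break allele (0/1)
    log: dict
    config: RcdaTrainConfig


def _mask_states(
    alleles_hl: np.ndarray, rng: np.random.Generator, cfg: RcdaTrainConfig
) -> np.ndarray:
    """Corrupt (haplotypes, length) alleles: per example draw a mask rate,
    then mask sites i.i.d. Bernoulli at that rate."""
    n_hap, length = alleles_hl.shape
    if cfg.fixed_mask_rate is not None:
        rates = np.full(n_hap, cfg.fixed_mask_rate)
    else:
        lo, hi = cfg.mask_rate_range
        rates = rng.uniform(lo, hi, size=n_hap)
    masked = alleles_hl.astype(np.int8).copy()
    masked[rng.random((n_hap, length)) < rates[:, None]] = MISSING
    return masked


def train_rcda(
    reference: HaplotypePanel,
    region: RegionSpec,
    config: RcdaTrainConfig,
    kernel_size: int = 5,
) -> TrainedRcda:
    """Train the region's RCDA on reference haplotypes with random masking.

    Validation individuals (both haplotypes) are held out with a mask that
    is fixed across epochs so validation losses are comparable; the
    parameters with the best validation loss are returned.
    """
    if reference.n_samples <= config.n_validation:
        raise ValueError(
            f"reference panel has {reference.n_samples} samples; "
            f"needs more than n_validation = {config.n_validation}"
        )
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 17]))
    markers = region.marker_sequence
    alleles = reference.alleles[markers, :].T.astype(np.int8)  # (hap, L)
    n_hap = alleles.shape[0]

    val_individuals = rng.choice(reference.n_samples, size=config.n_validation, replace=False)
    val_cols = np.sort(np.concatenate([2 * val_individuals, 2 * val_individuals + 1]))
    train_cols = np.setdiff1d(np.arange(n_hap), val_cols)
    train_x, val_x = alleles[train_cols], alleles[val_cols]
    val_masked = _mask_states(val_x, rng, config)
    val_input = encode_rcda_input(val_masked.T)
    val_labels = val_x.astype(np.int64)

    model = RcdaModel(kernel_size=kernel_size, seed=config.seed)
    optimizer = ad.Adam(model.params(), lr=config.learning_rate)
    log: dict = {"train_loss": [], "val_loss": [], "best_epoch": -1}
    best = (np.inf, None)
    for epoch in range(config.epochs):
        order = rng.permutation(train_x.shape[0])
        masked = _mask_states(train_x, rng, config)
        epoch_loss = 0.0
        for start in range(0, len(order), config.batch_size):
            batch = order[start : start + config.batch_size]
            x = encode_rcda_input(masked[batch].T)
            logits = model.forward(x, training=True)
            loss = ad.softmax_cross_entropy(
                ad.transpose(logits, (0, 2, 1)), train_x[batch].astype(np.int64)
            )
            optimizer.zero_grad()
            loss.backward()
            optimizer.step()
            epoch_loss += float(loss.data) * len(batch)
        log["train_loss"].append(epoch_loss / len(order))

        val_logits = model.forward(val_input, training=False)
        val_loss = float(
            ad.softmax_cross_entropy(ad.transpose(val_logits, (0, 2, 1)), val_labels).data
        )
        log["val_loss"].append(val_loss)
        if val_loss < best[0]:
            best = (val_loss, model.snapshot())
            log["best_epoch"] = epoch
    if best[1] is not None:
        model.load_snapshot(best[1])

    f_a1 = train_x.mean(axis=0)
    return TrainedRcda(
        model=model,
        region_hash=region.manifest_hash(),
        marker_rows=markers,
        major_allele=(f_a1 > 0.5).astype(np.int8),
        log=log,
        config=config,
    )


def fill_missing(
    trained: TrainedRcda, masked: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Fill MISSING entries of a (n_markers, n_haplotypes) state matrix.

    Missing positions get the argmax of the model's 2-class output (an
    exact tie falls back to the region-major allele); observed alleles are
    passed through verbatim.  Returns ``(filled, confidence)`` where
    confidence is the model's maximum output probability per entry.
    """
    masked = np.asarray(masked, dtype=np.int8)
    probs = trained.model.predict_proba(encode_rcda_input(masked))  # (hap, 2, L)
    p_a1 = probs[:, 1, :].T  # (L, hap)
    calls = np.where(
        p_a1 > 0.5, A1, np.where(p_a1 < 0.5, A0, trained.major_allele[:, None])
    ).astype(np.int8)
    filled = np.where(masked == MISSING, calls, masked)
    confidence = np.maximum(p_a1, 1.0 - p_a1)
    return filled, confidence
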