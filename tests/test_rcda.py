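"""The residual convolution denoising autoencoder (stage 1)."""

import numpy as np
import pytest

from hapnn import autodiff as ad
from hapnn.layers import ResidualBlock1d
from hapnn.rcda import (
    A0,
    A1,
    CHANNEL_SEQUENCE,
    MISSING,
    RcdaModel,
    RcdaTrainConfig,
    encode_rcda_input,
    fill_missing,
    train_rcda,
)
from hapnn.regions import build_regions, subdivide_blocks, uniform_blocks
from hapnn.sim import SimConfig, select_markers, simulate_panel


class TestEncoding:
    def test_state_to_channel_mapping(self):
        states = np.array([[A1], [MISSING], [A0]])  # 3 markers, 1 haplotype
        x = encode_rcda_input(states)
        assert x.shape == (1, 3, 3)
        assert x[0, :, 0].tolist() == [0, 0, 1]  # A1 -> (missing, a0, a1)
        assert x[0, :, 1].tolist() == [1, 0, 0]  # MISSING
        assert x[0, :, 2].tolist() == [0, 1, 0]  # A0

    def test_one_hot_sums_and_conservation(self, rng):
        states = rng.integers(-1, 2, size=(30, 8)).astype(np.int8)
        x = encode_rcda_input(states)
        assert np.array_equal(x.sum(axis=1), np.ones((8, 30), dtype=np.float32))
        assert x.sum() == states.size

    def test_invalid_state_rejected(self):
        with pytest.raises(ValueError):
            encode_rcda_input(np.array([[2]]))


class TestArchitecture:
    def test_layer_channel_sequence(self):
        model = RcdaModel(seed=0)
        assert model.channel_sequence() == CHANNEL_SEQUENCE
        assert CHANNEL_SEQUENCE == (
            32, 32, 32, 64, 64, 64, 128, 128, 64, 64, 64, 32, 32, 32, 2, 2,
        )

    def test_zero_init_residual_block_is_identity(self, rng):
        block = ResidualBlock1d(16, 16, 5, rng, zero_init=True)
        x = rng.normal(size=(2, 16, 12)).astype(np.float32)
        out = block.forward(ad.tensor(x), training=True)
        assert np.allclose(out.data, x, atol=1e-6)

    def test_output_probabilities_normalised(self, rng):
        model = RcdaModel(seed=1)
        states = rng.integers(-1, 2, size=(24, 5)).astype(np.int8)
        probs = model.predict_proba(encode_rcda_input(states))
        assert probs.shape == (5, 2, 24)
        assert np.abs(probs.sum(axis=1) - 1.0).max() < 1e-6

    @pytest.mark.parametrize("length", [37, 40, 1, 4])
    def test_output_length_matches_input(self, length, rng):
        """Lengths not divisible by 4 are padded internally and trimmed."""
        model = RcdaModel(seed=1)
        x = encode_rcda_input(rng.integers(-1, 2, size=(length, 3)).astype(np.int8))
        logits = model.forward(x)
        assert logits.data.shape == (3, 2, length)


def _tiny_training_setup(n_sites=120, n_samples=60, seed=11):
    panel = simulate_panel(SimConfig(n_sites=n_sites, n_samples=n_samples, seed=seed))
    asn = select_markers(panel, 40, 0.05, seed)
    blocks = uniform_blocks("22", int(panel.positions[-1]) + 1, 1)
    spans = subdivide_blocks(blocks, panel.positions[asn.marker_idx], 500)
    region = build_regions(spans, asn, panel.sites, 0)[0]
    return panel, asn, region


class TestTraining:
    def test_two_epoch_smoke_run_logs_finite_losses(self):
        panel, _, region = _tiny_training_setup()
        cfg = RcdaTrainConfig(epochs=2, n_validation=5, seed=1)
        trained = train_rcda(panel, region, cfg)
        assert len(trained.log["val_loss"]) == 2
        assert np.isfinite(trained.log["train_loss"]).all()
        assert np.isfinite(trained.log["val_loss"]).all()

    def test_returned_params_are_argmin_of_validation_log(self):
        panel, _, region = _tiny_training_setup()
        cfg = RcdaTrainConfig(epochs=4, n_validation=5, seed=2)
        trained = train_rcda(panel, region, cfg)
        assert trained.log["best_epoch"] == int(np.argmin(trained.log["val_loss"]))

    def test_training_reduces_validation_loss(self):
        panel, _, region = _tiny_training_setup()
        cfg = RcdaTrainConfig(epochs=25, n_validation=10, seed=3)
        trained = train_rcda(panel, region, cfg)
        assert min(trained.log["val_loss"]) < trained.log["val_loss"][0]

    def test_too_few_samples_rejected(self):
        panel, _, region = _tiny_training_setup(n_samples=20)
        with pytest.raises(ValueError, match="n_validation"):
            train_rcda(panel, region, RcdaTrainConfig(epochs=1, n_validation=20))


@pytest.fixture(scope="module")
def trained():
    panel, asn, region = _tiny_training_setup()
    cfg = RcdaTrainConfig(epochs=20, n_validation=10, seed=4)
    return train_rcda(panel, region, cfg), panel, asn, region


def test_constant_region_fills_the_constant_allele():
    """Degenerate case: a region monomorphic for a0 must be filled with a0
    even from a fully missing haplotype."""
    from hapnn.io import HaplotypePanel, SiteMeta
    from hapnn.regions import RegionSpec

    n_sites, n_samples = 16, 30
    panel = HaplotypePanel(
        sites=[SiteMeta("22", 100 * (i + 1), f"c{i}", "A", "C") for i in range(n_sites)],
        alleles=np.zeros((n_sites, 2 * n_samples), dtype=np.int8),
        sample_ids=[f"s{i}" for i in range(n_samples)],
    )
    region = RegionSpec(
        region_id=0,
        core_marker_idx=np.arange(n_sites),
        flank_left_idx=[],
        flank_right_idx=[],
        target_idx=[],
        span=(0, 100 * (n_sites + 1)),
    )
    trained = train_rcda(panel, region, RcdaTrainConfig(epochs=15, n_validation=5, seed=6))
    all_missing = np.full((n_sites, 1), MISSING, dtype=np.int8)
    filled, _ = fill_missing(trained, all_missing)
    assert (filled == A0).all()


class TestFillMissing:
    def test_no_missing_is_pass_through(self, trained):
        model, panel, asn, region = trained
        states = panel.alleles[region.marker_sequence, :10].astype(np.int8)
        filled, confidence = fill_missing(model, states)
        assert np.array_equal(filled, states)
        assert confidence.shape == states.shape

    def test_fill_replaces_all_missing_with_alleles(self, trained):
        model, panel, asn, region = trained
        states = panel.alleles[region.marker_sequence, :10].astype(np.int8)
        states[::3, :] = MISSING
        filled, _ = fill_missing(model, states)
        assert not (filled == MISSING).any()
        assert np.isin(filled, (A0, A1)).all()
        # observed entries untouched
        observed = states != MISSING
        assert np.array_equal(filled[observed], states[observed])
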