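"""The bidirectional recurrent imputer (stage 2)."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from hapnn.io import SiteMeta
from hapnn.rcda import MISSING
from hapnn.regions import build_regions, subdivide_blocks, uniform_blocks
from hapnn.rnn import (
    DosageResult,
    RnnConfig,
    RnnTrainConfig,
    build_rnn,
    combine_haplotypes_to_genotypes,
    encode_marker_inputs,
    impute_region,
    merge_regions,
    train_rnn,
)
from hapnn.sim import SimConfig, select_markers, simulate_panel


class TestEncodeMarkerInputs:
    def test_observed_alleles_one_hot(self):
        states = np.array([[0], [1]], dtype=np.int8)
        x = encode_marker_inputs(states, np.array([0.2, 0.8]))
        assert x[0, 0].tolist() == [1.0, 0.0]
        assert x[0, 1].tolist() == [0.0, 1.0]

    def test_missing_uses_reference_frequency(self):
        states = np.array([[MISSING]], dtype=np.int8)
        x = encode_marker_inputs(states, np.array([0.3]))
        assert np.allclose(x[0, 0], [0.7, 0.3])

    def test_missing_with_zero_frequency_matches_observed_a0(self):
        missing = encode_marker_inputs(np.array([[MISSING]], dtype=np.int8), np.array([0.0]))
        observed = encode_marker_inputs(np.array([[0]], dtype=np.int8), np.array([0.0]))
        assert np.array_equal(missing, observed)

    def test_components_sum_to_one(self, rng):
        states = rng.integers(-1, 2, size=(20, 6)).astype(np.int8)
        f = rng.uniform(0, 1, size=20)
        x = encode_marker_inputs(states, f)
        assert np.allclose(x.sum(axis=2), 1.0)

    def test_missing_frequency_must_be_present(self):
        states = np.array([[MISSING]], dtype=np.int8)
        with pytest.raises(ValueError):
            encode_marker_inputs(states, np.array([np.nan]))


def _toy_region(n_markers=10, n_targets=5):
    """Markers at 100,200,... with targets interleaved between them."""
    sites = []
    marker_idx, target_idx = [], []
    pos = 100
    idx = 0
    for m in range(n_markers):
        sites.append(SiteMeta("22", pos, f"m{m}", "A", "C"))
        marker_idx.append(idx)
        pos += 100
        idx += 1
        if m < n_targets:
            sites.append(SiteMeta("22", pos - 50 + 100, f"t{m}", "A", "C"))
            target_idx.append(idx)
            pos += 100
            idx += 1
    from hapnn.regions import RegionSpec

    region = RegionSpec(
        region_id=0,
        core_marker_idx=np.array(marker_idx),
        flank_left_idx=np.array([], dtype=int),
        flank_right_idx=np.array([], dtype=int),
        target_idx=np.array(target_idx),
        span=(0, pos + 100),
    )
    return region, sites


class TestBuildRnn:
    def test_parameter_count_closed_form(self):
        """Total parameter count matches the arithmetic of the layer sizes:
        per direction per layer 3H(d_in + H + 2); per target head 4H*2 + 2."""
        region, sites = _toy_region(n_markers=10, n_targets=5)
        h, n_layers, t = 6, 3, 5
        model = build_rnn(region, sites, RnnConfig(n_layers=n_layers, hidden_size=h), seed=0)
        expected = 0
        d_in = 2
        for _ in range(n_layers):
            expected += 2 * (3 * h * (d_in + h + 2))
            d_in = 2 * h
        expected += t * (4 * h * 2 + 2)
        assert model.n_params() == expected

    def test_target_outside_marker_range_duplicates_nearest(self):
        region, sites = _toy_region()
        # move the first target before all markers
        sites[region.target_idx[0]] = SiteMeta("22", 10, "early", "A", "C")
        model = build_rnn(region, sites, RnnConfig(n_layers=1, hidden_size=4), seed=0)
        assert model.left_bracket[0] == model.right_bracket[0] == 0

    def test_output_probabilities_sum_to_one(self, rng):
        region, sites = _toy_region()
        model = build_rnn(region, sites, RnnConfig(n_layers=2, hidden_size=5), seed=1)
        x = rng.random((4, model.n_markers, 2)).astype(np.float32)
        from hapnn import autodiff as ad

        probs = ad.softmax(model.forward(x).data, axis=-1)
        assert np.allclose(probs.sum(axis=-1), 1.0, atol=1e-6)

    def test_region_without_targets_rejected(self):
        region, sites = _toy_region()
        from hapnn.regions import RegionSpec

        empty = RegionSpec(0, region.core_marker_idx, [], [], [], region.span)
        with pytest.raises(ValueError):
            build_rnn(empty, sites, RnnConfig(), seed=0)


def _training_setup(seed=21):
    panel = simulate_panel(SimConfig(n_sites=150, n_samples=60, seed=seed))
    asn = select_markers(panel, 30, 0.05, seed)
    blocks = uniform_blocks("22", int(panel.positions[-1]) + 1, 1)
    spans = subdivide_blocks(blocks, panel.positions[asn.marker_idx], 500)
    region = build_regions(spans, asn, panel.sites, 0)[0]
    return panel, asn, region


class TestTrainRnn:
    def test_smoke_run_logs_finite_losses(self):
        panel, _, region = _training_setup()
        trained = train_rnn(
            panel, region,
            RnnConfig(n_layers=2, hidden_size=8),
            RnnTrainConfig(max_epochs=2, n_validation=5, seed=1),
        )
        assert len(trained.log["val_loss"]) == 2
        assert np.isfinite(trained.log["val_loss"]).all()

    def test_best_epoch_is_argmin_of_validation_log(self):
        panel, _, region = _training_setup()
        trained = train_rnn(
            panel, region,
            RnnConfig(n_layers=2, hidden_size=8),
            RnnTrainConfig(max_epochs=5, n_validation=5, seed=2),
        )
        assert trained.log["best_epoch"] == int(np.argmin(trained.log["val_loss"]))

    def test_too_few_samples_rejected(self):
        panel, _, region = _training_setup()
        with pytest.raises(ValueError, match="n_validation"):
            train_rnn(panel, region, RnnConfig(), RnnTrainConfig(n_validation=60))

    def test_mask_augmentation_mode_trains(self):
        panel, _, region = _training_setup()
        trained = train_rnn(
            panel, region,
            RnnConfig(n_layers=2, hidden_size=8),
            RnnTrainConfig(max_epochs=2, n_validation=5, mask_augment_rate=0.3, seed=4),
        )
        assert np.isfinite(trained.log["train_loss"]).all()


@pytest.fixture(scope="module")
def trained():
    panel, asn, region = _training_setup()
    model = train_rnn(
        panel, region,
        RnnConfig(n_layers=2, hidden_size=8),
        RnnTrainConfig(max_epochs=3, n_validation=5, seed=3),
    )
    f = panel.alleles[region.marker_sequence, :].mean(axis=1)
    return model, panel, region, f


class TestImputeRegion:
    def test_probability_bounds_and_repeatability(self, trained, rng):
        model, panel, region, f = trained
        states = panel.alleles[region.marker_sequence, :6].astype(np.int8)
        x = encode_marker_inputs(states, f)
        p1 = impute_region(model, region, x)
        p2 = impute_region(model, region, x)
        assert ((p1 >= 0) & (p1 <= 1)).all()
        assert np.array_equal(p1, p2)

    def test_identical_haplotypes_get_identical_outputs(self, trained):
        model, panel, region, f = trained
        one = panel.alleles[region.marker_sequence, :1].astype(np.int8)
        two = np.repeat(one, 2, axis=1)
        p = impute_region(model, region, encode_marker_inputs(two, f))
        assert np.array_equal(p[:, 0], p[:, 1])

    def test_all_missing_inputs_are_sample_independent(self, trained):
        """With every marker missing, the frequency encoding makes inputs
        identical across haplotypes, so outputs must match too."""
        model, panel, region, f = trained
        states = np.full((region.marker_sequence.size, 4), MISSING, dtype=np.int8)
        p = impute_region(model, region, encode_marker_inputs(states, f))
        assert np.allclose(p, p[:, :1])

    def test_manifest_mismatch_rejected(self, trained):
        model, panel, region, f = trained
        from hapnn.regions import RegionSpec

        other = RegionSpec(
            region_id=region.region_id + 1,
            core_marker_idx=region.core_marker_idx,
            flank_left_idx=region.flank_left_idx,
            flank_right_idx=region.flank_right_idx,
            target_idx=region.target_idx,
            span=region.span,
        )
        states = panel.alleles[region.marker_sequence, :2].astype(np.int8)
        with pytest.raises(ValueError, match="manifest"):
            impute_region(model, other, encode_marker_inputs(states, f))


class TestCombineHaplotypes:
    def _sites(self, n):
        return [SiteMeta("22", 100 * (i + 1), f"s{i}", "A", "C") for i in range(n)]

    def test_certain_homozygote(self):
        res = combine_haplotypes_to_genotypes(np.array([[1.0, 1.0]]), self._sites(1), ["i0"])
        assert res.dosage[0, 0] == 2.0
        assert np.allclose(res.gp[0, 0], [0, 0, 1])

    def test_certain_heterozygote(self):
        res = combine_haplotypes_to_genotypes(np.array([[1.0, 0.0]]), self._sites(1), ["i0"])
        assert res.dosage[0, 0] == 1.0
        assert np.allclose(res.gp[0, 0], [0, 1, 0])

    def test_hand_arithmetic(self):
        res = combine_haplotypes_to_genotypes(np.array([[0.6, 0.3]]), self._sites(1), ["i0"])
        assert np.isclose(res.dosage[0, 0], 0.9)
        assert np.allclose(res.gp[0, 0], [0.28, 0.54, 0.18])

    @given(st.floats(0, 1), st.floats(0, 1))
    def test_dosage_conservation(self, p, q):
        """dosage == P(het) + 2 P(hom-a1) exactly, for any hap probabilities."""
        res = combine_haplotypes_to_genotypes(
            np.array([[p, q]]), self._sites(1), ["i0"]
        )
        assert np.isclose(res.dosage[0, 0], res.gp[0, 0, 1] + 2 * res.gp[0, 0, 2], atol=1e-12)


class TestMergeRegions:
    def _result(self, positions, value):
        sites = [SiteMeta("22", p, f"s{p}", "A", "C") for p in positions]
        n = len(positions)
        gp = np.zeros((n, 1, 3))
        gp[:, :, 0] = 1.0
        res = DosageResult(sites=sites, sample_ids=["i0"], dosage=np.full((n, 1), value), gp=gp)
        res.dosage[:] = 0.0  # keep dosage consistent with gp
        return res

    def test_single_region_identity(self):
        r = self._result([100, 200], 0)
        merged = merge_regions([r])
        assert [s.pos for s in merged.sites] == [100, 200]

    def test_two_regions_sorted_union(self):
        merged = merge_regions([self._result([300, 400], 0), self._result([100, 200], 0)])
        assert [s.pos for s in merged.sites] == [100, 200, 300, 400]

    def test_duplicate_site_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            merge_regions([self._result([100], 0), self._result([100], 0)])

    def test_site_count_conserved_on_random_tiling(self, rng):
        positions = (np.sort(rng.choice(10000, size=30, replace=False)) + 1)
        chunks = np.array_split(positions, 4)
        rng.shuffle(chunks := list(chunks))
        merged = merge_regions([self._result(list(c), 0) for c in chunks if len(c)])
        assert [s.pos for s in merged.sites] == sorted(positions.tolist())
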