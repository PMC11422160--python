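"""The mosaic-of-founders simulator and its experiment plumbing."""

import numpy as np
import pytest

from hapnn.io import compute_freqs
from hapnn.sim import (
    MarkerAssignment,
    SimConfig,
    apply_marker_missingness,
    select_markers,
    simulate_panel,
    split_samples,
)


def _pairwise_r2(alleles, lag):
    """Brute-force mean squared correlation between sites `lag` apart."""
    vals = []
    a = alleles.astype(float)
    for i in range(alleles.shape[0] - lag):
        x, y = a[i], a[i + lag]
        if x.std() == 0 or y.std() == 0:
            continue
        vals.append(np.corrcoef(x, y)[0, 1] ** 2)
    return float(np.mean(vals))


class TestSimulatePanel:
    def test_seed_determinism(self):
        cfg = SimConfig(n_sites=50, n_samples=20, seed=1)
        a = simulate_panel(cfg)
        b = simulate_panel(cfg)
        assert np.array_equal(a.alleles, b.alleles)
        assert [s.pos for s in a.sites] == [s.pos for s in b.sites]

    def test_single_founder_no_mutation_is_constant(self):
        cfg = SimConfig(n_sites=30, n_samples=10, n_founders=1, mutation_rate=0.0, seed=2)
        panel = simulate_panel(cfg)
        # every haplotype is a copy of the single founder
        assert (panel.alleles == panel.alleles[:, :1]).all()

    def test_ld_decays_with_distance(self):
        cfg = SimConfig(n_sites=200, n_samples=200, switch_rate=0.005, seed=3)
        panel = simulate_panel(cfg)
        assert _pairwise_r2(panel.alleles, 1) > _pairwise_r2(panel.alleles, 50)

    def test_ld_monotone_over_lag_bins(self):
        panel = simulate_panel(SimConfig(n_sites=300, n_samples=200, seed=4))
        r2 = [
            np.median([_pairwise_r2(panel.alleles, lag) for lag in lags])
            for lags in (range(1, 6), range(20, 31, 5), range(80, 101, 10))
        ]
        assert r2[0] >= r2[1] >= r2[2]

    def test_frequency_control_with_large_panel(self):
        """Without mutation, sample frequencies track the founder-frequency
        mixture (each haplotype copies founders uniformly)."""
        cfg = SimConfig(n_sites=80, n_samples=500, mutation_rate=0.0, seed=5)
        panel = simulate_panel(cfg)
        rng = np.random.default_rng(np.random.SeedSequence([5, 2024]))
        founder_freqs = rng.beta(cfg.freq_alpha, cfg.freq_alpha, size=cfg.n_sites)
        founders = (rng.random((cfg.n_sites, cfg.n_founders)) < founder_freqs[:, None])
        expected = founders.mean(axis=1)
        observed = panel.alleles.mean(axis=1)
        assert np.abs(observed - expected).mean() < 0.05

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(n_sites=10, n_samples=5, switch_rate=0.0)
        with pytest.raises(ValueError):
            SimConfig(n_sites=10, n_samples=5, mutation_rate=0.5)


class TestSelectMarkers:
    def test_forced_choice_when_exactly_enough(self, small_panel):
        freqs = compute_freqs(small_panel)
        # pick a threshold leaving some definite number of eligible sites
        maf_min = np.sort(freqs.maf)[-10]
        eligible = np.flatnonzero(freqs.maf >= maf_min)
        asn = select_markers(small_panel, eligible.size, maf_min, seed=0)
        assert np.array_equal(asn.marker_idx, eligible)

    def test_zero_markers_all_targets(self, small_panel):
        asn = select_markers(small_panel, 0, 0.0, seed=0)
        assert asn.marker_idx.size == 0
        assert asn.target_idx.size == small_panel.n_sites

    def test_different_seeds_both_satisfy_constraint(self, small_panel):
        freqs = compute_freqs(small_panel)
        a = select_markers(small_panel, 20, 0.05, seed=1)
        b = select_markers(small_panel, 20, 0.05, seed=2)
        assert a.marker_idx.size == b.marker_idx.size == 20
        assert not np.array_equal(a.marker_idx, b.marker_idx)
        for asn in (a, b):
            assert (freqs.maf[asn.marker_idx] >= 0.05).all()
            assert np.intersect1d(asn.marker_idx, asn.target_idx).size == 0

    def test_insufficient_sites_report_deficit(self, small_panel):
        with pytest.raises(ValueError, match="MAF"):
            select_markers(small_panel, small_panel.n_sites + 1, 0.0, seed=0)


class TestSplitSamples:
    def test_zero_test_returns_everything_as_reference(self, small_panel):
        ref, test = split_samples(small_panel, 0, seed=0)
        assert test.n_samples == 0
        assert np.array_equal(ref.alleles, small_panel.alleles)

    def test_one_of_three_partition(self):
        from hapnn.sim import SimConfig, simulate_panel

        panel = simulate_panel(SimConfig(n_sites=10, n_samples=3, seed=9))
        ref, test = split_samples(panel, 1, seed=0)
        assert (ref.n_samples, test.n_samples) == (2, 1)

    def test_partition_disjoint_and_complete(self, small_panel):
        ref, test = split_samples(small_panel, 13, seed=4)
        assert set(ref.sample_ids) | set(test.sample_ids) == set(small_panel.sample_ids)
        assert set(ref.sample_ids) & set(test.sample_ids) == set()
        # pair-intactness: each test sample's columns equal its original pair
        for j, sid in enumerate(test.sample_ids):
            i = small_panel.sample_ids.index(sid)
            assert np.array_equal(
                test.alleles[:, 2 * j : 2 * j + 2],
                small_panel.alleles[:, 2 * i : 2 * i + 2],
            )

    def test_too_large_test_set_rejected(self, small_panel):
        with pytest.raises(ValueError):
            split_samples(small_panel, small_panel.n_samples, seed=0)


class TestMarkerMissingness:
    def test_rate_zero_empty(self):
        mask = apply_marker_missingness(np.arange(100), 0.0, seed=0)
        assert mask.removed_marker_idx.size == 0

    def test_rate_one_removes_everything(self):
        markers = np.arange(10, 60)
        mask = apply_marker_missingness(markers, 1.0, seed=0)
        assert np.array_equal(mask.removed_marker_idx, markers)

    def test_qc_style_rate_exact_count(self):
        # 20% is the upper end of typical array QC removal
        mask = apply_marker_missingness(np.arange(500), 0.2, seed=1)
        assert mask.removed_marker_idx.size == 100

    def test_reproducible_and_subset_of_markers(self):
        markers = np.arange(0, 1000, 7)
        a = apply_marker_missingness(markers, 0.1, seed=5)
        b = apply_marker_missingness(markers, 0.1, seed=5)
        assert np.array_equal(a.removed_marker_idx, b.removed_marker_idx)
        assert np.isin(a.removed_marker_idx, markers).all()
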