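"""Synthetic phased haplotype panels with tunable linkage disequilibrium.

The generator is a mosaic-of-founders model: a small set of founder
haplotypes is drawn site-by-site from Bernoulli(p_s) with per-site
frequencies p_s ~ Beta(alpha, alpha), and every emitted haplotype copies a
founder, switching to a uniformly chosen founder at each site with a small
per-site probability.  Geometric segment lengths approximate uniform
recombination; a per-allele flip rate adds mutation noise.  This gives the
block-correlated allele structure that the imputation models exploit
without needing a coalescent simulator or external data.

The module also provides the experiment plumbing around the panel: array
marker selection (common sites, as on a genotyping chip), reference/test
individual splits, and whole-marker missingness of the kind produced when
markers fail quality control.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import HaplotypePanel, SiteMeta, compute_freqs

__all__ = [
    "SimConfig",
    "MarkerAssignment",
    "MissingMask",
    "simulate_panel",
    "select_markers",
    "split_samples",
    "apply_marker_missingness",
]

_BP_STEP = 1000  # fixed spacing between simulated sites; only order matters


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the mosaic-of-founders haplotype generator."""

    n_sites: int
    n_samples: int
    n_founders: int = 12
    switch_rate: float = 0.01  # per-site founder-switch probability
    mutation_rate: float = 0.002  # per-allele flip probability
    freq_alpha: float = 0.4  # Beta shape for founder allele frequencies
    seed: int = 0
    chrom: str = "22"

    def __post_init__(self):
        if self.n_sites < 1 or self.n_samples < 1:
            raise ValueError("n_sites and n_samples must be positive")
        if self.n_founders < 1:
            raise ValueError("need at least one founder")
        if not 0.0 < self.switch_rate < 1.0:
            raise ValueError("switch_rate must lie in (0, 1)")
        if not 0.0 <= self.mutation_rate < 0.5:
            raise ValueError("mutation_rate must lie in [0, 0.5)")
        if self.freq_alpha <= 0:
            raise ValueError("freq_alpha must be positive")


@dataclass(frozen=True)
class MarkerAssignment:
    """Partition of panel sites into array markers and imputation targets."""

    marker_idx: np.ndarray
    target_idx: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "marker_idx", np.asarray(self.marker_idx, dtype=np.int64))
        object.__setattr__(self, "target_idx", np.asarray(self.target_idx, dtype=np.int64))
        if np.intersect1d(self.marker_idx, self.target_idx).size:
            raise ValueError("marker and target site sets must be disjoint")


@dataclass(frozen=True)
class MissingMask:
    """Whole-marker missingness: the listed markers are missing for every
    sample, mimicking markers dropped during array quality control."""

    removed_marker_idx: np.ndarray
    rate: float
    seed: int

    def __post_init__(self):
        object.__setattr__(
            self, "removed_marker_idx", np.asarray(self.removed_marker_idx, dtype=np.int64)
        )


def simulate_panel(config: SimConfig) -> HaplotypePanel:
    """Draw a phased haplotype panel from the mosaic-of-founders model.

    Fully reproducible from ``config.seed``; positions are consecutive
    multiples of a fixed 1 kb step.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 2024]))
    n_hap = 2 * config.n_samples
    founder_freqs = rng.beta(config.freq_alpha, config.freq_alpha, size=config.n_sites)
    founders = (
        rng.random((config.n_sites, config.n_founders)) < founder_freqs[:, None]
    ).astype(np.int8)

    # Founder path per haplotype: resample the founder index with
    # probability switch_rate at each site, else copy the previous one.
    proposals = rng.integers(0, config.n_founders, size=(config.n_sites, n_hap))
    switch = rng.random((config.n_sites, n_hap)) < config.switch_rate
    switch[0, :] = True
    site_idx = np.arange(config.n_sites)[:, None]
    last_switch = np.maximum.accumulate(np.where(switch, site_idx, 0), axis=0)
    founder_path = np.take_along_axis(proposals, last_switch, axis=0)
    alleles = founders[np.arange(config.n_sites)[:, None], founder_path]

    if config.mutation_rate > 0:
        flips = rng.random(alleles.shape) < config.mutation_rate
        alleles = np.where(flips, 1 - alleles, alleles).astype(np.int8)

    sites = [
        SiteMeta(
            chrom=config.chrom,
            pos=(i + 1) * _BP_STEP,
            id=f"sim{i}",
            a0="A",
            a1="G",
        )
        for i in range(config.n_sites)
    ]
    sample_ids = [f"S{i:05d}" for i in range(config.n_samples)]
    return HaplotypePanel(sites=sites, alleles=alleles, sample_ids=sample_ids)


def select_markers(
    panel: HaplotypePanel, n_markers: int, maf_min: float, seed: int
) -> MarkerAssignment:
    """Designate ``n_markers`` array markers, sampled uniformly without
    replacement from sites with MAF >= ``maf_min`` (chips target common
    variants); everything else becomes an imputation target."""
    freqs = compute_freqs(panel)
    eligible = np.flatnonzero(freqs.maf >= maf_min)
    if eligible.size < n_markers:
        raise ValueError(
            f"need {n_markers} sites with MAF >= {maf_min}, found only "
            f"{eligible.size} ({n_markers - eligible.size} short)"
        )
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 777]))
    marker_idx = np.sort(rng.choice(eligible, size=n_markers, replace=False))
    target_idx = np.setdiff1d(np.arange(panel.n_sites), marker_idx)
    return MarkerAssignment(marker_idx=marker_idx, target_idx=target_idx)


def split_samples(
    panel: HaplotypePanel, n_test: int, seed: int
) -> tuple[HaplotypePanel, HaplotypePanel]:
    """Split individuals into (reference, test) panels, haplotype pairs
    intact; the test set plays the role of array-genotyped individuals."""
    if n_test >= panel.n_samples:
        raise ValueError(
            f"n_test ({n_test}) must be smaller than the sample count ({panel.n_samples})"
        )
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 555]))
    test = np.sort(rng.choice(panel.n_samples, size=n_test, replace=False))
    reference = np.setdiff1d(np.arange(panel.n_samples), test)
    return panel.subset_samples(reference), panel.subset_samples(test)


def apply_marker_missingness(markers, rate: float, seed: int) -> MissingMask:
    """Remove ``round(rate * n_markers)`` whole markers uniformly at random
    (quality-control semantics: a removed marker is missing for all
    samples)."""
    if not 0.0 <= rate <= 1.0:
        raise ValueError("rate must lie in [0, 1]")
    markers = np.asarray(markers, dtype=np.int64)
    n_remove = int(round(rate * markers.size))
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 333]))
    removed = np.sort(rng.choice(markers, size=n_remove, replace=False))
    return MissingMask(removed_marker_idx=removed, rate=rate, seed=seed)
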