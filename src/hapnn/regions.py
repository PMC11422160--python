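"""Chromosome segmentation into model regions.

Both imputation models are trained per region.  Regions come from LD
blocks: each block is subdivided so that no region holds more than a
marker budget (about 200 array markers for the recurrent imputer, about
500 for the denoising autoencoder), with balanced marker counts and split
boundaries at the bp midpoint between adjacent markers.  Flanking markers
just outside each region are appended to the recurrent model's input so
targets near a boundary still see local LD context.

Segmentation is a pure function of its inputs; region manifests serialise
to JSON and carry a content hash so that training and imputation runs can
verify they are talking about the same regions.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from math import ceil

import numpy as np

from .io import FreqTable, IntervalSet
from .sim import MarkerAssignment

__all__ = [
    "RegionSpec",
    "subdivide_blocks",
    "build_regions",
    "filter_targets_by_maf",
    "uniform_blocks",
]


@dataclass(frozen=True)
class RegionSpec:
    """One model region: core markers, optional flank markers, and the
    target sites whose bp positions fall inside the core span."""

    region_id: int
    core_marker_idx: np.ndarray
    flank_left_idx: np.ndarray
    flank_right_idx: np.ndarray
    target_idx: np.ndarray
    span: tuple[int, int]  # half-open [start, end) in 1-based bp

    def __post_init__(self):
        for name in ("core_marker_idx", "flank_left_idx", "flank_right_idx", "target_idx"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=np.int64))

    @property
    def marker_sequence(self) -> np.ndarray:
        """All input markers in genomic order: left flank, core, right flank."""
        return np.concatenate([self.flank_left_idx, self.core_marker_idx, self.flank_right_idx])

    def to_dict(self) -> dict:
        return {
            "region_id": int(self.region_id),
            "core_marker_idx": self.core_marker_idx.tolist(),
            "flank_left_idx": self.flank_left_idx.tolist(),
            "flank_right_idx": self.flank_right_idx.tolist(),
            "target_idx": self.target_idx.tolist(),
            "span": [int(self.span[0]), int(self.span[1])],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RegionSpec":
        return cls(
            region_id=d["region_id"],
            core_marker_idx=d["core_marker_idx"],
            flank_left_idx=d["flank_left_idx"],
            flank_right_idx=d["flank_right_idx"],
            target_idx=d["target_idx"],
            span=(d["span"][0], d["span"][1]),
        )

    def manifest_hash(self) -> str:
        """Stable content hash used to pin trained models to their region."""
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def uniform_blocks(chrom: str, max_pos: int, n_blocks: int) -> IntervalSet:
    """Evenly spaced stand-in LD blocks covering [0, max_pos)."""
    edges = np.linspace(0, max_pos, n_blocks + 1).astype(np.int64)
    return IntervalSet(
        intervals=[(chrom, int(edges[i]), int(edges[i + 1])) for i in range(n_blocks)]
    )


def subdivide_blocks(
    blocks: IntervalSet,
    marker_positions,
    markers_per_region: int,
    greedy: bool = False,
) -> list[tuple[int, int]]:
    """Split LD blocks into sub-region spans holding at most
    ``markers_per_region`` markers each.

    A block with ``m`` markers becomes ``ceil(m / markers_per_region)``
    sub-regions with marker counts as equal as possible (balanced mode,
    sizes differing by at most one) or cut at every ``markers_per_region``-th
    marker (``greedy=True``).  Split boundaries sit at the bp midpoint
    between adjacent markers, so no region ever crosses a block boundary.
    Blocks containing no markers are merged into their left neighbour
    (the leftmost empty block merges rightward).

    Returns half-open spans ``[start, end)`` in 1-based bp coordinates.
    """
    positions = np.asarray(marker_positions, dtype=np.int64)
    if positions.size == 0:
        raise ValueError("marker position list is empty")
    if markers_per_region < 1:
        raise ValueError("markers_per_region must be >= 1")
    if (np.diff(positions) <= 0).any():
        raise ValueError("marker positions must be strictly increasing")

    # BED half-open 0-based -> 1-based position span: pos in block iff
    # start < pos <= end, i.e. the 1-based span [start+1, end+1).
    spans_1b = [(start + 1, end + 1) for _, start, end in blocks]
    counts = [
        int(((positions >= s) & (positions < e)).sum()) for s, e in spans_1b
    ]

    # Merge zero-marker blocks leftward (leftmost merges rightward).
    merged: list[tuple[int, int]] = []
    merged_counts: list[int] = []
    for (s, e), c in zip(spans_1b, counts):
        if merged and (c == 0 or merged_counts[-1] == 0):
            ps, _ = merged[-1]
            merged[-1] = (ps, e)
            merged_counts[-1] += c
        else:
            merged.append((s, e))
            merged_counts.append(c)
    if merged_counts and merged_counts[0] == 0 and len(merged) > 1:
        merged[1] = (merged[0][0], merged[1][1])
        merged_counts[1] += merged_counts[0]
        merged, merged_counts = merged[1:], merged_counts[1:]

    out: list[tuple[int, int]] = []
    for (s, e), m in zip(merged, merged_counts):
        if m == 0:
            continue  # a single block with zero markers anywhere
        in_block = positions[(positions >= s) & (positions < e)]
        k = ceil(m / markers_per_region)
        if greedy:
            sizes = [markers_per_region] * (m // markers_per_region)
            if m % markers_per_region:
                sizes.append(m % markers_per_region)
        else:
            base, extra = divmod(m, k)
            sizes = [base + 1] * extra + [base] * (k - extra)
        cut = 0
        prev_bound = s
        for j, size in enumerate(sizes):
            cut += size
            if j == len(sizes) - 1:
                bound = e
            else:
                bound = int((in_block[cut - 1] + in_block[cut]) // 2) + 1
            out.append((prev_bound, bound))
            prev_bound = bound
    return out


def build_regions(
    sub_spans,
    marker_assignment: MarkerAssignment,
    panel_sites,
    n_flank: int,
) -> list[RegionSpec]:
    """Attach flank markers and target sites to sub-region spans.

    Flanks are the ``n_flank`` markers nearest to each core boundary on the
    outside (fewer at chromosome ends).  Target sites are assigned by bp
    containment in the core span; the first and last spans are extended to
    the chromosome ends so every target belongs to exactly one region.
    """
    spans = sorted((int(s), int(e)) for s, e in sub_spans)
    for (s0, e0), (s1, e1) in zip(spans, spans[1:]):
        if s1 < e0:
            raise ValueError(f"overlapping spans {(s0, e0)} and {(s1, e1)}")
    positions = np.array([s.pos for s in panel_sites], dtype=np.int64)
    marker_idx = marker_assignment.marker_idx
    target_idx = marker_assignment.target_idx
    marker_pos = positions[marker_idx]
    target_pos = positions[target_idx]

    regions: list[RegionSpec] = []
    for rid, (s, e) in enumerate(spans):
        # Chromosome-end extension for target containment only.
        lo = 0 if rid == 0 else s
        hi = np.iinfo(np.int64).max if rid == len(spans) - 1 else e
        in_core = (marker_pos >= s) & (marker_pos < e)
        core = marker_idx[in_core]
        if core.size == 0:
            raise ValueError(f"span {(s, e)} contains no markers")
        first, last = np.flatnonzero(in_core)[[0, -1]]
        flank_left = marker_idx[max(0, first - n_flank) : first]
        flank_right = marker_idx[last + 1 : last + 1 + n_flank]
        targets = target_idx[(target_pos >= lo) & (target_pos < hi)]
        regions.append(
            RegionSpec(
                region_id=rid,
                core_marker_idx=core,
                flank_left_idx=flank_left,
                flank_right_idx=flank_right,
                target_idx=targets,
                span=(s, e),
            )
        )

    covered = np.concatenate([r.core_marker_idx for r in regions])
    if covered.size != marker_idx.size or not np.array_equal(np.sort(covered), marker_idx):
        raise ValueError("sub-spans do not tile the marker set exactly once")
    return regions


def filter_targets_by_maf(targets, freqs: FreqTable, maf_min: float) -> np.ndarray:
    """Drop rare target sites (MAF below ``maf_min``); rare variants are
    both hard to learn and dominate training cost, so they are excluded
    from the imputation target set."""
    targets = np.asarray(targets, dtype=np.int64)
    return targets[freqs.maf[targets] >= maf_min]


def save_manifest(regions: list[RegionSpec], path) -> None:
    with open(path, "w") as fh:
        json.dump([r.to_dict() for r in regions], fh)


def load_manifest(path) -> list[RegionSpec]:
    with open(path) as fh:
        return [RegionSpec.from_dict(d) for d in json.load(fh)]
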