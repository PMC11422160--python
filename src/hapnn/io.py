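"""Genotype I/O: phased-VCF haplotype panels, LD-block BED files, marker
site lists, and dosage-VCF output.

All variant sites are biallelic; the two alleles of each site are labelled
a0 (the VCF REF-orientation allele) and a1, and haplotype matrices store a
1 wherever a haplotype carries the a1 allele.  Each diploid sample owns two
consecutive haplotype columns ``(2i, 2i+1)``, a pairing that every
subsetting operation preserves.

Coordinate conventions: VCF positions are 1-based, BED intervals half-open
0-based; all internal region arithmetic downstream works in site-index
space so the conventions only matter at the file boundary.  Chromosome
labels are normalised by stripping any ``chr`` prefix.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pysam

logger = logging.getLogger(__name__)

__all__ = [
    "SiteMeta",
    "HaplotypePanel",
    "FreqTable",
    "IntervalSet",
    "VcfFormatError",
    "read_vcf_haplotypes",
    "write_dosage_vcf",
    "compute_freqs",
    "read_ld_blocks",
    "read_site_list",
    "write_phased_vcf",
    "match_sites_to_panel",
]


class VcfFormatError(ValueError):
    """Raised when an input file violates the expected format."""


def normalize_chrom(label: str) -> str:
    label = str(label)
    return label[3:] if label.lower().startswith("chr") else label


@dataclass(frozen=True)
class SiteMeta:
    """Metadata for one biallelic variant site."""

    chrom: str
    pos: int  # 1-based bp
    id: str
    a0: str
    a1: str

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if self.a0 == self.a1:
            raise ValueError(f"site {self.id}: a0 and a1 alleles are identical")


@dataclass
class HaplotypePanel:
    """A phased biallelic haplotype panel: sites × haplotypes allele matrix.

    ``alleles[s, h]`` is 1 when haplotype ``h`` carries the a1 allele at
    site ``s``.  Sample ``i`` owns haplotype columns ``2i`` and ``2i+1``.
    """

    sites: list[SiteMeta]
    alleles: np.ndarray  # (n_sites, n_haplotypes) of {0, 1}, int8
    sample_ids: list[str]

    def __post_init__(self):
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        if self.alleles.ndim != 2:
            raise ValueError("alleles must be a 2-D matrix (sites x haplotypes)")
        if self.alleles.shape[0] != len(self.sites):
            raise ValueError("row count does not match the site list")
        if self.alleles.shape[1] != 2 * len(self.sample_ids):
            raise ValueError("haplotype count must be 2 x sample count (diploid)")
        if self.alleles.size and not np.isin(self.alleles, (0, 1)).all():
            raise ValueError("allele matrix entries must be 0 or 1")
        positions = [s.pos for s in self.sites]
        if any(b <= a for a, b in zip(positions, positions[1:])):
            raise ValueError("sites must be strictly ascending in position")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_haplotypes(self) -> int:
        return self.alleles.shape[1]

    @property
    def positions(self) -> np.ndarray:
        return np.array([s.pos for s in self.sites], dtype=np.int64)

    def subset_samples(self, indices: Sequence[int]) -> "HaplotypePanel":
        """New panel with the given samples, haplotype pairs kept intact."""
        indices = list(indices)
        cols = np.array([[2 * i, 2 * i + 1] for i in indices], dtype=np.int64).reshape(-1)
        return HaplotypePanel(
            sites=list(self.sites),
            alleles=self.alleles[:, cols] if len(cols) else self.alleles[:, :0],
            sample_ids=[self.sample_ids[i] for i in indices],
        )

    def subset_sites(self, site_indices: Sequence[int]) -> "HaplotypePanel":
        site_indices = np.asarray(site_indices, dtype=np.int64)
        return HaplotypePanel(
            sites=[self.sites[i] for i in site_indices],
            alleles=self.alleles[site_indices, :],
            sample_ids=list(self.sample_ids),
        )

    def genotype_counts(self) -> np.ndarray:
        """Per-site a1-allele counts per sample in {0, 1, 2}; shape
        (n_sites, n_samples)."""
        return (
            self.alleles[:, 0::2].astype(np.int16)
            + self.alleles[:, 1::2].astype(np.int16)
        )


@dataclass
class FreqTable:
    """Per-site a1-allele frequency and derived minor-allele frequency."""

    f_a1: np.ndarray
    maf: np.ndarray = field(init=False)

    def __post_init__(self):
        self.f_a1 = np.asarray(self.f_a1, dtype=np.float64)
        if ((self.f_a1 < 0) | (self.f_a1 > 1)).any():
            raise ValueError("allele frequencies must lie in [0, 1]")
        self.maf = np.minimum(self.f_a1, 1.0 - self.f_a1)


@dataclass
class IntervalSet:
    """Sorted, non-overlapping half-open genomic intervals (0-based)."""

    intervals: list[tuple[str, int, int]]

    def __post_init__(self):
        for chrom, start, end in self.intervals:
            if start >= end:
                raise ValueError(f"empty/inverted interval {chrom}:{start}-{end}")
        starts = [iv[1] for iv in self.intervals]
        if starts != sorted(starts):
            raise ValueError("intervals must be sorted by start")
        for (_, _, e0), (_, s1, _) in zip(self.intervals, self.intervals[1:]):
            if s1 < e0:
                raise ValueError("intervals must not overlap")

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)


def read_vcf_haplotypes(
    path: str | Path,
    sample_subset: Sequence[str] | None = None,
    strict: bool = False,
) -> HaplotypePanel:
    """Read fully phased biallelic haplotypes from a VCF (gzip OK).

    Multiallelic or unphased records are dropped with a logged count by
    default; with ``strict=True`` they raise :class:`VcfFormatError` naming
    the offending record.
    """
    vf = pysam.VariantFile(str(path))
    if sample_subset is not None:
        missing = [s for s in sample_subset if s not in vf.header.samples]
        if missing:
            raise VcfFormatError(f"samples not present in VCF: {missing}")
        vf.subset_samples(list(sample_subset))
    samples = list(vf.header.samples)
    if not samples:
        raise VcfFormatError(f"{path}: VCF has no samples")

    sites: list[SiteMeta] = []
    rows: list[np.ndarray] = []
    n_dropped = 0
    for rec in vf:
        if rec.alts is None or len(rec.alts) != 1:
            if strict:
                raise VcfFormatError(
                    f"{path}: non-biallelic record at {rec.chrom}:{rec.pos}"
                )
            n_dropped += 1
            continue
        row = np.empty(2 * len(samples), dtype=np.int8)
        ok = True
        for i, name in enumerate(samples):
            call = rec.samples[name]
            gt = call.get("GT")
            if gt is None or len(gt) != 2 or any(a is None for a in gt):
                if strict:
                    raise VcfFormatError(
                        f"{path}: missing GT for sample {name} at {rec.chrom}:{rec.pos}"
                    )
                ok = False
                break
            if not call.phased:
                if strict:
                    raise VcfFormatError(
                        f"{path}: unphased genotype for sample {name} "
                        f"at {rec.chrom}:{rec.pos}"
                    )
                ok = False
                break
            row[2 * i] = gt[0]
            row[2 * i + 1] = gt[1]
        if not ok:
            n_dropped += 1
            continue
        sites.append(
            SiteMeta(
                chrom=normalize_chrom(rec.chrom),
                pos=rec.pos,
                id=rec.id or f"{normalize_chrom(rec.chrom)}:{rec.pos}",
                a0=rec.ref,
                a1=rec.alts[0],
            )
        )
        rows.append(row)
    vf.close()
    if n_dropped:
        logger.warning("%s: dropped %d non-biallelic/unphased records", path, n_dropped)
    alleles = np.stack(rows) if rows else np.zeros((0, 2 * len(samples)), dtype=np.int8)
    return HaplotypePanel(sites=sites, alleles=alleles, sample_ids=samples)


def write_dosage_vcf(sites: Sequence[SiteMeta], dosages, path: str | Path) -> None:
    """Write imputed genotypes as a VCF with GT (hard call), DS (a1 dosage)
    and GP (genotype probability triple) FORMAT fields.

    ``dosages`` is a :class:`~hapnn.rnn.DosageResult`-like object exposing
    ``sample_ids``, ``dosage`` (n_sites, n_samples) and ``gp``
    (n_sites, n_samples, 3).
    """
    dosage = np.asarray(dosages.dosage, dtype=np.float64)
    gp = np.asarray(dosages.gp, dtype=np.float64)
    if ((dosage < -1e-9) | (dosage > 2 + 1e-9)).any():
        raise ValueError("dosage values must lie in [0, 2]")
    if np.abs(gp.sum(axis=-1) - 1.0).max() > 1e-6:
        raise ValueError("genotype probabilities must sum to 1")

    header = pysam.VariantHeader()
    for chrom in dict.fromkeys(s.chrom for s in sites):
        header.contigs.add(chrom, length=max(s.pos for s in sites if s.chrom == chrom) + 1)
    header.formats.add("GT", 1, "String", "Genotype (argmax of GP)")
    header.formats.add("DS", 1, "Float", "Estimated a1 allele dosage")
    header.formats.add("GP", "G", "Float", "Genotype probabilities: hom-a0, het, hom-a1")
    for sid in dosages.sample_ids:
        header.add_sample(sid)

    hard_calls = [(0, 0), (0, 1), (1, 1)]
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for s_idx, site in enumerate(sites):
            rec = out.new_record(
                contig=site.chrom,
                start=site.pos - 1,
                stop=site.pos,
                alleles=(site.a0, site.a1),
                id=site.id,
            )
            for n_idx, sid in enumerate(dosages.sample_ids):
                probs = gp[s_idx, n_idx]
                call = rec.samples[sid]
                call["GT"] = hard_calls[int(np.argmax(probs))]
                call.phased = False
                call["DS"] = float(dosage[s_idx, n_idx])
                call["GP"] = tuple(float(p) for p in probs)
            out.write(rec)


def write_phased_vcf(panel: HaplotypePanel, path: str | Path) -> None:
    """Write a panel back out as a fully phased biallelic VCF."""
    header = pysam.VariantHeader()
    for chrom in dict.fromkeys(s.chrom for s in panel.sites):
        header.contigs.add(chrom, length=int(panel.positions[-1]) + 1)
    header.formats.add("GT", 1, "String", "Phased genotype")
    for sid in panel.sample_ids:
        header.add_sample(sid)
    with pysam.VariantFile(str(path), "w", header=header) as vf:
        for i, site in enumerate(panel.sites):
            rec = vf.new_record(
                contig=site.chrom, start=site.pos - 1, stop=site.pos,
                alleles=(site.a0, site.a1), id=site.id,
            )
            for j, sid in enumerate(panel.sample_ids):
                call = rec.samples[sid]
                call["GT"] = (
                    int(panel.alleles[i, 2 * j]),
                    int(panel.alleles[i, 2 * j + 1]),
                )
                call.phased = True
            vf.write(rec)


def compute_freqs(panel: HaplotypePanel) -> FreqTable:
    """Per-site a1-allele frequency: row mean of the allele matrix."""
    if panel.n_haplotypes == 0:
        raise ValueError("cannot compute frequencies on a panel with no haplotypes")
    return FreqTable(f_a1=panel.alleles.mean(axis=1))


def read_ld_blocks(path: str | Path, chrom: str) -> IntervalSet:
    """Read LD-block intervals from a BED-like file for one chromosome.

    Tolerates a header line and ``chr``-prefixed labels; returns intervals
    sorted by start, validated non-overlapping.
    """
    chrom = normalize_chrom(chrom)
    rows: list[tuple[str, int, int]] = []
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as fh:
        for line_no, line in enumerate(fh, start=1):
            fields = line.split()
            if not fields or fields[0].startswith(("#", "track", "browser")):
                continue
            if len(fields) < 3:
                raise VcfFormatError(f"{path}:{line_no}: expected >= 3 columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                if line_no == 1:
                    continue  # header line with column names
                raise VcfFormatError(f"{path}:{line_no}: non-integer coordinates")
            if start >= end:
                raise VcfFormatError(f"{path}:{line_no}: start >= end")
            if normalize_chrom(fields[0]) == chrom:
                rows.append((chrom, start, end))
    rows.sort(key=lambda iv: iv[1])
    return IntervalSet(intervals=rows)


def read_site_list(path: str | Path) -> list[tuple[str, int]]:
    """Read array-marker positions: one ``chrom:pos`` or ``chrom<TAB>pos``
    per line; deduplicated and sorted."""
    out: set[tuple[str, int]] = set()
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if ":" in line:
                parts = line.split(":")
            else:
                parts = line.split()
            if len(parts) != 2:
                raise VcfFormatError(f"{path}:{line_no}: expected 'chrom pos' or 'chrom:pos'")
            try:
                pos = int(parts[1])
            except ValueError:
                raise VcfFormatError(f"{path}:{line_no}: non-integer position {parts[1]!r}")
            out.add((normalize_chrom(parts[0]), pos))
    return sorted(out)


def match_sites_to_panel(
    site_list: Sequence[tuple[str, int]],
    panel: HaplotypePanel,
    by_alleles: dict[tuple[str, int], tuple[str, str]] | None = None,
) -> np.ndarray:
    """Indices of panel sites matching a (chrom, pos) site list.

    Default matching is by position only; pass ``by_alleles`` mapping
    (chrom, pos) -> (a0, a1) to additionally require allele agreement.
    """
    wanted = set(site_list)
    idx = []
    for i, s in enumerate(panel.sites):
        key = (s.chrom, s.pos)
        if key not in wanted:
            continue
        if by_alleles is not None:
            alleles = by_alleles.get(key)
            if alleles is not None and set(alleles) != {s.a0, s.a1}:
                continue
        idx.append(i)
    return np.asarray(idx, dtype=np.int64)
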