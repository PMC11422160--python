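"""Imputation accuracy readouts: per-site R², MAF-binned means, and
strategy/rate comparison tables.

R² for a target site is the square of the Pearson correlation between the
true a1 genotype counts (0/1/2 per individual) and the imputed a1 dosages
across individuals.  A site where either vector is constant has no defined
correlation; such sites are flagged (NaN) and excluded from binned means
rather than scored zero, with their count reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_MAF_BINS",
    "EvalTable",
    "r2_per_site",
    "bin_by_maf",
    "build_eval_table",
    "compare_strategies",
    "plot_r2_vs_maf",
]

#: Logarithmic-style MAF bin edges; imputation accuracy varies most at the
#: rare end, so bins narrow toward zero.
DEFAULT_MAF_BINS: tuple[float, ...] = (0.005, 0.01, 0.02, 0.05, 0.1, 0.2, 0.35, 0.5)


def r2_per_site(true_counts: np.ndarray, dosages: np.ndarray) -> np.ndarray:
    """Squared Pearson correlation per site between true a1 genotype
    counts and imputed dosages.

    Both arrays are (n_sites, n_samples) (or 1-D for a single site).
    Returns one value per site; NaN where either vector is constant.
    """
    t = np.atleast_2d(np.asarray(true_counts, dtype=np.float64))
    d = np.atleast_2d(np.asarray(dosages, dtype=np.float64))
    if t.shape != d.shape:
        raise ValueError(f"shape mismatch: true {t.shape} vs dosages {d.shape}")
    if t.shape[1] < 2:
        raise ValueError("need at least two samples per site")
    tc = t - t.mean(axis=1, keepdims=True)
    dc = d - d.mean(axis=1, keepdims=True)
    var_t = (tc * tc).sum(axis=1)
    var_d = (dc * dc).sum(axis=1)
    cov = (tc * dc).sum(axis=1)
    defined = (var_t > 0) & (var_d > 0)
    r2 = np.full(t.shape[0], np.nan)
    r2[defined] = (cov[defined] ** 2) / (var_t[defined] * var_d[defined])
    # Guard against floating-point spill just above 1 for perfect dosages.
    np.clip(r2, 0.0, 1.0, out=r2)
    if np.asarray(true_counts).ndim == 1:
        return r2[0]
    return r2


def bin_by_maf(
    r2: np.ndarray,
    mafs: np.ndarray,
    bin_edges=DEFAULT_MAF_BINS,
) -> pd.DataFrame:
    """Mean R² of defined-R² sites within half-open MAF bins
    [e_i, e_{i+1}); the first bin is (0, e_1).

    Empty bins are kept with ``n_sites == 0`` and NaN mean so plots can
    skip them explicitly.
    """
    r2 = np.asarray(r2, dtype=np.float64)
    mafs = np.asarray(mafs, dtype=np.float64)
    edges = np.asarray(bin_edges, dtype=np.float64)
    if (np.diff(edges) <= 0).any():
        raise ValueError("bin edges must be strictly increasing")
    if ((mafs <= 0) | (mafs > 0.5)).any():
        raise ValueError("MAF values must lie in (0, 0.5]")
    full_edges = np.concatenate([[0.0], edges])
    # digitize with right-open bins; maf == 0.5 falls in the last bin
    which = np.clip(np.digitize(mafs, full_edges[1:-1], right=False), 0, len(full_edges) - 2)
    defined = ~np.isnan(r2)
    rows = []
    for b in range(len(full_edges) - 1):
        in_bin = defined & (which == b)
        rows.append(
            {
                "maf_low": full_edges[b],
                "maf_high": full_edges[b + 1],
                "n_sites": int(in_bin.sum()),
                "mean_r2": float(r2[in_bin].mean()) if in_bin.any() else np.nan,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class EvalTable:
    """Per-site R² joined to MAF, with a MAF-binned summary."""

    sites: pd.DataFrame  # columns: site_idx, pos, maf, r2, n_samples
    binned: pd.DataFrame = field(default=None)  # type: ignore[assignment]
    bin_edges: tuple[float, ...] = DEFAULT_MAF_BINS

    @property
    def n_undefined(self) -> int:
        return int(self.sites["r2"].isna().sum())

    def mean_r2(self, maf_min: float = 0.0) -> float:
        """Mean of defined per-site R² over sites with MAF >= maf_min."""
        sel = self.sites[(self.sites["maf"] >= maf_min) & self.sites["r2"].notna()]
        return float(sel["r2"].mean())


def build_eval_table(
    site_idx: np.ndarray,
    positions: np.ndarray,
    mafs: np.ndarray,
    true_counts: np.ndarray,
    dosages: np.ndarray,
    bin_edges=DEFAULT_MAF_BINS,
) -> EvalTable:
    """Assemble the full per-site + binned accuracy table for one run."""
    r2 = r2_per_site(true_counts, dosages)
    sites = pd.DataFrame(
        {
            "site_idx": np.asarray(site_idx, dtype=np.int64),
            "pos": np.asarray(positions, dtype=np.int64),
            "maf": np.asarray(mafs, dtype=np.float64),
            "r2": r2,
            "n_samples": np.asarray(true_counts).shape[1],
        }
    )
    binnable = sites["maf"] > 0
    binned = bin_by_maf(
        sites.loc[binnable, "r2"].to_numpy(),
        sites.loc[binnable, "maf"].to_numpy(),
        bin_edges,
    )
    return EvalTable(sites=sites, binned=binned, bin_edges=tuple(bin_edges))


def plot_r2_vs_maf(tables: dict[tuple[str, float], EvalTable], path) -> None:
    """Binned mean R² against MAF, one curve per (strategy, rate)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4.5))
    for (strategy, rate), table in sorted(tables.items()):
        binned = table.binned[table.binned["n_sites"] > 0]
        centers = np.sqrt(binned["maf_low"].clip(lower=1e-3) * binned["maf_high"])
        ax.plot(centers, binned["mean_r2"], marker="o",
                label=f"{strategy}, rate {rate:g}")
    ax.set_xscale("log")
    ax.set_xlabel("minor allele frequency")
    ax.set_ylabel("mean $R^2$")
    ax.set_ylim(0, 1)
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def compare_strategies(tables: dict[tuple[str, float], EvalTable]) -> pd.DataFrame:
    """Tidy long-format comparison across (strategy, missing-rate)
    conditions sharing one site set: one row per site per condition."""
    reference_sites = None
    frames = []
    for (strategy, rate), table in tables.items():
        idx = tuple(table.sites["site_idx"])
        if reference_sites is None:
            reference_sites = idx
        elif idx != reference_sites:
            raise ValueError(
                f"condition ({strategy}, {rate}) evaluates a different site set"
            )
        frame = table.sites[["site_idx", "maf", "r2"]].copy()
        frame["strategy"] = strategy
        frame["rate"] = rate
        frames.append(frame)
    return pd.concat(frames, ignore_index=True)
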