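"""Weir-Cockerham Fst, windowed diversity-ratio scans and outlier calling.

Per-site variance components follow the Weir & Cockerham (1984) moment
estimator for two populations, computed from diploid allele frequencies
and observed heterozygosity.  Window Fst is the weighted ratio-of-sums
``sum(a) / sum(a + b + c)`` (the VCFtools "weighted Fst"), optionally
switchable to a mean of per-site ratios.  Window Fst values are
Z-transformed, the diversity contrast is ``log2(pi_control / pi_focal)``,
and windows at or above the empirical 95th percentile of both statistics
simultaneously are the joint sweep candidates; outlier windows are merged
into maximal regions and mapped to overlapping genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .diversity import WindowScheme, iter_windows, windowed_pi
from .errors import ComputationError, InputError
from .sim import GeneModel

logger = logging.getLogger(__name__)

__all__ = [
    "CandidateRegion",
    "per_site_fst_components",
    "windowed_fst",
    "z_transform",
    "log2_pi_ratio",
    "top_cutoff",
    "joint_outliers",
    "merge_and_map",
    "intersect_gene_sets",
    "fst_pi_scan",
]


@dataclass(frozen=True)
class CandidateRegion:
    """Maximal union of overlapping/book-ended outlier windows."""

    chrom: str
    start: int  # 0-based half-open
    end: int
    n_windows: int
    genes: tuple[str, ...]


def per_site_fst_components(table, populations: Optional[Sequence[str]] = None):
    """Weir-Cockerham per-site numerator ``a`` and denominator ``a+b+c``.

    Requires exactly two populations; sites where either population has
    fewer than two non-missing allele copies (or where the pooled sample
    is a single diploid per population) get NaN components.
    """
    if populations is None:
        populations = list(pd.unique(table.populations))
    if len(populations) != 2:
        raise InputError("exactly two populations required for Fst")
    r = 2.0
    n_i, p_i, h_i = [], [], []
    for pop in populations:
        idx = table.sample_indices(pop)
        g = table.gt[:, idx, :]
        ok = (g >= 0).all(axis=2)
        n = ok.sum(axis=1).astype(np.float64)  # diploids with data
        alt = np.where(ok, (g == 1).sum(axis=2), 0).sum(axis=1)
        het = np.where(ok, g[:, :, 0] != g[:, :, 1], False).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = alt / (2.0 * np.maximum(n, 1e-300))
            h = het / np.maximum(n, 1e-300)
        n_i.append(n)
        p_i.append(p)
        h_i.append(h)
    n1, n2 = n_i
    p1, p2 = p_i
    h1, h2 = h_i

    nbar = (n1 + n2) / r
    usable = (n1 >= 1) & (n2 >= 1) & (nbar > 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        a = (nbar / nc) * (
            s2
            - (pbar * (1 - pbar) - s2 * (r - 1) / r - hbar / 4.0) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - s2 * (r - 1) / r - hbar * (2 * nbar - 1) / (4 * nbar)
        )
        c = hbar / 2.0
    num = np.where(usable, a, np.nan)
    den = np.where(usable, a + b + c, np.nan)
    return num, den


def windowed_fst(
    positions: np.ndarray,
    numerator: np.ndarray,
    denominator: np.ndarray,
    scheme: WindowScheme,
    length: int,
    mode: str = "ratio_of_sums",
) -> pd.DataFrame:
    """Window Fst from per-site components: start, end, n_snps, fst.

    ratio_of_sums: sum(a)/sum(a+b+c) over usable in-window sites;
    mean_of_ratios averages per-site a/(a+b+c).  Windows without usable
    sites get NaN (excluded from downstream ranking); negative values are
    retained as computed.
    """
    if mode not in ("ratio_of_sums", "mean_of_ratios"):
        raise InputError("mode must be ratio_of_sums or mean_of_ratios")
    pos0 = np.asarray(positions) - 1
    usable = np.isfinite(numerator) & np.isfinite(denominator)
    rows = []
    for start, end in iter_windows(length, scheme):
        lo = np.searchsorted(pos0, start, side="left")
        hi = np.searchsorted(pos0, end, side="left")
        sel = slice(lo, hi)
        u = usable[sel]
        n_use = int(u.sum())
        if n_use == 0:
            rows.append((start, end, 0, np.nan))
            continue
        num = numerator[sel][u]
        den = denominator[sel][u]
        if mode == "ratio_of_sums":
            d = den.sum()
            fst = num.sum() / d if d != 0 else np.nan
        else:
            with np.errstate(invalid="ignore", divide="ignore"):
                ratios = np.where(den != 0, num / den, np.nan)
            fst = np.nanmean(ratios) if np.isfinite(ratios).any() else np.nan
        rows.append((start, end, n_use, float(fst)))
    return pd.DataFrame(rows, columns=["start", "end", "n_snps", "fst"])


def z_transform(values: np.ndarray) -> np.ndarray:
    """(x - mean) / sd with population (1/N) sd over finite entries.

    NaN entries stay NaN; fewer than two finite values or zero spread is
    a computation error.
    """
    x = np.asarray(values, dtype=np.float64)
    finite = np.isfinite(x)
    if finite.sum() < 2:
        raise ComputationError("z-transform needs >= 2 finite values")
    mu = x[finite].mean()
    sd = x[finite].std(ddof=0)
    if sd == 0:
        raise ComputationError("z-transform undefined for zero spread")
    out = np.full_like(x, np.nan)
    out[finite] = (x[finite] - mu) / sd
    return out


def log2_pi_ratio(pi_control: np.ndarray, pi_focal: np.ndarray) -> np.ndarray:
    """log2(pi_control / pi_focal) per window; NaN where either pi is 0."""
    c = np.asarray(pi_control, dtype=np.float64)
    f = np.asarray(pi_focal, dtype=np.float64)
    if c.shape != f.shape:
        raise InputError("window sets misaligned between populations")
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.log2(c / f)
    out[(c <= 0) | (f <= 0)] = np.nan
    return out


def top_cutoff(values: np.ndarray, quantile: float = 0.95) -> float:
    """Empirical top-tail cutoff: the ascending order statistic at index
    floor(quantile * N); flagging values >= cutoff captures exactly the
    top (1-quantile) fraction when quantile*N is integral and values are
    distinct, and includes ties otherwise."""
    x = np.asarray(values, dtype=np.float64)
    x = np.sort(x[np.isfinite(x)])
    if x.size == 0:
        raise ComputationError("no finite values to rank")
    idx = min(int(np.floor(quantile * x.size)), x.size - 1)
    return float(x[idx])


def joint_outliers(
    windows: pd.DataFrame, quantile: float = 0.95
) -> tuple[pd.DataFrame, float, float]:
    """Flag windows in the top tail of both Z(Fst) and log2 pi-ratio.

    Expects columns ``z_fst`` and ``log2_ratio``; adds boolean columns
    fst_top, ratio_top and joint and returns the two derived cutoffs.
    Windows with NaN in a statistic are excluded from that ranking.
    """
    df = windows.copy()
    usable = np.isfinite(df["z_fst"]) & np.isfinite(df["log2_ratio"])
    if usable.sum() < 20:
        logger.warning("joint_outliers: only %d usable windows", int(usable.sum()))
    z_cut = top_cutoff(df["z_fst"].to_numpy(), quantile)
    r_cut = top_cutoff(df["log2_ratio"].to_numpy(), quantile)
    df["fst_top"] = df["z_fst"].to_numpy() >= z_cut
    df["ratio_top"] = df["log2_ratio"].to_numpy() >= r_cut
    df["joint"] = df["fst_top"] & df["ratio_top"]
    return df, z_cut, r_cut


def merge_and_map(
    outlier_windows: pd.DataFrame,
    genes: Sequence[GeneModel],
    chrom: str = "chr1",
) -> list[CandidateRegion]:
    """Merge overlapping or book-ended outlier windows into maximal
    regions and attach genes overlapping each region by >= 1 bp."""
    if len(outlier_windows) == 0:
        return []
    wins = outlier_windows.sort_values(["start", "end"])[["start", "end"]].to_numpy()
    merged: list[list[int]] = []
    counts: list[int] = []
    for s, e in wins:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], int(e))
            counts[-1] += 1
        else:
            merged.append([int(s), int(e)])
            counts.append(1)
    regions = []
    for (s, e), n in zip(merged, counts):
        hit = tuple(
            sorted(
                g.gene_id
                for g in genes
                if g.chrom == chrom and (g.start - 1) < e and g.end > s
            )
        )
        regions.append(CandidateRegion(chrom, s, e, n, hit))
    return regions


def intersect_gene_sets(
    set_a: Sequence[str], set_b: Sequence[str]
) -> tuple[set[str], set[str], set[str]]:
    """Three-way partition (a_only, shared, b_only)."""
    a, b = set(set_a), set(set_b)
    return a - b, a & b, b - a


def fst_pi_scan(
    table,
    length: int,
    focal: str = "focal",
    control: str = "control",
    scheme: WindowScheme = WindowScheme(40_000, 20_000),
    quantile: float = 0.95,
    fst_mode: str = "ratio_of_sums",
) -> tuple[pd.DataFrame, float, float]:
    """Full Fst - pi-ratio window scan with joint outlier flags.

    Returns the window table (start, end, n_snps, fst, z_fst, pi_focal,
    pi_control, log2_ratio, fst_top, ratio_top, joint) and the derived
    Z(Fst) and log2-ratio cutoffs.
    """
    num, den = per_site_fst_components(table, [focal, control])
    fst_df = windowed_fst(table.pos, num, den, scheme, length, mode=fst_mode)
    pi_f = windowed_pi(table, focal, scheme, length)
    pi_c = windowed_pi(table, control, scheme, length)
    df = fst_df.copy()
    df["pi_focal"] = pi_f["pi"].to_numpy()
    df["pi_control"] = pi_c["pi"].to_numpy()
    df["log2_ratio"] = log2_pi_ratio(df["pi_control"].to_numpy(),
                                     df["pi_focal"].to_numpy())
    df["z_fst"] = z_transform(df["fst"].to_numpy())
    df, z_cut, r_cut = joint_outliers(df, quantile)
    return df, z_cut, r_cut
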