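"""Windowed nucleotide diversity, pairwise r-squared and LD decay.

Nucleotide diversity uses the unbiased per-site estimator
``pi_site = n/(n-1) * 2 p (1-p)`` over non-missing allele copies, summed
over sites in a window and divided by the window's bp width — invariant
sites are assumed monomorphic, so the denominator is physical width, the
conventional windowed-pi definition.  LD is the squared correlation of
allele frequencies between phased haplotypes,
``r2 = (p_AB - p_A p_B)^2 / (p_A(1-p_A) p_B(1-p_B))``, averaged within
distance bins to form a decay curve whose half-maximum crossing gives
the decay distance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterator, Optional

import numpy as np
import pandas as pd

from .errors import InputError

logger = logging.getLogger(__name__)

__all__ = [
    "WindowScheme",
    "LDConfig",
    "LDCurve",
    "iter_windows",
    "windowed_pi",
    "per_site_pi",
    "pairwise_r2",
    "ld_decay",
    "half_decay_distance",
]


@dataclass(frozen=True)
class WindowScheme:
    """Sliding windows tiling from position 1 (0-based starts 0, step, ...)."""

    width: int
    step: int

    def __post_init__(self) -> None:
        if self.width <= 0 or not 0 < self.step <= self.width:
            raise InputError("need width > 0 and 0 < step <= width")


def iter_windows(length: int, scheme: WindowScheme) -> Iterator[tuple[int, int]]:
    """0-based half-open (start, end) windows; terminal windows truncate."""
    for start in range(0, length, scheme.step):
        yield start, min(start + scheme.width, length)


@dataclass(frozen=True)
class LDConfig:
    max_dist: int = 500_000
    min_maf: float = 0.05
    max_miss: float = 0.1
    bin_width: int = 1_000

    def __post_init__(self) -> None:
        if min(self.max_dist, self.bin_width) <= 0:
            raise InputError("max_dist and bin_width must be positive")
        if not 0 <= self.min_maf <= 0.5:
            raise InputError("min_maf must lie in [0, 0.5]")
        if not 0 <= self.max_miss <= 1:
            raise InputError("max_miss must lie in [0, 1]")


@dataclass
class LDCurve:
    """Binned LD decay: mean r2 and pair count per distance bin."""

    bin_mid: np.ndarray
    mean_r2: np.ndarray
    n_pairs: np.ndarray

    def populated(self) -> "LDCurve":
        m = self.n_pairs > 0
        return LDCurve(self.bin_mid[m], self.mean_r2[m], self.n_pairs[m])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"bin_mid_bp": self.bin_mid, "mean_r2": self.mean_r2,
             "n_pairs": self.n_pairs}
        )


def per_site_pi(table, population: Optional[str] = None) -> np.ndarray:
    """Unbiased per-site heterozygosity 2p(1-p)·n/(n-1); 0 where n < 2."""
    ac, an = table.allele_stats(population)
    out = np.zeros(len(ac), dtype=np.float64)
    ok = an >= 2
    p = ac[ok] / an[ok]
    out[ok] = 2.0 * p * (1.0 - p) * an[ok] / (an[ok] - 1.0)
    return out


def windowed_pi(table, population: str, scheme: WindowScheme, length: int) -> pd.DataFrame:
    """Per-window pi (per bp): columns start, end, n_snps, pi.

    A site contributes to every window containing it; windows without
    SNPs report pi = 0 with n_snps = 0.
    """
    site_pi = per_site_pi(table, population)
    pos0 = table.pos - 1
    rows = []
    for start, end in iter_windows(length, scheme):
        lo = np.searchsorted(pos0, start, side="left")
        hi = np.searchsorted(pos0, end, side="left")
        width = end - start
        rows.append((start, end, hi - lo, float(site_pi[lo:hi].sum()) / width))
    return pd.DataFrame(rows, columns=["start", "end", "n_snps", "pi"])


def pairwise_r2(alleles_i: np.ndarray, alleles_j: np.ndarray) -> float:
    """r2 between two sites on phased haplotypes; NaN when a site is
    monomorphic after pairwise missing-data exclusion."""
    a = np.asarray(alleles_i)
    b = np.asarray(alleles_j)
    if a.shape != b.shape:
        raise InputError("allele vectors differ in length")
    ok = (a >= 0) & (b >= 0)
    a, b = a[ok].astype(float), b[ok].astype(float)
    if a.size == 0:
        return float("nan")
    pa, pb = a.mean(), b.mean()
    if pa in (0.0, 1.0) or pb in (0.0, 1.0):
        return float("nan")
    pab = (a * b).mean()
    d = pab - pa * pb
    return float(d * d / (pa * (1 - pa) * pb * (1 - pb)))


def ld_decay(
    haplotypes: np.ndarray,
    positions: np.ndarray,
    config: LDConfig = LDConfig(),
    n_resamples: int = 0,
    subsample_size: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> LDCurve:
    """Binned LD-decay curve over all within-range site pairs.

    Sites first pass MAF and missingness screens; every ordered pair
    within ``max_dist`` then contributes its r2 to the distance bin of the
    pair.  With ``n_resamples`` > 0 the curve is instead the average over
    that many random haplotype subsets of ``subsample_size`` chromosomes.
    """
    H = np.asarray(haplotypes, dtype=np.int8)
    positions = np.asarray(positions)
    if H.ndim != 2 or H.shape[1] != positions.size:
        raise InputError("haplotype matrix does not match positions")

    if n_resamples > 0:
        if rng is None:
            rng = np.random.default_rng(0)
        size = subsample_size or max(2, H.shape[0] // 2)
        curves = [
            ld_decay(H[rng.choice(H.shape[0], size=size, replace=False)],
                     positions, config)
            for _ in range(n_resamples)
        ]
        mean_r2 = np.nanmean([c.mean_r2 for c in curves], axis=0)
        n_pairs = np.mean([c.n_pairs for c in curves], axis=0)
        return LDCurve(curves[0].bin_mid, mean_r2, n_pairs)

    ok = H >= 0
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(ok, H, 0).sum(axis=0) / np.maximum(ok.sum(axis=0), 1)
    maf = np.minimum(p, 1 - p)
    miss = 1.0 - ok.mean(axis=0)
    screened = (maf >= config.min_maf) & (miss <= config.max_miss)
    H = H[:, screened]
    positions = positions[screened]

    edges = np.arange(0, config.max_dist + config.bin_width, config.bin_width)
    mids = edges[:-1] + config.bin_width / 2.0
    sums = np.zeros(len(mids))
    counts = np.zeros(len(mids), dtype=np.int64)

    n_sites = positions.size
    if n_sites < 2:
        logger.warning("ld_decay: no eligible site pairs")
        return LDCurve(mids, np.full(len(mids), np.nan), counts)

    M = (H >= 0)
    Hf = np.where(M, H, 0).astype(np.float64)
    Mf = M.astype(np.float64)
    for i in range(n_sites - 1):
        hi = np.searchsorted(positions, positions[i] + config.max_dist, side="right")
        if hi <= i + 1:
            continue
        J = slice(i + 1, hi)
        n_eff = Mf[:, i] @ Mf[:, J]
        with np.errstate(invalid="ignore", divide="ignore"):
            pa = (Hf[:, i] * Mf[:, J].T).sum(axis=1) / n_eff
            pb = (Hf[:, J].T * Mf[:, i]).sum(axis=1) / n_eff
            pab = (Hf[:, i] * Hf[:, J].T).sum(axis=1) / n_eff
            denom = pa * (1 - pa) * pb * (1 - pb)
            r2 = (pab - pa * pb) ** 2 / denom
        valid = (n_eff > 0) & (denom > 0) & np.isfinite(r2)
        if not valid.any():
            continue
        dist = positions[i + 1 : hi] - positions[i]
        bins = np.minimum(dist // config.bin_width, len(mids) - 1)
        np.add.at(sums, bins[valid], r2[valid])
        np.add.at(counts, bins[valid], 1)

    with np.errstate(invalid="ignore"):
        mean_r2 = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    if counts.sum() == 0:
        logger.warning("ld_decay: no eligible site pairs")
    return LDCurve(mids, mean_r2, counts)


def half_decay_distance(curve: LDCurve) -> Optional[float]:
    """Smallest bin midpoint where mean r2 <= max/2; None if never reached."""
    pop = curve.populated()
    if pop.bin_mid.size == 0:
        raise InputError("empty LD curve")
    target = np.nanmax(pop.mean_r2) / 2.0
    for mid, r2 in zip(pop.bin_mid, pop.mean_r2):
        if r2 <= target:
            return float(mid)
    return None
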