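"""Extended haplotype homozygosity and the cross-population XP-EHH scan.

EHH at extension x from a core site is the probability that two randomly
drawn chromosomes are identical over all sites strictly beyond the core
through x: ``EHH = sum_g C(c_g, 2) / C(n, 2)`` over identity groups of
sizes c_g.  The core's own alleles do not partition the sample, so EHH
starts at 1 and is non-increasing outward.  iHH is the trapezoidal
integral of EHH over genetic distance (cM), summed over both directions,
each truncated at the first site where EHH drops below a cutoff (default
0.05); the stopping site is determined on the combined two-population
panel so that both populations are integrated over identical support.
XP-EHH is ``ln(iHH_focal / iHH_control)``, standardized genome-wide
(unbinned), and window scores are the maximum normalized score among
in-window cores.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .diversity import WindowScheme, iter_windows
from .errors import ComputationError, InputError
from .sweep import merge_and_map, top_cutoff, z_transform
from .sim import GeneModel

logger = logging.getLogger(__name__)

__all__ = [
    "GeneticMap",
    "EHHCurve",
    "ehh_curve",
    "ihh",
    "IHHResult",
    "xpehh_raw",
    "xpehh_scan",
    "normalize_xpehh",
    "xpehh_windows",
]


@dataclass
class GeneticMap:
    """Piecewise-linear bp -> cM mapping (non-decreasing)."""

    positions: np.ndarray
    cm: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.float64)
        self.cm = np.asarray(self.cm, dtype=np.float64)
        if self.positions.size < 2:
            raise InputError("genetic map needs >= 2 anchor points")
        if np.any(np.diff(self.positions) <= 0) or np.any(np.diff(self.cm) < 0):
            raise InputError("genetic map must be non-decreasing in bp and cM")

    @classmethod
    def constant(cls, length: int, cm_per_mb: float = 2.53) -> "GeneticMap":
        return cls(np.array([1.0, float(length)]),
                   np.array([0.0, cm_per_mb * (length - 1) / 1e6]))

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GeneticMap":
        df = pd.read_csv(path, sep="\t")
        required = {"bp", "cm"}
        if not required.issubset(df.columns):
            raise InputError("genetic map TSV needs columns bp and cm")
        return cls(df["bp"].to_numpy(), df["cm"].to_numpy())

    def cm_at(self, bp: np.ndarray) -> np.ndarray:
        bp = np.asarray(bp, dtype=np.float64)
        if bp.size and (bp.min() < self.positions[0] or bp.max() > self.positions[-1]):
            raise InputError("genetic map does not cover all sites")
        return np.interp(bp, self.positions, self.cm)


@dataclass
class EHHCurve:
    """EHH values outward from a core site in one direction.

    ``site_index[0]`` is the core itself with EHH exactly 1; distances
    are non-negative offsets from the core in bp and (if a map was
    supplied) cM.
    """

    core: int
    direction: str
    site_index: np.ndarray
    dist_bp: np.ndarray
    dist_cm: Optional[np.ndarray]
    ehh: np.ndarray


def _ehh_values(
    haps: np.ndarray, core: int, order: np.ndarray,
    stop_below: Optional[float] = None,
) -> np.ndarray:
    """EHH at each successive site of ``order``; a missing allele is
    treated as a third allelic state for identity.  With ``stop_below``
    the walk ends just after the first value under that threshold (the
    crossing value is included), since EHH can only decrease further.
    """
    import bisect

    n = haps.shape[0]
    K = order.size
    if K == 0:
        return np.empty(0, dtype=np.float64)
    denom = n * (n - 1) / 2.0
    # Sort extension prefixes as byte strings; two haplotypes are in the
    # same identity group at step k iff, in sorted order, no adjacent pair
    # between them first differs at a column <= k.
    sub = np.ascontiguousarray(haps[:, order])
    keys = sub.view(np.dtype((np.void, K))).ravel()
    srt = sub[np.argsort(keys, kind="stable")]
    neq = srt[:-1] != srt[1:]
    has_diff = neq.any(axis=1)
    first_diff = np.where(has_diff, neq.argmax(axis=1), K)

    out = np.empty(K, dtype=np.float64)
    bounds = [0, n]  # run boundaries over sorted rows
    pairs = denom
    prev = 0
    for b in np.argsort(first_diff, kind="stable"):
        f = int(first_diff[b])
        if f >= K:
            break
        if f > prev:
            out[prev:f] = pairs / denom
            prev = f
        p = b + 1  # split between sorted rows b and b+1
        i = bisect.bisect_left(bounds, p)
        if bounds[i] != p:
            lo, hi = bounds[i - 1], bounds[i]
            pairs -= (hi - lo) * (hi - lo - 1) / 2.0
            pairs += (p - lo) * (p - lo - 1) / 2.0 + (hi - p) * (hi - p - 1) / 2.0
            bounds.insert(i, p)
    out[prev:K] = pairs / denom
    if stop_below is not None:
        below = np.nonzero((out < stop_below) | (out == 0.0))[0]
        if below.size:
            return out[: below[0] + 1]
    return out


def ehh_curve(
    haplotypes: np.ndarray,
    positions: np.ndarray,
    core: int,
    direction: str,
    gmap: Optional[GeneticMap] = None,
) -> EHHCurve:
    """EHH decay curve from ``core`` towards 'left' or 'right'."""
    H = np.asarray(haplotypes, dtype=np.int8)
    positions = np.asarray(positions)
    if H.ndim != 2 or H.shape[1] != positions.size:
        raise InputError("haplotype matrix does not match positions")
    if H.shape[0] < 2:
        raise InputError("need >= 2 haplotypes")
    if not 0 <= core < positions.size:
        raise InputError("core index out of range")
    alleles = H[:, core]
    seen = np.unique(alleles[alleles >= 0])
    if seen.size < 2:
        raise InputError("core site must be polymorphic")
    if direction == "right":
        order = np.arange(core + 1, positions.size)
    elif direction == "left":
        order = np.arange(core - 1, -1, -1)
    else:
        raise InputError("direction must be 'left' or 'right'")
    ehh = np.concatenate([[1.0], _ehh_values(H, core, order)])
    idx = np.concatenate([[core], order])
    dist_bp = np.abs(positions[idx] - positions[core]).astype(np.float64)
    dist_cm = None
    if gmap is not None:
        cm = gmap.cm_at(positions[idx])
        dist_cm = np.abs(cm - cm[0])
    return EHHCurve(core, direction, idx, dist_bp, dist_cm, ehh)


@dataclass
class IHHResult:
    total: float
    left: float
    right: float
    edge_truncated: bool
    undefined: bool = False


def _directional_ihh(
    ehh: np.ndarray, dist_cm: np.ndarray, cutoff: float,
    stop_at: Optional[int] = None,
) -> tuple[float, bool]:
    """Trapezoidal integral out to the first EHH < cutoff (inclusive of
    that trapezoid) or to ``stop_at``; flags hitting the chromosome edge."""
    if stop_at is None:
        below = np.nonzero(ehh < cutoff)[0]
        stop = int(below[0]) if below.size else len(ehh) - 1
        edge = below.size == 0
    else:
        stop = min(stop_at, len(ehh) - 1)
        edge = stop == len(ehh) - 1 and ehh[stop] >= cutoff
    if stop == 0:
        return 0.0, edge
    return float(np.trapezoid(ehh[: stop + 1], x=dist_cm[: stop + 1])), edge


def ihh(
    haplotypes: np.ndarray,
    positions: np.ndarray,
    core: int,
    gmap: GeneticMap,
    cutoff: float = 0.05,
) -> IHHResult:
    """Integrated EHH over cM, both directions summed.

    Each direction is truncated at the first site where EHH < cutoff;
    reaching a chromosome edge first sets the truncation flag.  A core
    with no integration support on either side is undefined.
    """
    H = np.asarray(haplotypes, dtype=np.int8)
    positions = np.asarray(positions)
    cm_all = gmap.cm_at(positions)
    vals = {}
    edges = {}
    for direction in ("left", "right"):
        if direction == "right":
            order = np.arange(core + 1, positions.size)
        else:
            order = np.arange(core - 1, -1, -1)
        alleles = H[:, core]
        if np.unique(alleles[alleles >= 0]).size < 2:
            raise InputError("core site must be polymorphic")
        ehh = np.concatenate([[1.0], _ehh_values(H, core, order, stop_below=cutoff)])
        idx = np.concatenate([[core], order[: ehh.size - 1]]).astype(np.intp)
        dist_cm = np.abs(cm_all[idx] - cm_all[core])
        vals[direction], edges[direction] = _directional_ihh(ehh, dist_cm, cutoff)
    l_val, l_edge = vals["left"], edges["left"]
    r_val, r_edge = vals["right"], edges["right"]
    total = l_val + r_val
    return IHHResult(
        total=total,
        left=l_val,
        right=r_val,
        edge_truncated=l_edge or r_edge,
        undefined=total == 0.0,
    )


def xpehh_raw(
    focal_haps: np.ndarray,
    control_haps: np.ndarray,
    positions: np.ndarray,
    core: int,
    gmap: GeneticMap,
    cutoff: float = 0.05,
) -> Optional[dict]:
    """Raw XP-EHH at one core: ln(iHH_focal / iHH_control).

    The stopping site in each direction comes from the EHH of the
    combined panel, so both populations integrate over the same support
    and the statistic is exactly antisymmetric under a population swap.
    Returns None (cores skipped) when either iHH is zero/undefined.
    """
    F = np.asarray(focal_haps, dtype=np.int8)
    C = np.asarray(control_haps, dtype=np.int8)
    combined = np.concatenate([F, C], axis=0)
    cm_all = gmap.cm_at(np.asarray(positions))
    pieces = {}
    edge = False
    for direction in ("left", "right"):
        if direction == "right":
            order = np.arange(core + 1, len(positions))
        else:
            order = np.arange(core - 1, -1, -1)
        comb_ehh = _ehh_values(combined, core, order, stop_below=cutoff)
        stop = comb_ehh.size  # index of the crossing site in the full curve
        edge = edge or (stop == order.size and (stop == 0 or comb_ehh[-1] >= cutoff))
        support = order[:stop]
        idx = np.concatenate([[core], support]).astype(np.intp)
        dist_cm = np.abs(cm_all[idx] - cm_all[core])
        for name, H in (("focal", F), ("control", C)):
            ehh_vals = np.concatenate([[1.0], _ehh_values(H, core, support)])
            val, _ = _directional_ihh(ehh_vals, dist_cm, cutoff, stop_at=stop)
            pieces[(name, direction)] = val
    ihh_f = pieces[("focal", "left")] + pieces[("focal", "right")]
    ihh_c = pieces[("control", "left")] + pieces[("control", "right")]
    if ihh_f <= 0 or ihh_c <= 0:
        return None
    return {
        "core": core,
        "pos": int(positions[core]),
        "ihh_focal": ihh_f,
        "ihh_control": ihh_c,
        "raw": float(np.log(ihh_f / ihh_c)),
        "edge_truncated": edge,
    }


def xpehh_scan(
    focal_haps: np.ndarray,
    control_haps: np.ndarray,
    positions: np.ndarray,
    gmap: GeneticMap,
    cutoff: float = 0.05,
    drop_edge_cores: bool = False,
    chrom: str = "chr1",
) -> pd.DataFrame:
    """Raw and normalized XP-EHH at every polymorphic core site.

    Cores whose EHH never reaches the cutoff before a chromosome edge are
    retained with ``edge_truncated`` set (dropped in strict mode), since
    on short sequences dropping them would empty the scan.
    """
    F = np.asarray(focal_haps, dtype=np.int8)
    C = np.asarray(control_haps, dtype=np.int8)
    if F.shape[1] != C.shape[1] or F.shape[1] != len(positions):
        raise InputError("panels and positions misaligned")
    combined = np.concatenate([F, C], axis=0)
    records = []
    n_skipped = 0
    for core in range(len(positions)):
        col = combined[:, core]
        if np.unique(col[col >= 0]).size < 2:
            n_skipped += 1
            continue
        rec = xpehh_raw(F, C, positions, core, gmap, cutoff)
        if rec is None or (drop_edge_cores and rec["edge_truncated"]):
            n_skipped += 1
            continue
        rec["chrom"] = chrom
        records.append(rec)
    if n_skipped:
        logger.info("xpehh_scan: skipped %d cores", n_skipped)
    df = pd.DataFrame(
        records,
        columns=["chrom", "core", "pos", "ihh_focal", "ihh_control", "raw",
                 "edge_truncated"],
    )
    if len(df) >= 2 and np.std(df["raw"]) > 0:
        df["norm"] = normalize_xpehh(df["raw"].to_numpy())
    else:
        df["norm"] = np.nan
    return df


def normalize_xpehh(raw_scores: np.ndarray) -> np.ndarray:
    """Genome-wide standardization of raw XP-EHH (population sd)."""
    return z_transform(raw_scores)


def xpehh_windows(
    records: pd.DataFrame,
    length: int,
    scheme: WindowScheme = WindowScheme(10_000, 5_000),
    quantile: float = 0.95,
    genes: Sequence[GeneModel] = (),
    chrom: str = "chr1",
):
    """Windowed outlier calling on normalized XP-EHH.

    Window score = max normalized score among in-window cores (peak
    preserving); windows without cores are excluded; outliers are windows
    at or above the empirical top-tail cutoff.  Returns (window table,
    cutoff, candidate regions with genes).
    """
    if "norm" not in records or not np.isfinite(records["norm"]).any():
        raise ComputationError("no normalized XP-EHH scores available")
    pos0 = records["pos"].to_numpy() - 1
    norm = records["norm"].to_numpy()
    order = np.argsort(pos0)
    pos0, norm = pos0[order], norm[order]
    rows = []
    for start, end in iter_windows(length, scheme):
        lo = np.searchsorted(pos0, start, side="left")
        hi = np.searchsorted(pos0, end, side="left")
        if hi <= lo:
            continue
        vals = norm[lo:hi]
        if not np.isfinite(vals).any():
            continue
        rows.append((start, end, hi - lo, float(np.nanmax(vals))))
    win = pd.DataFrame(rows, columns=["start", "end", "n_cores", "score"])
    if len(win) == 0:
        raise ComputationError("no windows contain XP-EHH cores")
    cutoff_val = top_cutoff(win["score"].to_numpy(), quantile)
    win["outlier"] = win["score"] >= cutoff_val
    regions = merge_and_map(win[win["outlier"]], genes, chrom=chrom)
    return win, cutoff_val, regions
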