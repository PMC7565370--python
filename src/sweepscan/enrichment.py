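"""Hypergeometric over-representation test for candidate gene sets.

For a term annotating K of N background genes, the p-value is the
upper-tail probability P(X >= k) of drawing at least the observed k
term genes in a candidate set of size n, under sampling without
replacement.  The default significance call uses raw p < 0.05 (no
multiple-testing correction); Bonferroni over the tested terms is
available.  Gene-length bias correction is out of scope.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .errors import InputError

logger = logging.getLogger(__name__)

__all__ = ["hypergeom_upper", "enrich", "read_term_map"]


def hypergeom_upper(k: int, n: int, K: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N population, K successes, n draws)."""
    if not (0 <= k <= n <= N) or not (0 <= K <= N):
        raise InputError("hypergeometric bounds violated")
    if k > K:
        raise InputError("cannot draw more term genes than the term has")
    return float(hypergeom.sf(k - 1, N, K, n))


def read_term_map(path: str | Path) -> dict[str, list[str]]:
    df = pd.read_csv(path, sep="\t", header=None, names=["term", "gene"],
                     dtype=str, comment="#")
    out: dict[str, list[str]] = {}
    for term, gene in zip(df["term"], df["gene"]):
        out.setdefault(term, []).append(gene)
    return out


def enrich(
    candidates: Iterable[str],
    background: Iterable[str],
    term_map: Mapping[str, Sequence[str]],
    alpha: float = 0.05,
    correction: str = "none",
) -> pd.DataFrame:
    """One-sided over-representation test per term.

    Results (term, k, n, K, N, p_raw, p_bonferroni, significant) are
    sorted by raw p-value and include every term with at least one
    candidate gene; genes outside the background are logged and dropped.
    """
    if correction not in ("none", "bonferroni"):
        raise InputError("correction must be 'none' or 'bonferroni'")
    bg = set(background)
    if not bg:
        raise InputError("empty background gene set")
    cand = set(candidates)
    stray = cand - bg
    if stray:
        logger.warning("enrich: dropping %d candidates outside background", len(stray))
        cand &= bg
    N, n = len(bg), len(cand)
    rows = []
    for term in sorted(term_map):
        genes = set(term_map[term])
        stray = genes - bg
        if stray:
            logger.warning(
                "enrich: term %s has %d genes outside background", term, len(stray)
            )
            genes &= bg
        K = len(genes)
        k = len(genes & cand)
        if k == 0:
            continue
        rows.append((term, k, n, K, N, hypergeom_upper(k, n, K, N)))
    df = pd.DataFrame(rows, columns=["term", "k", "n", "K", "N", "p_raw"])
    n_tested = len(df)
    df["p_bonferroni"] = np.minimum(1.0, df["p_raw"] * n_tested)
    p = df["p_raw"] if correction == "none" else df["p_bonferroni"]
    df["significant"] = p < alpha
    return df.sort_values(["p_raw", "term"], kind="stable").reset_index(drop=True)
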