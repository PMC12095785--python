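"""Gene-set over-representation testing (hypergeometric) with BH correction.

A generic replacement for web-service annotation tools: given a hit list (e.g.
genes surviving FIQT at |z| > 1.96) and a named collection of gene sets (e.g.
tissue-type annotation sets in GMT format) over a background universe, compute
the one-sided hypergeometric tail per set, fold enrichment, and multiplicity-
adjusted q-values. An optional EASE-style correction (overlap − 1) is exposed
for compatibility with DAVID-like scores.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


def bh_adjust(p: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values."""
    arr = np.asarray(p, dtype=float)
    if arr.size == 0:
        return arr
    if np.any((arr < 0) | (arr > 1)) or not np.isfinite(arr).all():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(arr, method="fdr_bh")[1]


def enrich(hits: Iterable[str], collection: Mapping[str, Sequence[str]],
           background: Iterable[str], ease: bool = False,
           correction: str = "fdr_bh") -> pd.DataFrame:
    """Over-representation of ``hits`` in each gene set of ``collection``.

    Per set: one-sided hypergeometric tail P(overlap >= observed) drawing
    |hits| genes from the background; fold enrichment
    (overlap/|hits|) / (|set ∩ background|/|background|). ``ease`` subtracts
    one hit from the overlap before the tail (conservative DAVID-style score).
    ``correction`` is one of "fdr_bh", "bonferroni", "none".

    Returns a DataFrame sorted by p with columns set, overlap, set_size,
    n_hits, background_size, fold, p, q.
    """
    bg = set(map(str, background))
    hit_set = set(map(str, hits))
    stray = sorted(hit_set - bg)
    if stray:
        raise ValueError(f"hit genes outside the background universe: {stray[:10]}"
                         + (" ..." if len(stray) > 10 else ""))
    N, n_hits = len(bg), len(hit_set)
    rows = []
    for name, genes in collection.items():
        gset = set(map(str, genes)) & bg
        if not gset:
            raise ValueError(f"gene set {name!r} has no genes in the background")
        K = len(gset)
        overlap = len(gset & hit_set)
        eff = max(overlap - 1, 0) if ease else overlap
        # P(X >= eff) with X ~ Hypergeom(N, K, n_hits); overlap 0 -> p = 1
        p = float(stats.hypergeom.sf(eff - 1, N, K, n_hits)) if eff > 0 else 1.0
        expected = K / N * n_hits
        fold = (overlap / n_hits) / (K / N) if n_hits > 0 else 0.0
        rows.append((name, overlap, K, n_hits, N, fold, min(p, 1.0)))
    table = pd.DataFrame(
        rows, columns=["set", "overlap", "set_size", "n_hits", "background_size",
                       "fold", "p"])
    if correction == "fdr_bh":
        table["q"] = bh_adjust(table["p"].to_numpy())
    elif correction == "bonferroni":
        table["q"] = np.minimum(table["p"].to_numpy() * len(table), 1.0)
    elif correction == "none":
        table["q"] = table["p"]
    else:
        raise ValueError(f"unknown correction {correction!r}")
    return table.sort_values("p", kind="stable").reset_index(drop=True)
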