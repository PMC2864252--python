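"""k-mer and category enrichment with hypergeometric tails and BH FDR.

The statistic throughout is presence/absence: a k-mer "hits" a 3'-UTR if it
occurs at least once (overlaps count as presence, not multiplicity), and
the enrichment p-value is the hypergeometric upper tail P[X >= x] of the
foreground hit count given the background hit count — sampling genes
without replacement.  ``scan_kmers`` scores every k-mer of a given length
(all 4^k) and attaches Benjamini-Hochberg q-values; ``category_enrichment``
applies the same machinery to gene-set categories (a local stand-in for
GO-style web services).  Foreground genes are counted inside the background
universe by default, matching a "core set vs all genes" comparison.
"""

from __future__ import annotations

import itertools
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .prep import canonical_dna

__all__ = [
    "kmer_presence",
    "hypergeometric_tail",
    "scan_kmers",
    "category_enrichment",
]

MAX_SCAN_K = 12

_CODE = np.full(256, -1, dtype=np.int64)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i


def _seq_codes(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]


def _unique_kmer_codes(seq: str, k: int) -> np.ndarray:
    """Base-4 codes of the distinct k-mers in one sequence (N windows skipped)."""
    codes = _seq_codes(seq)
    if codes.size < k:
        return np.empty(0, dtype=np.int64)
    windows = sliding_window_view(codes, k)
    powers = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    vals = windows @ powers
    valid = (windows >= 0).all(axis=1)
    return np.unique(vals[valid])


def _as_seq_dict(seqs) -> dict[str, str]:
    if isinstance(seqs, Mapping):
        return {str(k): canonical_dna(v) for k, v in seqs.items()}
    return {str(i): canonical_dna(s) for i, s in enumerate(seqs)}


def kmer_presence(seqs, kmer: str) -> tuple[pd.Series, float]:
    """Per-sequence presence of ``kmer`` and the containing fraction.

    ``seqs`` is a mapping id -> sequence (or an iterable of sequences).
    RNA input (U) is canonicalized to DNA (T) on both sides.
    """
    if not kmer:
        raise ValueError("empty k-mer")
    d = _as_seq_dict(seqs)
    if not d:
        raise ValueError("empty sequence set")
    kmer = canonical_dna(kmer)
    present = pd.Series({name: kmer in s for name, s in d.items()})
    return present, float(present.mean())


def hypergeometric_tail(x: int, n: int, K: int, N: int) -> float:
    """P[X >= x] for X ~ Hypergeometric(N, K, n).

    N genes total, K of them carrying the feature, n drawn (the foreground),
    x of the drawn carrying it.
    """
    if not (0 <= x <= n <= N) or not (0 <= K <= N):
        raise ValueError(f"inconsistent counts x={x}, n={n}, K={K}, N={N}")
    if x > K:
        raise ValueError(f"x={x} exceeds feature count K={K}")
    if x == 0:
        return 1.0
    return float(stats.hypergeom.sf(x - 1, N, K, n))


def _attach_q(df: pd.DataFrame) -> pd.DataFrame:
    if len(df):
        df["q_value"] = multipletests(df["p_value"].to_numpy(), method="fdr_bh")[1]
    else:
        df["q_value"] = np.array([], dtype=float)
    return df


def scan_kmers(
    fg_seqs,
    bg_seqs,
    k: int = 7,
    include_fg_in_bg: bool = True,
) -> pd.DataFrame:
    """Score every k-mer's presence enrichment in foreground vs background.

    ``bg_seqs`` is the gene universe (all UTRs); with ``include_fg_in_bg``
    (default) any foreground sequence absent from it is added, so the
    foreground is a subset of the universe.  Returns a frame with columns
    item/x/n/K/N/fg_fraction/bg_fraction/p_value/q_value, ascending by p
    (ties broken by item for determinism).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > MAX_SCAN_K:
        raise ValueError(f"k={k} exceeds the supported maximum {MAX_SCAN_K}")
    fg = _as_seq_dict(fg_seqs)
    bg = _as_seq_dict(bg_seqs)
    if not fg or not bg:
        raise ValueError("foreground and background must be non-empty")
    if include_fg_in_bg:
        for name, s in fg.items():
            bg.setdefault(name, s)
    n_kmers = 4**k
    K_counts = np.zeros(n_kmers, dtype=np.int64)
    x_counts = np.zeros(n_kmers, dtype=np.int64)
    for name, s in bg.items():
        u = _unique_kmer_codes(s, k)
        K_counts[u] += 1
        if name in fg:
            x_counts[u] += 1
    # foreground sequences outside the universe still count toward x
    for name, s in fg.items():
        if name not in bg:
            x_counts[_unique_kmer_codes(s, k)] += 1

    n = len(fg)
    N = len(bg)
    p = stats.hypergeom.sf(x_counts - 1, N, K_counts, n)
    p[x_counts == 0] = 1.0

    alphabet = "ACGT"
    items = ["".join(t) for t in itertools.product(alphabet, repeat=k)]
    df = pd.DataFrame(
        {
            "item": items,
            "x": x_counts,
            "n": n,
            "K": K_counts,
            "N": N,
            "fg_fraction": x_counts / n,
            "bg_fraction": K_counts / N,
            "p_value": p,
        }
    ).sort_values(["p_value", "item"], kind="mergesort", ignore_index=True)
    return _attach_q(df)


def category_enrichment(
    gene_set: Iterable[str],
    categories: Mapping[str, Iterable[str]],
    universe: Iterable[str],
) -> pd.DataFrame:
    """Hypergeometric enrichment of ``gene_set`` in each category.

    Categories are clipped to the universe; BH correction is applied across
    categories.  Output schema matches :func:`scan_kmers`.
    """
    uni = set(map(str, universe))
    if not uni:
        raise ValueError("empty universe")
    fg = set(map(str, gene_set))
    if not fg <= uni:
        raise ValueError("gene_set must be a subset of the universe")
    N, n = len(uni), len(fg)
    rows = []
    for name, members in categories.items():
        cat = set(map(str, members)) & uni
        K = len(cat)
        x = len(cat & fg)
        p = hypergeometric_tail(x, n, K, N)
        rows.append(
            {
                "item": name,
                "x": x,
                "n": n,
                "K": K,
                "N": N,
                "fg_fraction": x / n if n else 0.0,
                "bg_fraction": K / N,
                "p_value": p,
            }
        )
    df = pd.DataFrame(
        rows, columns=["item", "x", "n", "K", "N", "fg_fraction", "bg_fraction", "p_value"]
    ).sort_values(["p_value", "item"], kind="mergesort", ignore_index=True)
    return _attach_q(df)
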