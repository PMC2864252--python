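"""First-crossing response timing and kinetic clustering.

A gene's *response time* is the first sampled time point at which its
log2 fold change vs t=0 crosses the fold threshold (2.0-fold by default,
i.e. |log2fc| >= 1): no interpolation between samples, so cluster labels
are the sampling times themselves.  Genes are then grouped by response
time into kinetic clusters, split into early (<= 2 h, inclusive) vs late
responders, and — across several datasets — reduced to a core set of genes
early-induced in at least a minimum number of datasets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CoreSet",
    "assign_response_time",
    "build_response_table",
    "normalize_to_max",
    "kinetic_clusters",
    "partition_early_late",
    "identify_core_set",
]


@dataclass
class CoreSet:
    """Genes early-induced in at least ``min_datasets`` datasets."""

    gene_ids: pd.Index
    support_counts: pd.Series  # per core gene, number of datasets with early induction
    min_datasets: int

    def __post_init__(self) -> None:
        if (self.support_counts < self.min_datasets).any():
            raise ValueError("support count below the configured minimum")

    def to_tsv(self, path) -> None:
        out = self.support_counts.rename("n_datasets_early").to_frame()
        out.index.name = "gene_id"
        out.to_csv(path, sep="\t")


def assign_response_time(
    log2fc_profile,
    times,
    fold_threshold: float = 2.0,
    direction: str = "up",
) -> dict:
    """First sampled time at which the profile crosses the fold threshold.

    direction='up' looks for log2fc >= log2(threshold), 'down' for
    log2fc <= -log2(threshold); the t=0 point never counts.  Returns a dict
    with ``direction`` ('up'/'down'/'none'), ``response_time_h`` (NaN when
    never crossed), the maximal |log2fc|, the linear fold at the crossing
    point, and ``dual_response`` (crossed the opposite cut too).
    """
    if fold_threshold <= 1:
        raise ValueError(f"fold threshold must be > 1, got {fold_threshold}")
    if direction not in ("up", "down"):
        raise ValueError(f"direction must be 'up' or 'down', got {direction!r}")
    profile = np.asarray(log2fc_profile, dtype=float)
    times = np.asarray(times, dtype=float)
    if profile.shape != times.shape:
        raise ValueError("profile and times must align")
    cut = math.log2(fold_threshold)
    after = times > 0
    hits_up = after & (profile >= cut)
    hits_down = after & (profile <= -cut)
    hits, other = (hits_up, hits_down) if direction == "up" else (hits_down, hits_up)
    row = {
        "direction": "none",
        "response_time_h": math.nan,
        "max_abs_log2fc": float(np.max(np.abs(profile[after]))) if after.any() else 0.0,
        "fold_at_crossing": math.nan,
        "dual_response": False,
    }
    if hits.any():
        i = int(np.argmax(hits))
        row["direction"] = direction
        row["response_time_h"] = float(times[i])
        row["fold_at_crossing"] = float(2.0 ** abs(profile[i]))
        row["dual_response"] = bool(other.any())
    return row


def build_response_table(
    log2fc: pd.DataFrame, fold_threshold: float = 2.0, direction: str = "up"
) -> pd.DataFrame:
    """Vectorized ``assign_response_time`` over a genes x times frame.

    Columns of ``log2fc`` are sampling times in hours (first must be 0).
    Returns one row per gene with the same fields as
    :func:`assign_response_time`.
    """
    if fold_threshold <= 1:
        raise ValueError(f"fold threshold must be > 1, got {fold_threshold}")
    if direction not in ("up", "down"):
        raise ValueError(f"direction must be 'up' or 'down', got {direction!r}")
    times = np.asarray(log2fc.columns, dtype=float)
    vals = log2fc.to_numpy(dtype=float)
    cut = math.log2(fold_threshold)
    after = times > 0
    signed = vals if direction == "up" else -vals
    hits = (signed >= cut) & after
    other_hits = (-signed >= cut) & after
    any_hit = hits.any(axis=1)
    first = np.argmax(hits, axis=1)

    resp_time = np.full(vals.shape[0], np.nan)
    resp_time[any_hit] = times[first[any_hit]]
    fold_at = np.full(vals.shape[0], np.nan)
    fold_at[any_hit] = 2.0 ** np.abs(vals[np.nonzero(any_hit)[0], first[any_hit]])
    dirs = np.where(any_hit, direction, "none")
    return pd.DataFrame(
        {
            "direction": dirs,
            "response_time_h": resp_time,
            "max_abs_log2fc": np.abs(vals[:, after]).max(axis=1)
            if after.any()
            else np.zeros(vals.shape[0]),
            "fold_at_crossing": fold_at,
            "dual_response": any_hit & other_hits.any(axis=1),
        },
        index=log2fc.index,
    )


def normalize_to_max(log2fc) -> pd.DataFrame | np.ndarray:
    """Scale each gene's log2fc profile by its maximal |log2fc|.

    Output lies in [-1, 1]; genes with the same kinetics but different
    response magnitudes become identical.  All-zero profiles are rejected.
    """
    is_frame = isinstance(log2fc, pd.DataFrame)
    vals = log2fc.to_numpy(dtype=float) if is_frame else np.asarray(log2fc, float)
    one_d = vals.ndim == 1
    mat = vals[None, :] if one_d else vals
    denom = np.abs(mat).max(axis=1)
    if np.any(denom == 0):
        raise ValueError("cannot normalize an all-zero profile")
    out = mat / denom[:, None]
    if is_frame:
        return pd.DataFrame(out, index=log2fc.index, columns=log2fc.columns)
    return out[0] if one_d else out


def kinetic_clusters(
    table: pd.DataFrame, normalized: pd.DataFrame
) -> tuple[pd.DataFrame, pd.Series]:
    """Group responders by response time; mean normalized profile + size.

    Returns (means, sizes): ``means`` has one row per cluster (indexed by
    response time in hours) holding the elementwise mean of the member
    genes' normalized profiles, ``sizes`` the member counts.
    """
    resp = table.loc[table["response_time_h"].notna()]
    if resp.empty:
        raise ValueError("no responding genes to cluster")
    profiles = normalized.loc[resp.index]
    grouped = profiles.groupby(resp["response_time_h"])
    means = grouped.mean()
    sizes = grouped.size().rename("n_genes")
    means.index.name = "response_time_h"
    return means, sizes


def partition_early_late(
    table: pd.DataFrame, cutoff: float = 2.0
) -> tuple[pd.Index, pd.Index]:
    """Split responders at the cutoff: early (<= cutoff, inclusive) vs late.

    Non-responders are excluded from both sets.
    """
    resp = table.loc[table["response_time_h"].notna()]
    early = resp.index[resp["response_time_h"] <= cutoff]
    late = resp.index[resp["response_time_h"] > cutoff]
    return early, late


def identify_core_set(
    tables: list[pd.DataFrame], cutoff: float = 2.0, min_datasets: int = 3
) -> CoreSet:
    """Genes early-responding in at least ``min_datasets`` of the datasets."""
    if min_datasets > len(tables):
        raise ValueError(
            f"min_datasets={min_datasets} exceeds the {len(tables)} datasets given"
        )
    counts: pd.Series | None = None
    for table in tables:
        early, _ = partition_early_late(table, cutoff)
        inc = pd.Series(1, index=early)
        counts = inc if counts is None else counts.add(inc, fill_value=0)
    if counts is None:
        counts = pd.Series(dtype=int)
    support = counts[counts >= min_datasets].astype(int).sort_index()
    return CoreSet(
        gene_ids=support.index, support_counts=support, min_datasets=min_datasets
    )
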