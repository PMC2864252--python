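"""Half-life and length association statistics, and the shut-off flagger.

The statistical core of the analysis: Wilcoxon/Mann-Whitney rank-sum
comparisons of half-life (and genomic-length) distributions between kinetic
clusters, and a per-gene test of whether an observed suppression is too
fast to be explained by a complete transcriptional shut-off given the
transcript's resting half-life.

The rank-sum test uses exact enumeration of the null (with midranks, so
ties are handled) whenever the combined sample size is small, and the
tie-corrected, continuity-corrected normal approximation otherwise.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .kinetics import shutoff_max_half_life

logger = logging.getLogger(__name__)

__all__ = [
    "HalfLifeAtlas",
    "RankTestResult",
    "rank_sum_test",
    "pairwise_cluster_tests",
    "early_late_stability_test",
    "length_association",
    "flag_destabilized",
    "read_half_life_atlas_tsv",
]

EXACT_LIMIT_DEFAULT = 12


@dataclass
class HalfLifeAtlas:
    """Gene -> half-life (hours). Joins are case-insensitive on gene id."""

    half_life_h: pd.Series
    source: str = ""

    def __post_init__(self) -> None:
        s = self.half_life_h.astype(float)
        s.index = s.index.astype(str)
        if s.index.has_duplicates:
            raise ValueError("duplicate gene ids in atlas")
        if not np.all(s.to_numpy() > 0):
            raise ValueError("half-lives must be positive")
        self.half_life_h = s
        self._upper = pd.Series(s.to_numpy(), index=s.index.str.upper())
        if self._upper.index.has_duplicates:
            raise ValueError("atlas gene ids collide after case folding")

    def lookup(self, gene_ids) -> pd.Series:
        """Half-lives for the given genes; missing genes are dropped (logged)."""
        idx = pd.Index([str(g).upper() for g in gene_ids])
        found = idx[idx.isin(self._upper.index)]
        missing = len(idx) - len(found)
        if missing:
            logger.info("atlas lookup: %d/%d genes missing, dropped", missing, len(idx))
        return self._upper.loc[found]

    def to_tsv(self, path) -> None:
        out = self.half_life_h.rename("t_half_hours").to_frame()
        out.index.name = "gene_id"
        out.to_csv(path, sep="\t", float_format="%.10g")


def read_half_life_atlas_tsv(path, units: str = "hours", source: str = "") -> HalfLifeAtlas:
    """Read a gene/half-life TSV; ``units`` may be 'hours' or 'minutes'."""
    df = pd.read_csv(path, sep="\t", comment="#")
    s = pd.Series(df.iloc[:, 1].to_numpy(float), index=df.iloc[:, 0].astype(str))
    if units == "minutes":
        s = s / 60.0
    elif units != "hours":
        raise ValueError(f"units must be 'hours' or 'minutes', got {units!r}")
    return HalfLifeAtlas(half_life_h=s, source=source)


@dataclass(frozen=True)
class RankTestResult:
    n_a: int
    n_b: int
    statistic: float  # rank-sum W of sample a (exact) or Mann-Whitney U (approx.)
    p_value: float
    alternative: str  # less | greater | two-sided
    method: str  # exact | normal-approximation


def _exact_rank_sum_p(a: np.ndarray, b: np.ndarray, alternative: str) -> tuple[float, float]:
    """Exact rank-sum p by enumerating all assignments of pooled midranks.

    Midranks are multiples of 1/2, so doubling gives integers and the
    comparison with the observed statistic is exact.
    """
    pooled = np.concatenate([a, b])
    ranks2 = np.rint(2.0 * stats.rankdata(pooled)).astype(np.int64)
    n_a = a.size
    w_obs = int(ranks2[:n_a].sum())
    total = 0
    n_le = 0
    n_ge = 0
    for combo in itertools.combinations(range(ranks2.size), n_a):
        w = int(ranks2[list(combo)].sum())
        total += 1
        if w <= w_obs:
            n_le += 1
        if w >= w_obs:
            n_ge += 1
    p_less = n_le / total
    p_greater = n_ge / total
    if alternative == "less":
        p = p_less
    elif alternative == "greater":
        p = p_greater
    elif alternative == "two-sided":
        p = min(1.0, 2.0 * min(p_less, p_greater))
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return w_obs / 2.0, p


def rank_sum_test(
    a,
    b,
    alternative: str = "two-sided",
    exact_limit: int = EXACT_LIMIT_DEFAULT,
) -> RankTestResult:
    """Wilcoxon/Mann-Whitney rank-sum test of samples ``a`` vs ``b``.

    ``alternative='less'`` tests whether a's values tend to be smaller than
    b's.  Combined samples of at most ``exact_limit`` observations use exact
    enumeration of the permutation null (ties handled via midranks); larger
    samples use the tie- and continuity-corrected normal approximation.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    if alternative not in ("less", "greater", "two-sided"):
        raise ValueError(f"unknown alternative {alternative!r}")

    if a.size + b.size <= exact_limit:
        statistic, p = _exact_rank_sum_p(a, b, alternative)
        method = "exact"
    else:
        res = stats.mannwhitneyu(
            a, b, alternative=alternative, method="asymptotic", use_continuity=True
        )
        statistic, p = float(res.statistic), float(res.pvalue)
        method = "normal-approximation"
    return RankTestResult(
        n_a=int(a.size),
        n_b=int(b.size),
        statistic=float(statistic),
        p_value=float(p),
        alternative=alternative,
        method=method,
    )


def pairwise_cluster_tests(
    clusters: dict[float, pd.Index | list],
    atlas: HalfLifeAtlas,
    alternative: str = "less",
    exact_limit: int = EXACT_LIMIT_DEFAULT,
) -> pd.DataFrame:
    """One-sided rank-sum tests of half-life between every pair of clusters.

    ``clusters`` maps response time (hours) to gene ids.  For each ordered
    pair (earlier, later) the test is "earlier cluster has lower half-life"
    (alternative='less' by default).  Returns a long-format frame with one
    row per pair; genes missing from the atlas are dropped per pair.
    """
    values = {}
    for t, genes in sorted(clusters.items()):
        hl = atlas.lookup(genes)
        if len(hl):
            values[t] = hl.to_numpy()
    if len(values) < 2:
        raise ValueError("need at least two clusters with atlas-matched genes")
    rows = []
    times = sorted(values)
    for t1, t2 in itertools.combinations(times, 2):
        res = rank_sum_test(values[t1], values[t2], alternative, exact_limit)
        rows.append(
            {
                "earlier_h": t1,
                "later_h": t2,
                "n_earlier": res.n_a,
                "n_later": res.n_b,
                "p_value": res.p_value,
                "method": res.method,
            }
        )
    return pd.DataFrame(rows)


def early_late_stability_test(
    early,
    late,
    atlas: HalfLifeAtlas,
    alternative: str = "less",
    exclude=None,
    exact_limit: int = EXACT_LIMIT_DEFAULT,
) -> RankTestResult:
    """Rank-sum test of half-life between early- and late-induced genes.

    ``exclude`` (e.g. a cross-dataset core set) removes genes from both
    groups before testing — the remove-the-core retest.
    """
    early = pd.Index(early)
    late = pd.Index(late)
    if exclude is not None:
        ex = pd.Index(exclude)
        early = early.difference(ex, sort=False)
        late = late.difference(ex, sort=False)
    hl_early = atlas.lookup(early)
    hl_late = atlas.lookup(late)
    return rank_sum_test(
        hl_early.to_numpy(), hl_late.to_numpy(), alternative, exact_limit
    )


def length_association(
    table: pd.DataFrame,
    annotation: pd.DataFrame,
    key: str = "genomic_length_bp",
    alternative: str = "less",
    exact_limit: int = EXACT_LIMIT_DEFAULT,
) -> dict:
    """Length distributions per kinetic cluster + earliest-vs-rest test.

    ``table`` is a response-time table (index gene_id, column
    ``response_time_h``); ``annotation`` carries one row per gene with the
    length column ``key``.  Returns per-cluster length arrays, and a
    one-sided test of whether the earliest cluster's lengths are shorter
    than those of all other responding genes.  Run with
    ``key='mature_length_bp'`` for the spliced-length negative control.
    """
    lengths = annotation.set_index("gene_id")[key]
    resp = table.loc[table["response_time_h"].notna()]
    merged = resp.join(lengths, how="inner")
    if merged.empty:
        raise ValueError("no responding genes with length annotation")
    by_cluster = {
        float(t): grp[key].to_numpy()
        for t, grp in merged.groupby("response_time_h", sort=True)
    }
    times = sorted(by_cluster)
    result: dict = {"by_cluster": by_cluster, "key": key}
    if len(times) >= 2:
        earliest = by_cluster[times[0]]
        rest = np.concatenate([by_cluster[t] for t in times[1:]])
        result["earliest_vs_rest"] = rank_sum_test(
            earliest, rest, alternative, exact_limit
        )
    return result


def flag_destabilized(
    down_table: pd.DataFrame,
    atlas: HalfLifeAtlas,
    margin: float = 1.0,
) -> pd.DataFrame:
    """Flag suppressed genes whose drop outruns a complete shut-off.

    ``down_table`` needs, per gene (index), the first crossing time
    ``response_time_h`` and the observed linear fold decrease at that time
    ``fold_at_crossing``.  A gene is flagged when its atlas half-life
    exceeds ``margin`` times the shut-off bound t*ln2/ln(fold): even zero
    transcription could not drop its mRNA that fast, so its stability must
    have been actively reduced.  ``margin`` > 1 buys robustness to noise.

    Returns a frame with the implied maximal half-life and the flag.
    """
    if margin <= 0:
        raise ValueError("margin must be positive")
    resp = down_table.loc[down_table["response_time_h"].notna()]
    hl = atlas.lookup(resp.index)
    # map back to original-case ids present in the atlas
    keep = resp.index[pd.Index(resp.index.astype(str).str.upper()).isin(hl.index)]
    resp = resp.loc[keep]
    rows = []
    for gene in resp.index:
        t = float(resp.at[gene, "response_time_h"])
        fold = float(resp.at[gene, "fold_at_crossing"])
        if not (fold > 1):
            continue  # did not actually drop below threshold; defensive
        bound = shutoff_max_half_life(fold, t)
        atlas_hl = float(hl.loc[str(gene).upper()])
        rows.append(
            {
                "gene_id": gene,
                "crossing_time_h": t,
                "fold_down": fold,
                "implied_max_half_life_h": bound,
                "atlas_half_life_h": atlas_hl,
                "flagged": atlas_hl > margin * bound,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "gene_id",
            "crossing_time_h",
            "fold_down",
            "implied_max_half_life_h",
            "atlas_half_life_h",
            "flagged",
        ],
    ).set_index("gene_id") if rows else pd.DataFrame(
        columns=[
            "crossing_time_h",
            "fold_down",
            "implied_max_half_life_h",
            "atlas_half_life_h",
            "flagged",
        ]
    )
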