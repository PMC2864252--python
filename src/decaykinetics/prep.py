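"""Input readers and pre-processing filters for time-course expression data.

Mirrors the standard microarray workflow this pipeline consumes: expression
matrices come in already summarized (e.g. RMA), with MAS5-style detection
flags alongside.  Pre-processing is

* presence filtering — keep rows called 'Present' on at least ``min_present``
  chips ('M'/marginal counts as not present);
* probe-set -> gene collapse — for genes covered by several probe-sets, keep
  the one with the highest median intensity across the dataset;
* longest-isoform / longest-UTR selection for annotation tables;
* log2 fold change of every column against the t=0 column.

All tabular I/O is TSV via pandas; UTR sequences are FASTA via Biopython
(U mapped to T, upper-cased).  Intensities must be strictly positive on the
linear scale; ``read_expression_tsv(..., log2=True)`` unlogs a file stored
in log2 units at the boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionTimeCourse",
    "filter_by_presence",
    "collapse_probesets",
    "log2_fold_change",
    "select_longest",
    "read_expression_tsv",
    "write_expression_tsv",
    "read_flags_tsv",
    "write_flags_tsv",
    "read_probe_gene_map",
    "read_annotation_tsv",
    "read_utr_fasta",
    "write_utr_fasta",
]


@dataclass
class ExpressionTimeCourse:
    """A rows-by-times intensity matrix (linear scale, > 0).

    ``data`` is indexed by probe-set or gene identifiers with one float
    column per sampling time in hours; the first time must be 0 (the
    stimulation point) and times must be strictly increasing.
    """

    data: pd.DataFrame
    level: str = "probeset"  # "probeset" | "gene"

    def __post_init__(self) -> None:
        if self.level not in ("probeset", "gene"):
            raise ValueError(f"level must be 'probeset' or 'gene', got {self.level!r}")
        self.data = self.data.astype(float)
        self.data.columns = [float(c) for c in self.data.columns]
        times = np.asarray(self.data.columns, dtype=float)
        if times.size == 0 or np.any(np.diff(times) <= 0):
            raise ValueError("sampling times must be strictly increasing and non-empty")
        if self.data.index.has_duplicates:
            dup = self.data.index[self.data.index.duplicated()][:3].tolist()
            raise ValueError(f"duplicate row identifiers, e.g. {dup}")
        if not np.all(self.data.to_numpy() > 0):
            raise ValueError("intensities must be strictly positive (linear scale)")

    @property
    def times(self) -> np.ndarray:
        return np.asarray(self.data.columns, dtype=float)

    @property
    def row_ids(self) -> pd.Index:
        return self.data.index

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()


def filter_by_presence(
    x: ExpressionTimeCourse, flags: pd.DataFrame, min_present: int = 2
) -> ExpressionTimeCourse:
    """Keep rows flagged 'P' on at least ``min_present`` chips.

    ``flags`` holds one MAS5-style letter (P/A/M) per row per chip, aligned
    to ``x`` rows; 'M' counts as not present.  Row order is preserved.
    """
    if not flags.index.equals(x.data.index) or flags.shape[0] != x.data.shape[0]:
        raise ValueError("flags rows are not aligned to the expression matrix")
    if flags.shape[1] != x.data.shape[1]:
        raise ValueError(
            f"flags have {flags.shape[1]} chips but matrix has {x.data.shape[1]}"
        )
    n_present = (flags == "P").sum(axis=1)
    keep = n_present >= min_present
    dropped = int((~keep).sum())
    if dropped:
        logger.info("presence filter dropped %d/%d rows", dropped, len(keep))
    return ExpressionTimeCourse(data=x.data.loc[keep], level=x.level)


def collapse_probesets(
    x: ExpressionTimeCourse, probe2gene: Mapping[str, str] | pd.Series
) -> ExpressionTimeCourse:
    """Collapse a probe-set level matrix to one row per gene.

    For a gene covered by several probe-sets the row with the highest median
    intensity across all columns is kept verbatim; median ties break to the
    lexicographically smallest probe-set id.  Unmapped probe-sets are
    dropped (count logged).
    """
    if x.level != "probeset":
        raise ValueError("collapse_probesets expects a probe-set level matrix")
    mapping = pd.Series(dict(probe2gene)) if not isinstance(probe2gene, pd.Series) else probe2gene
    if mapping.empty:
        raise ValueError("empty probe-set to gene mapping")

    genes = x.data.index.map(mapping)
    unmapped = genes.isna()
    if unmapped.any():
        logger.info("dropping %d unmapped probe-sets", int(unmapped.sum()))
    df = x.data.loc[~unmapped]
    genes = pd.Index(genes[~unmapped])

    medians = df.median(axis=1)
    # sort by (gene, -median, probe id) and keep the first row per gene
    order = pd.DataFrame(
        {
            "probe": df.index.to_numpy(),
            "gene": genes.to_numpy(),
            "neg_median": -medians.to_numpy(),
        }
    ).sort_values(["gene", "neg_median", "probe"], kind="mergesort")
    winners = order.groupby("gene", sort=True).head(1)
    collapsed = df.loc[winners["probe"]].copy()
    collapsed.index = pd.Index(winners["gene"].to_numpy(), name="gene_id")
    return ExpressionTimeCourse(data=collapsed, level="gene")


def log2_fold_change(x: ExpressionTimeCourse) -> pd.DataFrame:
    """log2 ratio of every column to the t=0 column (t=0 column is zero)."""
    times = x.times
    if times[0] != 0.0:
        raise ValueError("first sampling time must be 0 (the stimulation point)")
    vals = x.values
    return pd.DataFrame(
        np.log2(vals / vals[:, [0]]), index=x.data.index, columns=x.data.columns
    )


def select_longest(
    annotation: pd.DataFrame, key: str = "genomic_length_bp"
) -> pd.DataFrame:
    """One annotation row per gene: the transcript maximal by ``key``.

    Expects columns ``gene_id``, ``transcript_id`` and the length column
    ``key`` (e.g. genomic_length_bp, mature_length_bp, utr3_length_bp).
    Ties break to the smallest transcript id, so the pick is stable.
    """
    if key not in annotation.columns:
        raise ValueError(f"annotation lacks column {key!r}")
    ordered = annotation.sort_values(
        by=["gene_id", key, "transcript_id"],
        ascending=[True, False, True],
        kind="mergesort",
    )
    return ordered.groupby("gene_id", sort=True).head(1).reset_index(drop=True)


# --------------------------------------------------------------------------
# I/O


def _time_to_column(t: float) -> str:
    return f"t_{t:g}h"


def _column_to_time(name: str) -> float:
    s = name.strip()
    if s.startswith("t_"):
        s = s[2:]
    if s.endswith("h"):
        s = s[:-1]
    return float(s)


def read_expression_tsv(
    path, level: str = "probeset", log2: bool = False
) -> ExpressionTimeCourse:
    """Read an expression matrix TSV (first column ids, columns 't_0.5h'...).

    With ``log2=True`` the file stores log2 intensities and is converted to
    the linear scale on read.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    df.columns = [_column_to_time(c) for c in df.columns]
    if log2:
        df = 2.0**df
    return ExpressionTimeCourse(data=df, level=level)


def write_expression_tsv(x: ExpressionTimeCourse, path) -> None:
    out = x.data.copy()
    out.columns = [_time_to_column(t) for t in x.times]
    out.index.name = "row_id"
    out.to_csv(path, sep="\t", float_format="%.10g")


def read_flags_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str, comment="#")
    df.columns = [_column_to_time(c) for c in df.columns]
    bad = set(np.unique(df.to_numpy())) - {"P", "A", "M"}
    if bad:
        raise ValueError(f"unexpected detection flags {sorted(bad)}; expected P/A/M")
    return df


def write_flags_tsv(flags: pd.DataFrame, path) -> None:
    out = flags.copy()
    out.columns = [_time_to_column(float(t)) for t in out.columns]
    out.index.name = "row_id"
    out.to_csv(path, sep="\t")


def read_probe_gene_map(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    return pd.Series(df.iloc[:, 1].to_numpy(), index=df.iloc[:, 0].to_numpy())


def read_annotation_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    for col in ("genomic_length_bp", "mature_length_bp"):
        if col in df.columns and (df[col] < 0).any():
            raise ValueError(f"negative lengths in column {col}")
    if {"genomic_length_bp", "mature_length_bp"} <= set(df.columns):
        if (df["genomic_length_bp"] < df["mature_length_bp"]).any():
            raise ValueError("genomic length smaller than mature length")
    return df


def canonical_dna(seq: str) -> str:
    """Upper-case and map U->T; reject letters outside A/C/G/T/N."""
    s = seq.upper().replace("U", "T")
    if set(s) - set("ACGTN"):
        raise ValueError(f"non-DNA letters in sequence: {sorted(set(s) - set('ACGTN'))}")
    return s


def read_utr_fasta(path) -> dict[str, str]:
    """Read 3'-UTR sequences keyed by record id (DNA-canonicalized)."""
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seqs[rec.id] = canonical_dna(str(rec.seq))
    if not seqs:
        raise ValueError(f"no FASTA records in {path}")
    return seqs


def write_utr_fasta(seqs: Mapping[str, str], path, width: int = 60) -> None:
    records = [
        SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)
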