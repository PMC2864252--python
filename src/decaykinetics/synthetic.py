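"""Synthetic time-course experiments with known ground truth.

Every input the downstream analysis consumes — half-life atlas, probe-level
expression matrix with detection flags, probe-set to gene mapping, gene
annotation and 3'-UTR FASTA — is generated from the kinetic model's own
assumptions, so the full pipeline can be verified end to end without any
external download.

Generative structure, per gene:

* half-life drawn log-normally (median 274 min, the published murine
  median; log-sd 1.0 spans minutes to days), alpha = ln2/T_1/2;
* an induced gene's transcription rate rises by a factor L (log-uniform in
  [3, 30]) at t=0; its latent fold change follows the closed form
  fold(t) = 1 + (L-1)(1 - e^{-alpha t});
* a suppressed gene's rate falls by L < 1; a configurable fraction is
  additionally *destabilized* (alpha multiplied by a factor in [3, 10] at
  t=0 — the simplest mechanism by which observed suppression can outrun a
  complete transcriptional shut-off);
* observed intensity = baseline (log-uniform over a plausible microarray
  range 2^5..2^14) x latent fold x 2^Normal(0, noise_log2_sd), independent
  per chip;
* genes may carry one or two probe-sets with distinct affinities, so the
  presence filter and max-median probe collapse are exercised;
* the AU-rich element 7-mer (DNA TATTTAT) is planted in 52% of the UTRs of
  the fastest-decaying induced genes and 18% of all others (the published
  foreground/background frequencies as generator parameters); chance
  occurrences are scrubbed so the planting rates are exact Bernoulli rates;
* induced genes whose theoretical 2-fold induction time is very early get
  stochastically shorter genomic transcribed lengths; mature (spliced)
  lengths are drawn independently of timing as a negative control.

Child random streams are derived from the master seed with fixed component
keys, so adding a generator never perturbs existing streams.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import prep
from .kinetics import LN2, FoldTarget, time_to_fold_induction
from .stability import HalfLifeAtlas

__all__ = [
    "SyntheticConfig",
    "ExperimentBundle",
    "generate_half_life_atlas",
    "generate_utr_sequences",
    "generate_experiment",
    "generate_dataset_series",
    "write_fixture_bundle",
]

# fixed spawn keys for per-component child streams
_STREAMS = {
    "atlas": 0,
    "folds": 1,
    "baseline": 2,
    "probes": 3,
    "noise": 4,
    "lengths": 5,
    "utrs": 6,
    "destab": 7,
}


def _rng(seed: int, component: str, extra: int = 0) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(seed, spawn_key=(_STREAMS[component], extra))
    )


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for one synthetic experiment.

    Defaults are the conditions the analysis assumes: 5000 genes of which
    500 are induced and 500 suppressed, sampled at 0, 0.5, 1, 2, 4, 6, 8
    and 10 h after stimulation, atlas median 274 min, ARE 7-mer planted at
    52% foreground / 18% background.
    """

    n_genes: int = 5000
    n_induced: int = 500
    n_suppressed: int = 500
    atlas_median_minutes: float = 274.0
    atlas_log_sd: float = 1.0
    induction_fold_range: tuple[float, float] = (3.0, 30.0)
    suppression_fold_range: tuple[float, float] = (3.0, 30.0)  # L = 1/draw
    fold_threshold_k: float = 2.0
    sampling_times: tuple[float, ...] = (0.0, 0.5, 1.0, 2.0, 4.0, 6.0, 8.0, 10.0)
    noise_log2_sd: float = 0.25
    baseline_log2_range: tuple[float, float] = (5.0, 14.0)
    second_probeset_rate: float = 0.2
    motif: str = "TATTTAT"
    plant_rate_fg: float = 0.52
    plant_rate_bg: float = 0.18
    n_motif_foreground: int = 52
    utr_length_range: tuple[int, int] = (300, 1500)
    frac_destabilized: float = 0.0
    destab_multiplier_range: tuple[float, float] = (3.0, 10.0)
    length_model: bool = True
    early_length_cutoff_h: float = 1.0
    early_length_median_bp: float = 9474.0
    late_length_median_bp: float = 39789.0
    length_log_sd: float = 0.6
    mature_length_median_bp: float = 2500.0
    mature_log_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        if self.n_induced + self.n_suppressed > self.n_genes:
            raise ValueError("n_induced + n_suppressed exceeds n_genes")
        for p in (self.plant_rate_fg, self.plant_rate_bg, self.frac_destabilized,
                  self.second_probeset_rate):
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"probability {p} outside [0, 1]")
        times = np.asarray(self.sampling_times, float)
        if times[0] != 0.0 or np.any(np.diff(times) <= 0):
            raise ValueError("sampling_times must start at 0 and strictly increase")
        if self.induction_fold_range[0] <= 1.0:
            raise ValueError("induction fold factors must be > 1")


@dataclass
class ExperimentBundle:
    """Everything one synthetic experiment produces."""

    expression: prep.ExpressionTimeCourse  # probe-set level, noisy
    flags: pd.DataFrame
    probe2gene: pd.Series
    atlas: HalfLifeAtlas
    annotation: pd.DataFrame
    utrs: dict[str, str] | None
    truth: pd.DataFrame
    config: SyntheticConfig


def generate_half_life_atlas(
    n: int,
    median_minutes: float = 274.0,
    log_sd: float = 1.0,
    seed: int = 0,
    gene_ids: Sequence[str] | None = None,
    source: str = "synthetic",
) -> HalfLifeAtlas:
    """Log-normal half-life atlas in hours with the given median in minutes."""
    if n <= 0:
        raise ValueError("n must be positive")
    if median_minutes <= 0:
        raise ValueError("median must be positive")
    rng = _rng(seed, "atlas")
    minutes = np.exp(rng.normal(math.log(median_minutes), log_sd, size=n))
    ids = list(gene_ids) if gene_ids is not None else [f"g{i:05d}" for i in range(n)]
    if len(ids) != n:
        raise ValueError("gene_ids length mismatch")
    return HalfLifeAtlas(
        half_life_h=pd.Series(minutes / 60.0, index=pd.Index(ids, name="gene_id")),
        source=source,
    )


def _scrub_motif(seq: np.ndarray, motif_codes: np.ndarray,
                 rng: np.random.Generator) -> None:
    """Destroy every occurrence of the motif in-place (mutate a middle base)."""
    k = motif_codes.size
    while True:
        if seq.size < k:
            return
        windows = np.lib.stride_tricks.sliding_window_view(seq, k)
        hits = np.nonzero((windows == motif_codes).all(axis=1))[0]
        if hits.size == 0:
            return
        for pos in hits:
            old = seq[pos + k // 2]
            seq[pos + k // 2] = (old + rng.integers(1, 4)) % 4


_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def generate_utr_sequences(
    n: int,
    plant_rate: float,
    motif: str = "TATTTAT",
    length_range: tuple[int, int] = (300, 1500),
    rng: np.random.Generator | None = None,
    prefix: str = "g",
) -> tuple[dict[str, str], np.ndarray]:
    """Random UTRs with the motif present in exactly Bernoulli(plant_rate) of them.

    Chance occurrences of the motif are scrubbed before planting, so motif
    presence is a clean Bernoulli indicator; returns (sequences, planted).
    """
    if rng is None:
        rng = np.random.default_rng(0)
    motif = prep.canonical_dna(motif)
    motif_codes = np.array(["ACGT".index(b) for b in motif], dtype=np.int64)
    k = motif_codes.size
    lengths = rng.integers(length_range[0], length_range[1] + 1, size=n)
    planted = rng.random(n) < plant_rate
    seqs: dict[str, str] = {}
    for i in range(n):
        codes = rng.integers(0, 4, size=lengths[i])
        _scrub_motif(codes, motif_codes, rng)
        if planted[i]:
            pos = int(rng.integers(0, lengths[i] - k + 1))
            codes[pos : pos + k] = motif_codes
        seqs[f"{prefix}{i:05d}"] = _BASES[codes].tobytes().decode()
    return seqs, planted


def _latent_fold(alpha: np.ndarray, alpha_post: np.ndarray, L: np.ndarray,
                 times: np.ndarray) -> np.ndarray:
    """Latent fold change vs t=0 for a step in (beta, alpha) at t=0.

    From X0 = beta/alpha, with beta -> L*beta and alpha -> alpha_post, the
    relaxation toward the new steady state s*X0 (s = L*alpha/alpha_post) is
    fold(t) = s + (1-s) e^{-alpha_post t}; for alpha_post = alpha this is
    the familiar 1 + (L-1)(1 - e^{-alpha t}).
    """
    s = (L * alpha / alpha_post)[:, None]
    return s + (1.0 - s) * np.exp(-np.outer(alpha_post, times))


def _theoretical_down_time(s: np.ndarray, alpha_post: np.ndarray, k: float) -> np.ndarray:
    """Time at which the latent fold first reaches 1/k (inf if it never does)."""
    target = 1.0 / k
    out = np.full(s.shape, np.inf)
    reachable = s < target
    ratio = (target - s[reachable]) / (1.0 - s[reachable])
    out[reachable] = -np.log(ratio) / alpha_post[reachable]
    return out


def generate_experiment(
    cfg: SyntheticConfig,
    with_sequences: bool = True,
    atlas: HalfLifeAtlas | None = None,
) -> ExperimentBundle:
    """Generate one complete synthetic experiment with ground truth.

    An ``atlas`` may be supplied to share half-lives across several
    experiments (decay rates are gene-intrinsic; stimuli differ).
    """
    n, seed = cfg.n_genes, cfg.seed
    times = np.asarray(cfg.sampling_times, float)
    gene_ids = np.array([f"g{i:05d}" for i in range(n)])

    if atlas is None:
        atlas = generate_half_life_atlas(
            n, cfg.atlas_median_minutes, cfg.atlas_log_sd, seed=seed, gene_ids=gene_ids
        )
    elif len(atlas.half_life_h) != n:
        raise ValueError("supplied atlas does not cover n_genes")
    t_half = atlas.half_life_h.to_numpy()
    alpha = LN2 / t_half

    group = np.array(["unchanged"] * n, dtype=object)
    group[: cfg.n_induced] = "induced"
    group[cfg.n_induced : cfg.n_induced + cfg.n_suppressed] = "suppressed"
    induced = group == "induced"
    suppressed = group == "suppressed"

    rng_folds = _rng(seed, "folds")
    L = np.ones(n)
    lo, hi = cfg.induction_fold_range
    L[induced] = np.exp(rng_folds.uniform(math.log(lo), math.log(hi), induced.sum()))
    slo, shi = cfg.suppression_fold_range
    L[suppressed] = 1.0 / np.exp(
        rng_folds.uniform(math.log(slo), math.log(shi), suppressed.sum())
    )

    alpha_post = alpha.copy()
    rng_destab = _rng(seed, "destab")
    destabilized = np.zeros(n, dtype=bool)
    if cfg.frac_destabilized > 0 and suppressed.any():
        pick = rng_destab.random(n) < cfg.frac_destabilized
        destabilized = suppressed & pick
        dlo, dhi = cfg.destab_multiplier_range
        mult = np.exp(
            rng_destab.uniform(math.log(dlo), math.log(dhi), destabilized.sum())
        )
        alpha_post[destabilized] = alpha[destabilized] * mult

    # theoretical k-fold response times (hours)
    k = cfg.fold_threshold_k
    t_resp = np.full(n, np.inf)
    for i in np.nonzero(induced)[0]:
        t_resp[i] = time_to_fold_induction(FoldTarget(k=k, L=L[i]), t_half[i])
    s_all = L * alpha / alpha_post
    t_resp[suppressed] = _theoretical_down_time(
        s_all[suppressed], alpha_post[suppressed], k
    )

    # latent levels
    rng_base = _rng(seed, "baseline")
    blo, bhi = cfg.baseline_log2_range
    baseline = 2.0 ** rng_base.uniform(blo, bhi, n)
    fold = _latent_fold(alpha, alpha_post, L, times)
    latent = baseline[:, None] * fold

    # probe-sets: every gene has "<gene>_at"; some a second "<gene>_x_at"
    rng_probes = _rng(seed, "probes")
    second = rng_probes.random(n) < cfg.second_probeset_rate
    probe_ids = [f"{g}_at" for g in gene_ids] + [
        f"{g}_x_at" for g in gene_ids[second]
    ]
    affin1 = 2.0 ** rng_probes.uniform(-1.0, 1.0, n)
    affin2 = 2.0 ** rng_probes.uniform(-1.0, 1.0, int(second.sum()))
    probe_latent = np.vstack(
        [latent * affin1[:, None], latent[second] * affin2[:, None]]
    )
    probe_genes = np.concatenate([gene_ids, gene_ids[second]])

    rng_noise = _rng(seed, "noise")
    if cfg.noise_log2_sd > 0:
        noise = 2.0 ** rng_noise.normal(0.0, cfg.noise_log2_sd, probe_latent.shape)
    else:
        noise = 1.0
    observed = probe_latent * noise

    expression = prep.ExpressionTimeCourse(
        data=pd.DataFrame(
            observed, index=pd.Index(probe_ids, name="row_id"), columns=times
        ),
        level="probeset",
    )
    flags = pd.DataFrame(
        "P", index=expression.data.index, columns=expression.data.columns
    )
    probe2gene = pd.Series(probe_genes, index=pd.Index(probe_ids, name="probe_id"))

    # lengths: very early induced genes are stochastically shorter
    rng_len = _rng(seed, "lengths")
    log_median = np.full(n, math.log(cfg.late_length_median_bp))
    if cfg.length_model:
        very_early = induced & (t_resp <= cfg.early_length_cutoff_h)
        log_median[very_early] = math.log(cfg.early_length_median_bp)
    genomic = np.exp(rng_len.normal(log_median, cfg.length_log_sd))
    mature = np.exp(
        rng_len.normal(math.log(cfg.mature_length_median_bp), cfg.mature_log_sd, n)
    )
    mature = np.minimum(mature, genomic)
    annotation = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "transcript_id": [f"{g}.1" for g in gene_ids],
            "genomic_length_bp": np.round(genomic).astype(int),
            "mature_length_bp": np.round(mature).astype(int),
        }
    )

    # motif foreground: the fastest-decaying induced genes
    induced_idx = np.nonzero(induced)[0]
    fg_order = induced_idx[np.argsort(-alpha[induced_idx], kind="stable")]
    motif_fg = np.zeros(n, dtype=bool)
    # clamp: a small experiment cannot have more foreground genes than induced
    motif_fg[fg_order[: min(cfg.n_motif_foreground, fg_order.size)]] = True

    utrs: dict[str, str] | None = None
    motif_planted = np.zeros(n, dtype=bool)
    if with_sequences:
        rng_utr = _rng(seed, "utrs")
        rates = np.where(motif_fg, cfg.plant_rate_fg, cfg.plant_rate_bg)
        motif = prep.canonical_dna(cfg.motif)
        motif_codes = np.array(["ACGT".index(b) for b in motif], dtype=np.int64)
        km = motif_codes.size
        lengths = rng_utr.integers(
            cfg.utr_length_range[0], cfg.utr_length_range[1] + 1, size=n
        )
        motif_planted = rng_utr.random(n) < rates
        utrs = {}
        for i in range(n):
            codes = rng_utr.integers(0, 4, size=lengths[i])
            _scrub_motif(codes, motif_codes, rng_utr)
            if motif_planted[i]:
                pos = int(rng_utr.integers(0, lengths[i] - km + 1))
                codes[pos : pos + km] = motif_codes
            utrs[gene_ids[i]] = _BASES[codes].tobytes().decode()

    truth = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "group": group,
            "alpha": alpha,
            "alpha_post": alpha_post,
            "L": L,
            "t_half_h": t_half,
            "baseline": baseline,
            "theoretical_response_time_h": t_resp,
            "destabilized": destabilized,
            "motif_foreground": motif_fg,
            "motif_planted": motif_planted,
            "genomic_length_bp": annotation["genomic_length_bp"].to_numpy(),
            "mature_length_bp": annotation["mature_length_bp"].to_numpy(),
        }
    ).set_index("gene_id")

    return ExperimentBundle(
        expression=expression,
        flags=flags,
        probe2gene=probe2gene,
        atlas=atlas,
        annotation=annotation,
        utrs=utrs,
        truth=truth,
        config=cfg,
    )


def generate_dataset_series(
    cfg: SyntheticConfig, n_datasets: int, with_sequences: bool = False
) -> list[ExperimentBundle]:
    """Several datasets sharing gene identities and half-lives.

    Dataset j reuses the same atlas/ground-truth structure but re-draws
    noise, folds and baselines with seed offset j — emulating the same
    transcriptome probed by independent stimuli with gene-specific but
    condition-independent decay rates.
    """
    if n_datasets < 1:
        raise ValueError("n_datasets must be >= 1")
    shared_atlas = generate_half_life_atlas(
        cfg.n_genes, cfg.atlas_median_minutes, cfg.atlas_log_sd, seed=cfg.seed
    )
    out = []
    for j in range(n_datasets):
        cfg_j = replace(cfg, seed=cfg.seed + 100_000 * j) if j else cfg
        out.append(
            generate_experiment(
                cfg_j,
                with_sequences=with_sequences and j == 0,
                atlas=shared_atlas,
            )
        )
    return out


def write_fixture_bundle(bundle: ExperimentBundle, directory) -> dict[str, Path]:
    """Write the bundle as plain-text fixtures; round-trips via `prep` readers."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": directory / "expression.tsv",
        "flags": directory / "flags.tsv",
        "probe2gene": directory / "probe2gene.tsv",
        "atlas": directory / "atlas.tsv",
        "annotation": directory / "annotation.tsv",
        "truth": directory / "truth.tsv",
    }
    prep.write_expression_tsv(bundle.expression, paths["expression"])
    prep.write_flags_tsv(bundle.flags, paths["flags"])
    pd.DataFrame(
        {"probe_id": bundle.probe2gene.index, "gene_id": bundle.probe2gene.to_numpy()}
    ).to_csv(paths["probe2gene"], sep="\t", index=False)
    bundle.atlas.to_tsv(paths["atlas"])
    bundle.annotation.to_csv(paths["annotation"], sep="\t", index=False)
    bundle.truth.to_csv(paths["truth"], sep="\t", float_format="%.10g")
    if bundle.utrs is not None:
        paths["utrs"] = directory / "utrs.fasta"
        prep.write_utr_fasta(bundle.utrs, paths["utrs"])
    return paths
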