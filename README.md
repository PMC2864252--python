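# decaykinetics

Tools for analyzing how mRNA degradation rate shapes the *temporal order*
of gene induction in time-course expression data.

In mammalian transcriptional responses, genes split into early,
intermediate and late kinetic waves.  The usual explanation is sequential
activation of transcription factors, but a first-order kinetic model makes
a sharper prediction: the speed of a transcript's response is set by its
own decay rate.  With production rate β (concentration·h⁻¹) and
degradation rate constant α (h⁻¹),

    dX/dt = β − αX,          X_ss = β/α,
    X(t)  = X₀ + (β/α − X₀)(1 − e^{−αt}),

so *any* transition between steady states is half complete at
T₁/₂ = ln2/α — the transcript half-life.  If transcription rises by a
factor L, the time to reach a k-fold increase in abundance is

    T_k = −log₂(1 − f) · T₁/₂,      f = (k − 1)/(L − 1),

linear in the half-life: short-lived mRNAs are induced first.  The same
model bounds suppression: even a complete transcriptional shut-off can only
achieve a fold-down drop by time t if T₁/₂ ≤ t·ln2/ln(fold) — an observed
drop faster than that implies *active destabilization* of the transcript.

The package provides, as an importable library:

- **`kinetics`** — the closed-form model, a piecewise-exact pulse
  simulator, the T_k formula, rate calibration, and the shut-off bound;
- **`synthetic`** — a generator of complete synthetic experiments
  (log-normal half-life atlas, noisy probe-level time courses, detection
  flags, gene annotation, 3′-UTR FASTA) with per-gene ground truth;
- **`prep`** — microarray-style pre-processing: presence filtering,
  max-median probe-set→gene collapse, longest-isoform/UTR selection, log2
  fold change;
- **`timing`** — first-crossing response times, kinetic clusters,
  early/late partition, cross-dataset core-set extraction;
- **`stability`** — exact/approximate Wilcoxon rank-sum machinery,
  per-cluster half-life and genomic-length comparisons, and the
  destabilization flagger;
- **`enrichment`** — exhaustive k-mer presence enrichment in 3′-UTRs
  (hypergeometric tail, Benjamini–Hochberg FDR) and category enrichment;
- **`pipeline`** — configuration-driven orchestration with TSV/JSON
  reports, plus a thin `decaykinetics` command-line front end
  (`simulate`, `generate`, `induce`, `suppress`, `enrich`).

## Worked example

Run the induction analysis end to end on synthetic data (`examples/`
contains one narrative script per capability):

```sh
python examples/03_induction_analysis.py
```

```
responders: 536 (early <= 2 h: 388, late: 148)
cluster sizes: {'0.5': 201, '1': 105, '2': 82, '4': 74, '6': 40, '8': 18, '10': 16}
cluster median half-life (h): {'0.5': 2.1, '1': 5.42, '2': 4.93, '4': 6.25, '6': 7.94, '8': 13.69, '10': 7.85}
early vs late half-life, one-sided rank-sum p = 2.18e-21
earliest cluster shorter genes, p = 4.09e-31
```

Of 5000 genes, 536 cross the 2-fold induction threshold; genes are
clustered by the first sampled time at which they cross.  The median
half-life of the 0.5 h cluster (2.1 h) is far below that of the late
clusters, and a one-sided rank-sum test of early (≤ 2 h) versus late
responders confirms the association the model predicts (p ≈ 10⁻²¹).  The
earliest cluster is also strongly enriched for short genomic transcribed
lengths, the second physical limit on rapid induction.

The motif example recovers the AU-rich element from sequence alone:

```sh
python examples/04_motif_enrichment.py
```

```
   item  x  n  fg_fraction  bg_fraction  p_value  q_value
TATTTAT 27 52        0.519        0.184 4.33e-08 0.000709
```

TATTTAT (RNA UAUUUAU) is present in 52% of the 52 core-gene UTRs versus
18% of 5000 background UTRs, and ranks first among all 16384 7-mers.

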