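"""Full induction analysis on synthetic data with known ground truth.

Generates a 5000-gene time course (500 induced genes following the kinetic
model), clusters genes by first 2-fold crossing, and tests whether early
responders carry shorter-lived mRNAs — the association the model predicts.
"""

from decaykinetics import PipelineConfig, SyntheticConfig, run_induction_analysis

cfg = PipelineConfig(synthetic=SyntheticConfig(seed=7), seed=7)
res = run_induction_analysis(cfg)
s = res["summary"]

print(f"responders: {s['n_responders']} "
      f"(early <= 2 h: {s['n_early']}, late: {s['n_late']})")
print("cluster sizes:", s["cluster_sizes"])
print("cluster median half-life (h):",
      {k: round(v, 2) for k, v in s["cluster_median_half_life_h"].items()})
print(f"early vs late half-life, one-sided rank-sum p = {s['early_late_p']:.3g}")
print(f"earliest cluster shorter genes, p = {s['length_earliest_vs_rest_p']:.3g}")
print(
    "-> genes crossing the threshold early have systematically shorter\n"
    "   half-lives (and shorter genomic lengths), exactly as planted by the\n"
    "   generator and predicted by T_k = -log2(1-f) * T_1/2."
)
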