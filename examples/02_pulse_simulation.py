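"""Square-pulse response of four transcripts with different decay rates.

First all four share the same transcription rate (beta = 5): they reach
different steady levels but the unstable ones get there fastest.  Then the
rates are recalibrated so all four meet at the same level at t = 5 h,
isolating response *speed* from steady-state *level*.
"""

import numpy as np

from decaykinetics import run_figure1_simulation

ALPHAS = (2.0, 1.0, 0.5, 0.2)

out = run_figure1_simulation(alphas=ALPHAS, beta=5.0, pulse=(0.0, 5.0))
print("Equal transcription rate (beta = 5), pulse on [0, 5] h:")
for alpha, df in out.items():
    at5 = df.loc[np.isclose(df.time_h, 5.0), "level"].iloc[0]
    frac = at5 / (5.0 / alpha)
    print(
        f"  alpha = {alpha:>3}: level at t=5 is {at5:6.2f} "
        f"({100 * frac:5.1f}% of its steady state)"
    )
print("-> high-alpha transcripts complete their transition almost fully;\n"
      "   the stable one (alpha = 0.2) is still far from equilibrium.\n")

out_eq = run_figure1_simulation(alphas=ALPHAS, equalize_at=5.0, target_level=10.0)
print("Rates recalibrated so all meet at level 10 at t = 5 h:")
for alpha, df in out_eq.items():
    at1 = df.loc[np.isclose(df.time_h, 1.0), "level"].iloc[0]
    at5 = df.loc[np.isclose(df.time_h, 5.0), "level"].iloc[0]
    print(f"  alpha = {alpha:>3}: level at t=1 is {at1:5.2f}, at t=5 is {at5:5.2f}")
print("-> same endpoint, but the unstable transcripts are far ahead at t=1:\n"
      "   decay rate alone orders the response times.")
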