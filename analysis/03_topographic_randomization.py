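"""Step 2b: randomization TANOVA on GFP-normalized topography.

Sample-wise restricted-permutation tests of Side, Session and their
interaction on the puff ERP configuration (999 permutations, add-one p,
>= 20 ms duration criterion).  The planted effect is a pure crossover, so
the interaction should light up inside 250-550 ms; the same analysis on
sham stimuli is the negative control.
"""

import pandas as pd

import topoplast as tp

from _common import COHORT_SEED, load_cohort, out

dataset, _ = load_cohort()

frames = []
for stimulus in ("puff", "sham"):
    for i, effect in enumerate(("side", "session", "interaction")):
        res = tp.tanova(dataset, stimulus=stimulus, effect=effect,
                        n_permutations=999, seed=COHORT_SEED + i,
                        window=(-100.0, 700.0))
        df = res.to_frame()
        df["stimulus"] = stimulus
        frames.append(df)
        label = ", ".join(f"{a:.0f}-{b:.0f} ms"
                          for a, b in res.significant_runs) or "none"
        print(f"TANOVA [{stimulus}] {effect:<12s} runs: {label}")

pd.concat(frames, ignore_index=True).to_csv(out("tanova.csv"), index=False)
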