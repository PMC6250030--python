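"""Step 5: behavioral asymmetries and brain-behavior correlations.

One-tailed paired tests between hands per sensory/sensory-motor measure,
two-sided pre/post change tests, and pooled-hand Spearman correlations of
the focus map's duration (and its pre-to-post change) with each measure
that differentiates the hands before the intervention.
"""

import pandas as pd

import topoplast as tp

from _common import COHORT_SEED, load_cohort, out

_, behavior = load_cohort()
durations = pd.read_csv(out("map_durations.csv"))
contrasts = pd.read_csv(out("duration_contrasts.csv"))

focus = (contrasts[contrasts.contrast == "pre: more vs less"]
         .set_index("map")["t"].abs().idxmax())
print(f"focus map (largest pre-intervention hand difference): {focus}")

hand = tp.paired_hand_tests(behavior, session="pre")
hand.to_csv(out("behavior_hand_tests_pre.csv"), index=False)
print("pre-intervention between-hand tests (one-tailed):")
for _, r in hand.iterrows():
    flag = "*" if r.p < 0.05 else " "
    print(f" {flag} {r.test:<13s} t({r.df}) = {r.t:6.2f}, p = {r.p:.4f}")

change = tp.pre_post_change_tests(behavior)
change.to_csv(out("behavior_change_tests.csv"), index=False)
sig = change.query("p < 0.05")
print("pre->post changes (two-tailed, p < 0.05):")
for _, r in sig.iterrows():
    print(f"   {r.test:<13s} {r.side:<14s} t({r.df}) = {r.t:6.2f}, "
          f"p = {r.p:.4f}")

rows = []
asym = hand.query("p < 0.05")["test"]
for measure in asym:
    for kind, kwargs in (("pre", dict(session="pre")),
                         ("change", dict(session=None, change=True))):
        res = tp.pooled_hand_correlation(durations, behavior, focus, measure,
                                         seed=COHORT_SEED, **kwargs)
        rows.append({"map": focus, "measure": measure, "kind": kind,
                     "rho": res.rho, "n": res.n, "p": res.p,
                     "method": res.method})
corr = pd.DataFrame(rows)
corr.to_csv(out("behavior_correlations.csv"), index=False)
print(f"pooled-hand Spearman correlations with {focus} duration:")
for _, r in corr.iterrows():
    print(f"   {r['measure']:<13s} [{r['kind']:<6s}] rho({r.n - 2}) = "
          f"{r.rho:6.3f}, p = {r.p:.4f}")
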