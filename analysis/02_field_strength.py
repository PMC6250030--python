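"""Step 1-2a: topography sequence and response-strength (GFP) statistics.

Exports the group-average topographies at 100 ms intervals, then runs the
sample-wise Session x Side repeated-measures ANOVA on global field power
over -100..700 ms with the 20 ms duration criterion.  In the simulated
cohort all conditions share one GFP envelope, so the expected finding is
silence: the intervention signature is topographic, not strength-based.
"""

import topoplast as tp

from _common import DATA_DIR, load_cohort, out

dataset, _ = load_cohort()

topo = tp.export_topography_sequence(dataset, interval_ms=100.0,
                                     window=(0.0, 700.0),
                                     outdir=DATA_DIR.parent / "figures")
topo.to_csv(out("topography_sequence.csv"), index=False)
n_maps = topo.groupby(["side", "session"])["time_ms"].nunique().iloc[0]
print(f"exported {n_maps} maps per puff condition (100 ms steps, 0-700 ms)")

res = tp.gfp_anova(dataset, stimulus="puff", window=(-100.0, 700.0))
res.table.to_csv(out("gfp_anova.csv"), index=False)
for effect, runs in res.significant_runs.items():
    label = ", ".join(f"{a:.0f}-{b:.0f} ms" for a, b in runs) or "none"
    print(f"GFP {effect:<12s} significant runs (>=20 ms): {label}")
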