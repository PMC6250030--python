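"""Step 3: spatial correlation of each condition with the reference ERP.

Tracks the moment-by-moment spatial correlation between the reference
topography (pre-intervention, less affected hand, puff) and the other
three puff conditions.  The crossover prediction: within 250-550 ms only
the post-intervention more-affected response resembles the reference.
"""

import topoplast as tp

from _common import load_cohort, out

dataset, _ = load_cohort()

series = tp.spatial_correlation_series(
    dataset, reference_condition=("less_affected", "pre"),
    stimulus="puff", window=(0.0, 700.0))
series.to_csv(out("spatial_correlation.csv"), index=False)

win = series[(series.time_ms >= 250) & (series.time_ms < 550)]
early = series[(series.time_ms >= 50) & (series.time_ms < 200)]
print("mean spatial correlation with the reference (less affected, pre):")
print(f"{'condition':>22s}  {'50-200 ms':>9s}  {'250-550 ms':>10s}")
for (side, sess), grp in win.groupby(["side", "session"]):
    e = early[(early.side == side) & (early.session == sess)]
    print(f"{side + '/' + sess:>22s}  {e.correlation.mean():9.3f}  "
          f"{grp.correlation.mean():10.3f}")
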