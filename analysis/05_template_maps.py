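"""Step 4: template-map clustering, model selection, back-fitting.

AAHC clustering of the four puff group-average ERPs within 250-550 ms,
Krzanowski-Lai choice of the number of template maps, single-subject
back-fitting by best spatial correlation, and the duration statistics:
the 3-way Map x Session x Side ANOVA, per-map 2x2 ANOVAs, and the planned
paired contrasts.
"""

import numpy as np


import topoplast as tp
from topoplast.clustering import clinically_relevant_maps
from topoplast.dataset import SESSIONS, SIDES

from _common import load_cohort, out

dataset, _ = load_cohort()
window = (250.0, 550.0)

mask = dataset.time_mask(window)
group = {(sd, ss): dataset.group_mean("puff", sd, ss)[:, mask]
         for sd in SIDES for ss in SESSIONS}
seg = tp.cluster_topographies(group, dataset.times[mask], k_range=(1, 8))
k = tp.select_k_krzanowski_lai(seg)
print(f"Krzanowski-Lai selects k = {k} template maps "
      f"(GEV {seg.gev[k]:.3f}); GEV by k: "
      + ", ".join(f"{kk}:{v:.3f}" for kk, v in sorted(seg.gev.items())))

np.savetxt(out("template_maps.tsv"), seg.templates[k], delimiter="\t")
fits = tp.backfit(dataset, seg.templates[k], window)
fits.frame.to_csv(out("map_durations.csv"), index=False)

stats = tp.duration_anova(fits)
stats.three_way.to_csv(out("duration_anova_3way.csv"), index=False)
stats.per_map.to_csv(out("duration_anova_per_map.csv"), index=False)
stats.contrasts.to_csv(out("duration_contrasts.csv"), index=False)

three = stats.three_way.set_index("effect")
row = three.loc["Map:Session:Side"]
print(f"3-way Map x Session x Side: F({row.df_num:.0f},{row.df_den:.0f}) = "
      f"{row.F:.2f}, p = {row.p:.4f}")
for name in fits.map_names:
    r = stats.per_map.query("map == @name and effect == 'interaction'").iloc[0]
    print(f"{name}: Session x Side F(1,{r.df_den:.0f}) = {r.F:.2f}, "
          f"p = {r.p:.4f}, partial eta^2 = {r.partial_eta_sq:.2f}")
print("paired contrasts (duration fractions):")
for _, r in stats.contrasts.iterrows():
    print(f"  {r['map']} {r['contrast']:<28s} t({r.df}) = {r.t:7.2f}, "
          f"p = {r.p:.4f}")
print("clinically relevant maps:",
      ", ".join(clinically_relevant_maps(stats)) or "none")

mean = fits.wide().groupby(level=["side", "session"]).mean().round(3)
print("group-mean duration fractions:")
print(mean.to_string())
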