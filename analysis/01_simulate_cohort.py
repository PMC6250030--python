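"""Simulate the study cohort with known ground truth.

Generates the default scenario — 10 subjects, 2x2x2 design (puff/sham x
more/less affected x pre/post), shared GFP envelope, crossover template
occupancy in 250-550 ms, behavioral scores linked to map 1's duration —
and writes the ERP dataset, trial counts, behavioral table, flip map and
ground-truth sidecar for the downstream step scripts.
"""

import json

import topoplast as tp
from topoplast.montage import synthetic_montage, write_flip_map

from _common import COHORT_SEED, DATA_DIR, out

cfg = tp.default_config(seed=COHORT_SEED)
dataset, truth = tp.generate_erp_dataset(cfg)
behavior = tp.generate_behavioral_table(cfg, truth)
counts = tp.generate_trial_counts(cfg)
_, _, flip = synthetic_montage(cfg.n_channels)

DATA_DIR.mkdir(parents=True, exist_ok=True)
tp.write_dataset(dataset, DATA_DIR / "erp")
counts.to_csv(DATA_DIR / "trial_counts.csv", index=False)
behavior.to_csv(DATA_DIR / "behavior.csv", index=False)
write_flip_map(flip, DATA_DIR / "flip_map.txt")
(DATA_DIR / "ground_truth.json").write_text(
    json.dumps(truth.to_json_dict()))

truth.durations_frame().to_csv(out("true_map_durations.csv"), index=False)

low = counts.groupby("subject")["n_trials"].min()
print(f"cohort: {cfg.n_subjects} subjects, {cfg.n_channels} channels, "
      f"{cfg.sampling_rate:.0f} Hz, epoch {cfg.epoch_window} ms")
print(f"trial counts {counts.n_trials.min()}-{counts.n_trials.max()} "
      f"(subjects below the 12-trial threshold: "
      f"{sorted(low.index[low < 12])})")
print("planted puff occupancy (map1, map2, map3):")
for (stim, side, sess), frac in cfg.occupancy_schedule.items():
    if stim == "puff":
        print(f"  {side:>14s}/{sess:<4s} {tuple(round(f, 3) for f in frac)}")
print(f"written to {DATA_DIR}")
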