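"""Shared paths and cohort loading for the numbered analysis scripts."""

from pathlib import Path

import pandas as pd

import topoplast as tp

ROOT = Path(__file__).resolve().parents[1]
DATA_DIR = ROOT / "scratch" / "sim_cohort"
RESULTS = ROOT / "results"
COHORT_SEED = 42


def load_cohort():
    """Load the simulated cohort written by 01_simulate_cohort.py and apply
    the structural preprocessing (trial filter, laterality relabeling,
    average reference)."""
    dataset = tp.read_dataset(DATA_DIR / "erp")
    counts = pd.read_csv(DATA_DIR / "trial_counts.csv")
    behavior = pd.read_csv(DATA_DIR / "behavior.csv")
    flip = tp.read_flip_map(DATA_DIR / "flip_map.txt")
    dataset = tp.filter_min_trials(dataset, counts, min_trials=12)
    dataset = tp.relabel_laterality(dataset, flip, "left")
    dataset = tp.apply_average_reference(dataset)
    return dataset, behavior


def out(name: str) -> Path:
    RESULTS.mkdir(exist_ok=True)
    return RESULTS / name
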