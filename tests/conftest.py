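import numpy as np
import pytest

import topoplast as tp
from topoplast.montage import synthetic_montage


@pytest.fixture(scope="session")
def study_bundle():
    """One realization of the default study-conditions scenario.

    Desk-scale geometry (32 channels, 250 Hz), 10 subjects, crossover
    occupancy schedule, behavioral links — shared across tests that only
    read from it.  Returned in common laterality space (relabeled).
    """
    cfg = tp.default_config(seed=3)
    dataset, truth = tp.generate_erp_dataset(cfg)
    table = tp.generate_behavioral_table(cfg, truth)
    counts = tp.generate_trial_counts(cfg)
    _, _, flip = synthetic_montage(cfg.n_channels)
    relabeled = tp.relabel_laterality(dataset, flip, cfg.reference_side)
    return {
        "config": cfg, "dataset": dataset, "relabeled": relabeled,
        "truth": truth, "behavior": table, "counts": counts, "flip": flip,
    }


@pytest.fixture()
def tiny_dataset():
    """Handmade 2-subject, 4-channel dataset with constant-in-time maps."""
    rng = np.random.default_rng(0)
    data = rng.standard_normal((2, 2, 2, 2, 4, 10))
    data -= data.mean(axis=-2, keepdims=True)
    return tp.ErpDataset(
        data=data,
        subjects=["s01", "s02"],
        channels=["c1", "c2", "c3", "c4"],
        sampling_rate=1000.0,
        epoch_window=(0.0, 10.0),
        affected_side={"s01": "left", "s02": "right"},
    )


def fast_config(**overrides):
    """Small, quick simulation config for statistics-heavy tests."""
    overrides.setdefault("n_channels", 16)
    overrides.setdefault("sampling_rate", 125.0)
    overrides.setdefault("randomize_affected_side", False)
    return tp.default_config(**overrides)
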