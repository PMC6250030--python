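"""Time-sample-wise GFP statistics with a minimum-duration criterion.

Response strength is compared across the 2x2 Session x Side design by a
classical repeated-measures ANOVA on subject-level GFP at every
peri-stimulus time sample.  To guard against isolated false positives in
sample-wise testing, only contiguous runs of sub-alpha samples lasting at
least ``min_duration_ms`` (inclusive, default 20 ms) are reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._anova import rm_anova_2x2
from .dataset import ErpDataset, SIDES, SESSIONS
from .metrics import gfp

#: Reported effects of the Session x Side design, in output order.
GFP_EFFECTS = ("side", "session", "interaction")


@dataclass
class TimewiseStatResult:
    """Sample-wise F/p series plus duration-thresholded significant runs."""

    table: pd.DataFrame  # columns: time_ms, effect, F, p
    significant_runs: dict[str, list[tuple[float, float]]]
    alpha: float
    min_duration_ms: float
    window: tuple[float, float]
    meta: dict = field(default_factory=dict)


def enforce_duration(
    p_series: np.ndarray,
    times_ms: np.ndarray,
    alpha: float,
    min_duration_ms: float,
) -> list[tuple[float, float]]:
    """Maximal contiguous runs of ``p < alpha`` lasting >= the threshold.

    Times must be a uniform grid (ms); each sample covers one sampling
    period, so a run of ``n`` samples lasts ``n * dt`` ms and the runs are
    reported half-open ``[start, start + n * dt)``.  A run touching the
    window edge counts if its observed length reaches the threshold.
    """
    p = np.asarray(p_series, dtype=float)
    t = np.asarray(times_ms, dtype=float)
    if p.shape != t.shape:
        raise ValueError("p_series and times_ms must have the same length")
    if len(t) < 2:
        raise ValueError("need at least 2 samples")
    steps = np.diff(t)
    dt = steps[0]
    if not np.allclose(steps, dt, rtol=1e-6, atol=1e-9):
        raise ValueError("time grid is not uniform")

    sig = p < alpha
    runs: list[tuple[float, float]] = []
    i = 0
    n = len(sig)
    while i < n:
        if sig[i]:
            j = i
            while j + 1 < n and sig[j + 1]:
                j += 1
            length_ms = (j - i + 1) * dt
            if length_ms >= min_duration_ms - 1e-9:
                runs.append((float(t[i]), float(t[i] + length_ms)))
            i = j + 1
        else:
            i += 1
    return runs


def gfp_anova(
    dataset: ErpDataset,
    stimulus: str = "puff",
    window: tuple[float, float] = (-100.0, 700.0),
    alpha: float = 0.05,
    min_duration_ms: float = 20.0,
) -> TimewiseStatResult:
    """2-way Session x Side repeated-measures ANOVA on GFP, per time sample.

    GFP is computed per subject, condition and sample (spatial SD, hence
    reference-free); each sample's 2x2 within-subject table is tested with
    exact single-df F statistics.  Runs of significant samples shorter
    than the duration criterion are discarded.
    """
    if dataset.n_subjects < 2:
        raise ValueError("at least 2 subjects are required")
    mask = dataset.time_mask(window)
    times = dataset.times[mask]
    block = dataset.stimulus_block(stimulus)[..., mask]  # (S, side, sess, C, T)
    g = gfp(block, axis=-2)  # (S, side, sess, T)

    res = rm_anova_2x2(g)
    effect_map = {"side": "factor_a", "session": "factor_b",
                  "interaction": "interaction"}
    rows = []
    runs: dict[str, list[tuple[float, float]]] = {}
    for effect in GFP_EFFECTS:
        f_vals, p_vals = res[effect_map[effect]]
        rows.append(pd.DataFrame({
            "time_ms": times, "effect": effect, "F": f_vals, "p": p_vals,
        }))
        runs[effect] = enforce_duration(p_vals, times, alpha, min_duration_ms)
    return TimewiseStatResult(
        table=pd.concat(rows, ignore_index=True),
        significant_runs=runs,
        alpha=alpha,
        min_duration_ms=min_duration_ms,
        window=window,
        meta={"stimulus": stimulus, "factors": {"a": SIDES, "b": SESSIONS},
              "n_subjects": dataset.n_subjects},
    )
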