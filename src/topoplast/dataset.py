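"""Core containers for multi-subject ERP averages in a 2x2x2 within-subject design.

The design crosses Stimulus (puff vs. sham) x Side (more vs. less affected
hand) x Session (pre vs. post intervention).  A dataset holds one
channels-x-time average per subject and condition cell, on a uniform time
grid, together with montage metadata and each subject's affected body side.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

STIMULI = ("puff", "sham")
SIDES = ("more_affected", "less_affected")
SESSIONS = ("pre", "post")

#: All eight condition cells in canonical order.
CONDITIONS = tuple(
    (stim, side, sess) for stim in STIMULI for side in SIDES for sess in SESSIONS
)


class DatasetError(ValueError):
    """Structural problem in an ERP dataset (missing cell, shape mismatch...)."""


def condition_index(stimulus: str, side: str, session: str) -> tuple[int, int, int]:
    """Map condition labels to (stimulus, side, session) axis indices."""
    try:
        return STIMULI.index(stimulus), SIDES.index(side), SESSIONS.index(session)
    except ValueError as exc:
        raise DatasetError(
            f"unknown condition cell ({stimulus!r}, {side!r}, {session!r})"
        ) from exc


@dataclass
class ErpDataset:
    """Per-subject, per-condition ERP averages.

    Parameters
    ----------
    data
        Array of shape ``(n_subjects, 2, 2, 2, n_channels, n_times)`` with
        axes (subject, stimulus, side, session, channel, time), amplitudes
        in microvolts.
    subjects
        Subject identifiers, one per row of the first axis.
    channels
        Channel labels.
    sampling_rate
        Samples per second.
    epoch_window
        ``(start_ms, end_ms)`` of the epoch relative to stimulus onset.
        Sample ``i`` covers ``start_ms + i / rate * 1000`` (half-open grid,
        onset included in post-stimulus).
    affected_side
        Per subject, ``"left"`` or ``"right"`` — which body side is more
        affected.
    positions
        Optional 2-D channel positions (n_channels, 2) for rendering.
    """

    data: np.ndarray
    subjects: list[str]
    channels: list[str]
    sampling_rate: float
    epoch_window: tuple[float, float]
    affected_side: dict[str, str]
    positions: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 6 or self.data.shape[1:4] != (2, 2, 2):
            raise DatasetError(
                "data must have shape (n_subjects, 2, 2, 2, n_channels, n_times); "
                f"got {self.data.shape}"
            )
        n_sub, _, _, _, n_ch, n_t = self.data.shape
        if n_sub != len(self.subjects):
            raise DatasetError(
                f"{len(self.subjects)} subject labels for {n_sub} data rows"
            )
        if n_ch != len(self.channels):
            raise DatasetError(
                f"{len(self.channels)} channel labels for {n_ch} data rows"
            )
        if n_ch < 2:
            raise DatasetError("at least 2 channels are required")
        start, end = self.epoch_window
        expected = int(round((end - start) / 1000.0 * self.sampling_rate))
        if expected != n_t:
            raise DatasetError(
                f"epoch window {self.epoch_window} ms at {self.sampling_rate} Hz "
                f"implies {expected} samples, data has {n_t}"
            )
        missing = [s for s in self.subjects if s not in self.affected_side]
        if missing:
            raise DatasetError(f"affected_side missing for subjects {missing}")

    # ------------------------------------------------------------------ axes

    @property
    def n_subjects(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[4]

    @property
    def n_times(self) -> int:
        return self.data.shape[5]

    @property
    def times(self) -> np.ndarray:
        """Time axis in ms (one value per sample, half-open grid)."""
        start = self.epoch_window[0]
        step = 1000.0 / self.sampling_rate
        return start + step * np.arange(self.n_times)

    def time_mask(self, window: tuple[float, float]) -> np.ndarray:
        """Boolean mask for samples with ``window[0] <= t < window[1]`` ms."""
        lo, hi = window
        t = self.times
        if lo < self.epoch_window[0] - 1e-9 or hi > self.epoch_window[1] + 1e-9:
            raise DatasetError(
                f"window {window} outside epoch {self.epoch_window}"
            )
        return (t >= lo - 1e-9) & (t < hi - 1e-9)

    # --------------------------------------------------------------- access

    def get(self, subject: str, stimulus: str, side: str, session: str) -> np.ndarray:
        """One channels-x-time matrix for a subject and condition cell."""
        i = self.subjects.index(subject)
        a, b, c = condition_index(stimulus, side, session)
        return self.data[i, a, b, c]

    def stimulus_block(self, stimulus: str) -> np.ndarray:
        """All data for one stimulus: (n_subjects, 2, 2, n_channels, n_times)."""
        return self.data[:, STIMULI.index(stimulus)]

    def group_mean(self, stimulus: str, side: str, session: str) -> np.ndarray:
        """Group-average ERP (channels x time) for one condition cell."""
        a, b, c = condition_index(stimulus, side, session)
        return self.data[:, a, b, c].mean(axis=0)

    def copy_with(self, **changes) -> "ErpDataset":
        if "data" not in changes:
            changes["data"] = self.data.copy()
        if "meta" not in changes:
            changes["meta"] = dict(self.meta)
        return replace(self, **changes)


def check_full_crossing(present: Sequence[tuple[str, str, str]]) -> None:
    """Raise listing any condition cell absent from `present`."""
    missing = [c for c in CONDITIONS if c not in set(present)]
    if missing:
        raise DatasetError(f"missing condition cells: {missing}")
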