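"""Reference-independent field metrics: GFP, DISS and spatial correlation.

All metrics are computed on average-referenced scalp maps, so they are
invariant to the recording reference.  Global field power (GFP) is the
spatial standard deviation of a map — after subtracting the spatial mean,
the root mean square across channels equals the standard deviation, which
is why the two phrasings describe the same quantity.  Global dissimilarity
(DISS) between two maps is the RMS of the difference of their GFP-normalized
versions; it ranges from 0 (identical topography) to 2 (polarity inversion)
and relates to the spatial Pearson correlation r by ``DISS**2 = 2 * (1 - r)``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .dataset import SIDES, SESSIONS, ErpDataset

#: Maps with GFP below this are treated as degenerate (spatially constant).
GFP_TOL = 1e-12


class DegenerateMapError(ValueError):
    """A metric was requested on a spatially constant (zero-GFP) map."""


def average_reference(values: np.ndarray, axis: int = -1) -> np.ndarray:
    """Subtract the spatial mean across channels along `axis`."""
    values = np.asarray(values, dtype=float)
    return values - values.mean(axis=axis, keepdims=True)


def gfp(values: np.ndarray, axis: int = -1) -> np.ndarray:
    """Global field power: spatial SD across channels along `axis`.

    The spatial mean is subtracted internally, so the result does not
    depend on the recording reference.
    """
    values = np.asarray(values, dtype=float)
    if values.shape[axis] < 2:
        raise ValueError("GFP requires at least 2 channels")
    centred = average_reference(values, axis=axis)
    return np.sqrt(np.mean(centred**2, axis=axis))


def normalize_by_gfp(values: np.ndarray, axis: int = -1) -> np.ndarray:
    """Scale a map (or stack of maps) to unit GFP, preserving direction.

    Raises :class:`DegenerateMapError` if any map is spatially constant.
    """
    centred = average_reference(values, axis=axis)
    g = np.sqrt(np.mean(centred**2, axis=axis, keepdims=True))
    if np.any(g < GFP_TOL):
        raise DegenerateMapError("cannot GFP-normalize a spatially constant map")
    return centred / g


def diss(map_a: np.ndarray, map_b: np.ndarray, axis: int = -1) -> np.ndarray:
    """Global dissimilarity between two maps, in [0, 2].

    Both maps are average-referenced and GFP-normalized internally; the
    result is the RMS of their channel-wise difference and is symmetric in
    its arguments.
    """
    ua = normalize_by_gfp(map_a, axis=axis)
    ub = normalize_by_gfp(map_b, axis=axis)
    return np.sqrt(np.mean((ua - ub) ** 2, axis=axis))


def spatial_correlation(map_a: np.ndarray, map_b: np.ndarray, axis: int = -1) -> np.ndarray:
    """Pearson correlation across channels of two average-referenced maps.

    Satisfies ``diss(a, b)**2 == 2 * (1 - spatial_correlation(a, b))`` to
    float tolerance.
    """
    ua = normalize_by_gfp(map_a, axis=axis)
    ub = normalize_by_gfp(map_b, axis=axis)
    return np.mean(ua * ub, axis=axis)


def gfp_series(dataset: ErpDataset) -> np.ndarray:
    """GFP per subject, condition and time sample: (n_sub, 2, 2, 2, n_times)."""
    return gfp(dataset.data, axis=-2)


def spatial_correlation_series(
    dataset: ErpDataset,
    reference_condition: tuple[str, str] = ("less_affected", "pre"),
    stimulus: str = "puff",
    window: tuple[float, float] | None = None,
) -> pd.DataFrame:
    """Moment-by-moment spatial correlation of each condition's group-average
    topography with a reference condition's.

    The reference is a (side, session) cell of the given stimulus; the study
    design uses the pre-intervention less-affected-hand response, against
    which the other cells are tracked over time.  Samples where either group
    map is degenerate yield NaN.

    Returns a tidy frame with columns ``side``, ``session``, ``time_ms``,
    ``correlation``.
    """
    mask = (
        dataset.time_mask(window) if window is not None
        else np.ones(dataset.n_times, dtype=bool)
    )
    times = dataset.times[mask]
    ref_side, ref_session = reference_condition
    ref = dataset.group_mean(stimulus, ref_side, ref_session)[:, mask]  # (C, T)

    rows = []
    for side in SIDES:
        for session in SESSIONS:
            if (side, session) == (ref_side, ref_session):
                continue
            other = dataset.group_mean(stimulus, side, session)[:, mask]
            r = _corr_columns(ref, other)
            rows.append(pd.DataFrame({
                "side": side,
                "session": session,
                "time_ms": times,
                "correlation": r,
            }))
    return pd.concat(rows, ignore_index=True)


def _corr_columns(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Columnwise spatial correlation of two (channels x time) arrays.

    Degenerate columns (zero GFP in either map) give NaN rather than an
    arbitrary value.
    """
    a = average_reference(a, axis=0)
    b = average_reference(b, axis=0)
    ga = np.sqrt(np.mean(a**2, axis=0))
    gb = np.sqrt(np.mean(b**2, axis=0))
    ok = (ga >= GFP_TOL) & (gb >= GFP_TOL)
    r = np.full(a.shape[1], np.nan)
    r[ok] = np.mean(a[:, ok] * b[:, ok], axis=0) / (ga[ok] * gb[ok])
    return r
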