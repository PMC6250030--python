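"""Randomization-based topographic ANOVA (TANOVA) for the 2x2 within design.

Tests whether the *configuration* of the scalp field — independent of its
strength — differs with Session, Side, or their interaction.  Per time
sample, every subject-condition map is average-referenced and normalized
to unit GFP; the effect statistic is the GFP of the relevant contrast of
the cell-mean maps (a generalized-dissimilarity measure of the effect
topography: for unit-GFP maps ``DISS^2 = 2 (1 - r)``, so a larger contrast
GFP means a larger topographic difference).  The null distribution is
built by restricted permutations that rearrange condition labels only
*within* each subject: for a main effect, the two levels of the tested
factor are swapped (consistently across the untested factor) in a random
subset of subjects; for the interaction, one factor's levels are swapped
within a random subset of subjects after the statistic is reduced to the
subject-level double-difference map.  Either transformation simply flips
the sign of the subject's contrast map, so the scheme is the exact
sign-flip randomization of the per-subject effect contrast — valid in the
presence of the other effects, because the tested contrast annihilates
them.  (Permuting the four within-subject residual maps across cells is
*not* used: after residualizing, a 2x2 within-subject cell structure has
a single degree of freedom per subject, and cell permutations collapse
most subjects' contributions to zero, biasing the null downward.)

p-values use the add-one rule ``(#{null >= observed} + 1) / (n_perm + 1)``
so they are never zero, and the same >= 20 ms duration criterion as the
GFP analysis prunes isolated significant samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataset import ErpDataset
from .metrics import GFP_TOL, average_reference
from .pointwise import enforce_duration

EFFECTS = ("side", "session", "interaction")

#: Contrast coefficients over cells ordered (side, session) row-major:
#: (more/pre, more/post, less/pre, less/post).
_COEFFS = {
    "side": np.array([+1.0, +1.0, -1.0, -1.0]) / 4.0,
    "session": np.array([+1.0, -1.0, +1.0, -1.0]) / 4.0,
    "interaction": np.array([+1.0, -1.0, -1.0, +1.0]) / 4.0,
}


@dataclass
class PermutationResult:
    """Observed statistic and permutation p per sample, plus pruned runs."""

    effect: str
    times_ms: np.ndarray
    statistic: np.ndarray
    p: np.ndarray
    significant_runs: list[tuple[float, float]]
    n_permutations: int
    seed: int
    alpha: float
    min_duration_ms: float
    meta: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time_ms": self.times_ms, "effect": self.effect,
            "statistic": self.statistic, "p": self.p,
        })


def effect_statistic(cell_maps: np.ndarray, effect: str) -> float:
    """Generalized-dissimilarity statistic from 2x2 unit-GFP group maps.

    `cell_maps` has shape (2, 2, C) with axes (side, session, channel).
    The statistic is the GFP of the contrast map — the double difference
    ``(m11 - m12 - m21 + m22) / 4`` for the interaction, half the
    difference of marginal means for a main effect.  Identical cell means
    give exactly 0.
    """
    if effect not in _COEFFS:
        raise ValueError(f"unknown effect {effect!r}; choose from {EFFECTS}")
    maps = np.asarray(cell_maps, dtype=float).reshape(4, -1)
    contrast = _COEFFS[effect] @ maps
    contrast -= contrast.mean()
    return float(np.sqrt(np.mean(contrast**2)))


def _normalized_cells(
    dataset: ErpDataset, stimulus: str, mask: np.ndarray
) -> np.ndarray:
    """Unit-GFP subject maps, shape (S, 4 cells, C, T); degenerate maps
    (spatially constant) are zeroed so they contribute nothing."""
    block = dataset.stimulus_block(stimulus)[..., mask]  # (S, 2, 2, C, T)
    s, _, _, c, t = block.shape
    cells = average_reference(block.reshape(s, 4, c, t), axis=2)
    g = np.sqrt(np.mean(cells**2, axis=2, keepdims=True))
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(g > GFP_TOL, cells / np.where(g > 0, g, 1.0), 0.0)
    return out


def tanova(
    dataset: ErpDataset,
    stimulus: str = "puff",
    effect: str = "interaction",
    n_permutations: int = 999,
    seed: int = 0,
    alpha: float = 0.05,
    min_duration_ms: float = 20.0,
    window: tuple[float, float] = (-100.0, 700.0),
) -> PermutationResult:
    """Sample-wise TANOVA for one effect of the Session x Side design."""
    if effect not in _COEFFS:
        raise ValueError(f"unknown effect {effect!r}; choose from {EFFECTS}")
    if n_permutations < 99:
        raise ValueError("n_permutations must be >= 99")
    if dataset.n_subjects < 2:
        raise ValueError("at least 2 subjects are required")
    rng = np.random.default_rng(seed)
    mask = dataset.time_mask(window)
    times = dataset.times[mask]
    cells = _normalized_cells(dataset, stimulus, mask)  # (S, 4, C, T)
    n_sub, _, n_ch, n_t = cells.shape

    # per-subject contrast map; a within-subject label swap of the tested
    # factor (consistent across the untested one) flips its sign, so the
    # restricted permutation group acts as per-subject sign flips
    d = np.tensordot(_COEFFS[effect], cells, axes=(0, 1))  # (S, C, T)
    obs_contrast = d.mean(axis=0)
    signs = rng.integers(0, 2, size=(n_permutations, n_sub)) * 2 - 1
    null_contrast = np.einsum("ps,sct->pct", signs, d) / n_sub

    obs_contrast = obs_contrast - obs_contrast.mean(axis=0, keepdims=True)
    null_contrast = null_contrast - null_contrast.mean(axis=1, keepdims=True)
    obs = np.sqrt(np.mean(obs_contrast**2, axis=0))  # (T,)
    null = np.sqrt(np.mean(null_contrast**2, axis=1))  # (P, T)

    p = (np.sum(null >= obs[None, :] - 1e-15, axis=0) + 1.0) / (
        n_permutations + 1.0
    )
    runs = enforce_duration(p, times, alpha, min_duration_ms)
    return PermutationResult(
        effect=effect,
        times_ms=times,
        statistic=obs,
        p=p,
        significant_runs=runs,
        n_permutations=n_permutations,
        seed=seed,
        alpha=alpha,
        min_duration_ms=min_duration_ms,
        meta={"stimulus": stimulus, "n_subjects": n_sub,
              "n_channels": n_ch, "n_samples": n_t},
    )
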