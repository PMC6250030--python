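"""Topographic clustering, model selection, back-fitting and duration stats.

The segmentation follows the atomize-and-agglomerate hierarchical scheme
(AAHC): every GFP-normalized time-sample map starts as its own cluster;
at each step the cluster contributing least explained variance is
dissolved and its members are reassigned to the remaining cluster whose
centroid they correlate with best.  Because maps are normalized first the
procedure is sensitive only to topography, and it makes no orthogonality
assumption about the derived template maps.  Polarity is treated as
meaningful (these are evoked responses, not spontaneous microstates), so
signed spatial correlation drives both reassignment and back-fitting.

The number of clusters is chosen by a modified Krzanowski-Lai criterion:
an elbow index on the within-cluster dispersion curve W(k) (dissimilarity
based), forced to zero at the ends of the candidate range and wherever the
dispersion fails to improve, with ties broken toward the smaller k.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._anova import anova_rm_long, paired_t, rm_anova_2x2
from .dataset import SESSIONS, SIDES, ErpDataset
from .metrics import GFP_TOL, average_reference


class ClusteringError(ValueError):
    pass


@dataclass
class SegmentationResult:
    """AAHC segmentations for every candidate k, plus model selection.

    ``templates[k]`` is a (k, n_channels) array of unit-GFP maps;
    ``labels[k]`` assigns each input sample map to a template row;
    ``gev[k]`` is the global explained variance and ``dispersion[k]`` the
    within-cluster DISS^2 sum W(k).  ``kl`` and ``k_opt`` are filled by
    :func:`select_k_krzanowski_lai`.
    """

    templates: dict[int, np.ndarray]
    labels: dict[int, np.ndarray]
    gev: dict[int, float]
    dispersion: dict[int, float]
    sample_info: pd.DataFrame  # side, session, time_ms per input map
    k_range: tuple[int, int]
    kl: dict[int, float] = field(default_factory=dict)
    k_opt: int | None = None


def _unit(maps: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Average-reference + unit-GFP rows; returns (units, gfp, ok_mask)."""
    centred = average_reference(maps, axis=1)
    g = np.sqrt(np.mean(centred**2, axis=1))
    ok = g > GFP_TOL
    units = np.zeros_like(centred)
    units[ok] = centred[ok] / g[ok, None]
    return units, g, ok


def _centroid(units: np.ndarray) -> np.ndarray:
    """Unit-GFP centroid of a set of unit maps (signed mean)."""
    mean = units.mean(axis=0)
    mean -= mean.mean()
    g = np.sqrt(np.mean(mean**2))
    if g < GFP_TOL:
        # members cancel; fall back to the first member's direction
        return units[0].copy()
    return mean / g


def cluster_topographies(
    group_erps: dict[tuple[str, str], np.ndarray],
    times_ms: np.ndarray,
    k_range: tuple[int, int] = (1, 8),
) -> SegmentationResult:
    """AAHC segmentation of condition-mean ERP maps in a time window.

    Parameters
    ----------
    group_erps
        Per (side, session) cell, a (n_channels, n_window_samples)
        group-average ERP restricted to the analysis window.
    times_ms
        The window time axis (shared by all cells).
    k_range
        Inclusive candidate range for the number of template maps.
    """
    if not group_erps:
        raise ClusteringError("no group ERPs given")
    cells = list(group_erps)
    stack = np.concatenate(
        [np.asarray(group_erps[c], float).T for c in cells], axis=0
    )  # (N, C)
    info = pd.DataFrame({
        "side": np.repeat([c[0] for c in cells], len(times_ms)),
        "session": np.repeat([c[1] for c in cells], len(times_ms)),
        "time_ms": np.tile(times_ms, len(cells)),
    })
    if stack.shape[0] == 0:
        raise ClusteringError("empty analysis window")
    units, gfp_w, ok = _unit(stack)
    if not ok.any():
        raise ClusteringError("all window maps are spatially constant")
    units, gfp_w, info = units[ok], gfp_w[ok], info.loc[ok].reset_index(drop=True)
    n, n_ch = units.shape
    k_min, k_max = k_range
    if not (1 <= k_min <= k_max <= n):
        raise ClusteringError(f"k_range {k_range} not within [1, {n}]")
    weights = gfp_w**2

    labels = np.arange(n)
    centroids = {i: units[i].copy() for i in range(n)}
    result = SegmentationResult({}, {}, {}, {}, info, k_range)

    def snapshot(k: int) -> None:
        ids = sorted(centroids)
        remap = {c: j for j, c in enumerate(ids)}
        lab = np.array([remap[c] for c in labels])
        cent = np.stack([centroids[c] for c in ids])
        r = np.mean(units * cent[lab], axis=1)
        result.templates[k] = cent
        result.labels[k] = lab
        result.gev[k] = float((weights * r**2).sum() / weights.sum())
        # rounding can push |r| a few ulp above 1; dispersion is >= 0
        result.dispersion[k] = float(np.sum(np.maximum(2.0 * (1.0 - r), 0.0)))

    if n <= k_max:
        snapshot(n)
    while len(centroids) > k_min:
        ids = sorted(centroids)
        cent = np.stack([centroids[c] for c in ids])
        col = {c: j for j, c in enumerate(ids)}
        r_all = units @ cent.T / n_ch  # (N, k) signed correlations
        own_col = np.array([col[c] for c in labels])
        own = r_all[np.arange(n), own_col] ** 2
        masked = r_all**2
        masked[np.arange(n), own_col] = -np.inf
        best_other = masked.max(axis=1)
        # a cluster's contribution is the explained variance actually lost
        # by dissolving it (members fall back to their next-best centroid);
        # redundant near-duplicate clusters cost ~0 and dissolve first
        loss = weights * (own - best_other)
        contrib = {c: float(loss[labels == c].sum()) for c in ids}
        worst = min(ids, key=lambda c: contrib[c])
        freed = np.flatnonzero(labels == worst)
        del centroids[worst]
        keep_cols = [col[c] for c in sorted(centroids)]
        r_free = r_all[np.ix_(freed, keep_cols)]
        labels[freed] = np.array(sorted(centroids))[np.argmax(r_free, axis=1)]
        # refresh all centroids (cheap, keeps them exact after each step)
        for c in sorted(centroids):
            centroids[c] = _centroid(units[labels == c])
        if k_min <= len(centroids) <= k_max:
            snapshot(len(centroids))
    return result


def select_k_krzanowski_lai(
    result: SegmentationResult, dimensionality: int | None = None
) -> int:
    """Pick the number of template maps by the modified Krzanowski-Lai index.

    ``DIFF(k) = (k-1)^(2/m) W(k-1) - k^(2/m) W(k)`` measures the drop of
    the scaled dispersion curve W between consecutive k; the index
    ``KL(k) = DIFF(k) / DIFF(k+1)`` peaks at the elbow, where a large
    drop is followed by a flat tail.  The modification forces the index
    to zero (i) at the ends of the candidate range, (ii) wherever the
    dispersion does not decrease, and (iii) wherever the drop at k is
    negligible — below 5% of the total dispersion range — since a ratio
    of two near-zero drops in the flat tail is numerical noise, not an
    elbow.  Ties break toward the smaller k (parsimony).  m is the
    topographic dimensionality (channels - 1 under the average
    reference).
    """
    ks = sorted(result.dispersion)
    if len(ks) < 3:
        raise ClusteringError(
            f"k_range {result.k_range} too narrow for the KL criterion "
            "(need at least 3 candidate k)"
        )
    if dimensionality is None:
        dimensionality = result.templates[ks[0]].shape[1] - 1
    expo = 2.0 / dimensionality
    w = {k: result.dispersion[k] for k in ks}

    def diff(k: int) -> float:
        return (k - 1) ** expo * w[k - 1] - k**expo * w[k]

    scaled = {k: k**expo * w[k] for k in ks}
    span = scaled[ks[0]] - min(scaled.values())
    if span < 1e-9:  # flat dispersion curve: nothing left to explain
        span = np.inf
    floor = 0.05 * span
    kl: dict[int, float] = {ks[0]: 0.0, ks[-1]: 0.0}
    for k in ks[1:-1]:
        d_k, d_next = diff(k), diff(k + 1)
        if d_k <= floor or w[k] > w[k - 1]:
            kl[k] = 0.0
        elif d_next <= 0:
            kl[k] = np.inf
        else:
            kl[k] = d_k / d_next
    result.kl = kl
    best = max(kl.values())
    if best <= 0:
        warnings.warn(
            "Krzanowski-Lai index degenerate (no elbow); falling back to "
            f"the smallest candidate k = {ks[0]}", stacklevel=2,
        )
        result.k_opt = ks[0]
    else:
        result.k_opt = min(k for k, v in kl.items() if v == best)
    return result.k_opt


# --------------------------------------------------------------------------
# back-fitting


@dataclass
class FitDurations:
    """Per subject x condition x map: fraction of window samples assigned.

    Fractions per subject and condition sum to 1 including the
    ``unlabeled`` share (degenerate samples no template can claim).
    """

    frame: pd.DataFrame  # subject, side, session, map, fraction
    labels: np.ndarray  # (S, 2, 2, n_window) template index, -1 = unlabeled
    map_names: list[str]
    window: tuple[float, float]
    stimulus: str

    def wide(self, include_unlabeled: bool = False) -> pd.DataFrame:
        frame = self.frame
        if not include_unlabeled:
            frame = frame[frame["map"] != "unlabeled"]
        return frame.pivot_table(
            index=["subject", "side", "session"], columns="map",
            values="fraction", sort=False,
        )


def backfit(
    dataset: ErpDataset,
    templates: np.ndarray,
    window: tuple[float, float] = (250.0, 550.0),
    stimulus: str = "puff",
) -> FitDurations:
    """Label every single-subject sample with its best-correlated template.

    The winner is the template with the highest *signed* spatial
    correlation.  On an exact tie the previous sample's label is kept if
    it is among the tied set (temporal stability), else the lowest
    template index wins.  Spatially constant samples stay unlabeled.
    """
    templates = np.asarray(templates, dtype=float)
    if templates.ndim != 2 or templates.shape[0] == 0:
        raise ClusteringError("empty template list")
    tmpl, _, t_ok = _unit(templates)
    if not t_ok.all():
        raise ClusteringError("templates must be non-degenerate maps")
    k, n_ch = tmpl.shape
    mask = dataset.time_mask(window)
    block = dataset.stimulus_block(stimulus)[..., mask]  # (S, 2, 2, C, T)
    n_sub = block.shape[0]
    n_win = int(mask.sum())

    centred = average_reference(block, axis=-2)
    g = np.sqrt(np.mean(centred**2, axis=-2))  # (S, 2, 2, T)
    ok = g > GFP_TOL
    units = np.where(
        ok[..., None, :], centred / np.where(g > 0, g, 1.0)[..., None, :], 0.0
    )
    corr = np.einsum("kc,abdct->abdkt", tmpl, units) / n_ch  # (S,2,2,k,T)

    labels = np.full((n_sub, 2, 2, n_win), -1, dtype=int)
    tol = 1e-12
    for i in range(n_sub):
        for b in range(2):
            for c in range(2):
                r = corr[i, b, c]  # (k, T)
                win = np.argmax(r, axis=0)
                top = r[win, np.arange(n_win)]
                prev = -1
                for t in range(n_win):
                    if not ok[i, b, c, t]:
                        prev = -1
                        continue
                    tied = np.flatnonzero(r[:, t] >= top[t] - tol)
                    if len(tied) > 1 and prev in tied:
                        labels[i, b, c, t] = prev
                    else:
                        labels[i, b, c, t] = tied[0]
                    prev = labels[i, b, c, t]

    map_names = [f"map{m + 1}" for m in range(k)]
    rows = []
    for i, subject in enumerate(dataset.subjects):
        for b, side in enumerate(SIDES):
            for c, session in enumerate(SESSIONS):
                lab = labels[i, b, c]
                for m, name in enumerate(map_names):
                    rows.append({
                        "subject": subject, "side": side, "session": session,
                        "map": name, "fraction": np.mean(lab == m),
                    })
                rows.append({
                    "subject": subject, "side": side, "session": session,
                    "map": "unlabeled", "fraction": np.mean(lab == -1),
                })
    return FitDurations(
        frame=pd.DataFrame(rows),
        labels=labels,
        map_names=map_names,
        window=window,
        stimulus=stimulus,
    )


# --------------------------------------------------------------------------
# duration statistics


@dataclass
class DurationAnovaResult:
    three_way: pd.DataFrame
    per_map: pd.DataFrame
    contrasts: pd.DataFrame


def duration_anova(fit: FitDurations, alpha: float = 0.05) -> DurationAnovaResult:
    """Map x Session x Side ANOVA on durations, per-map 2x2 follow-ups and
    the planned paired contrasts.

    The three-way within-subject ANOVA uses the template maps as the Map
    factor (the unlabeled share is excluded — it is the complement of the
    others).  Each map then gets its own Session x Side ANOVA with partial
    eta squared, plus paired two-sided t contrasts for (i) the pre-
    intervention more- vs. less-affected difference and (ii) the pre- vs.
    post change within each hand.
    """
    frame = fit.frame[fit.frame["map"] != "unlabeled"].copy()
    n_sub = frame["subject"].nunique()
    if n_sub < 2:
        raise ValueError("at least 2 subjects are required")
    counts = frame.groupby(["subject"]).size()
    expected = 4 * len(fit.map_names)
    bad = counts[counts != expected]
    if len(bad):
        raise ValueError(f"incomplete crossing for subjects {list(bad.index)}")

    three = anova_rm_long(
        frame.rename(columns={"map": "Map", "session": "Session",
                              "side": "Side"}),
        dv="fraction", subject="subject", within=["Map", "Session", "Side"],
    ).reset_index(names="effect")

    per_map_rows, contrast_rows = [], []
    for name in fit.map_names:
        wide = (
            frame[frame["map"] == name]
            .pivot_table(index="subject", columns=["side", "session"],
                         values="fraction", sort=False)
        )
        y = np.stack([
            [[wide[(side, sess)].to_numpy() for sess in SESSIONS]
             for side in SIDES]
        ])[0]  # (side, session, S)
        y = np.moveaxis(y, -1, 0)  # (S, side, session)
        res = rm_anova_2x2(y)
        for effect, key in (("side", "factor_a"), ("session", "factor_b"),
                            ("interaction", "interaction")):
            f, p = res[key]
            per_map_rows.append({
                "map": name, "effect": effect, "F": float(f),
                "df_num": 1, "df_den": n_sub - 1, "p": float(p),
                "partial_eta_sq": float(f / (f + (n_sub - 1)))
                if np.isfinite(f) else 1.0,
            })
        more_pre = y[:, 0, 0]
        less_pre = y[:, 1, 0]
        t, p, df = paired_t(more_pre, less_pre)
        contrast_rows.append({"map": name, "contrast": "pre: more vs less",
                              "t": t, "df": df, "p": p})
        for b, side in enumerate(SIDES):
            t, p, df = paired_t(y[:, b, 1], y[:, b, 0])
            contrast_rows.append({
                "map": name, "contrast": f"{side}: post vs pre",
                "t": t, "df": df, "p": p,
            })
    return DurationAnovaResult(
        three_way=three,
        per_map=pd.DataFrame(per_map_rows),
        contrasts=pd.DataFrame(contrast_rows),
    )


def clinically_relevant_maps(
    result: DurationAnovaResult, alpha: float = 0.05
) -> list[str]:
    """Maps whose Session x Side interaction is significant *and* whose
    pre-intervention duration differs between hands — the selection rule
    used to focus the brain-behavior step."""
    inter = result.per_map.query("effect == 'interaction' and p < @alpha")
    pre_diff = result.contrasts.query(
        "contrast == 'pre: more vs less' and p < @alpha"
    )
    return [m for m in inter["map"] if m in set(pre_diff["map"])]
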