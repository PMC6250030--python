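"""Brain-behavior statistics on the sensory and sensory-motor score table.

Covers the three inferential pieces of the behavioral step: one-tailed
paired comparisons between hands (directional hypothesis: the less
affected hand performs better), two-sided pre/post change tests per hand,
and Spearman correlations between a template map's duration and the
scores, pooling the two hands of each subject as individual data points
(2 x n_subjects pairs).  An explicit between-hand correlation diagnostic
is reported alongside the pooled correlation, mirroring the independence
check that motivates the pooling; it is informative, not a gate.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._anova import paired_t
from .dataset import SIDES
from .simulate import BEHAVIOR_TESTS

#: Exact permutation p-values up to this many pooled points; a seeded
#: 10,000-draw permutation p up to 10; the t approximation beyond.
EXACT_N = 8
MC_N = 10
MC_DRAWS = 10_000


class BehaviorError(ValueError):
    pass


@dataclass
class CorrelationResult:
    rho: float
    n: int
    p: float
    variables: tuple[str, str]
    method: str
    degenerate: bool = False


def _pivot_scores(table: pd.DataFrame, test: str, session: str) -> pd.DataFrame:
    sub = table.query("test == @test and session == @session")
    if sub.empty:
        raise BehaviorError(f"no scores for test {test!r}, session {session!r}")
    return sub.pivot_table(index="subject", columns="side", values="score",
                           sort=False)


def paired_hand_tests(
    table: pd.DataFrame, session: str = "pre", one_tailed: bool = True
) -> pd.DataFrame:
    """Per-test paired t comparing hands within one session.

    Scores are oriented so that higher means better performance before
    differencing; the one-tailed alternative is that the less affected
    hand performs better.  Returns a tidy frame (test, t, df, p, n).
    """
    rows = []
    for test in table["test"].unique():
        wide = _pivot_scores(table, test, session).dropna()
        if len(wide) < 3:
            raise BehaviorError(
                f"test {test!r}: only {len(wide)} complete pairs (need >= 3)"
            )
        direction = BEHAVIOR_TESTS.get(test, ("", +1))[1]
        less = direction * wide["less_affected"].to_numpy()
        more = direction * wide["more_affected"].to_numpy()
        alt = "greater" if one_tailed else "two-sided"
        t, p, df = paired_t(less, more, alternative=alt)
        rows.append({"test": test, "session": session, "t": t, "df": df,
                     "p": p, "n": len(wide),
                     "degenerate": not np.isfinite(t)})
    return pd.DataFrame(rows)


def pre_post_change_tests(table: pd.DataFrame) -> pd.DataFrame:
    """Two-sided paired t of post vs. pre scores, per test and hand."""
    rows = []
    for test in table["test"].unique():
        for side in SIDES:
            sub = table.query("test == @test and side == @side")
            wide = sub.pivot_table(index="subject", columns="session",
                                   values="score", sort=False).dropna()
            if len(wide) < 3:
                raise BehaviorError(
                    f"test {test!r}, {side}: fewer than 3 complete pairs"
                )
            t, p, df = paired_t(wide["post"].to_numpy(),
                                wide["pre"].to_numpy())
            rows.append({"test": test, "side": side, "t": t, "df": df,
                         "p": p, "n": len(wide)})
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# pooled-hand Spearman correlation


def spearman(
    x: np.ndarray, y: np.ndarray, seed: int = 0
) -> tuple[float, float, str]:
    """Spearman rho with average ranks and a two-sided p-value.

    Small samples get permutation inference (exact enumeration up to
    8 points, a seeded Monte-Carlo permutation p up to 10); larger
    samples use the usual t approximation.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    if n < 3:
        raise BehaviorError("need at least 3 points")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    if np.std(rx) == 0 or np.std(ry) == 0:
        return np.nan, np.nan, "degenerate"
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if n <= EXACT_N:
        perms = np.array(list(itertools.permutations(range(n))))
        rho_null = _rank_corr_batch(rx, ry[perms])
        p = float(np.mean(np.abs(rho_null) >= abs(rho) - 1e-12))
        return rho, p, "exact permutation"
    if n <= MC_N:
        rng = np.random.default_rng(seed)
        idx = np.array([rng.permutation(n) for _ in range(MC_DRAWS)])
        rho_null = _rank_corr_batch(rx, ry[idx])
        p = float((np.sum(np.abs(rho_null) >= abs(rho) - 1e-12) + 1)
                  / (MC_DRAWS + 1))
        return rho, p, "monte-carlo permutation"
    # t approximation on n-2 df
    t = rho * np.sqrt((n - 2) / max(1e-12, 1.0 - rho**2))
    p = float(2 * stats.t.sf(abs(t), n - 2))
    return rho, p, "t approximation"


def _rank_corr_batch(rx: np.ndarray, ry_perm: np.ndarray) -> np.ndarray:
    """Pearson correlation of a rank vector with many permuted rank rows."""
    rx_c = rx - rx.mean()
    ry_c = ry_perm - ry_perm.mean(axis=1, keepdims=True)
    num = ry_c @ rx_c
    den = np.sqrt((rx_c**2).sum() * (ry_c**2).sum(axis=1))
    return num / den


def _duration_points(
    durations: pd.DataFrame, map_label: str, session: str | None, change: bool
) -> pd.DataFrame:
    d = durations[durations["map"] == map_label]
    if d.empty:
        raise BehaviorError(f"no durations for map {map_label!r}")
    wide = d.pivot_table(index=["subject", "side"], columns="session",
                         values="fraction", sort=False)
    if change:
        out = (wide["post"] - wide["pre"]).rename("x")
    else:
        out = wide[session].rename("x")
    return out.reset_index()


def pooled_hand_correlation(
    durations: pd.DataFrame | "object",
    table: pd.DataFrame,
    map_label: str,
    measure: str,
    session: str | None = "pre",
    change: bool = False,
    seed: int = 0,
) -> CorrelationResult:
    """Spearman correlation of a map's duration with a behavioral score,
    pooling both hands of every subject as individual points.

    With ``change=True`` the pre-to-post change of both variables is
    correlated instead of a single session's values.  `durations` may be
    a tidy frame (subject, side, session, map, fraction) or a
    ``FitDurations`` object.
    """
    if hasattr(durations, "frame"):
        durations = durations.frame
    x = _duration_points(durations, map_label, session, change)

    scores = table[table["test"] == measure]
    if scores.empty:
        raise BehaviorError(f"no scores for measure {measure!r}")
    wide = scores.pivot_table(index=["subject", "side"], columns="session",
                              values="score", sort=False)
    y = ((wide["post"] - wide["pre"]) if change else wide[session]).rename("y")
    merged = x.merge(y.reset_index(), on=["subject", "side"]).dropna()

    rho, p, method = spearman(merged["x"].to_numpy(), merged["y"].to_numpy(),
                              seed=seed)
    label = f"{map_label} duration" + (" change" if change else f" ({session})")
    score_label = measure + (" change" if change else f" ({session})")
    return CorrelationResult(
        rho=rho, n=len(merged), p=p,
        variables=(label, score_label), method=method,
        degenerate=(method == "degenerate"),
    )


def between_hand_independence(
    durations: pd.DataFrame | "object",
    table: pd.DataFrame,
    map_label: str,
    measure: str,
    session: str = "pre",
) -> pd.DataFrame:
    """Between-hand correlation diagnostic for the pooled analysis.

    Reports, per variable, the Spearman correlation of the two hands'
    values across subjects.  High dependence would argue against treating
    the hands as independent points; the result is reported, not used as
    a gate.
    """
    if hasattr(durations, "frame"):
        durations = durations.frame
    rows = []
    d = durations.query("map == @map_label and session == @session")
    wide_d = d.pivot_table(index="subject", columns="side", values="fraction",
                           sort=False)
    s = table.query("test == @measure and session == @session")
    wide_s = s.pivot_table(index="subject", columns="side", values="score",
                           sort=False)
    for name, wide in ((f"{map_label} duration", wide_d), (measure, wide_s)):
        rho, p, method = spearman(
            wide["more_affected"].to_numpy(), wide["less_affected"].to_numpy()
        )
        rows.append({"variable": name, "session": session,
                     "rho_between_hands": rho, "p": p, "method": method,
                     "n": len(wide)})
    return pd.DataFrame(rows)
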