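"""Within-subject ANOVA helpers.

For a fully within-subject 2x2 design each effect has a single degree of
freedom, so its classical repeated-measures F equals the squared paired t
of the corresponding per-subject contrast:

    F(1, n-1) = n * mean(c)^2 / var(c, ddof=1)

with ``c`` the subject-level contrast (difference of marginal means for a
main effect, double difference for the interaction).  This closed form is
exact, needs no sphericity correction (2-level factors), and vectorizes
over trailing axes, which makes sample-wise time series ANOVA cheap.
Higher-order designs go through :func:`anova_rm_long`
(``statsmodels.stats.anova.AnovaRM``, classical univariate F).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.anova import AnovaRM

#: Effect names of the 2x2 design in reporting order.
EFFECTS_2X2 = ("factor_a", "factor_b", "interaction")


def contrast_f(c: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """F(1, n-1) and p for per-subject contrast values.

    `c` has subjects on axis 0; trailing axes are carried through.
    Zero-variance contrasts (identical data in all cells) give F = 0 when
    the mean contrast is also zero, and +inf otherwise.
    """
    c = np.asarray(c, dtype=float)
    n = c.shape[0]
    if n < 2:
        raise ValueError("need at least 2 subjects")
    mean = c.mean(axis=0)
    var = c.var(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = n * mean**2 / var
    f = np.where(var > 0, f, np.where(np.abs(mean) > 0, np.inf, 0.0))
    p = stats.f.sf(f, 1, n - 1)
    return f, p


def rm_anova_2x2(y: np.ndarray) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Classical repeated-measures ANOVA for a 2x2 within design.

    `y` has shape ``(n_subjects, 2, 2, ...)``; trailing axes (e.g. time)
    are vectorized.  Returns ``{effect: (F, p)}`` with effects
    ``factor_a`` (axis 1), ``factor_b`` (axis 2) and ``interaction``.
    """
    y = np.asarray(y, dtype=float)
    if y.ndim < 3 or y.shape[1:3] != (2, 2):
        raise ValueError(f"expected shape (n, 2, 2, ...); got {y.shape}")
    c_a = y[:, 0].mean(axis=1) - y[:, 1].mean(axis=1)
    c_b = y[:, :, 0].mean(axis=1) - y[:, :, 1].mean(axis=1)
    c_ab = y[:, 0, 0] - y[:, 0, 1] - y[:, 1, 0] + y[:, 1, 1]
    return {
        "factor_a": contrast_f(c_a),
        "factor_b": contrast_f(c_b),
        "interaction": contrast_f(c_ab),
    }


def anova_rm_long(
    df: pd.DataFrame, dv: str, subject: str, within: list[str]
) -> pd.DataFrame:
    """Classical within-subject ANOVA on long-format data via statsmodels.

    Adds partial eta squared (``SS_effect / (SS_effect + SS_error)``,
    recovered from F and its degrees of freedom) to the AnovaRM table.

    Compositional dependent variables (e.g. duration fractions summing to
    1 within each cell) make effects that average over the composition
    exactly degenerate (0 effect and 0 error SS); their F is NaN/inf and
    the numpy divide warnings are expected, so they are suppressed here.
    """
    with np.errstate(divide="ignore", invalid="ignore"):
        res = AnovaRM(df, depvar=dv, subject=subject, within=within).fit()
    table = res.anova_table.copy()
    table.columns = ["F", "df_num", "df_den", "p"]
    table["partial_eta_sq"] = (
        table["F"] * table["df_num"]
        / (table["F"] * table["df_num"] + table["df_den"])
    )
    return table


def paired_t(
    x: np.ndarray, y: np.ndarray, alternative: str = "two-sided"
) -> tuple[float, float, int]:
    """Paired t-test returning (t, p, df); zero-variance differences are
    flagged with an infinite t (p of 0 or 1) rather than NaN."""
    d = np.asarray(x, dtype=float) - np.asarray(y, dtype=float)
    n = d.shape[0]
    if n < 2:
        raise ValueError("need at least 2 pairs")
    sd = d.std(ddof=1)
    if sd == 0:
        if d.mean() == 0:
            t = 0.0
        else:
            t = np.inf if d.mean() > 0 else -np.inf
        p = _t_p(t, n - 1, alternative)
        return t, p, n - 1
    t = d.mean() / (sd / np.sqrt(n))
    return float(t), _t_p(t, n - 1, alternative), n - 1


def _t_p(t: float, df: int, alternative: str) -> float:
    if alternative == "two-sided":
        return float(2 * stats.t.sf(abs(t), df))
    if alternative == "greater":
        return float(stats.t.sf(t, df))
    if alternative == "less":
        return float(stats.t.cdf(t, df))
    raise ValueError(f"unknown alternative {alternative!r}")
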