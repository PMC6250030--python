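"""Independent brute-force oracles used by the test suite.

The within-subject ANOVA oracle computes sums of squares for a fully
crossed balanced design directly from inclusion-exclusion over marginal
means — no shortcut shared with the package implementation.
"""

from __future__ import annotations

import itertools

import numpy as np


def within_anova_oracle(y: np.ndarray) -> dict[tuple[int, ...], tuple[float, int, int]]:
    """Classical repeated-measures F for every within-subject effect.

    `y` has subjects on axis 0 and one axis per within factor.  Returns
    ``{factor-axes tuple: (F, df_num, df_den)}`` where the error term for
    an effect is its interaction with subjects.
    """
    y = np.asarray(y, dtype=float)
    factor_axes = tuple(range(1, y.ndim))

    def effect_ss(axes: tuple[int, ...]) -> float:
        est = np.zeros((1,) * y.ndim)
        for r in range(len(axes) + 1):
            for sub in itertools.combinations(axes, r):
                collapse = tuple(a for a in range(y.ndim) if a not in sub)
                sign = (-1) ** (len(axes) - len(sub))
                est = est + sign * y.mean(axis=collapse, keepdims=True)
        return float(np.sum(np.broadcast_to(est, y.shape) ** 2))

    def df(axes: tuple[int, ...]) -> int:
        out = 1
        for a in axes:
            out *= y.shape[a] - 1
        return out

    results = {}
    for r in range(1, len(factor_axes) + 1):
        for eff in itertools.combinations(factor_axes, r):
            ss_eff = effect_ss(eff)
            err_axes = (0,) + eff
            ss_err = effect_ss(err_axes)
            df1, df2 = df(eff), df(err_axes)
            f = (ss_eff / df1) / (ss_err / df2) if ss_err > 0 else np.nan
            results[eff] = (f, df1, df2)
    return results


def diss_bruteforce(a: np.ndarray, b: np.ndarray) -> float:
    """RMS of the difference of mean-centred, RMS-normalized vectors."""
    a = np.asarray(a, float) - np.mean(a)
    b = np.asarray(b, float) - np.mean(b)
    a = a / np.sqrt(np.mean(a**2))
    b = b / np.sqrt(np.mean(b**2))
    return float(np.sqrt(np.mean((a - b) ** 2)))


def tanova_exact_p(dataset, stimulus, effect, window) -> np.ndarray:
    """Exact sign-flip permutation p per sample by full 2^S enumeration.

    Recomputes the per-subject contrast maps from scratch (normalization
    and contrast formed independently of the package's vectorized path).
    """
    coeffs = {
        "side": np.array([+1.0, +1.0, -1.0, -1.0]) / 4.0,
        "session": np.array([+1.0, -1.0, +1.0, -1.0]) / 4.0,
        "interaction": np.array([+1.0, -1.0, -1.0, +1.0]) / 4.0,
    }[effect]
    mask = dataset.time_mask(window)
    block = dataset.stimulus_block(stimulus)[..., mask]
    n_sub = block.shape[0]
    n_t = int(mask.sum())

    d = []
    for i in range(n_sub):
        cells = []
        for b in range(2):
            for c in range(2):
                m = block[i, b, c]
                m = m - m.mean(axis=0, keepdims=True)
                g = np.sqrt(np.mean(m**2, axis=0, keepdims=True))
                cells.append(m / g)
        d.append(sum(co * cell for co, cell in zip(coeffs, cells)))
    d = np.stack(d)  # (S, C, T)

    def stat(signs):
        contrast = np.tensordot(signs, d, axes=(0, 0)) / n_sub
        contrast = contrast - contrast.mean(axis=0, keepdims=True)
        return np.sqrt(np.mean(contrast**2, axis=0))

    obs = stat(np.ones(n_sub))
    null = np.stack([
        stat(np.array(s))
        for s in itertools.product((1, -1), repeat=n_sub)
    ])  # includes identity
    return np.mean(null >= obs[None, :] - 1e-15, axis=0)
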