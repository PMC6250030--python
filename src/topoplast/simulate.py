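"""Ground-truth simulator for the 2x2x2 within-subject somatosensory ERP study.

The generator emulates the study design the analysis assumes: 10 children,
high-density montage, epochs from -200 to 700 ms, factors Stimulus
(puff/sham) x Side (more/less affected hand) x Session (pre/post
intervention).  Condition effects live exclusively in *which* template
topographies occupy the 250-550 ms analysis window (their occupancy
fractions), while a single GFP envelope is shared by all conditions — i.e.
topographic plasticity without response-strength changes.  Behavioral
scores are generated with a planted monotone (Spearman) link to one
designated template map's duration.

Every random draw flows from ``SimulationConfig.seed``; the same seed
reproduces the dataset bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np
import pandas as pd

from .dataset import CONDITIONS, SESSIONS, SIDES, STIMULI, ErpDataset
from .metrics import normalize_by_gfp
from .montage import synthetic_montage

#: Behavioral tests with (unit, direction) where direction +1 means a higher
#: score is better performance, -1 means lower is better.
BEHAVIOR_TESTS: dict[str, tuple[str, int]] = {
    "registration": ("grams", -1),
    "localization": ("count (max 4)", +1),
    "two_point": ("mm", -1),
    "stereognosis": ("count (max 9)", +1),
    "pinch": ("psi", +1),
    "grip": ("psi", +1),
}


class SimulationError(ValueError):
    """Invalid simulation configuration."""


@dataclass(frozen=True)
class GaussianBumps:
    """Sum-of-Gaussians GFP envelope: ``sum(amp * exp(-((t-mu)/sigma)^2))``.

    Shared across all conditions so that simulated data carry no GFP
    effects, only topographic ones.
    """

    bumps: tuple[tuple[float, float, float], ...] = (
        (3.0, 120.0, 50.0),
        (2.5, 400.0, 140.0),
    )

    def __call__(self, t_ms: np.ndarray) -> np.ndarray:
        t = np.asarray(t_ms, dtype=float)
        out = np.zeros_like(t)
        for amp, mu, sigma in self.bumps:
            out += amp * np.exp(-(((t - mu) / sigma) ** 2))
        return out

    @property
    def peak(self) -> float:
        grid = np.linspace(-500.0, 1200.0, 4001)
        return float(self(grid).max())


def _default_schedule() -> dict[tuple[str, str, str], tuple[float, ...]]:
    """Crossover occupancy schedule for the puff conditions.

    Map 1 (the "less functional" pattern) dominates the pre-intervention
    more-affected response and the post-intervention less-affected
    response; maps 2-3 dominate the reference (pre/less-affected) cell and
    the post/more-affected cell.  The two cells of each crossover pair
    share their schedule exactly — emulating the finding that the
    post-intervention more-affected response *resembles* the reference
    (and the post less-affected response the pre more-affected one), which
    also gives them a shared block order and hence high moment-by-moment
    spatial correlation.  Sham cells share a single flat schedule (no
    condition effect).  The effect sizes are illustrative — chosen once
    for detectability at n = 10.
    """
    puff = {
        ("more_affected", "pre"): (0.90, 0.05, 0.05),
        ("less_affected", "pre"): (0.05, 0.55, 0.40),
        ("more_affected", "post"): (0.05, 0.55, 0.40),
        ("less_affected", "post"): (0.90, 0.05, 0.05),
    }
    sham = (1.0 / 3.0, 1.0 / 3.0, 1.0 / 3.0)
    schedule: dict[tuple[str, str, str], tuple[float, ...]] = {}
    for side in SIDES:
        for session in SESSIONS:
            schedule[("puff", side, session)] = puff[(side, session)]
            schedule[("sham", side, session)] = sham
    return schedule


@dataclass
class SimulationConfig:
    """Everything the generator needs, including ground-truth structure.

    Defaults are desk-scale (32 channels, 250 Hz) for test runtime; pass
    ``paper_scale=True`` to :func:`default_config` for the study's
    128-channel / 1000-Hz geometry.
    """

    n_subjects: int = 10
    n_channels: int = 32
    sampling_rate: float = 250.0
    epoch_window: tuple[float, float] = (-200.0, 700.0)
    analysis_window: tuple[float, float] = (250.0, 550.0)
    n_templates: int = 3
    template_bank: np.ndarray | None = None  # (k, C), unit GFP, average-referenced
    occupancy_schedule: dict[tuple[str, str, str], tuple[float, ...]] = field(
        default_factory=_default_schedule
    )
    #: Dirichlet precision for between-subject occupancy variation; 0 turns
    #: subject variation off (every subject realizes the cell schedule).
    occupancy_jitter_kappa: float = 60.0
    gfp_envelope: Callable[[np.ndarray], np.ndarray] = field(
        default_factory=GaussianBumps
    )
    noise_sd: float = 1.0
    #: Optional AR(1)-style spatial correlation of the additive noise
    #: (correlation rho^|i-j| between channel indices); 0 = white.
    noise_spatial_ar1: float = 0.0
    #: Planted Spearman link (signed) between each test's performance and
    #: the designated template map's duration; tests not listed are null.
    behavior_links: dict[str, float] = field(
        default_factory=lambda: {"grip": -0.6, "pinch": -0.6, "stereognosis": -0.4}
    )
    link_map: int = 0  # template index whose duration drives behavior
    #: Extra performance deficit (z units) of the more affected hand, per test.
    hand_shift: dict[str, float] = field(default_factory=dict)
    #: Extra post-session performance change (z units) per (test, side).
    prepost_shift: dict[tuple[str, str], float] = field(default_factory=dict)
    behavior_session_noise: float = 0.3
    trial_count_offset: int = 6
    trial_count_mean: float = 20.0
    #: Assign half the cohort a right-side impairment and store data in
    #: native channel space (undone by laterality relabeling).
    randomize_affected_side: bool = True
    reference_side: str = "left"
    seed: int = 0

    # ------------------------------------------------------------ validation

    def validate(self) -> None:
        if self.n_channels < 2:
            raise SimulationError("n_channels must be >= 2")
        if self.n_subjects < 2:
            raise SimulationError("n_subjects must be >= 2")
        e0, e1 = self.epoch_window
        a0, a1 = self.analysis_window
        if not (e0 <= a0 < a1 <= e1):
            raise SimulationError(
                f"analysis window {self.analysis_window} not inside epoch "
                f"{self.epoch_window}"
            )
        for cell in CONDITIONS:
            if cell not in self.occupancy_schedule:
                raise SimulationError(f"occupancy schedule missing cell {cell}")
            frac = np.asarray(self.occupancy_schedule[cell], dtype=float)
            if len(frac) != self.n_templates:
                raise SimulationError(
                    f"cell {cell}: {len(frac)} occupancy fractions for "
                    f"{self.n_templates} templates"
                )
            if np.any(frac < 0) or abs(frac.sum() - 1.0) > 1e-9:
                raise SimulationError(
                    f"cell {cell}: occupancy fractions must be >= 0 and sum to 1"
                )
        if self.template_bank is not None:
            bank = np.asarray(self.template_bank, dtype=float)
            if bank.shape != (self.n_templates, self.n_channels):
                raise SimulationError(
                    f"template bank shape {bank.shape} != "
                    f"({self.n_templates}, {self.n_channels})"
                )
        for test in self.behavior_links:
            if test not in BEHAVIOR_TESTS:
                raise SimulationError(f"unknown behavioral test {test!r}")

    def replace(self, **changes) -> "SimulationConfig":
        return replace(self, **changes)


def default_config(paper_scale: bool = False, **overrides) -> SimulationConfig:
    """The study-conditions configuration (desk-scale by default)."""
    if paper_scale:
        overrides.setdefault("n_channels", 128)
        overrides.setdefault("sampling_rate", 1000.0)
    cfg = SimulationConfig(**overrides)
    cfg.validate()
    return cfg


@dataclass
class GroundTruth:
    """What the generator actually planted, for recovery tests.

    ``labels`` holds the template index active at each analysis-window
    sample, per subject and condition (subject, stimulus, side, session,
    window sample); ``durations`` the realized occupancy fractions
    (subject, stimulus, side, session, template).  Both are stored in the
    common-laterality space regardless of channel relabeling.
    """

    labels: np.ndarray
    durations: np.ndarray
    template_bank: np.ndarray
    background_map: np.ndarray
    window_mask: np.ndarray
    behavior_latent: pd.DataFrame | None = None

    def durations_frame(self, stimulus: str = "puff") -> pd.DataFrame:
        """Tidy realized durations: subject, side, session, map, fraction."""
        s = STIMULI.index(stimulus)
        n_sub, _, _, _, k = self.durations.shape
        rows = []
        for i in range(n_sub):
            for b, side in enumerate(SIDES):
                for c, session in enumerate(SESSIONS):
                    for m in range(k):
                        rows.append({
                            "subject": f"s{i + 1:02d}",
                            "side": side,
                            "session": session,
                            "map": f"map{m + 1}",
                            "fraction": self.durations[i, s, b, c, m],
                        })
        return pd.DataFrame(rows)

    def to_json_dict(self) -> dict:
        return {
            "labels": self.labels.tolist(),
            "durations": self.durations.tolist(),
            "template_bank": self.template_bank.tolist(),
            "background_map": self.background_map.tolist(),
        }


# --------------------------------------------------------------------------
# templates and block schedules


def make_template_bank(
    n_templates: int, n_channels: int, rng: np.random.Generator
) -> np.ndarray:
    """Random mutually orthogonal unit-GFP maps in the average-reference
    (zero-mean) channel subspace.  Returns (n_templates + 1, C); the last
    row is the background map used outside the analysis window."""
    if n_templates + 1 > n_channels - 1:
        raise SimulationError(
            "need n_channels - 1 > n_templates to build orthogonal maps"
        )
    raw = rng.standard_normal((n_channels, n_templates + 1))
    raw -= raw.mean(axis=0, keepdims=True)
    q, _ = np.linalg.qr(raw)
    maps = q.T  # rows orthonormal, still zero-mean
    return normalize_by_gfp(maps, axis=1)


def _block_lengths(fractions: np.ndarray, n_samples: int) -> np.ndarray:
    """Integer sample counts per template by largest remainder."""
    ideal = fractions * n_samples
    base = np.floor(ideal).astype(int)
    short = n_samples - base.sum()
    order = np.argsort(-(ideal - base))
    base[order[:short]] += 1
    return base


def _label_sequence(
    fractions: np.ndarray, n_samples: int, order: np.ndarray
) -> np.ndarray:
    """Contiguous occupancy blocks in the given order covering the window."""
    lengths = _block_lengths(fractions, n_samples)
    return np.concatenate([
        np.full(lengths[m], m, dtype=np.int8) for m in order
    ])


def _block_orders(
    config: SimulationConfig, rng: np.random.Generator
) -> dict[tuple[str, str, str], np.ndarray]:
    """One template block order per *distinct* occupancy schedule.

    Orders are shared across subjects — component latencies are broadly
    consistent across participants, which is what lets template periods
    survive group averaging.  Cells with identical schedules (e.g. the
    four sham cells under a shared null schedule) also share the order,
    so they differ only by noise and per-subject occupancy jitter: a true
    sample-level null.
    """
    orders: dict[tuple[float, ...], np.ndarray] = {}
    out = {}
    for cell in CONDITIONS:
        key = tuple(config.occupancy_schedule[cell])
        if key not in orders:
            orders[key] = rng.permutation(config.n_templates)
        out[cell] = orders[key]
    return out


def _noise_mixer(config: SimulationConfig) -> np.ndarray | None:
    rho = config.noise_spatial_ar1
    if rho <= 0:
        return None
    idx = np.arange(config.n_channels)
    cov = rho ** np.abs(idx[:, None] - idx[None, :])
    return np.linalg.cholesky(cov)


# --------------------------------------------------------------------------
# main generators


def generate_erp_dataset(
    config: SimulationConfig,
) -> tuple[ErpDataset, GroundTruth]:
    """Simulate the full 2x2x2 ERP dataset plus its ground truth.

    Each subject-condition ERP is, sample by sample, the scheduled template
    (or the shared background map outside the analysis window) scaled by
    the common GFP envelope, plus independent channel noise, then
    average-referenced.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 101])

    channels, positions, _flip = synthetic_montage(config.n_channels)
    if config.template_bank is None:
        bank_plus = make_template_bank(config.n_templates, config.n_channels, rng)
        bank, background = bank_plus[:-1], bank_plus[-1]
    else:
        bank = normalize_by_gfp(
            np.asarray(config.template_bank, dtype=float), axis=1
        )
        background = normalize_by_gfp(
            rng.standard_normal(config.n_channels), axis=0
        )

    n_sub, n_ch = config.n_subjects, config.n_channels
    start, end = config.epoch_window
    n_t = int(round((end - start) / 1000.0 * config.sampling_rate))
    times = start + 1000.0 / config.sampling_rate * np.arange(n_t)
    a0, a1 = config.analysis_window
    win = (times >= a0 - 1e-9) & (times < a1 - 1e-9)
    n_win = int(win.sum())
    envelope = np.asarray(config.gfp_envelope(times), dtype=float)
    if np.any(envelope < 0):
        raise SimulationError("gfp_envelope must be nonnegative")

    mixer = _noise_mixer(config)
    orders = _block_orders(config, rng)
    k = config.n_templates
    data = np.empty((n_sub, 2, 2, 2, n_ch, n_t))
    labels = np.empty((n_sub, 2, 2, 2, n_win), dtype=np.int8)
    durations = np.zeros((n_sub, 2, 2, 2, k))

    for i in range(n_sub):
        for a, stim in enumerate(STIMULI):
            for b, side in enumerate(SIDES):
                for c, session in enumerate(SESSIONS):
                    frac = np.asarray(
                        config.occupancy_schedule[(stim, side, session)], float
                    )
                    if config.occupancy_jitter_kappa > 0:
                        pos_mask = frac > 0
                        jit = np.zeros_like(frac)
                        jit[pos_mask] = rng.dirichlet(
                            config.occupancy_jitter_kappa * frac[pos_mask]
                        )
                        frac = jit
                    seq = _label_sequence(frac, n_win, orders[(stim, side, session)])
                    labels[i, a, b, c] = seq
                    counts = np.bincount(seq, minlength=k)
                    durations[i, a, b, c] = counts / n_win

                    source = np.tile(background[:, None], (1, n_t))
                    source[:, win] = bank[seq].T
                    clean = source * envelope[None, :]
                    noise = rng.standard_normal((n_ch, n_t)) * config.noise_sd
                    if mixer is not None:
                        noise = mixer @ noise
                    data[i, a, b, c] = clean + noise

    data -= data.mean(axis=-2, keepdims=True)

    subjects = [f"s{j + 1:02d}" for j in range(n_sub)]
    if config.randomize_affected_side:
        other = "right" if config.reference_side == "left" else "left"
        affected = {
            s: (config.reference_side if j % 2 == 0 else other)
            for j, s in enumerate(subjects)
        }
    else:
        affected = {s: config.reference_side for s in subjects}

    dataset = ErpDataset(
        data=data,
        subjects=subjects,
        channels=channels,
        sampling_rate=config.sampling_rate,
        epoch_window=config.epoch_window,
        affected_side=affected,
        positions=positions,
        meta={"generator": "topoplast.simulate", "seed": config.seed,
              "laterality_space": "common"},
    )
    truth = GroundTruth(
        labels=labels,
        durations=durations,
        template_bank=bank,
        background_map=background,
        window_mask=win,
    )

    if config.randomize_affected_side:
        # store in native channel space; laterality relabeling restores
        # the common space used above
        from .erp_io import relabel_laterality  # local import, no cycle at load

        dataset = relabel_laterality(dataset, _flip, config.reference_side)
        dataset.meta["laterality_space"] = "native"
        dataset.meta.pop("laterality_relabeled", None)
    return dataset, truth


def generate_behavioral_table(
    config: SimulationConfig, truth: GroundTruth
) -> pd.DataFrame:
    """Behavioral scores with planted monotone links to one map's duration.

    For each test a latent performance z-score is built through a Gaussian
    copula: ``z = rho_p * z_dur + sqrt(1 - rho_p^2) * eps`` with
    ``rho_p = 2 sin(pi * rho_s / 6)`` so the population Spearman
    correlation with the designated map's (standardized) duration equals
    the configured link.  The latent is then pushed through a strictly
    monotone transform onto each test's natural scale.  Count-valued tests
    are rounded, which can only attenuate rank correlations slightly.

    Returns a tidy frame: subject, side, session, test, score, unit.
    """
    if truth is None:
        raise SimulationError("ground truth is required to plant behavior links")
    config.validate()
    rng = np.random.default_rng([config.seed, 202])
    n_sub = config.n_subjects
    subjects = [f"s{j + 1:02d}" for j in range(n_sub)]
    s_puff = STIMULI.index("puff")

    dur = truth.durations[:, s_puff, :, :, config.link_map]  # (S, side, session)
    pre = dur[:, :, SESSIONS.index("pre")]
    mu, sd = pre.mean(), pre.std(ddof=1)
    if sd < 1e-12:
        sd = 1.0
    z_dur = (dur - mu) / sd

    rows = []
    latents = []
    for test, (unit, _direction) in BEHAVIOR_TESTS.items():
        rho_s = float(config.behavior_links.get(test, 0.0))
        if abs(rho_s) >= 1.0:
            rho_p = float(np.sign(rho_s))  # sin(pi/6) rounds below 0.5
        else:
            rho_p = float(2.0 * np.sin(np.pi * rho_s / 6.0))
        eps_base = rng.standard_normal((n_sub, 2))
        z = np.empty((n_sub, 2, 2))
        for c, session in enumerate(SESSIONS):
            innov = rng.standard_normal((n_sub, 2)) * config.behavior_session_noise
            eps = (eps_base + innov) / np.sqrt(
                1.0 + config.behavior_session_noise**2
            )
            z[:, :, c] = rho_p * z_dur[:, :, c] + np.sqrt(1.0 - rho_p**2) * eps
        shift = config.hand_shift.get(test, 0.0)
        z[:, SIDES.index("more_affected"), :] -= shift
        for b, side in enumerate(SIDES):
            z[:, b, SESSIONS.index("post")] += config.prepost_shift.get(
                (test, side), 0.0
            )
        scores = _to_natural_scale(test, z)
        for i, subj in enumerate(subjects):
            for b, side in enumerate(SIDES):
                for c, session in enumerate(SESSIONS):
                    rows.append({
                        "subject": subj, "side": side, "session": session,
                        "test": test, "score": scores[i, b, c], "unit": unit,
                    })
                    latents.append({
                        "subject": subj, "side": side, "session": session,
                        "test": test, "z": z[i, b, c],
                    })
    truth.behavior_latent = pd.DataFrame(latents)
    return pd.DataFrame(rows)


def _to_natural_scale(test: str, z: np.ndarray) -> np.ndarray:
    """Strictly monotone map from performance z-scores to each test's units.

    Higher z is always better performance; for tests where lower raw
    scores are better (registration grams, two-point mm) the transform is
    monotone *decreasing* in z accordingly.
    """
    if test == "registration":
        return np.exp(-0.5 - 0.8 * z)  # grams; lower = better
    if test == "localization":
        return np.clip(np.round(2.5 + 0.8 * z), 0, 4)
    if test == "two_point":
        return np.exp(1.3 - 0.4 * z)  # mm; lower = better
    if test == "stereognosis":
        return np.clip(np.round(5.5 + 1.8 * z), 0, 9)
    if test == "pinch":
        return np.maximum(8.0 + 1.8 * z, 0.5)
    if test == "grip":
        return np.maximum(13.0 + 2.8 * z, 1.0)
    raise SimulationError(f"unknown behavioral test {test!r}")


def generate_trial_counts(config: SimulationConfig) -> pd.DataFrame:
    """Usable-trial counts per subject and condition (shifted Poisson).

    ``count = offset + Poisson(mean - offset)`` puts realistic mass just
    below and above the study's >= 12 usable-trials inclusion threshold so
    the filter is exercisable.
    """
    config.validate()
    if config.trial_count_mean <= config.trial_count_offset:
        raise SimulationError("trial_count_mean must exceed trial_count_offset")
    rng = np.random.default_rng([config.seed, 303])
    lam = config.trial_count_mean - config.trial_count_offset
    rows = []
    for j in range(config.n_subjects):
        for stim, side, session in CONDITIONS:
            rows.append({
                "subject": f"s{j + 1:02d}",
                "stimulus": stim, "side": side, "session": session,
                "n_trials": int(config.trial_count_offset + rng.poisson(lam)),
            })
    return pd.DataFrame(rows)
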