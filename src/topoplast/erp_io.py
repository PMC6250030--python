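"""Dataset I/O and structural preprocessing of ERP averages.

The native on-disk format is deliberately transparent: one tab-delimited
channels-x-time matrix per subject and condition cell, plus a versioned
JSON sidecar carrying subjects, channel labels, sampling metadata and each
subject's affected side.  Structural preprocessing covers average
referencing, left-right laterality relabeling to a common hemisphere, and
the usable-trials inclusion filter; spectral filtering, artifact screening
and channel interpolation are assumed to have happened upstream of the ERP
averages this package ingests.
"""

from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .dataset import CONDITIONS, DatasetError, ErpDataset
from .montage import ChannelFlipMap

logger = logging.getLogger(__name__)

SIDECAR_NAME = "dataset.json"
SCHEMA_VERSION = 1


def _cell_filename(subject: str, stimulus: str, side: str, session: str) -> str:
    return f"{subject}_{stimulus}_{side}_{session}.tsv"


def write_dataset(dataset: ErpDataset, path: str | Path) -> Path:
    """Write a dataset directory: one TSV per subject x condition + sidecar."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    for subject in dataset.subjects:
        for stim, side, session in CONDITIONS:
            mat = dataset.get(subject, stim, side, session)
            df = pd.DataFrame(mat, index=dataset.channels)
            df.index.name = "channel"
            df.to_csv(path / _cell_filename(subject, stim, side, session), sep="\t")
    sidecar = {
        "schema_version": SCHEMA_VERSION,
        "subjects": dataset.subjects,
        "channels": dataset.channels,
        "sampling_rate": dataset.sampling_rate,
        "epoch_window": list(dataset.epoch_window),
        "affected_side": dataset.affected_side,
        "positions": None if dataset.positions is None
        else dataset.positions.tolist(),
        "meta": dataset.meta,
    }
    (path / SIDECAR_NAME).write_text(json.dumps(sidecar, indent=1))
    return path


def read_dataset(path: str | Path) -> ErpDataset:
    """Read a dataset directory written by :func:`write_dataset`.

    A missing condition file or a channel-count mismatch raises a
    :class:`DatasetError` naming the offending subject and condition cell.
    """
    path = Path(path)
    sidecar = json.loads((path / SIDECAR_NAME).read_text())
    subjects = list(sidecar["subjects"])
    channels = list(sidecar["channels"])
    blocks = []
    for subject in subjects:
        per_cond = []
        for stim, side, session in CONDITIONS:
            f = path / _cell_filename(subject, stim, side, session)
            if not f.exists():
                raise DatasetError(
                    f"missing condition cell for subject {subject!r}: "
                    f"({stim}, {side}, {session}) — expected {f.name}"
                )
            df = pd.read_csv(f, sep="\t", index_col=0)
            if list(df.index) != channels:
                raise DatasetError(
                    f"channel labels in {f.name} do not match the sidecar "
                    f"(subject {subject!r}, cell ({stim}, {side}, {session}))"
                )
            per_cond.append(df.to_numpy(dtype=float))
        blocks.append(np.stack(per_cond).reshape(2, 2, 2, len(channels), -1))
    positions = sidecar.get("positions")
    return ErpDataset(
        data=np.stack(blocks),
        subjects=subjects,
        channels=channels,
        sampling_rate=float(sidecar["sampling_rate"]),
        epoch_window=tuple(sidecar["epoch_window"]),
        affected_side=dict(sidecar["affected_side"]),
        positions=None if positions is None else np.asarray(positions, float),
        meta=dict(sidecar.get("meta", {})),
    )


def apply_average_reference(dataset: ErpDataset) -> ErpDataset:
    """Re-reference every map to the average reference (idempotent)."""
    data = dataset.data - dataset.data.mean(axis=-2, keepdims=True)
    out = dataset.copy_with(data=data)
    out.meta["average_referenced"] = True
    return out


def relabel_laterality(
    dataset: ErpDataset, flip: ChannelFlipMap, reference_side: str = "left"
) -> ErpDataset:
    """Anchor the hemisphere contralateral to the more affected hand.

    Subjects whose affected side equals `reference_side` are left
    unchanged; for the others, left-right homologous channel rows are
    swapped so that, across the whole group, activity contralateral vs.
    ipsilateral to the more affected hand sits in the same hemisphere.
    Applying the operation twice restores the original data.
    """
    if reference_side not in ("left", "right"):
        raise ValueError("reference_side must be 'left' or 'right'")
    perm = flip.permutation(dataset.channels)
    data = dataset.data.copy()
    flipped = []
    for i, subject in enumerate(dataset.subjects):
        if dataset.affected_side[subject] != reference_side:
            data[i] = data[i][:, :, :, perm, :]
            flipped.append(subject)
    out = dataset.copy_with(data=data)
    out.meta["laterality_relabeled"] = {
        "reference_side": reference_side,
        "flipped_subjects": flipped,
    }
    return out


def filter_min_trials(
    dataset: ErpDataset, counts: pd.DataFrame, min_trials: int = 12
) -> ErpDataset:
    """Drop subjects with any condition below the usable-trials threshold.

    The inclusion rule is per subject and dataset-wide: *every* individual
    condition must have at least `min_trials` usable trials (boundary
    inclusive), otherwise the subject is removed from all conditions.
    """
    needed = {"subject", "stimulus", "side", "session", "n_trials"}
    if not needed.issubset(counts.columns):
        raise ValueError(f"counts table must have columns {sorted(needed)}")
    kept, removed = [], []
    for subject in dataset.subjects:
        sub = counts[counts["subject"] == subject]
        cells = {
            (r.stimulus, r.side, r.session): r.n_trials
            for r in sub.itertuples()
        }
        missing = [c for c in CONDITIONS if c not in cells]
        if missing:
            raise DatasetError(
                f"trial counts missing for subject {subject!r}, cells {missing}"
            )
        if all(cells[c] >= min_trials for c in CONDITIONS):
            kept.append(subject)
        else:
            removed.append(subject)
    if removed:
        logger.info("excluded subjects (min %d trials): %s", min_trials, removed)
    if not kept:
        warnings.warn(
            f"no subject satisfies the >= {min_trials} usable-trials criterion; "
            "returning an empty dataset", stacklevel=2,
        )
    idx = [dataset.subjects.index(s) for s in kept]
    out = dataset.copy_with(
        data=dataset.data[idx] if idx else dataset.data[:0],
        subjects=kept,
        affected_side={s: dataset.affected_side[s] for s in kept},
    )
    out.meta["min_trials_filter"] = {"min_trials": min_trials, "removed": removed}
    return out


def export_topography_sequence(
    dataset: ErpDataset,
    interval_ms: float = 100.0,
    window: tuple[float, float] = (0.0, 700.0),
    stimulus: str = "puff",
    outdir: str | Path | None = None,
) -> pd.DataFrame:
    """Group-average topographies at fixed intervals over the post-stimulus
    period, as a tidy numeric table and (optionally) rendered maps.

    One map per condition per interval boundary (inclusive of both ends
    when they land on the grid).  Rendering requires channel positions; if
    absent, the numeric export still happens and a warning is issued.
    """
    from .dataset import SESSIONS, SIDES

    lo, hi = window
    boundaries = np.arange(lo, hi + 1e-9, interval_ms)
    times = dataset.times
    rows = []
    picked: list[tuple[str, str, float, np.ndarray]] = []
    for side in SIDES:
        for session in SESSIONS:
            mean = dataset.group_mean(stimulus, side, session)
            for t in boundaries:
                j = int(np.argmin(np.abs(times - t)))
                picked.append((side, session, times[j], mean[:, j]))
                for ch, v in zip(dataset.channels, mean[:, j]):
                    rows.append({
                        "side": side, "session": session,
                        "time_ms": times[j], "channel": ch, "amplitude": v,
                    })
    table = pd.DataFrame(rows)

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        table.to_csv(outdir / f"topo_sequence_{stimulus}.csv", index=False)
        if dataset.positions is None:
            warnings.warn(
                "no channel positions in the montage; skipping map rendering",
                stacklevel=2,
            )
        else:
            _render_sequence(dataset, picked, boundaries, stimulus, outdir)
    return table


def _render_sequence(dataset, picked, boundaries, stimulus, outdir: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    xy = dataset.positions
    conds = sorted({(s, ses) for s, ses, _, _ in picked})
    fig, axes = plt.subplots(
        len(conds), len(boundaries),
        figsize=(1.4 * len(boundaries), 1.6 * len(conds)), squeeze=False,
    )
    vmax = max(np.abs(v).max() for *_xs, v in picked) or 1.0
    for r, cond in enumerate(conds):
        maps = [(t, v) for s, ses, t, v in picked if (s, ses) == cond]
        for c, (t, v) in enumerate(maps):
            ax = axes[r][c]
            ax.tricontourf(
                xy[:, 0], xy[:, 1], v, levels=12, cmap="RdBu_r",
                vmin=-vmax, vmax=vmax,
            )
            ax.scatter(xy[:, 0], xy[:, 1], s=1, c="k")
            ax.set_aspect("equal")
            ax.set_axis_off()
            if r == 0:
                ax.set_title(f"{t:.0f} ms", fontsize=7)
        axes[r][0].set_axis_on()
        axes[r][0].set_ylabel("\n".join(cond), fontsize=7)
        axes[r][0].set_xticks([]); axes[r][0].set_yticks([])
    fig.suptitle(f"topography sequence — {stimulus}")
    fig.savefig(outdir / f"topo_sequence_{stimulus}.png", dpi=110,
                bbox_inches="tight")
    plt.close(fig)
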