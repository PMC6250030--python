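"""Montage metadata: channel labels, 2-D positions, left-right homologous pairs.

The laterality-relabeling step needs to know, for every lateral channel,
its mirror-image partner on the other hemisphere; midline channels map to
themselves.  Real high-density nets publish these homologous pairs; the
synthetic montage here builds an idealized layout (mirrored left/right
columns plus a midline chain) so the same machinery is exercisable without
a vendor file.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np


class FlipMapError(ValueError):
    """Inconsistent left-right channel pairing."""


@dataclass(frozen=True)
class ChannelFlipMap:
    """Left-right homologous channel pairs plus self-mapped midline channels.

    Applying the map twice is the identity (involution); every channel of
    the montage must appear exactly once.
    """

    pairs: tuple[tuple[str, str], ...]
    midline: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        seen: list[str] = []
        for left, right in self.pairs:
            seen.extend((left, right))
        seen.extend(self.midline)
        if len(seen) != len(set(seen)):
            raise FlipMapError("a channel appears more than once in the flip map")

    @property
    def channels(self) -> set[str]:
        return {ch for pair in self.pairs for ch in pair} | set(self.midline)

    def permutation(self, channel_order: list[str]) -> np.ndarray:
        """Index permutation implementing the flip for a given channel order."""
        missing = set(channel_order) - self.channels
        if missing:
            raise FlipMapError(f"channels absent from flip map: {sorted(missing)}")
        target = {ch: ch for ch in self.midline}
        for left, right in self.pairs:
            target[left] = right
            target[right] = left
        index = {ch: i for i, ch in enumerate(channel_order)}
        try:
            perm = np.array([index[target[ch]] for ch in channel_order])
        except KeyError as exc:
            raise FlipMapError(f"flip target {exc} not in the montage") from exc
        return perm


def read_flip_map(path: str | Path) -> ChannelFlipMap:
    """Read a two-column text flip map; a line with one label is midline."""
    pairs, midline = [], []
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#")[0].strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) == 1 or parts[0] == parts[1]:
            midline.append(parts[0])
        elif len(parts) == 2:
            pairs.append((parts[0], parts[1]))
        else:
            raise FlipMapError(f"cannot parse flip-map line: {raw!r}")
    return ChannelFlipMap(tuple(pairs), tuple(midline))


def write_flip_map(flip: ChannelFlipMap, path: str | Path) -> None:
    lines = [f"{l}\t{r}" for l, r in flip.pairs] + list(flip.midline)
    Path(path).write_text("\n".join(lines) + "\n")


def synthetic_montage(
    n_channels: int,
) -> tuple[list[str], np.ndarray, ChannelFlipMap]:
    """Idealized mirrored montage: labels, 2-D positions and flip map.

    Lateral channels come in mirrored pairs ``L<i>``/``R<i>`` at positions
    ``(-x, y)``/``(x, y)``; remaining channels form a midline chain ``M<i>``
    at ``x = 0``.  Any ``n_channels >= 2`` is supported.
    """
    if n_channels < 2:
        raise ValueError("a montage needs at least 2 channels")
    n_mid = 2 if n_channels % 2 == 0 else 1
    if n_channels <= 3:
        n_mid = n_channels % 2
    n_pairs = (n_channels - n_mid) // 2

    labels: list[str] = []
    pos: list[tuple[float, float]] = []
    # lateral pairs on nested arcs, mirrored in x
    for i in range(n_pairs):
        frac = (i + 0.5) / n_pairs
        angle = np.pi * (0.15 + 0.7 * frac)
        radius = 0.35 + 0.6 * ((i % 3) + 1) / 3.0
        x, y = radius * np.sin(angle), radius * np.cos(angle)
        labels.append(f"L{i + 1:02d}")
        pos.append((-abs(x), y))
        labels.append(f"R{i + 1:02d}")
        pos.append((abs(x), y))
    for i in range(n_mid):
        labels.append(f"M{i + 1:02d}")
        pos.append((0.0, -0.9 + 1.8 * (i + 0.5) / max(n_mid, 1)))

    flip = ChannelFlipMap(
        tuple((f"L{i + 1:02d}", f"R{i + 1:02d}") for i in range(n_pairs)),
        tuple(f"M{i + 1:02d}" for i in range(n_mid)),
    )
    return labels, np.array(pos), flip
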