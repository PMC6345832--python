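"""Sensor layout: channel positions on a unit scalp disc and the neighbor
relation used for channel-level clustering.

The layout is a deterministic stand-in for an electrode montage: channels
are placed on concentric rings (plus a center electrode for larger counts)
covering the unit disc, and two channels are neighbors when their Euclidean
distance is below ``neighbor_radius``. The cluster statistics only consume
the adjacency relation, so the exact geometry is immaterial as long as the
neighbor graph is connected and every channel has enough neighbors for the
minimum-neighbor-channel rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError

__all__ = ["SensorLayout", "make_layout"]


@dataclass(frozen=True)
class SensorLayout:
    """Channel names, 2-D positions on the unit disc, and symmetric,
    irreflexive boolean adjacency."""

    channel_names: tuple
    positions: np.ndarray  # (n_channels, 2)
    adjacency: np.ndarray  # (n_channels, n_channels) bool

    def __post_init__(self):
        adj = np.asarray(self.adjacency, dtype=bool)
        if adj.shape != (self.n_channels, self.n_channels):
            raise ConfigurationError("adjacency shape does not match channel count")
        if np.any(np.diag(adj)):
            raise ConfigurationError("adjacency must be irreflexive")
        if not np.array_equal(adj, adj.T):
            raise ConfigurationError("adjacency must be symmetric")
        degrees = adj.sum(axis=1)
        if np.any(degrees == 0):
            bad = self.channel_names[int(np.argmin(degrees))]
            raise ConfigurationError(
                f"channel {bad!r} has no neighbors; increase neighbor_radius"
            )

    @property
    def n_channels(self) -> int:
        return len(self.channel_names)

    def neighbor_counts(self) -> np.ndarray:
        return self.adjacency.sum(axis=1)

    def to_dict(self) -> dict:
        pairs = np.argwhere(np.triu(self.adjacency, 1))
        return {
            "channel_names": list(self.channel_names),
            "positions": self.positions.tolist(),
            "adjacent_pairs": pairs.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SensorLayout":
        names = tuple(d["channel_names"])
        pos = np.asarray(d["positions"], dtype=float)
        adj = np.zeros((len(names), len(names)), dtype=bool)
        for i, j in d["adjacent_pairs"]:
            adj[i, j] = adj[j, i] = True
        return cls(names, pos, adj)


def _ring_positions(n_channels: int) -> np.ndarray:
    """Deterministic positions: concentric rings covering the unit disc,
    with a center electrode when at least two rings are used."""
    n_rings = max(1, round(np.sqrt(n_channels / np.pi)))
    center = 1 if n_rings >= 2 else 0
    remaining = n_channels - center
    weights = np.arange(1, n_rings + 1, dtype=float)
    raw = remaining * weights / weights.sum()
    counts = np.floor(raw).astype(int)
    # largest-remainder rounding keeps the total exact and deterministic
    order = np.argsort(-(raw - counts), kind="stable")
    for k in order[: remaining - counts.sum()]:
        counts[k] += 1
    pts = []
    if center:
        pts.append((0.0, 0.0))
    for ring, cnt in enumerate(counts, start=1):
        if cnt == 0:
            continue
        radius = ring / n_rings
        offset = (np.pi / cnt) * (ring % 2)  # stagger alternate rings
        ang = offset + 2 * np.pi * np.arange(cnt) / cnt
        pts.extend(zip(radius * np.cos(ang), radius * np.sin(ang)))
    return np.asarray(pts, dtype=float)


def make_layout(n_channels: int, neighbor_radius: float) -> SensorLayout:
    """Place ``n_channels`` sensors on the unit disc and derive adjacency.

    Parameters
    ----------
    n_channels : int
        Number of sensors; at least 4.
    neighbor_radius : float
        Two channels are neighbors iff their distance is strictly below
        this radius. Must be positive. A radius leaving any channel
        isolated raises :class:`ConfigurationError` naming the channel.
    """
    if n_channels < 4:
        raise ValueError(f"n_channels must be >= 4, got {n_channels}")
    if not neighbor_radius > 0:
        raise ValueError(f"neighbor_radius must be > 0, got {neighbor_radius}")
    pos = _ring_positions(n_channels)
    names = tuple(f"C{i:02d}" for i in range(n_channels))
    diff = pos[:, None, :] - pos[None, :, :]
    dist = np.sqrt((diff**2).sum(axis=-1))
    adj = (dist < neighbor_radius) & ~np.eye(n_channels, dtype=bool)
    return SensorLayout(names, pos, adj)
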