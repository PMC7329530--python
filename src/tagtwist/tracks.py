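"""Material-point track container shared by both tracking engines."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class MaterialPointTracks:
    """Per-point, per-frame tracked positions in physical mm.

    ``positions`` is (N, T, 2); frame-0 positions equal the seed points
    exactly. ``valid`` is (N, T) and monotone: once a point is flagged
    invalid it stays invalid at all later frames.
    """

    positions: np.ndarray
    valid: np.ndarray
    source: str = "unknown"   # "harp" | "ffd" | "truth"

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.positions.ndim != 3 or self.positions.shape[2] != 2:
            raise ValueError("positions must be (N, T, 2)")
        if self.valid.shape != self.positions.shape[:2]:
            raise ValueError("valid must be (N, T)")
        # enforce monotone invalidation
        self.valid = np.logical_and.accumulate(self.valid, axis=1)

    @property
    def n_points(self) -> int:
        return self.positions.shape[0]

    @property
    def n_frames(self) -> int:
        return self.positions.shape[1]

    @property
    def seeds(self) -> np.ndarray:
        return self.positions[:, 0, :]

    def valid_at(self, frame: int) -> np.ndarray:
        return self.valid[:, frame]


def tracks_from_truth(truth_positions: np.ndarray) -> MaterialPointTracks:
    """Wrap exact ground-truth trajectories (N, T, 2) as tracks."""
    pos = np.asarray(truth_positions, dtype=float)
    return MaterialPointTracks(
        positions=pos, valid=np.ones(pos.shape[:2], dtype=bool), source="truth"
    )
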