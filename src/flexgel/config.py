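"""Polymer configuration container and periodic-geometry helpers."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np


def minimum_image(disp: np.ndarray, box_edge: float) -> np.ndarray:
    """Apply the minimum-image convention to displacement vectors.

    Valid for displacements between wrapped coordinates (components in
    (-L, L)).
    """
    return disp - box_edge * np.rint(disp / box_edge)


def wrap_positions(positions: np.ndarray, box_edge: float) -> np.ndarray:
    """Wrap coordinates into [0, L)."""
    return np.mod(positions, box_edge)


def chain_topology(chain_lengths: Sequence[int]):
    """Build (chain_of, bonds, angles) index arrays for consecutive chains.

    Beads are numbered contiguously chain after chain; bonds join beads with
    consecutive indices within a chain, and every interior bead is the vertex
    of exactly one angle triad.
    """
    chain_of = []
    bonds = []
    angles = []
    start = 0
    for ci, n in enumerate(chain_lengths):
        if n < 1:
            raise ValueError("chain length must be >= 1")
        chain_of.extend([ci] * n)
        for k in range(start, start + n - 1):
            bonds.append((k, k + 1))
        for k in range(start + 1, start + n - 1):
            angles.append((k - 1, k, k + 1))
        start += n
    return (
        np.asarray(chain_of, dtype=np.int64),
        np.asarray(bonds, dtype=np.int64).reshape(-1, 2),
        np.asarray(angles, dtype=np.int64).reshape(-1, 3),
    )


@dataclass
class PolymerConfiguration:
    """State of a polymer mixture in a cubic periodic box.

    Attributes
    ----------
    positions, velocities : (N, 3) float arrays in reduced units.
    chain_of : (N,) chain index per bead.
    bonds : (nb, 2) consecutive-bead pairs within chains.
    angles : (na, 3) consecutive bonded triads (vertex in the middle).
    crosslinks : (nc, 2) harmonic springs joining beads of different chains.
    box_edge : cubic box edge length.
    flexible : when True the angular potential is identically zero.
    """

    positions: np.ndarray
    velocities: np.ndarray
    chain_of: np.ndarray
    bonds: np.ndarray
    angles: np.ndarray
    crosslinks: np.ndarray = field(
        default_factory=lambda: np.empty((0, 2), dtype=np.int64)
    )
    box_edge: float = 1.0
    flexible: bool = False

    def __post_init__(self) -> None:
        self.positions = np.ascontiguousarray(self.positions, dtype=np.float64)
        self.velocities = np.ascontiguousarray(self.velocities, dtype=np.float64)
        self.chain_of = np.asarray(self.chain_of, dtype=np.int64)
        self.bonds = np.asarray(self.bonds, dtype=np.int64).reshape(-1, 2)
        self.angles = np.asarray(self.angles, dtype=np.int64).reshape(-1, 3)
        self.crosslinks = np.asarray(self.crosslinks, dtype=np.int64).reshape(-1, 2)
        if self.box_edge <= 0:
            raise ValueError("box_edge must be strictly positive")
        if self.positions.shape != (self.n_beads, 3):
            raise ValueError("positions must have shape (N, 3)")
        if self.velocities.shape != self.positions.shape:
            raise ValueError("velocities must match positions in shape")

    @property
    def n_beads(self) -> int:
        return int(self.positions.shape[0])

    @property
    def n_chains(self) -> int:
        return int(self.chain_of.max()) + 1 if self.chain_of.size else 0

    def validate(self) -> None:
        """Check topology invariants; raise ValueError on violation."""
        n = self.n_beads
        for name, arr in (("bonds", self.bonds), ("angles", self.angles),
                          ("crosslinks", self.crosslinks)):
            if arr.size and (arr.min() < 0 or arr.max() >= n):
                raise ValueError(f"{name} reference beads outside [0, N)")
        for i, j in self.bonds:
            if self.chain_of[i] != self.chain_of[j] or abs(i - j) != 1:
                raise ValueError("bonds must join consecutive beads of one chain")
        for i, j, k in self.angles:
            if not (j == i + 1 and k == j + 1):
                raise ValueError("angle triads must be consecutive beads")
        for i, j in self.crosslinks:
            if self.chain_of[i] == self.chain_of[j]:
                raise ValueError("crosslinks must join beads of different chains")
        if np.any(self.positions < 0) or np.any(self.positions >= self.box_edge):
            raise ValueError("positions must be wrapped into [0, box_edge)")

    def wrap(self) -> None:
        """Wrap positions into the periodic box in place."""
        self.positions = wrap_positions(self.positions, self.box_edge)

    def copy(self) -> "PolymerConfiguration":
        return PolymerConfiguration(
            positions=self.positions.copy(),
            velocities=self.velocities.copy(),
            chain_of=self.chain_of.copy(),
            bonds=self.bonds.copy(),
            angles=self.angles.copy(),
            crosslinks=self.crosslinks.copy(),
            box_edge=float(self.box_edge),
            flexible=bool(self.flexible),
        )

    def with_crosslinks(self, crosslinks: np.ndarray) -> "PolymerConfiguration":
        out = self.copy()
        out.crosslinks = np.asarray(crosslinks, dtype=np.int64).reshape(-1, 2)
        return out

    def unwrapped_chain(self, chain_index: int) -> np.ndarray:
        """Return the coordinates of one chain unwrapped across the box.

        The first bead keeps its wrapped position; each subsequent bead is
        placed at the minimum-image displacement from its predecessor, so the
        chain is contiguous even when it straddles a periodic boundary.
        """
        idx = np.flatnonzero(self.chain_of == chain_index)
        pos = self.positions[idx]
        out = np.empty_like(pos)
        out[0] = pos[0]
        steps = minimum_image(np.diff(pos, axis=0), self.box_edge)
        out[1:] = pos[0] + np.cumsum(steps, axis=0)
        return out
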