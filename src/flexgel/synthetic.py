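"""Synthetic input generation: initial chain mixtures, single-chain test
systems and named presets.

The generator emulates the study conditions: linear chains placed at random
positions and orientations without overlap in a large cubic box, which are
subsequently compressed and self-assembled by the protocol.  The ``full``
preset carries the reference system (200 chains of 50 beads in a
(399.6 sigma)^3 box, compressed to (48 sigma)^3 then (30 sigma)^3); the
``demo`` and ``ci`` presets are density-preserving reductions (box edges
scaled by the cube root of the bead-count ratio) sized for desk-scale runs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np
from scipy.spatial import cKDTree

from .calibration import calibrate_bending_constant
from .config import PolymerConfiguration, chain_topology, wrap_positions
from .errors import DensityError
from .params import SimulationParameters
from .protocol import ProtocolPlan

#: Reference persistence length of the stiff stage, in bead radii.
STIFF_LP_OVER_R = 50.0

_MAX_CHAIN_ATTEMPTS = 2000


@dataclass
class SystemSpec:
    """Specification of a random initial mixture of linear chains."""

    n_chains: int
    dp: int                     # degree of polymerization (beads per chain)
    box_edge: float
    min_separation: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_chains < 1:
            raise ValueError("n_chains must be >= 1")
        if self.dp < 3:
            raise ValueError("dp must be >= 3 (angle triads need three beads)")
        if self.box_edge <= 0 or self.min_separation <= 0:
            raise ValueError("box_edge and min_separation must be positive")

    @property
    def n_beads(self) -> int:
        return self.n_chains * self.dp

    def to_dict(self) -> dict:
        return {
            "n_chains": self.n_chains, "dp": self.dp,
            "box_edge": self.box_edge,
            "min_separation": self.min_separation, "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SystemSpec":
        return cls(**d)


def _thermal_velocities(n: int, params: SimulationParameters, rng) -> np.ndarray:
    return rng.normal(0.0, math.sqrt(params.kBT / params.m), size=(n, 3))


def generate_initial_chains(
    spec: SystemSpec,
    params: SimulationParameters,
    rng: Optional[np.random.Generator] = None,
) -> PolymerConfiguration:
    """Place straight chains at random positions/orientations without overlap.

    Each chain is a straight segment of ``dp`` beads at spacing 2r with a
    uniformly random orientation; candidate chains are rejected (and redrawn)
    whenever any bead comes closer than ``min_separation`` to an already
    placed bead under periodic minimum-image distances.  Velocities are
    thermal at kBT.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    L = spec.box_edge
    b = params.bond_length
    offsets = np.arange(spec.dp)[:, None] * b

    placed: List[np.ndarray] = []
    tree: Optional[cKDTree] = None
    for _ in range(spec.n_chains):
        for attempt in range(_MAX_CHAIN_ATTEMPTS):
            origin = rng.uniform(0.0, L, size=3)
            # uniform random direction
            u = rng.normal(size=3)
            u /= np.linalg.norm(u)
            beads = wrap_positions(origin + offsets * u, L)
            # intra-chain spacing is b >= min_separation by construction for
            # the default settings; still verify against previous chains
            if tree is not None:
                d, _ = tree.query(beads, k=1)
                if d.min() < spec.min_separation:
                    continue
            placed.append(beads)
            tree = cKDTree(np.vstack(placed), boxsize=L)
            break
        else:
            raise DensityError(
                f"failed to place chain {len(placed)} after "
                f"{_MAX_CHAIN_ATTEMPTS} attempts; increase the box or lower "
                f"min_separation"
            )
    positions = np.vstack(placed)
    chain_of, bonds, angles = chain_topology([spec.dp] * spec.n_chains)
    return PolymerConfiguration(
        positions=positions,
        velocities=_thermal_velocities(spec.n_beads, params, rng),
        chain_of=chain_of, bonds=bonds, angles=angles,
        box_edge=L, flexible=False,
    )


def single_chain_system(
    dp: int,
    flexible: bool,
    params: SimulationParameters,
    seed: int = 0,
    box_factor: float = 2.5,
) -> PolymerConfiguration:
    """One straight chain in a box large enough to suppress self-images.

    The box edge is ``box_factor`` times the contour length (>= 2x), so a
    chain can never interact with its periodic images.  Used for
    persistence-length measurements.
    """
    if dp < 10:
        raise ValueError("dp must be >= 10 for a meaningful chain")
    if box_factor < 2.0:
        raise ValueError("box_factor must be >= 2 to isolate periodic images")
    rng = np.random.default_rng(seed)
    b = params.bond_length
    contour = (dp - 1) * b
    L = box_factor * contour
    start = L / 2.0 - contour / 2.0
    positions = np.zeros((dp, 3))
    positions[:, 0] = start + np.arange(dp) * b
    positions[:, 1] = L / 2.0
    positions[:, 2] = L / 2.0
    chain_of, bonds, angles = chain_topology([dp])
    return PolymerConfiguration(
        positions=positions,
        velocities=_thermal_velocities(dp, params, rng),
        chain_of=chain_of, bonds=bonds, angles=angles,
        box_edge=L, flexible=flexible,
    )


def _scaled(value: float, n_beads: int, ref_beads: int = 10_000) -> float:
    """Density-preserving box-edge scaling by the cube root of the count ratio."""
    return value * (n_beads / ref_beads) ** (1.0 / 3.0)


def preset(
    name: str, seed: int = 0
) -> Tuple[SystemSpec, ProtocolPlan, SimulationParameters]:
    """Named study conditions: ``full``, ``demo`` or ``ci``.

    ``full`` mirrors the reference protocol (200 chains x 50 beads,
    compression over 1e7 + 1e6 steps to (48 sigma)^3 then (30 sigma)^3,
    6e8 assembly steps, 2e8-step stiff/flexible stages, P_CL in
    {0, 5, 15, 25}%, 3 replicas).  ``demo`` is a minutes-scale reduction
    (20 chains x 25 beads) preserving the compressed density and the
    stage structure; ``ci`` is a seconds-scale smoke test.

    All presets ship with K_theta calibrated so the quadrature persistence
    length of the stiff stage is 50 bead radii.
    """
    params = SimulationParameters()
    cal = calibrate_bending_constant(
        STIFF_LP_OVER_R * params.r, params.bond_length, params.kBT
    )
    params = params.with_(K_theta=cal.K_theta)

    if name == "full":
        n_beads = 200 * 50
        spec = SystemSpec(n_chains=200, dp=50, box_edge=399.6, seed=seed)
        plan = ProtocolPlan(
            n_chains=200, dp=50, initial_box=399.6,
            compression_targets=[(48.0, 10_000_000), (30.0, 1_000_000)],
            assembly_steps=600_000_000,
            n_conformations=4,
            pcl_values=[0.0, 0.05, 0.15, 0.25],
            stage_steps=200_000_000,
            n_replicas=3,
            record_every=100_000,
            snapshot_every=3_000_000,
            master_seed=seed,
        )
    elif name == "demo":
        n_beads = 20 * 25
        # short cutoff: the r^-12 repulsion is < 4e-3 kBT beyond 1.8 sigma,
        # and the shorter interaction range keeps desk-scale runs fast.
        # epsilon = 0.25 kBT puts the mixture in the contact-rich regime
        # where the Bernoulli crosslinking rule yields a spanning network
        # (O(1) links per chain at P_CL = 25%)
        params = params.with_(d_cutoff=1.8, epsilon=0.25)
        spec = SystemSpec(
            n_chains=20, dp=25, box_edge=_scaled(399.6, n_beads), seed=seed
        )
        plan = ProtocolPlan(
            n_chains=20, dp=25, initial_box=spec.box_edge,
            compression_targets=[
                (_scaled(48.0, n_beads), 10_000),
                (_scaled(30.0, n_beads), 1_000),
            ],
            assembly_steps=200_000,
            n_conformations=4,
            pcl_values=[0.0, 0.05, 0.15, 0.25],
            stage_steps=100_000,
            n_replicas=3,
            record_every=200,
            snapshot_every=1_000,
            master_seed=seed,
        )
    elif name == "ci":
        n_beads = 10 * 10
        params = params.with_(d_cutoff=1.8, epsilon=0.25)
        spec = SystemSpec(
            n_chains=10, dp=10, box_edge=_scaled(399.6, n_beads), seed=seed
        )
        plan = ProtocolPlan(
            n_chains=10, dp=10, initial_box=spec.box_edge,
            compression_targets=[
                (_scaled(48.0, n_beads), 500),
                (_scaled(30.0, n_beads), 200),
            ],
            assembly_steps=2_000,
            n_conformations=2,
            pcl_values=[0.0, 0.25],
            stage_steps=1_000,
            n_replicas=1,
            record_every=20,
            snapshot_every=100,
            master_seed=seed,
        )
    else:
        raise ValueError(
            f"unknown preset {name!r}; available presets: full, demo, ci"
        )
    return spec, plan, params
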