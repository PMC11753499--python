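"""Langevin dynamics engine with optional Berendsen pressure coupling.

The integrator is the BAOAB splitting of the Langevin equation (half kick,
half drift, exact Ornstein-Uhlenbeck velocity update, half drift, half
kick).  In the free-particle limit it reproduces the Einstein relation
D = kBT/(m*gamma) and a harmonic degree of freedom equilibrates to
<KE> = kBT/2 per dof, which the test suite verifies.  Pressure coupling is
the Berendsen weak-coupling scheme: each step the box and all coordinates
are rescaled isotropically by mu = [1 - kappa*(dt/tau_p)*(p_target - P)]^(1/3),
clamped to configured bounds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np

from . import _kernels
from .analysis import VolumeTrace, closed_packing_volume
from .config import PolymerConfiguration
from .errors import GeometryError, OverlapError, StabilityError
from .params import SimulationParameters
from .potentials import _exclusion_keys, repulsion_shift

logger = logging.getLogger(__name__)

_MAX_SEED = 2**31 - 1


@dataclass
class StageOptions:
    """Options controlling one dynamics stage.

    ``box_schedule`` is an optional ``(target_edge, n_schedule_steps)`` pair
    requesting a deterministic affine box interpolation; it is mutually
    exclusive with ``barostat_on``.  ``flexible=None`` inherits the flag from
    the configuration.
    """

    n_steps: int
    barostat_on: bool = False
    flexible: Optional[bool] = None
    box_schedule: Optional[Tuple[float, int]] = None
    record_every: int = 100
    snapshot_every: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_steps <= 0:
            raise ValueError("n_steps must be strictly positive")
        if self.record_every < 1:
            raise ValueError("record_every must be >= 1")
        if self.box_schedule is not None and self.barostat_on:
            raise ValueError("box_schedule and barostat_on are mutually exclusive")


@dataclass
class StageResult:
    """Outcome of one stage: volume trace, final state, per-stage averages."""

    label: str
    trace: VolumeTrace
    final_config: PolymerConfiguration
    mean_volume: float
    mean_volume_tail: float
    pressure: np.ndarray
    e_pot: np.ndarray
    e_angle: np.ndarray
    snapshots: List[PolymerConfiguration]
    n_clamped: int
    seed: int


def _pair_capacity(n: int) -> int:
    return int(min(n * (n - 1) // 2, max(4096, 192 * n)))


def _super_capacity(n: int) -> int:
    return int(min(n * (n - 1) // 2, max(8192, 384 * n)))


def run_stage(
    config: PolymerConfiguration,
    options: StageOptions,
    params: SimulationParameters,
    label: str = "stage",
) -> StageResult:
    """Run one Langevin stage and return its result.

    Bit-reproducible for a fixed seed on one platform.  The input
    configuration is not modified.
    """
    flexible = config.flexible if options.flexible is None else options.flexible
    rlist = params.d_cutoff + params.skin
    if config.box_edge <= 2.0 * rlist:
        raise GeometryError(
            f"box edge {config.box_edge:.3g} must exceed twice the interaction "
            f"range {rlist:.3g} (cutoff + skin)"
        )
    if options.box_schedule is not None:
        target_edge, schedule_steps = options.box_schedule
        if target_edge >= config.box_edge:
            raise ValueError("box_schedule target must be smaller than current edge")
        if target_edge <= 2.0 * rlist:
            raise GeometryError("box_schedule target too small for interaction range")
        schedule_on = True
    else:
        target_edge, schedule_steps = config.box_edge, 0
        schedule_on = False

    pos = np.mod(config.positions.copy(), config.box_edge)
    vel = config.velocities.copy()
    bonded = (
        np.vstack([config.bonds, config.crosslinks])
        if config.crosslinks.size
        else config.bonds.copy()
    )
    if bonded.size == 0:
        bonded = np.empty((0, 2), dtype=np.int64)
    excl = _exclusion_keys(config)

    n_rec = options.n_steps // options.record_every + 1
    rec_step = np.zeros(n_rec, dtype=np.int64)
    rec_vol = np.zeros(n_rec)
    rec_pres = np.zeros(n_rec)
    rec_epot = np.zeros(n_rec)
    rec_eang = np.zeros(n_rec)
    n_snap_cap = (
        options.n_steps // options.snapshot_every if options.snapshot_every > 0 else 0
    )
    snaps_pos = np.zeros((n_snap_cap, config.n_beads, 3))
    snaps_vel = np.zeros((n_snap_cap, config.n_beads, 3))
    snaps_L = np.zeros(n_snap_cap)
    cap = _pair_capacity(config.n_beads)
    pair_i = np.zeros(cap, dtype=np.int32)
    pair_j = np.zeros(cap, dtype=np.int32)
    super_cap = _super_capacity(config.n_beads)
    super_i = np.zeros(super_cap, dtype=np.int32)
    super_j = np.zeros(super_cap, dtype=np.int32)

    status, final_L, got_rec, got_snap, n_clamped = _kernels.run_stage_kernel(
        *_kernels.STEP_FUNCS,
        pos, vel, float(config.box_edge),
        np.ascontiguousarray(bonded), np.ascontiguousarray(config.angles),
        excl,
        int(options.n_steps), params.dt, params.gamma, params.m, params.kBT,
        params.K_bond, params.bond_length, params.K_theta,
        float(np.cos(np.deg2rad(params.theta0))), bool(flexible),
        params.epsilon, params.sigma, params.d_cutoff,
        repulsion_shift(params), params.skin,
        bool(options.barostat_on), params.p_target, params.tau_p,
        params.kappa, params.mu_min, params.mu_max,
        schedule_on, float(target_edge), int(schedule_steps),
        int(options.record_every), int(options.snapshot_every),
        int(options.seed) & _MAX_SEED,
        rec_step, rec_vol, rec_pres, rec_epot, rec_eang,
        snaps_pos, snaps_vel, snaps_L, pair_i, pair_j, super_i, super_j,
    )

    if status & _kernels.STATUS_STABILITY:
        raise StabilityError(
            "per-step displacement exceeded half the neighbor-list skin; "
            "reduce dt or increase skin"
        )
    if status & _kernels.STATUS_OVERLAP:
        raise OverlapError("overlapping beads encountered during dynamics")
    if status & _kernels.STATUS_PAIR_OVERFLOW:
        raise GeometryError("neighbor-list capacity exceeded (system too dense)")
    if n_clamped:
        logger.warning(
            "%s: barostat scale factor clamped on %d steps", label, n_clamped
        )

    final = PolymerConfiguration(
        positions=pos, velocities=vel,
        chain_of=config.chain_of.copy(), bonds=config.bonds.copy(),
        angles=config.angles.copy(), crosslinks=config.crosslinks.copy(),
        box_edge=float(final_L), flexible=bool(flexible),
    )
    v_cp = closed_packing_volume(config.n_beads, params.r)
    trace = VolumeTrace(
        steps=rec_step[:got_rec].copy(),
        volume=rec_vol[:got_rec].copy(),
        normalized=rec_vol[:got_rec].copy() / v_cp,
    )
    snapshots = []
    for k in range(got_snap):
        snapshots.append(
            PolymerConfiguration(
                positions=snaps_pos[k].copy(), velocities=snaps_vel[k].copy(),
                chain_of=config.chain_of.copy(), bonds=config.bonds.copy(),
                angles=config.angles.copy(), crosslinks=config.crosslinks.copy(),
                box_edge=float(snaps_L[k]), flexible=bool(flexible),
            )
        )
    vol = trace.volume
    tail = vol[len(vol) // 2:]
    return StageResult(
        label=label, trace=trace, final_config=final,
        mean_volume=float(vol.mean()), mean_volume_tail=float(tail.mean()),
        pressure=rec_pres[:got_rec].copy(), e_pot=rec_epot[:got_rec].copy(),
        e_angle=rec_eang[:got_rec].copy(), snapshots=snapshots,
        n_clamped=int(n_clamped), seed=int(options.seed),
    )


def langevin_step(
    config: PolymerConfiguration,
    params: SimulationParameters,
    seed: int = 0,
) -> PolymerConfiguration:
    """Advance the configuration by a single BAOAB Langevin step."""
    res = run_stage(
        config,
        StageOptions(n_steps=1, record_every=1, seed=seed),
        params,
        label="single-step",
    )
    return res.final_config


def berendsen_rescale(
    config: PolymerConfiguration,
    p_inst: float,
    params: SimulationParameters,
) -> Tuple[PolymerConfiguration, float]:
    """Apply one Berendsen weak-coupling rescale; returns (config, mu).

    mu = [1 - kappa*(dt/tau_p)*(p_target - P)]^(1/3), clamped to
    [mu_min, mu_max]; mu = 1 leaves the configuration unchanged.
    """
    mu3 = 1.0 - params.kappa * (params.dt / params.tau_p) * (
        params.p_target - p_inst
    )
    if mu3 <= 0.0:
        logger.warning(
            "pathological pressure excursion (mu^3 = %.3g <= 0); clamping", mu3
        )
        mu = params.mu_min
    else:
        mu = float(np.clip(mu3 ** (1.0 / 3.0), params.mu_min, params.mu_max))
        if mu != mu3 ** (1.0 / 3.0):
            logger.warning("barostat scale factor clamped to %.4f", mu)
    out = config.copy()
    if mu != 1.0:
        out.positions = out.positions * mu
        out.box_edge = out.box_edge * mu
    return out, mu


def neighbor_pairs(
    config: PolymerConfiguration, cutoff: float, skin: float
) -> np.ndarray:
    """Candidate interaction pairs within cutoff + skin.

    A superset of all pairs within the cutoff, excluding bonded (chain or
    crosslink) pairs.  Raises GeometryError when the box is too small for the
    requested interaction range.
    """
    rlist = cutoff + skin
    if rlist >= config.box_edge / 2.0:
        raise GeometryError(
            f"cutoff + skin = {rlist:.3g} must be below half the box edge "
            f"{config.box_edge / 2.0:.3g}"
        )
    pos = np.mod(config.positions, config.box_edge)
    cap = _pair_capacity(config.n_beads)
    while True:
        pair_i = np.zeros(cap, dtype=np.int32)
        pair_j = np.zeros(cap, dtype=np.int32)
        cnt = _kernels.build_pairs(
            pos, float(config.box_edge), rlist * rlist,
            _exclusion_keys(config), pair_i, pair_j,
        )
        if cnt >= 0:
            break
        cap *= 2
    return np.column_stack([pair_i[:cnt], pair_j[:cnt]]).astype(np.int64)
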