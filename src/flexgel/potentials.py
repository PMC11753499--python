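"""Interaction energies, forces and the pairwise virial.

Three terms act on the beads:

* a harmonic bond ``V_bond = K_bond (d - 2r)^2 / 2`` between consecutive
  beads of a chain and between crosslinked beads,
* the purely repulsive ``V_rep = 4 eps (sigma / d)^12`` between all
  non-bonded pairs within a cutoff (energy-shifted so it vanishes at the
  cutoff; the force is untouched),
* a bending term ``V_angle = K_theta (cos(theta) - cos(theta0))^2 / 2`` on
  every triad of consecutive bonded beads, switched off entirely when the
  configuration is flagged flexible.

This module is the plain-NumPy reference implementation; the compiled engine
kernels (:mod:`flexgel._kernels`) must agree with it, which the test suite
checks by finite differences and direct comparison.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np

from .config import PolymerConfiguration, minimum_image
from .errors import InvalidGeometryError, OverlapError
from .params import SimulationParameters

_OVERLAP_D2 = 1e-12


def repulsion_shift(params: SimulationParameters) -> float:
    """Energy shift making V_rep continuous (zero) at the cutoff."""
    return -4.0 * params.epsilon * (params.sigma / params.d_cutoff) ** 12


def bond_energy(d: float, params: SimulationParameters) -> Tuple[float, float]:
    """Harmonic bond energy and signed scalar force -dV/dd at separation d."""
    if d <= 0:
        raise InvalidGeometryError(f"bond distance must be positive, got {d}")
    x = d - params.bond_length
    return 0.5 * params.K_bond * x * x, -params.K_bond * x


def repulsive_energy(d_ij: float, params: SimulationParameters) -> Tuple[float, float]:
    """Shifted r^-12 repulsion energy and signed scalar force -dV/dd."""
    if d_ij <= 0:
        raise OverlapError(f"pair distance must be positive, got {d_ij}")
    if d_ij >= params.d_cutoff:
        return 0.0, 0.0
    s_over_d12 = (params.sigma / d_ij) ** 12
    energy = 4.0 * params.epsilon * s_over_d12 + repulsion_shift(params)
    force = 48.0 * params.epsilon * s_over_d12 / d_ij
    return energy, force


def angle_energy(
    theta: float, params: SimulationParameters, flexible: bool = False
) -> Tuple[float, float]:
    """Bending energy and torque magnitude |dV/dtheta| at interior angle theta.

    ``theta`` is in degrees (interface convention); a straight chain has
    theta = 180. When ``flexible`` the term is identically zero.
    """
    if not (0.0 <= theta <= 180.0):
        raise InvalidGeometryError(f"theta must lie in [0, 180] degrees, got {theta}")
    if flexible or params.K_theta == 0.0:
        return 0.0, 0.0
    th = np.deg2rad(theta)
    c0 = np.cos(np.deg2rad(params.theta0))
    dc = np.cos(th) - c0
    energy = 0.5 * params.K_theta * dc * dc
    torque = abs(params.K_theta * dc * np.sin(th))
    return float(energy), float(torque)


@dataclass
class ForceResult:
    """Forces, total energy, scalar virial and an energy breakdown."""

    forces: np.ndarray
    energy: float
    virial: float
    e_bond: float
    e_rep: float
    e_angle: float


def _exclusion_keys(config: PolymerConfiguration) -> np.ndarray:
    """Sorted pair keys (i*N+j, i<j) excluded from the repulsion.

    Both chain bonds and crosslinks are bonded interactions with rest length
    2r; the repulsion is excluded for both.
    """
    n = config.n_beads
    pairs = np.vstack([config.bonds, config.crosslinks]) if config.crosslinks.size \
        else config.bonds
    if pairs.size == 0:
        return np.empty(0, dtype=np.int64)
    lo = np.minimum(pairs[:, 0], pairs[:, 1])
    hi = np.maximum(pairs[:, 0], pairs[:, 1])
    return np.unique(lo * n + hi)


def compute_forces(
    config: PolymerConfiguration, params: SimulationParameters
) -> ForceResult:
    """Evaluate all interactions for a configuration (O(N^2) reference path).

    Forces are the negative gradient of the summed energy under periodic
    minimum-image distances; the scalar virial is sum(f_ij . d_ij) over all
    pairwise terms, with the three-body bending term accumulated through its
    two vertex-relative displacement vectors.
    """
    pos = config.positions
    n = config.n_beads
    box = config.box_edge
    forces = np.zeros_like(pos)
    virial = 0.0
    e_bond = 0.0
    e_rep = 0.0
    e_angle = 0.0

    # --- repulsion over all non-bonded pairs within the cutoff -------------
    if n > 1:
        disp = minimum_image(pos[:, None, :] - pos[None, :, :], box)
        d2 = np.einsum("ijk,ijk->ij", disp, disp)
        iu, ju = np.triu_indices(n, k=1)
        d2u = d2[iu, ju]
        if np.any(d2u < _OVERLAP_D2):
            raise OverlapError("overlapping beads: pair distance ~ 0")
        keys = iu * n + ju
        excluded = np.isin(keys, _exclusion_keys(config))
        within = (d2u < params.d_cutoff**2) & ~excluded
        if np.any(within):
            ii, jj = iu[within], ju[within]
            d2w = d2u[within]
            inv2 = params.sigma**2 / d2w
            inv12 = inv2**6
            e_rep = float(np.sum(4.0 * params.epsilon * inv12
                                 + repulsion_shift(params)))
            # f/d along the displacement: 48 eps (sigma/d)^12 / d^2
            f_over_d = 48.0 * params.epsilon * inv12 / d2w
            fvec = f_over_d[:, None] * disp[ii, jj]
            np.add.at(forces, ii, fvec)
            np.add.at(forces, jj, -fvec)
            virial += float(np.sum(f_over_d * d2w))

    # --- bonds and crosslinks ----------------------------------------------
    bonded = np.vstack([config.bonds, config.crosslinks]) if config.crosslinks.size \
        else config.bonds
    if bonded.size:
        bi, bj = bonded[:, 0], bonded[:, 1]
        dvec = minimum_image(pos[bi] - pos[bj], box)
        d = np.linalg.norm(dvec, axis=1)
        if np.any(d <= 0):
            raise OverlapError("bonded beads coincide")
        x = d - params.bond_length
        e_bond = float(np.sum(0.5 * params.K_bond * x * x))
        f_over_d = -params.K_bond * x / d
        fvec = f_over_d[:, None] * dvec
        np.add.at(forces, bi, fvec)
        np.add.at(forces, bj, -fvec)
        virial += float(np.sum(f_over_d * d * d))

    # --- bending ------------------------------------------------------------
    if not config.flexible and params.K_theta > 0.0 and config.angles.size:
        ia, ja, ka = config.angles[:, 0], config.angles[:, 1], config.angles[:, 2]
        a = minimum_image(pos[ia] - pos[ja], box)
        b = minimum_image(pos[ka] - pos[ja], box)
        la = np.linalg.norm(a, axis=1)
        lb = np.linalg.norm(b, axis=1)
        c = np.clip(np.einsum("ij,ij->i", a, b) / (la * lb), -1.0, 1.0)
        c0 = np.cos(np.deg2rad(params.theta0))
        dc = c - c0
        e_angle = float(np.sum(0.5 * params.K_theta * dc * dc))
        dVdc = params.K_theta * dc
        ga = b / (la * lb)[:, None] - (c / la**2)[:, None] * a
        gb = a / (la * lb)[:, None] - (c / lb**2)[:, None] * b
        fi = -dVdc[:, None] * ga
        fk = -dVdc[:, None] * gb
        np.add.at(forces, ia, fi)
        np.add.at(forces, ka, fk)
        np.add.at(forces, ja, -(fi + fk))
        virial += float(np.sum(np.einsum("ij,ij->i", fi, a)
                               + np.einsum("ij,ij->i", fk, b)))

    energy = e_bond + e_rep + e_angle
    return ForceResult(forces=forces, energy=energy, virial=virial,
                       e_bond=e_bond, e_rep=e_rep, e_angle=e_angle)


def instantaneous_pressure(
    config: PolymerConfiguration, virial: float, params: SimulationParameters
) -> float:
    """Virial pressure P = (N kBT + W/3) / V with W = sum(f_ij . d_ij)."""
    volume = config.box_edge**3
    if volume <= 0:
        raise InvalidGeometryError("box volume must be positive")
    return (config.n_beads * params.kBT + virial / 3.0) / volume
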