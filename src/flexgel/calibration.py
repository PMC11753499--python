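"""Bending-constant calibration and reduced-unit audits.

The bending potential V_angle = K_theta [cos(theta) - cos(theta0)]^2 / 2 is
quartic (not harmonic) around its minimum at theta0 = 180 deg, so no
closed-form worm-like-chain mapping applies.  Instead the single-angle
Boltzmann average <cos theta> is computed by adaptive quadrature and the
persistence length follows from the freely rotating chain relation

    exp(-b / l_p) = -<cos theta>,

where b is the bond length and the minus sign comes from the interior-angle
convention: a straight chain has theta = 180 deg, so consecutive tangents
are aligned when cos(theta) = -1.  Calibration root-solves this relation for
K_theta.  The quadrature ignores excluded volume (single-angle
factorization); agreement with simulation is established by the round-trip
test in the suite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.integrate import quad
from scipy.optimize import brentq

from .errors import CalibrationError


@dataclass
class CalibrationResult:
    """Outcome of the bending-constant calibration."""

    K_theta: float
    target_lp: float
    bond_length: float
    kBT: float
    predicted_cos: float       # <cos theta> at the solved K_theta
    predicted_lp: float        # quadrature-level persistence length
    residual: float            # |achieved - target| / target at quadrature level

    def to_dict(self) -> dict:
        return {
            "K_theta": self.K_theta,
            "target_lp": self.target_lp,
            "bond_length": self.bond_length,
            "kBT": self.kBT,
            "predicted_cos": self.predicted_cos,
            "predicted_lp": self.predicted_lp,
            "residual": self.residual,
        }


def predicted_cos_theta(K_theta: float, kBT: float = 1.0) -> float:
    """Boltzmann average <cos theta> of a single interior angle.

    <cos theta> = int_0^pi cos(t) w(t) sin(t) dt / int_0^pi w(t) sin(t) dt
    with w = exp(-K_theta (cos t + 1)^2 / (2 kBT)).  Substituting c = cos t
    turns both integrals into smooth 1-D integrals over [-1, 1].
    Monotone decreasing in K_theta, from 0 (isotropic) toward -1 (pinned at
    theta = 180 deg).
    """
    if K_theta < 0:
        raise ValueError("K_theta must be non-negative")
    if K_theta == 0:
        return 0.0
    beta = K_theta / kBT

    # weight relative to the maximum (at c = -1) to avoid underflow
    def w(c):
        return np.exp(-0.5 * beta * (c + 1.0) ** 2)

    num, num_err = quad(lambda c: c * w(c), -1.0, 1.0,
                        limit=500, epsabs=1e-13, epsrel=1e-11)
    den, den_err = quad(w, -1.0, 1.0, limit=500, epsabs=1e-13, epsrel=1e-11)
    if den <= 0 or den_err > 1e-6 * abs(den):
        raise ArithmeticError("quadrature failed to converge")
    return float(num / den)


def quadrature_lp(K_theta: float, bond_length: float, kBT: float = 1.0) -> float:
    """Persistence length predicted from the single-angle quadrature."""
    mc = -predicted_cos_theta(K_theta, kBT)
    if mc <= 0:
        raise CalibrationError("no tangent alignment at this K_theta")
    return -bond_length / math.log(mc)


def calibrate_bending_constant(
    target_lp: float, bond_length: float, kBT: float = 1.0,
    tol: float = 1e-10,
) -> CalibrationResult:
    """Solve for the K_theta whose quadrature persistence length is target_lp.

    Solves exp(-b/target_lp) = -<cos theta>(K_theta) by bracketing and Brent
    root-finding; monotonicity of <cos theta> in K_theta guarantees a unique
    root for any target correlation in (0, 1).
    """
    if target_lp <= 0:
        raise CalibrationError("target_lp must be positive")
    if bond_length <= 0:
        raise ValueError("bond_length must be positive")
    target_corr = math.exp(-bond_length / target_lp)  # in (0, 1)

    def f(K):
        return -predicted_cos_theta(K, kBT) - target_corr

    k_lo, k_hi = 0.0, 1.0
    # expand until the bracket contains the root
    for _ in range(80):
        if f(k_hi) > 0:
            break
        k_lo = k_hi
        k_hi *= 2.0
    else:
        raise CalibrationError(
            f"target_lp = {target_lp:.3g} unreachable: required tangent "
            f"correlation {target_corr:.6f} not attained at K_theta = {k_hi:.3g}"
        )
    K = brentq(f, k_lo, k_hi, xtol=tol, rtol=1e-14)
    achieved_cos = predicted_cos_theta(K, kBT)
    achieved_lp = -bond_length / math.log(-achieved_cos) if achieved_cos < 0 else math.inf
    residual = abs(achieved_lp - target_lp) / target_lp
    return CalibrationResult(
        K_theta=float(K), target_lp=float(target_lp),
        bond_length=float(bond_length), kBT=float(kBT),
        predicted_cos=float(achieved_cos), predicted_lp=float(achieved_lp),
        residual=float(residual),
    )


@dataclass
class TimeAudit:
    """Implied time step and converted durations from a printed conversion."""

    dt_tau: float              # implied time step in units of tau
    duration_tau: float        # steps * dt_tau
    consistent: bool           # within 1% of an independently stated duration
    mismatch: float            # relative mismatch (0 when no reference given)


def audit_time_units(
    steps: int,
    reference_steps: int,
    reference_tau: float,
    stage_tau: float | None = None,
) -> TimeAudit:
    """Convert a step count to tau units via a reference conversion.

    ``reference_steps`` steps are stated to span ``reference_tau`` diffusion
    times; the implied time step is their ratio.  When ``stage_tau`` is
    given, the converted duration is checked against it and flagged if the
    two disagree by more than 1%.
    """
    if reference_steps <= 0 or reference_tau <= 0:
        raise ValueError("reference conversion must be positive")
    if steps < 0:
        raise ValueError("steps must be non-negative")
    dt_tau = reference_tau / reference_steps
    duration = steps * dt_tau
    if stage_tau is None:
        return TimeAudit(dt_tau, duration, True, 0.0)
    mismatch = abs(duration - stage_tau) / stage_tau if stage_tau else 0.0
    return TimeAudit(dt_tau, duration, mismatch <= 0.01, mismatch)
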