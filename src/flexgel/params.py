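"""Model constants and reduced-unit bookkeeping.

Reduced units: lengths in the repulsion length sigma, energies in kBT, masses
in bead masses.  The bead radius is tied to sigma through the minimum of the
r^-12 repulsion, r = sigma * 2**(1/6) / 2, so the bond rest length 2r equals
the distance at which two soft spheres of radius r touch.  The natural time
unit of the model is the bead diffusion time tau = (2r)^2 / D with
D = kBT / (m * gamma).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, replace
from typing import Optional

# Time step expressed as a fraction of the bead diffusion time tau.  The
# default reproduces the step-to-tau conversion used throughout the protocol
# (6e8 steps of self-assembly correspond to 0.952e6 tau).
DT_OVER_TAU = 1.587e-3

# Barostat coupling time as a fraction of tau (about 50 time steps).
TAU_P_OVER_TAU = 0.07937


@dataclass
class SimulationParameters:
    """All interaction constants, Langevin settings and barostat settings.

    Parameters are expressed in reduced units (sigma, kBT, bead mass).
    ``r``, ``D`` and ``tau`` are derived quantities and cannot be set
    directly; ``dt`` and ``tau_p`` default to fixed fractions of ``tau``.
    """

    K_bond: float = 200.0        # bond elastic constant [kBT / sigma^2]
    epsilon: float = 1.0         # repulsion strength [kBT]
    sigma: float = 1.0           # repulsion length [sigma]
    d_cutoff: float = 2.5        # repulsion cutoff [sigma]
    K_theta: float = 0.0         # bending constant [kBT]; 0 = fully flexible
    theta0: float = 180.0        # reference bond angle [degrees]
    gamma: float = 1.0           # velocity relaxation rate [1/t0]
    m: float = 1.0               # bead mass
    kBT: float = 1.0             # thermal energy
    dt: Optional[float] = None   # integration time step; default DT_OVER_TAU * tau
    p_target: float = 0.5        # barostat target pressure [kBT / sigma^3]
    tau_p: Optional[float] = None  # barostat coupling time; default TAU_P_OVER_TAU * tau
    kappa: float = 1.0           # barostat compressibility factor [sigma^3 / kBT]
    mu_min: float = 0.99         # lower clamp on the isotropic scale factor
    mu_max: float = 1.01         # upper clamp on the isotropic scale factor
    skin: float = 0.4            # neighbor-list buffer [sigma]

    def __post_init__(self) -> None:
        for name in ("K_bond", "epsilon", "sigma", "gamma", "m", "kBT"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.K_theta < 0:
            raise ValueError("K_theta must be non-negative")
        if self.d_cutoff < self.sigma:
            raise ValueError("d_cutoff must be at least sigma")
        if self.dt is None:
            self.dt = DT_OVER_TAU * self.tau
        if self.dt <= 0:
            raise ValueError("dt must be strictly positive")
        if self.tau_p is None:
            self.tau_p = TAU_P_OVER_TAU * self.tau
        if self.tau_p <= 0:
            raise ValueError("tau_p must be strictly positive")
        if not (0 < self.mu_min <= 1.0 <= self.mu_max):
            raise ValueError("mu bounds must bracket 1")
        if self.skin <= 0:
            raise ValueError("skin must be strictly positive")

    @property
    def r(self) -> float:
        """Bead radius: r = sigma * 2**(1/6) / 2."""
        return self.sigma * 2.0 ** (1.0 / 6.0) / 2.0

    @property
    def bond_length(self) -> float:
        """Rest length of bonds and crosslinks, 2r."""
        return 2.0 * self.r

    @property
    def D(self) -> float:
        """Single-bead diffusion coefficient, kBT / (m * gamma)."""
        return self.kBT / (self.m * self.gamma)

    @property
    def tau(self) -> float:
        """Bead diffusion time, (2r)^2 / D."""
        return (2.0 * self.r) ** 2 / self.D

    def with_(self, **kwargs) -> "SimulationParameters":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationParameters":
        return cls(**d)
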