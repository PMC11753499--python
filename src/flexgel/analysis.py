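"""Observables: close-packing normalization, swelling factor, persistence
length and the (volume, crosslinking-probability) phase map.

The central observable is the swelling factor ``S_V``, the ratio of the
time-averaged box volume in the flexible stage to that in the stiff stage;
``S_V < 1`` means the network shrank when the chains lost their bending
rigidity.  Volumes are normalized by the theoretical close-packing volume
``V_CP`` of N spheres of radius r, ``V_CP = N * V_mon / phi_cp`` with
``phi_cp = pi / (3 sqrt 2)`` the close-packing fraction, which simplifies to
``4 sqrt(2) r^3 N``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence, Union

import numpy as np
import pandas as pd

from .errors import EstimationError

#: Sphere close-packing fraction pi / (3 sqrt 2) ~ 0.7405.
CLOSE_PACKING_FRACTION = math.pi / (3.0 * math.sqrt(2.0))


@dataclass
class VolumeTrace:
    """A (step, volume, V/V_CP) series recorded during one stage."""

    steps: np.ndarray
    volume: np.ndarray
    normalized: np.ndarray

    def __post_init__(self) -> None:
        self.steps = np.asarray(self.steps, dtype=np.int64)
        self.volume = np.asarray(self.volume, dtype=np.float64)
        self.normalized = np.asarray(self.normalized, dtype=np.float64)
        if not (len(self.steps) == len(self.volume) == len(self.normalized)):
            raise ValueError("trace series must have equal lengths")

    @classmethod
    def from_volumes(cls, steps, volume, v_cp: float) -> "VolumeTrace":
        volume = np.asarray(volume, dtype=np.float64)
        return cls(steps=steps, volume=volume, normalized=volume / v_cp)

    def __len__(self) -> int:
        return len(self.steps)

    def tail(self, window_fraction: float) -> "VolumeTrace":
        """Trailing fraction of the trace (at least one entry)."""
        if not (0.0 < window_fraction <= 1.0):
            raise ValueError("window_fraction must lie in (0, 1]")
        k = max(1, int(math.ceil(len(self) * window_fraction)))
        return VolumeTrace(self.steps[-k:], self.volume[-k:], self.normalized[-k:])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"step": self.steps, "volume": self.volume, "v_over_vcp": self.normalized}
        )


@dataclass
class PhaseMapEntry:
    """One cell of the swelling phase map."""

    v_stiff_norm: float   # <V_stiff> / V_CP
    pcl: float            # crosslinking probability
    sv: float             # swelling factor <V_flex>/<V_stiff>
    n_replicas: int
    conformation: str = ""

    def __post_init__(self) -> None:
        if not (0.0 <= self.pcl <= 1.0):
            raise ValueError("pcl must lie in [0, 1]")
        if self.sv <= 0:
            raise ValueError("sv must be positive")


def closed_packing_volume(n_monomers: int, r: float) -> float:
    """Close-packing volume of ``n_monomers`` spheres of radius ``r``.

    V_CP = V_mon * N / phi_cp = (3 sqrt 2 / pi) * (4 pi r^3 / 3) * N
         = 4 sqrt(2) r^3 N.
    """
    if n_monomers < 0:
        raise ValueError("monomer count must be non-negative")
    if r <= 0:
        raise ValueError("bead radius must be positive")
    v_mon = 4.0 * math.pi * r**3 / 3.0
    return v_mon * n_monomers / CLOSE_PACKING_FRACTION


TraceOrTraces = Union[VolumeTrace, Sequence[VolumeTrace]]


def _pooled_tail(traces: TraceOrTraces, window_fraction: float) -> np.ndarray:
    if isinstance(traces, VolumeTrace):
        traces = [traces]
    if len(traces) == 0:
        raise EstimationError("no traces supplied")
    parts = [t.tail(window_fraction).volume for t in traces]
    pooled = np.concatenate(parts)
    if pooled.size == 0:
        raise EstimationError("empty averaging window")
    return pooled


def pooled_tail_mean(
    traces: TraceOrTraces, window_fraction: float = 0.5, normalized: bool = False
) -> float:
    """Replica-pooled time average over the trailing window of each trace."""
    if isinstance(traces, VolumeTrace):
        traces = [traces]
    if normalized:
        parts = [t.tail(window_fraction).normalized for t in traces]
    else:
        parts = [t.tail(window_fraction).volume for t in traces]
    pooled = np.concatenate(parts)
    if pooled.size == 0:
        raise EstimationError("empty averaging window")
    return float(pooled.mean())


def swelling_factor(
    stiff: TraceOrTraces,
    flexible: TraceOrTraces,
    window_fraction: float = 0.5,
) -> float:
    """Swelling factor S_V = <V_flexible> / <V_stiff>.

    Time averages are taken over the trailing ``window_fraction`` of each
    trace; replicas are pooled (trailing windows concatenated) before
    averaging.  The default trailing half mirrors averaging the last half of
    each stage.
    """
    v_stiff = _pooled_tail(stiff, window_fraction).mean()
    v_flex = _pooled_tail(flexible, window_fraction).mean()
    return float(v_flex / v_stiff)


@dataclass
class PersistenceLengthResult:
    """Fitted persistence length with a bootstrap confidence interval."""

    lp: float
    ci_low: float
    ci_high: float
    bond_length: float
    correlation: np.ndarray      # mean tangent correlation C(s)
    n_fit: int                   # number of separations used in the fit
    n_snapshots: int
    capped: bool = False         # slope was flat; lp reported at the cap


def _tangent_correlation(snapshots: np.ndarray) -> tuple[np.ndarray, float]:
    """Mean tangent-tangent correlation C(s) and mean bond length.

    ``snapshots`` has shape (S, n_beads, 3) with unwrapped coordinates.
    """
    bonds = np.diff(snapshots, axis=1)                     # (S, nb, 3)
    lengths = np.linalg.norm(bonds, axis=2)
    t = bonds / lengths[..., None]
    nb = t.shape[1]
    corr = np.empty(nb)
    for s in range(nb):
        if s == 0:
            corr[s] = 1.0
        else:
            corr[s] = float(np.mean(np.einsum("sid,sid->si", t[:, :-s], t[:, s:])))
    return corr, float(lengths.mean())


def _fit_lp(
    corr: np.ndarray, bond_length: float, lp_cap: float,
    threshold: float, min_points: int, max_points: int,
) -> tuple[float, bool, int]:
    """Log-linear fit of C(s) = exp(-s b / lp); returns (lp, capped, n_fit).

    The fit range runs from s = 0 while the mean correlation stays above
    ``threshold``, but never beyond about one persistence length (estimated
    from the nearest-neighbor decay): past that point the decay of a real
    chain is dominated by excluded-volume correlations, which the worm-like
    chain model does not describe and which would bias the fit upward.  It
    is additionally capped at ``max_points`` separations: the statistical
    error of C(s) at large s is controlled by the chain's slowest bending
    modes (relaxation ~ s^4), so long fit ranges add noise much faster than
    signal.
    """
    n_fit = 1
    while n_fit < len(corr) and corr[n_fit] > threshold:
        n_fit += 1
    if 0.0 < corr[1] < 1.0:
        lp_bonds = -1.0 / math.log(corr[1])
        n_fit = min(n_fit, int(round(lp_bonds)) + 1)
    n_fit = max(min(n_fit, max_points, len(corr)), min_points)
    c = corr[:n_fit]
    if np.any(c <= 0):
        raise EstimationError(
            "no positive-correlation regime: tangent correlations are not "
            "positive over the minimum fit range"
        )
    s = np.arange(n_fit, dtype=float)
    slope = np.polyfit(s, np.log(c), 1)[0]
    if slope >= -bond_length / lp_cap:
        return lp_cap, True, n_fit
    return float(-bond_length / slope), False, n_fit


def persistence_length(
    chain_snapshots: np.ndarray,
    lp_cap: float = 1e5,
    threshold: float = 0.05,
    min_points: int = 3,
    max_points: int = 13,
    n_bootstrap: int = 200,
    seed: int = 0,
) -> PersistenceLengthResult:
    """Persistence length from an ensemble of single-chain conformations.

    Fits ``<t_i . t_{i+s}> = exp(-s b / l_p)`` (b = mean bond length) by
    log-linear least squares over the separations where the mean correlation
    exceeds ``threshold`` (at least ``min_points`` separations, counting
    s = 0).  The confidence interval is a moving-block bootstrap over
    snapshots, which tolerates residual correlation between consecutive
    samples.  A perfectly straight ensemble yields a flat correlation; the
    estimate is then reported at ``lp_cap`` and flagged.

    Parameters
    ----------
    chain_snapshots : (S, n_beads, 3) array of unwrapped coordinates, with
        S >= 100 decorrelated snapshots of a chain with >= 10 bonds.
    """
    snaps = np.asarray(chain_snapshots, dtype=np.float64)
    if snaps.ndim != 3 or snaps.shape[2] != 3:
        raise ValueError("chain_snapshots must have shape (S, n_beads, 3)")
    n_snap, n_beads = snaps.shape[0], snaps.shape[1]
    if n_snap < 100:
        raise ValueError("need at least 100 snapshots")
    if n_beads < 11:
        raise ValueError("need a chain with at least 10 bonds")

    corr, b = _tangent_correlation(snaps)
    lp, capped, n_fit = _fit_lp(corr, b, lp_cap, threshold, min_points,
                                max_points)

    rng = np.random.default_rng(seed)
    block = max(1, n_snap // 50)
    n_blocks = int(math.ceil(n_snap / block))
    estimates = []
    for _ in range(n_bootstrap):
        starts = rng.integers(0, n_snap - block + 1, size=n_blocks)
        idx = np.concatenate([np.arange(s, s + block) for s in starts])[:n_snap]
        c_b, b_b = _tangent_correlation(snaps[idx])
        try:
            lp_b, _, _ = _fit_lp(c_b, b_b, lp_cap, threshold, min_points,
                                 max_points)
        except EstimationError:
            continue
        estimates.append(lp_b)
    if len(estimates) >= 10:
        ci_low, ci_high = np.percentile(estimates, [2.5, 97.5])
    else:
        ci_low, ci_high = lp, lp
    return PersistenceLengthResult(
        lp=float(lp), ci_low=float(ci_low), ci_high=float(ci_high),
        bond_length=b, correlation=corr, n_fit=n_fit,
        n_snapshots=n_snap, capped=capped,
    )


def phase_map(entries: Sequence[PhaseMapEntry]) -> pd.DataFrame:
    """Tabulate phase-map entries; cells carry a shrink/swell flag.

    Grid values equal the input S_V exactly (no interpolation).
    """
    if len(entries) == 0:
        raise ValueError("phase_map needs at least one entry")
    rows = []
    for e in entries:
        rows.append(
            {
                "v_stiff_norm": e.v_stiff_norm,
                "pcl": e.pcl,
                "sv": e.sv,
                "n_replicas": e.n_replicas,
                "conformation": e.conformation,
                "flag": "shrink" if e.sv < 1.0 else ("swell" if e.sv > 1.0 else "neutral"),
            }
        )
    return pd.DataFrame(rows).sort_values(["pcl", "v_stiff_norm"]).reset_index(drop=True)


def plot_phase_map(df: pd.DataFrame, path: str) -> None:
    """Render the swelling-factor map as a scatter heat map (PNG/PDF)."""
    from matplotlib.figure import Figure
    from matplotlib.colors import TwoSlopeNorm

    fig = Figure(figsize=(5, 4))
    ax = fig.add_subplot(111)
    sv = df["sv"].to_numpy()
    span = max(abs(np.log(sv)).max(), 0.05)
    norm = TwoSlopeNorm(vcenter=1.0, vmin=float(np.exp(-span)),
                        vmax=float(np.exp(span)))
    sc = ax.scatter(
        df["v_stiff_norm"], 100.0 * df["pcl"], c=sv, s=220, marker="s",
        cmap="coolwarm_r", norm=norm, edgecolors="k", linewidths=0.5,
    )
    fig.colorbar(sc, ax=ax, label=r"$S_V = \langle V_{flex}\rangle/\langle V_{stiff}\rangle$")
    ax.set_xlabel(r"$\langle V_{stiff}\rangle / V_{CP}$")
    ax.set_ylabel(r"$P_{CL}$ (%)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
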