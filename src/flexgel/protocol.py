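"""The four-phase pipeline: compression, self-assembly, crosslinking and the
stiff/flexible stage pair, over replicas and crosslinking probabilities.

A run proceeds as: random straight chains in a large box -> two deterministic
box compressions -> barostat-coupled self-assembly -> selection of k
conformations with different volumes -> for each conformation and each
crosslinking probability P_CL, Bernoulli crosslinking of close inter-chain
contacts followed by a "stiff" stage (bending potential on) and a "flexible"
stage (bending potential zeroed, crosslinks retained).  The P_CL = 0 control
reuses the tail of the self-assembly as its stiff stage and continues without
angular restraints for its flexible stage.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .analysis import (
    PhaseMapEntry,
    VolumeTrace,
    persistence_length,
    PersistenceLengthResult,
    pooled_tail_mean,
    swelling_factor,
)
from .config import PolymerConfiguration
from .engine import StageOptions, StageResult, run_stage
from .params import SimulationParameters

logger = logging.getLogger(__name__)

_LABELS = "abcdefghijklmnopqrstuvwxyz"


def seed_for(master_seed: int, *key) -> int:
    """Deterministic sub-seed (< 2^31) derived from a master seed and a key.

    Key parts are hashed with crc32 (stable across processes, unlike
    Python's randomized ``hash``) and folded into a SeedSequence.
    """
    h = [master_seed & 0x7FFFFFFF]
    for part in key:
        if isinstance(part, (int, np.integer)):
            h.append(int(part) & 0xFFFFFFFF)
        else:
            h.append(zlib.crc32(str(part).encode()) & 0xFFFFFFFF)
    return int(np.random.SeedSequence(h).generate_state(1)[0] & 0x7FFFFFFF)


@dataclass
class ProtocolPlan:
    """Plan for a full protocol run."""

    n_chains: int
    dp: int
    initial_box: float
    compression_targets: List[Tuple[float, int]]
    assembly_steps: int
    n_conformations: int
    pcl_values: List[float]
    stage_steps: int
    n_replicas: int
    record_every: int = 100
    snapshot_every: int = 1000
    master_seed: int = 0
    window_fraction: float = 0.5

    def __post_init__(self) -> None:
        edges = [e for e, _ in self.compression_targets]
        if any(b >= a for a, b in zip([self.initial_box] + edges, edges)):
            raise ValueError("compression targets must be strictly decreasing")
        if any(not (0.0 <= p <= 1.0) for p in self.pcl_values):
            raise ValueError("crosslinking probabilities must lie in [0, 1]")
        if self.n_replicas < 1:
            raise ValueError("n_replicas must be >= 1")
        if self.n_conformations < 1:
            raise ValueError("n_conformations must be >= 1")

    def to_dict(self) -> dict:
        return {
            "n_chains": self.n_chains, "dp": self.dp,
            "initial_box": self.initial_box,
            "compression_targets": [list(t) for t in self.compression_targets],
            "assembly_steps": self.assembly_steps,
            "n_conformations": self.n_conformations,
            "pcl_values": list(self.pcl_values),
            "stage_steps": self.stage_steps,
            "n_replicas": self.n_replicas,
            "record_every": self.record_every,
            "snapshot_every": self.snapshot_every,
            "master_seed": self.master_seed,
            "window_fraction": self.window_fraction,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ProtocolPlan":
        d = dict(d)
        d["compression_targets"] = [tuple(t) for t in d["compression_targets"]]
        return cls(**d)


# ---------------------------------------------------------------------------
# individual stages
# ---------------------------------------------------------------------------

def compress_to_volume(
    config: PolymerConfiguration,
    target_edge: float,
    n_steps: int,
    params: SimulationParameters,
    seed: int = 0,
    record_every: int = 100,
) -> StageResult:
    """Gradually reduce the box to ``target_edge`` while dynamics runs.

    The edge is interpolated linearly over ``n_steps`` and coordinates are
    scaled affinely each step; the final edge equals the target exactly.
    """
    if target_edge >= config.box_edge:
        raise ValueError("compression target must be below the current box edge")
    opts = StageOptions(
        n_steps=n_steps, barostat_on=False,
        box_schedule=(target_edge, n_steps),
        record_every=record_every, seed=seed,
    )
    return run_stage(config, opts, params, label="compress")


def self_assembly_stage(
    config: PolymerConfiguration,
    n_steps: int,
    params: SimulationParameters,
    seed: int = 0,
    record_every: int = 100,
    snapshot_every: int = 1000,
) -> StageResult:
    """Barostat-coupled (NPT) self-assembly, recording snapshots for
    conformation selection."""
    opts = StageOptions(
        n_steps=n_steps, barostat_on=True,
        record_every=record_every, snapshot_every=snapshot_every, seed=seed,
    )
    return run_stage(config, opts, params, label="assemble")


def stiff_stage(
    config: PolymerConfiguration,
    n_steps: int,
    params: SimulationParameters,
    seed: int = 0,
    record_every: int = 100,
) -> StageResult:
    """NPT dynamics with the bending potential active."""
    opts = StageOptions(
        n_steps=n_steps, barostat_on=True, flexible=False,
        record_every=record_every, seed=seed,
    )
    return run_stage(config, opts, params, label="stiff")


def flexible_stage(
    config: PolymerConfiguration,
    n_steps: int,
    params: SimulationParameters,
    seed: int = 0,
    record_every: int = 100,
) -> StageResult:
    """NPT dynamics with the bending potential zeroed; crosslinks retained."""
    opts = StageOptions(
        n_steps=n_steps, barostat_on=True, flexible=True,
        record_every=record_every, seed=seed,
    )
    return run_stage(config, opts, params, label="flexible")


# ---------------------------------------------------------------------------
# conformation selection and crosslinking
# ---------------------------------------------------------------------------

def select_conformations(
    snapshots: Sequence[PolymerConfiguration], k: int
) -> List[Tuple[str, PolymerConfiguration]]:
    """Pick k snapshots whose volumes span the observed range.

    Target volumes are evenly spaced between the largest and smallest
    recorded volume; each target is matched by the closest unused snapshot
    (earliest on ties).  The smallest-volume slot is by convention the final
    snapshot of the stage, labelled last.  Labels run 'a' (largest volume)
    to the k-th letter (final snapshot).  Deterministic given the snapshots.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if len(snapshots) < k:
        raise ValueError(f"need at least {k} snapshots, got {len(snapshots)}")
    vols = np.array([s.box_edge**3 for s in snapshots])
    chosen: List[int] = []
    last = len(snapshots) - 1
    if k == 1:
        chosen = [last]
    else:
        vmax, vmin = float(vols.max()), float(vols.min())
        used = {last}
        for j in range(k - 1):
            target = vmax - j * (vmax - vmin) / (k - 1)
            order = np.argsort(np.abs(vols - target), kind="stable")
            pick = next(int(i) for i in order if int(i) not in used)
            used.add(pick)
            chosen.append(pick)
        chosen.append(last)
    chosen_sorted = sorted(
        chosen, key=lambda i: (-vols[i], i)
    )
    # keep the final snapshot in the last (smallest-volume) slot
    if chosen_sorted[-1] != last:
        chosen_sorted.remove(last)
        chosen_sorted.append(last)
    return [
        (_LABELS[j], snapshots[i].copy()) for j, i in enumerate(chosen_sorted)
    ]


@dataclass
class CrosslinkReport:
    """Counts from one crosslink assignment."""

    eligible_pairs: int
    realized_links: int
    pcl: float


def assign_crosslinks(
    config: PolymerConfiguration,
    pcl: float,
    rng: Optional[np.random.Generator] = None,
    params: Optional[SimulationParameters] = None,
) -> Tuple[PolymerConfiguration, CrosslinkReport]:
    """Bernoulli-crosslink close inter-chain contacts.

    Every pair of beads on different chains closer than 2r (minimum image)
    is independently linked with probability ``pcl``; links behave as
    harmonic bonds with rest length 2r.  A bead may carry several links.
    """
    if not (0.0 <= pcl <= 1.0):
        raise ValueError("pcl must lie in [0, 1]")
    if rng is None:
        rng = np.random.default_rng(0)
    if params is None:
        params = SimulationParameters()
    pos = np.mod(config.positions, config.box_edge)
    tree = cKDTree(pos, boxsize=config.box_edge)
    candidates = tree.query_pairs(r=params.bond_length, output_type="ndarray")
    if candidates.size:
        different = (
            config.chain_of[candidates[:, 0]] != config.chain_of[candidates[:, 1]]
        )
        eligible = candidates[different]
    else:
        eligible = np.empty((0, 2), dtype=np.int64)
    if pcl >= 1.0:
        links = eligible
    elif pcl <= 0.0 or eligible.shape[0] == 0:
        links = np.empty((0, 2), dtype=np.int64)
    else:
        links = eligible[rng.random(eligible.shape[0]) < pcl]
    out = config.with_crosslinks(links.astype(np.int64))
    return out, CrosslinkReport(
        eligible_pairs=int(eligible.shape[0]),
        realized_links=int(links.shape[0]),
        pcl=pcl,
    )


# ---------------------------------------------------------------------------
# full protocol
# ---------------------------------------------------------------------------

@dataclass
class ProtocolResult:
    """All traces and the aggregated phase map of a protocol run."""

    cells: pd.DataFrame                     # per replica x conformation x pcl
    entries: List[PhaseMapEntry]
    assembly_traces: List[VolumeTrace]
    stiff_traces: Dict[Tuple[str, float], List[VolumeTrace]]
    flexible_traces: Dict[Tuple[str, float], List[VolumeTrace]]
    crosslink_reports: List[dict]


def _trace_tail_by_steps(trace: VolumeTrace, n_tail_steps: int) -> VolumeTrace:
    cut = trace.steps.max() - n_tail_steps
    mask = trace.steps > cut
    return VolumeTrace(trace.steps[mask] - cut, trace.volume[mask],
                       trace.normalized[mask])


def run_full_protocol(
    plan: ProtocolPlan,
    params: SimulationParameters,
    checkpoint_dir: Optional[str] = None,
) -> ProtocolResult:
    """Execute the whole pipeline for every replica, conformation and P_CL.

    Per replica: compression, self-assembly, conformation selection; then
    for each (conformation, P_CL > 0): crosslink -> stiff -> flexible.  The
    P_CL = 0 control takes the trailing ``stage_steps`` of the assembly as
    its stiff stage and a fresh angular-restraint-free continuation as its
    flexible stage.  A failing cell is logged and skipped; the rest proceed.
    When ``checkpoint_dir`` is set, completed stages are written there and
    reused on rerun.
    """
    from .synthetic import SystemSpec, generate_initial_chains

    store = None
    if checkpoint_dir is not None:
        from .io import StageStore

        store = StageStore(checkpoint_dir, params)

    positive_pcls = [p for p in plan.pcl_values if p > 0.0]
    has_control = any(p == 0.0 for p in plan.pcl_values)

    stiff_traces: Dict[Tuple[str, float], List[VolumeTrace]] = {}
    flexible_traces: Dict[Tuple[str, float], List[VolumeTrace]] = {}
    assembly_traces: List[VolumeTrace] = []
    rows = []
    xlink_reports: List[dict] = []

    def _run_or_load(key, fn):
        if store is not None:
            cached = store.load(key)
            if cached is not None:
                return cached
        result = fn()
        if store is not None:
            store.save(key, result)
        return result

    for rep in range(plan.n_replicas):
        spec = SystemSpec(
            n_chains=plan.n_chains, dp=plan.dp, box_edge=plan.initial_box,
            seed=seed_for(plan.master_seed, "init", rep),
        )
        config = generate_initial_chains(spec, params)
        for ci, (edge, steps) in enumerate(plan.compression_targets):
            result = _run_or_load(
                f"r{rep}_compress{ci}",
                lambda config=config, edge=edge, steps=steps, ci=ci: compress_to_volume(
                    config, edge, steps, params,
                    seed=seed_for(plan.master_seed, "compress", rep, ci),
                    record_every=plan.record_every,
                ),
            )
            config = result.final_config

        assembly = _run_or_load(
            f"r{rep}_assembly",
            lambda config=config: self_assembly_stage(
                config, plan.assembly_steps, params,
                seed=seed_for(plan.master_seed, "assembly", rep),
                record_every=plan.record_every,
                snapshot_every=plan.snapshot_every,
            ),
        )
        assembly_traces.append(assembly.trace)
        selected = select_conformations(assembly.snapshots, plan.n_conformations)

        for conf_label, conf in selected:
            for pcl in positive_pcls:
                key = f"r{rep}_{conf_label}_pcl{int(round(1000 * pcl))}"
                try:
                    rng = np.random.default_rng(
                        seed_for(plan.master_seed, "xlink", rep, conf_label, pcl)
                    )
                    linked, report = assign_crosslinks(conf, pcl, rng, params)
                    xlink_reports.append(
                        {
                            "replica": rep, "conformation": conf_label,
                            "pcl": pcl, "eligible": report.eligible_pairs,
                            "links": report.realized_links,
                        }
                    )
                    stiff = _run_or_load(
                        key + "_stiff",
                        lambda linked=linked, key=key: stiff_stage(
                            linked, plan.stage_steps, params,
                            seed=seed_for(plan.master_seed, key, "stiff"),
                            record_every=plan.record_every,
                        ),
                    )
                    flex = _run_or_load(
                        key + "_flex",
                        lambda stiff=stiff, key=key: flexible_stage(
                            stiff.final_config, plan.stage_steps, params,
                            seed=seed_for(plan.master_seed, key, "flex"),
                            record_every=plan.record_every,
                        ),
                    )
                except Exception:
                    logger.exception("cell %s failed; skipping", key)
                    continue
                stiff_traces.setdefault((conf_label, pcl), []).append(stiff.trace)
                flexible_traces.setdefault((conf_label, pcl), []).append(flex.trace)
                rows.append(_cell_row(rep, conf_label, pcl, stiff.trace,
                                      flex.trace, plan.window_fraction))

        if has_control:
            key = f"r{rep}_control"
            try:
                control_stiff = _trace_tail_by_steps(
                    assembly.trace, plan.stage_steps
                )
                control_flex = _run_or_load(
                    key + "_flex",
                    lambda: flexible_stage(
                        assembly.final_config, plan.stage_steps, params,
                        seed=seed_for(plan.master_seed, key, "flex"),
                        record_every=plan.record_every,
                    ),
                )
            except Exception:
                logger.exception("cell %s failed; skipping", key)
            else:
                label = _LABELS[plan.n_conformations - 1]
                stiff_traces.setdefault((label, 0.0), []).append(control_stiff)
                flexible_traces.setdefault((label, 0.0), []).append(
                    control_flex.trace
                )
                rows.append(_cell_row(rep, label, 0.0, control_stiff,
                                      control_flex.trace, plan.window_fraction))

    entries = []
    for (conf_label, pcl), stiffs in sorted(stiff_traces.items()):
        flexes = flexible_traces.get((conf_label, pcl), [])
        if not flexes:
            continue
        entries.append(
            PhaseMapEntry(
                v_stiff_norm=pooled_tail_mean(
                    stiffs, plan.window_fraction, normalized=True
                ),
                pcl=pcl,
                sv=swelling_factor(stiffs, flexes, plan.window_fraction),
                n_replicas=len(stiffs),
                conformation=conf_label,
            )
        )
    cells = pd.DataFrame(
        rows,
        columns=["replica", "conformation", "pcl", "v_stiff", "v_flex",
                 "v_stiff_norm", "sv_cell"],
    )
    return ProtocolResult(
        cells=cells, entries=entries, assembly_traces=assembly_traces,
        stiff_traces=stiff_traces, flexible_traces=flexible_traces,
        crosslink_reports=xlink_reports,
    )


def _cell_row(rep, conf_label, pcl, stiff_trace, flex_trace, wf):
    v_stiff = pooled_tail_mean(stiff_trace, wf)
    return {
        "replica": rep, "conformation": conf_label, "pcl": pcl,
        "v_stiff": v_stiff,
        "v_flex": pooled_tail_mean(flex_trace, wf),
        "v_stiff_norm": pooled_tail_mean(stiff_trace, wf, normalized=True),
        "sv_cell": swelling_factor(stiff_trace, flex_trace, wf),
    }


# ---------------------------------------------------------------------------
# single-chain sampling (persistence-length measurements)
# ---------------------------------------------------------------------------

def sample_single_chain(
    dp: int,
    flexible: bool,
    params: SimulationParameters,
    n_snapshots: int = 2000,
    sample_every: int = 1000,
    burn_in_steps: int = 50_000,
    seed: int = 0,
) -> np.ndarray:
    """Equilibrate one isolated chain and sample unwrapped conformations.

    Returns an (n_snapshots, dp, 3) array suitable for
    :func:`flexgel.analysis.persistence_length`.
    """
    from .synthetic import single_chain_system

    config = single_chain_system(dp, flexible, params, seed=seed)
    if burn_in_steps > 0:
        burn = run_stage(
            config,
            StageOptions(n_steps=burn_in_steps, record_every=burn_in_steps,
                         seed=seed_for(seed, "burn")),
            params, label="burn-in",
        )
        config = burn.final_config
    prod = run_stage(
        config,
        StageOptions(
            n_steps=n_snapshots * sample_every,
            record_every=max(sample_every, 1),
            snapshot_every=sample_every,
            seed=seed_for(seed, "production"),
        ),
        params, label="chain-sampling",
    )
    return np.stack([snap.unwrapped_chain(0) for snap in prod.snapshots])


def measure_chain_persistence(
    dp: int,
    flexible: bool,
    params: SimulationParameters,
    n_snapshots: int = 2000,
    sample_every: int = 1000,
    burn_in_steps: int = 50_000,
    seed: int = 0,
) -> PersistenceLengthResult:
    """Sample an isolated chain and fit its persistence length."""
    snaps = sample_single_chain(
        dp, flexible, params, n_snapshots=n_snapshots,
        sample_every=sample_every, burn_in_steps=burn_in_steps, seed=seed,
    )
    return persistence_length(snaps, seed=seed_for(seed, "bootstrap"))
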