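"""File formats: extended-XYZ trajectories, CSV traces, TOML run
configurations and JSON summaries.

Extended-XYZ was chosen over binary trajectory formats because it is
human-inspectable and adequate at desk scale: the comment line carries the
cubic lattice, a per-bead chain index column, the flexible flag and the
crosslink list, so a frame is a complete, self-describing configuration.
"""

from __future__ import annotations

import hashlib
import json
import math
import os
from dataclasses import dataclass
from typing import IO, List, Optional

import numpy as np
import pandas as pd

from .analysis import VolumeTrace
from .calibration import CalibrationResult
from .config import PolymerConfiguration, chain_topology
from .engine import StageResult
from .errors import ConfigError, FlexgelError
from .params import SimulationParameters
from .protocol import ProtocolPlan
from .synthetic import SystemSpec

__version__ = "0.1.0"


class FrameParseError(FlexgelError):
    """Malformed extended-XYZ frame; carries the offending line number."""


# ---------------------------------------------------------------------------
# extended-XYZ
# ---------------------------------------------------------------------------

def write_frame(config: PolymerConfiguration, stream: IO[str]) -> None:
    """Write one configuration as an extended-XYZ frame."""
    n = config.n_beads
    L = config.box_edge
    links = " ".join(f"{i}-{j}" for i, j in config.crosslinks)
    comment = (
        f'Lattice="{L:.12g} 0 0 0 {L:.12g} 0 0 0 {L:.12g}" '
        f"Properties=species:S:1:pos:R:3:velo:R:3:chain:I:1 "
        f"Flexible={'T' if config.flexible else 'F'} "
        f'Crosslinks="{links}"'
    )
    stream.write(f"{n}\n{comment}\n")
    for i in range(n):
        x, y, z = config.positions[i]
        vx, vy, vz = config.velocities[i]
        stream.write(
            f"C {x:.12g} {y:.12g} {z:.12g} "
            f"{vx:.12g} {vy:.12g} {vz:.12g} {config.chain_of[i]}\n"
        )


def _comment_field(comment: str, key: str, lineno: int) -> str:
    marker = key + "="
    idx = comment.find(marker)
    if idx < 0:
        raise FrameParseError(f"line {lineno}: missing {key!r} in comment")
    rest = comment[idx + len(marker):]
    if rest.startswith('"'):
        end = rest.find('"', 1)
        if end < 0:
            raise FrameParseError(f"line {lineno}: unterminated {key!r}")
        return rest[1:end]
    return rest.split()[0] if rest.split() else ""


def read_frame(stream: IO[str], lineno_start: int = 1) -> Optional[PolymerConfiguration]:
    """Read one extended-XYZ frame; returns None at end of stream."""
    header = stream.readline()
    if header == "":
        return None
    lineno = lineno_start
    try:
        n = int(header.strip())
    except ValueError:
        raise FrameParseError(f"line {lineno}: expected an atom count")
    comment = stream.readline()
    if comment == "":
        raise FrameParseError(f"line {lineno + 1}: missing comment line")
    lattice = _comment_field(comment, "Lattice", lineno + 1).split()
    if len(lattice) != 9:
        raise FrameParseError(f"line {lineno + 1}: Lattice must have 9 numbers")
    L = float(lattice[0])
    flexible = _comment_field(comment, "Flexible", lineno + 1).upper() in ("T", "TRUE")
    links_text = _comment_field(comment, "Crosslinks", lineno + 1)
    crosslinks = []
    for part in links_text.split():
        try:
            i, j = part.split("-")
            crosslinks.append((int(i), int(j)))
        except ValueError:
            raise FrameParseError(
                f"line {lineno + 1}: malformed crosslink entry {part!r}"
            )
    positions = np.zeros((n, 3))
    velocities = np.zeros((n, 3))
    chain_ids = np.zeros(n, dtype=np.int64)
    for i in range(n):
        row = stream.readline()
        if row == "":
            raise FrameParseError(f"line {lineno + 2 + i}: truncated frame")
        parts = row.split()
        if len(parts) != 8:
            raise FrameParseError(
                f"line {lineno + 2 + i}: expected 8 columns, got {len(parts)}"
            )
        try:
            positions[i] = [float(v) for v in parts[1:4]]
            velocities[i] = [float(v) for v in parts[4:7]]
            chain_ids[i] = int(parts[7])
        except ValueError:
            raise FrameParseError(f"line {lineno + 2 + i}: non-numeric field")
    # rebuild bonded topology from contiguous chain-id runs
    lengths = []
    for cid in pd.unique(chain_ids) if n else []:
        lengths.append(int(np.sum(chain_ids == cid)))
    if lengths:
        chain_of, bonds, angles = chain_topology(lengths)
        if not np.array_equal(chain_of, chain_ids):
            raise FrameParseError(
                f"line {lineno + 2}: chain ids must be contiguous runs"
            )
    else:
        chain_of = chain_ids
        bonds = np.empty((0, 2), dtype=np.int64)
        angles = np.empty((0, 3), dtype=np.int64)
    return PolymerConfiguration(
        positions=positions, velocities=velocities, chain_of=chain_of,
        bonds=bonds, angles=angles,
        crosslinks=np.asarray(crosslinks, dtype=np.int64).reshape(-1, 2),
        box_edge=L, flexible=flexible,
    )


def write_frames(configs, path: str) -> None:
    with open(path, "w") as fh:
        for c in configs:
            write_frame(c, fh)


def read_frames(path: str) -> List[PolymerConfiguration]:
    out = []
    with open(path) as fh:
        while True:
            frame = read_frame(fh)
            if frame is None:
                break
            out.append(frame)
    return out


# ---------------------------------------------------------------------------
# stage persistence (traces + checkpoints)
# ---------------------------------------------------------------------------

def stage_frame(result: StageResult) -> pd.DataFrame:
    """Volume trace plus pressure/energy series as a DataFrame."""
    df = result.trace.to_frame()
    df["pressure"] = result.pressure
    df["e_pot"] = result.e_pot
    df["e_angle"] = result.e_angle
    return df


class StageStore:
    """Per-stage checkpoints: CSV trace + extended-XYZ final configuration.

    The metadata JSON is written last so a partially written stage is never
    mistaken for a completed one; interrupted runs resume from the last
    completed stage.
    """

    def __init__(self, directory: str, params: SimulationParameters):
        self.directory = directory
        self.params = params
        os.makedirs(directory, exist_ok=True)

    def _paths(self, key: str):
        base = os.path.join(self.directory, key)
        return (base + ".trace.csv", base + ".final.xyz",
                base + ".snaps.xyz", base + ".meta.json")

    def save(self, key: str, result: StageResult) -> None:
        trace_p, final_p, snaps_p, meta_p = self._paths(key)
        stage_frame(result).to_csv(trace_p, index=False)
        write_frames([result.final_config], final_p)
        if result.snapshots:
            write_frames(result.snapshots, snaps_p)
        meta = {
            "label": result.label,
            "seed": result.seed,
            "n_clamped": result.n_clamped,
            "n_snapshots": len(result.snapshots),
        }
        with open(meta_p, "w") as fh:
            json.dump(meta, fh, indent=1)

    def load(self, key: str) -> Optional[StageResult]:
        trace_p, final_p, snaps_p, meta_p = self._paths(key)
        if not (os.path.exists(meta_p) and os.path.exists(trace_p)
                and os.path.exists(final_p)):
            return None
        with open(meta_p) as fh:
            meta = json.load(fh)
        df = pd.read_csv(trace_p)
        final = read_frames(final_p)[0]
        snapshots = (
            read_frames(snaps_p)
            if meta.get("n_snapshots", 0) and os.path.exists(snaps_p)
            else []
        )
        trace = VolumeTrace(
            steps=df["step"].to_numpy(),
            volume=df["volume"].to_numpy(),
            normalized=df["v_over_vcp"].to_numpy(),
        )
        vol = trace.volume
        return StageResult(
            label=meta["label"], trace=trace, final_config=final,
            mean_volume=float(vol.mean()),
            mean_volume_tail=float(vol[len(vol) // 2:].mean()),
            pressure=df["pressure"].to_numpy(),
            e_pot=df["e_pot"].to_numpy(),
            e_angle=df["e_angle"].to_numpy(),
            snapshots=snapshots,
            n_clamped=int(meta.get("n_clamped", 0)),
            seed=int(meta.get("seed", 0)),
        )


# ---------------------------------------------------------------------------
# run configuration (TOML)
# ---------------------------------------------------------------------------

@dataclass
class RunConfiguration:
    """One self-describing document driving a full protocol run."""

    parameters: SimulationParameters
    system: SystemSpec
    plan: ProtocolPlan
    calibration: Optional[CalibrationResult] = None
    outdir: str = "flexgel-out"
    preset_name: str = ""

    def to_dict(self) -> dict:
        d = {
            "outdir": self.outdir,
            "preset_name": self.preset_name,
            "parameters": self.parameters.to_dict(),
            "system": self.system.to_dict(),
            "plan": self.plan.to_dict(),
        }
        if self.calibration is not None:
            d["calibration"] = self.calibration.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfiguration":
        try:
            params = SimulationParameters.from_dict(d["parameters"])
            system = SystemSpec.from_dict(d["system"])
            plan = ProtocolPlan.from_dict(d["plan"])
        except (KeyError, TypeError, ValueError) as exc:
            raise ConfigError(f"invalid run configuration: {exc}") from exc
        cal = None
        if "calibration" in d:
            try:
                cal = CalibrationResult(**d["calibration"])
            except TypeError as exc:
                raise ConfigError(f"invalid calibration block: {exc}") from exc
        return cls(
            parameters=params, system=system, plan=plan, calibration=cal,
            outdir=str(d.get("outdir", "flexgel-out")),
            preset_name=str(d.get("preset_name", "")),
        )

    def validate(self) -> None:
        if self.plan.n_chains != self.system.n_chains or self.plan.dp != self.system.dp:
            raise ConfigError("plan and system disagree on chain counts")
        if not math.isclose(self.plan.initial_box, self.system.box_edge,
                            rel_tol=1e-9):
            raise ConfigError("plan and system disagree on the initial box")


def _toml_scalar(v) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, (int, np.integer)):
        return str(int(v))
    if isinstance(v, (float, np.floating)):
        return repr(float(v))
    if isinstance(v, str):
        return json.dumps(v)
    if isinstance(v, (list, tuple)):
        return "[" + ", ".join(_toml_scalar(x) for x in v) + "]"
    raise ConfigError(f"cannot serialize {type(v).__name__} to TOML")


def dumps_toml(doc: dict) -> str:
    """Serialize a {section: {key: scalar-or-list}} document to TOML."""
    lines = []
    for key, value in doc.items():
        if not isinstance(value, dict):
            lines.append(f"{key} = {_toml_scalar(value)}")
    for section, table in doc.items():
        if isinstance(table, dict):
            lines.append("")
            lines.append(f"[{section}]")
            for key, value in table.items():
                if value is None:
                    continue
                lines.append(f"{key} = {_toml_scalar(value)}")
    return "\n".join(lines) + "\n"


def save_run_configuration(cfg: RunConfiguration, path: str) -> None:
    with open(path, "w") as fh:
        fh.write(dumps_toml(cfg.to_dict()))


def load_run_configuration(path: str) -> RunConfiguration:
    import tomllib

    with open(path, "rb") as fh:
        try:
            doc = tomllib.load(fh)
        except tomllib.TOMLDecodeError as exc:
            raise ConfigError(f"malformed TOML in {path}: {exc}") from exc
    cfg = RunConfiguration.from_dict(doc)
    cfg.validate()
    return cfg


def config_hash(path: str) -> str:
    with open(path, "rb") as fh:
        return hashlib.sha256(fh.read()).hexdigest()


def provenance_block(config_path: Optional[str], seeds) -> dict:
    block = {"package": "flexgel", "version": __version__, "seeds": list(seeds)}
    if config_path is not None and os.path.exists(config_path):
        block["config_sha256"] = config_hash(config_path)
    return block
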