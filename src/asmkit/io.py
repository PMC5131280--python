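"""Format readers/writers, provenance headers, and pipeline configuration.

Result tables are plain TSV with '#'-prefixed provenance header lines
(tool version, config hash, seed) so every artifact records how it was
produced.  Trajectories travel as CSV with the schema
``bead_id,frame,t_s,x_nm,y_nm``; twisting records as CSV
``t_s,torque_pa,disp_nm``; image stacks as multi-page 16-bit TIFF;
sequences as FASTA.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import __version__
from .microrheology import TwistRecord
from .tracking import Trajectory

__all__ = [
    "PipelineConfig", "load_config",
    "write_trajectories_csv", "read_trajectories_csv",
    "write_mtc_csv", "read_mtc_csv",
    "write_stack_tiff", "read_stack_tiff",
    "write_fasta", "read_fasta",
    "write_table", "read_table",
]


# ---------------------------------------------------------------------------
# configuration

@dataclass
class PipelineConfig:
    """Acquisition and analysis settings shared across pipeline stages.

    Acquisition defaults mirror the live-cell protocol (12 frames/s for
    300 s); the twisting drive frequency is not fixed by that protocol
    and must be treated as configurable.  Every stochastic stage requires
    an explicit seed.
    """

    frame_rate: float = 12.0            # Hz
    duration: float = 300.0             # s
    pixel_size_nm: float = 333.0        # nm/px
    msd_window: tuple[float, float] = (10.0, 300.0)  # s
    mtc_frequency: float = 0.75         # Hz
    threshold_quantile: float = 0.995
    min_separation_px: float = 5.0
    max_step_nm: float = 500.0
    seed: int = 0
    outdir: str = "results"

    def __post_init__(self) -> None:
        if self.frame_rate <= 0 or self.duration <= 0 or self.pixel_size_nm <= 0:
            raise ValueError("acquisition settings must be positive")
        self.msd_window = tuple(float(v) for v in self.msd_window)  # type: ignore[assignment]
        if self.msd_window[0] >= self.msd_window[1]:
            raise ValueError("msd_window must be (lo, hi) with lo < hi")

    def hash(self) -> str:
        # outdir is excluded: where artifacts land does not alter them
        payload = {k: v for k, v in asdict(self).items() if k != "outdir"}
        blob = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def load_config(path: str | Path) -> PipelineConfig:
    """Load a PipelineConfig from a YAML/key-value file."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    unknown = set(data) - set(PipelineConfig.__dataclass_fields__)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return PipelineConfig(**data)


# ---------------------------------------------------------------------------
# provenance-stamped tables

def _provenance_lines(config: PipelineConfig | None, seed: int | None) -> list[str]:
    lines = [f"# asmkit {__version__}"]
    if config is not None:
        lines.append(f"# config_hash {config.hash()}")
    if seed is not None:
        lines.append(f"# seed {seed}")
    return lines


def write_table(df: pd.DataFrame, path: str | Path,
                config: PipelineConfig | None = None,
                seed: int | None = None, sep: str = "\t") -> None:
    """Write a TSV with '#'-prefixed provenance header lines."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for line in _provenance_lines(config, seed):
            fh.write(line + "\n")
        df.to_csv(fh, sep=sep, index=False)


def read_table(path: str | Path, sep: str = "\t") -> pd.DataFrame:
    return pd.read_csv(path, sep=sep, comment="#")


# ---------------------------------------------------------------------------
# trajectories

def write_trajectories_csv(trajectories: list[Trajectory], path: str | Path,
                           config: PipelineConfig | None = None,
                           seed: int | None = None) -> None:
    frames = []
    for t in trajectories:
        frames.append(pd.DataFrame({
            "bead_id": t.bead_id,
            "frame": np.round(t.times * t.frame_rate).astype(int),
            "t_s": t.times,
            "x_nm": t.x,
            "y_nm": t.y,
        }))
    write_table(pd.concat(frames, ignore_index=True), path,
                config=config, seed=seed, sep=",")


def read_trajectories_csv(path: str | Path,
                          frame_rate: float | None = None) -> list[Trajectory]:
    df = pd.read_csv(path, comment="#")
    out = []
    for bead_id, sub in df.groupby("bead_id", sort=True):
        sub = sub.sort_values("frame")
        times = sub["t_s"].to_numpy()
        fr = frame_rate if frame_rate is not None else 1.0 / np.median(np.diff(times))
        out.append(Trajectory(bead_id=int(bead_id), times=times,
                              x=sub["x_nm"].to_numpy(), y=sub["y_nm"].to_numpy(),
                              frame_rate=float(fr)))
    return out


# ---------------------------------------------------------------------------
# twisting records

def write_mtc_csv(rec: TwistRecord, path: str | Path,
                  config: PipelineConfig | None = None,
                  seed: int | None = None) -> None:
    df = pd.DataFrame({"t_s": rec.t, "torque_pa": rec.specific_torque,
                       "disp_nm": rec.displacement})
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for line in _provenance_lines(config, seed):
            fh.write(line + "\n")
        fh.write(f"# frequency_hz {rec.frequency}\n")
        df.to_csv(fh, index=False)


def read_mtc_csv(path: str | Path, frequency: float | None = None) -> TwistRecord:
    freq = frequency
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            parts = line[1:].split()
            if len(parts) == 2 and parts[0] == "frequency_hz" and freq is None:
                freq = float(parts[1])
    if freq is None:
        raise ValueError("drive frequency not in file header; pass frequency=")
    df = pd.read_csv(path, comment="#")
    return TwistRecord(t=df["t_s"].to_numpy(),
                       specific_torque=df["torque_pa"].to_numpy(),
                       displacement=df["disp_nm"].to_numpy(),
                       frequency=freq)


# ---------------------------------------------------------------------------
# image stacks and sequences

def write_stack_tiff(stack: np.ndarray, path: str | Path) -> None:
    """Write a multi-page 16-bit TIFF, clipping at the dtype range."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    data = np.clip(np.round(stack), 0, np.iinfo(np.uint16).max).astype(np.uint16)
    tifffile.imwrite(path, data, photometric="minisblack")


def read_stack_tiff(path: str | Path) -> np.ndarray:
    return tifffile.imread(path)


def write_fasta(records: list[tuple[str, str]], path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    seqs = [SeqRecord(Seq(seq), id=name, description="") for name, seq in records]
    SeqIO.write(seqs, path, "fasta")


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]
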