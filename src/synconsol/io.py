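"""Plain-text readers/writers and run manifests.

Everything round-trips through TSV with ``#``-prefixed metadata headers and
full-precision (``%.17g``) decimal serialisation, so states, pattern sets and
trajectory tables survive a write/read cycle bit-exactly. There is no
domain-standard container for factorised synaptic states, hence the bespoke
but deliberately simple sectioned format.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .network import SynapticState
from .patterns import PatternSet
from .synapse_sim import TrajectoryTable

__all__ = [
    "FormatError",
    "read_patterns",
    "write_patterns",
    "read_state",
    "write_state",
    "read_trajectory_table",
    "write_trajectory_table",
    "Manifest",
]

FMT = "%.17g"


class FormatError(ValueError):
    """Malformed or inconsistent on-disk data."""


def _read_meta(path: Path) -> dict:
    meta: dict = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line[1:].strip()
            if "=" in body:
                key, _, val = body.partition("=")
                meta[key.strip()] = val.strip()
    return meta


def write_patterns(path: str | Path, patterns: PatternSet) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# N={patterns.N}\n# M={patterns.M}\n# f={FMT % patterns.f}\n")
        fh.write(f"# seed={patterns.seed}\n")
        np.savetxt(fh, patterns.xi, fmt="%d", delimiter="\t")


def read_patterns(path: str | Path) -> PatternSet:
    path = Path(path)
    meta = _read_meta(path)
    try:
        f = float(meta["f"])
    except KeyError as exc:
        raise FormatError(f"{path}: missing 'f' in header") from exc
    seed = None if meta.get("seed") in (None, "None") else int(meta["seed"])
    xi = np.loadtxt(path, dtype=np.int8, delimiter="\t", comments="#", ndmin=2)
    if "N" in meta and xi.shape[1] != int(meta["N"]):
        raise FormatError(f"{path}: header N={meta['N']} but matrix has {xi.shape[1]} columns")
    if "M" in meta and xi.shape[0] != int(meta["M"]):
        raise FormatError(f"{path}: header M={meta['M']} but matrix has {xi.shape[0]} rows")
    return PatternSet(xi=xi, f=f, seed=seed)


def write_state(path: str | Path, state: SynapticState) -> None:
    """Sectioned TSV: header, inhibitory currents, then one N x N block per factor."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# N={state.N}\n# z={state.z}\n")
        fh.write(f"# volatile_index={state.volatile_index}\n")
        fh.write("# section=I_inh\n")
        np.savetxt(fh, state.I_inh[None, :], fmt=FMT, delimiter="\t")
        for k in range(state.z):
            fh.write(f"# section=u k={k}\n")
            np.savetxt(fh, state.u[:, :, k], fmt=FMT, delimiter="\t")


def read_state(path: str | Path, expect_z: int | None = None) -> SynapticState:
    path = Path(path)
    meta = _read_meta(path)
    try:
        N, z = int(meta["N"]), int(meta["z"])
    except KeyError as exc:
        raise FormatError(f"{path}: missing N/z header") from exc
    if expect_z is not None and z != expect_z:
        raise FormatError(f"{path}: file has z={z}, expected z={expect_z}")
    rows = np.loadtxt(path, delimiter="\t", comments="#", ndmin=2)
    expected = 1 + z * N
    if rows.shape != (expected, N):
        raise FormatError(
            f"{path}: expected {expected} data rows of width {N}, got {rows.shape}"
        )
    I_inh = rows[0]
    u = np.stack([rows[1 + k * N : 1 + (k + 1) * N] for k in range(z)], axis=2)
    return SynapticState(u=u, I_inh=I_inh, volatile_index=int(meta.get("volatile_index", 0)))


def write_trajectory_table(path: str | Path, table: TrajectoryTable) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        for key, val in table.meta.items():
            fh.write(f"# {key}={val}\n")
        fh.write("synapse_id\ttime\tstrength\n")
        table.df.to_csv(fh, sep="\t", index=False, header=False, float_format=FMT)


def read_trajectory_table(path: str | Path) -> TrajectoryTable:
    """Read and validate a long-format (synapse_id, time, strength) TSV.

    Raises :class:`FormatError` naming the offending line for missing
    columns, negative strengths, or duplicated (synapse, time) records.
    """
    path = Path(path)
    meta = _read_meta(path)
    n_meta = 0
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                n_meta += 1
            else:
                header = line.strip().split("\t")
                break
        else:
            raise FormatError(f"{path}: empty file")
    required = ["synapse_id", "time", "strength"]
    missing = [c for c in required if c not in header]
    if missing:
        raise FormatError(f"{path}: missing columns {missing} in header line {n_meta + 1}")
    df = pd.read_csv(path, sep="\t", comment="#", float_precision="round_trip")
    bad = df.index[df["strength"] < 0]
    if len(bad):
        line_no = int(bad[0]) + n_meta + 2  # +header +1-based
        raise FormatError(f"{path}: negative strength at line {line_no}")
    dup = df.duplicated(subset=["synapse_id", "time"])
    if dup.any():
        line_no = int(df.index[dup][0]) + n_meta + 2
        raise FormatError(f"{path}: duplicate (synapse_id, time) at line {line_no}")
    df = df.sort_values(["time", "synapse_id"], kind="stable").reset_index(drop=True)
    for key in ("z", "n_synapses", "seed"):
        if key in meta and meta[key] != "None":
            meta[key] = int(meta[key])
    for key in ("sigma", "relax", "T", "dt"):
        if key in meta:
            meta[key] = float(meta[key])
    if "homeostatic" in meta:
        meta["homeostatic"] = meta["homeostatic"] == "True"
    return TrajectoryTable(df=df[required], meta=meta)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class Manifest:
    """Record of a run: seed, config snapshot, output checksums, timings."""

    run_id: str
    seed: int | None
    config: dict = field(default_factory=dict)
    files: dict = field(default_factory=dict)
    timings: dict = field(default_factory=dict)

    def add_file(self, path: str | Path) -> None:
        path = Path(path)
        self.files[path.name] = _sha256(path)

    def add_timing(self, stage: str, seconds: float) -> None:
        self.timings[stage] = round(seconds, 3)

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "run_id": self.run_id,
                    "seed": self.seed,
                    "created": time.strftime("%Y-%m-%dT%H:%M:%S"),
                    "config": self.config,
                    "files": self.files,
                    "timings": self.timings,
                },
                fh,
                indent=2,
                default=str,
            )
            fh.write("\n")
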