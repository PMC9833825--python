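"""File-format adapters: strict CSV tables, FASTQ, motif TSV, run manifests.

CSV dialect is fixed: UTF-8, comma separator, dot decimal, mandatory header
row.  FASTQ is 4-line records only; qualities are read but ignored by the
assays.  Every artifact-producing command records a JSON manifest (package
version, config hash, seeds, input checksums) sufficient to reproduce the
output bit for bit.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from . import __version__
from .evolve import PopulationState, Trajectory

__all__ = [
    "read_csv_strict",
    "read_plate_csv",
    "read_event_csv",
    "read_cq_csv",
    "write_tidy_csv",
    "read_fastq",
    "write_fastq",
    "read_motif_tsv",
    "write_motif_tsv",
    "write_trajectories_csv",
    "read_trajectories_csv",
    "write_manifest",
]

PLATE_COLUMNS = ["well", "day", "od", "yfp", "cfp"]
EVENT_COLUMNS = ["event", "yfp", "cfp"]
CQ_COLUMNS = ["sample", "channel", "cq", "dilution"]
TRAJECTORY_COLUMNS = ["replicate", "day", "k", "m", "count"]


def read_csv_strict(
    path: str | Path, required: Sequence[str], numeric: Sequence[str]
) -> pd.DataFrame:
    """Read a CSV enforcing the fixed dialect and the required header.

    Non-numeric entries in numeric columns (including locale comma decimals
    like "1,5") are rejected with the offending column and data row number.
    """
    df = pd.read_csv(path, sep=",", encoding="utf-8", dtype=str, skipinitialspace=True)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    for col in numeric:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad)[0]) + 2  # 1-based, counting the header line
            raise ValueError(
                f"{path}: non-numeric value {df[col][bad].iloc[0]!r} in column {col!r} "
                f"at line {row} (decimal separator must be '.')"
            )
        # exact strtod conversion (pandas' fast parser can be 1 ulp off)
        exact = df[col].astype(np.float64)
        if converted.notna().all() and (exact == np.round(exact)).all() and not df[col].str.contains(r"[.eE]").any():
            exact = exact.astype(np.int64)
        df[col] = exact
    return df


def read_plate_csv(path: str | Path) -> pd.DataFrame:
    return read_csv_strict(path, PLATE_COLUMNS, ["day", "od", "yfp", "cfp"])


def read_event_csv(path: str | Path) -> pd.DataFrame:
    return read_csv_strict(path, EVENT_COLUMNS, EVENT_COLUMNS)


def read_cq_csv(path: str | Path) -> pd.DataFrame:
    return read_csv_strict(path, CQ_COLUMNS, ["cq", "dilution"])


def write_tidy_csv(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, encoding="utf-8")


def read_fastq(path: str | Path):
    """Iterate SeqRecords from a FASTQ file; parse errors name the record.

    A truncated or malformed 4-line record raises ValueError carrying the
    1-based index of the offending record.
    """
    def _iter():
        idx = 0
        try:
            for rec in SeqIO.parse(str(path), "fastq"):
                idx += 1
                yield rec
        except ValueError as exc:
            raise ValueError(f"{path}: malformed FASTQ at record {idx + 1}: {exc}") from exc

    return _iter()


def write_fastq(sequences: Iterable[str], path: str | Path, quality_char: str = "I") -> int:
    """Write plain sequences as 4-line FASTQ records with constant quality."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    n = 0
    with open(path, "w", encoding="utf-8") as fh:
        for i, seq in enumerate(sequences):
            fh.write(f"@read_{i}\n{seq}\n+\n{quality_char * len(seq)}\n")
            n += 1
    return n


def write_motif_tsv(motifs, path: str | Path) -> None:
    """Motif set as TSV (name, sequence, role)."""
    rows = [("ancestral", motifs.ancestral, "p0")]
    rows += [(name, seq, "p0_evolved") for name, seq in motifs.evolved.items()]
    rows.append(("control", motifs.control, "control"))
    rows += [(f"contaminant_{i}", seq, "contaminant") for i, seq in enumerate(motifs.contaminants)]
    pd.DataFrame(rows, columns=["name", "sequence", "role"]).to_csv(path, sep="\t", index=False)


def read_motif_tsv(path: str | Path):
    from .assays import AmpliconMotifSet

    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("name", "sequence", "role"):
        if col not in df.columns:
            raise ValueError(f"{path}: motif TSV must have columns name, sequence, role")
    anc = df[df["role"] == "p0"]["sequence"].iloc[0]
    evolved = dict(zip(df[df["role"] == "p0_evolved"]["name"], df[df["role"] == "p0_evolved"]["sequence"]))
    control = df[df["role"] == "control"]["sequence"].iloc[0]
    contaminants = tuple(df[df["role"] == "contaminant"]["sequence"])
    length = len(anc)
    return AmpliconMotifSet(anc, evolved, control, contaminants, length)


def write_trajectories_csv(trajectories: Iterable[Trajectory], path: str | Path) -> None:
    """Tidy long format: (replicate, day, k, m, count), nonzero classes only."""
    frames = [t.to_frame() for t in trajectories]
    write_tidy_csv(pd.concat(frames, ignore_index=True), path)


def read_trajectories_csv(path: str | Path, kmax: int) -> list[Trajectory]:
    df = read_csv_strict(path, TRAJECTORY_COLUMNS, TRAJECTORY_COLUMNS)
    out = []
    for rep, grp in df.groupby("replicate"):
        states = []
        for day, day_grp in grp.groupby("day"):
            counts = np.zeros((kmax, kmax + 1))
            counts[day_grp["k"].astype(int) - 1, day_grp["m"].astype(int)] = day_grp["count"]
            states.append(PopulationState(counts, day=int(day)))
        out.append(Trajectory(states, replicate=int(rep)))
    return out


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(
    path: str | Path,
    *,
    command: str,
    config_hash: str | None = None,
    seeds: Sequence[int] = (),
    inputs: Sequence[str | Path] = (),
    outputs: Sequence[str | Path] = (),
    extra: dict | None = None,
) -> None:
    """JSON manifest recording how an artifact was produced."""
    manifest = {
        "package": "dupdiv",
        "version": __version__,
        "command": command,
        "config_hash": config_hash,
        "seeds": list(map(int, seeds)),
        "inputs": {str(p): _sha256(p) for p in inputs},
        "outputs": [str(p) for p in outputs],
    }
    if extra:
        manifest.update(extra)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
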