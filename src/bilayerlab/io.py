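"""Plain-text readers and writers for every interchange format.

All files are small text formats: two-column CSV traces, a NOESY volume
matrix with a mixing-time header line, multi-frame XYZ (comment line
carries the box and frame index) and a minimal GRO dialect.
"""

from __future__ import annotations

import io as _io
from pathlib import Path
from typing import Optional, TextIO, Union

import numpy as np
import pandas as pd

from .types import DiffractionPattern, GroupTrajectory, NoesyVolumeTable, Spectrum31P, Thermogram

PathLike = Union[str, Path]


# ---------------------------------------------------------------------------
# two-column CSV traces

def write_thermogram_csv(t: Thermogram, path: PathLike) -> None:
    with open(path, "w") as fh:
        fh.write(f"# scan_rate_C_per_min={t.scan_rate:g}\n")
        fh.write("T_degC,Cp\n")
        for temp, cp in zip(t.temperature, t.cp):
            fh.write(f"{temp:.6g},{cp:.10g}\n")


def read_thermogram_csv(path: PathLike) -> Thermogram:
    scan_rate = 1.0
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#"):
            if "scan_rate" in first:
                scan_rate = float(first.split("=", 1)[1])
            body = fh.read()
        else:
            body = first + fh.read()
    df = pd.read_csv(_io.StringIO(body))
    return Thermogram(temperature=df["T_degC"].to_numpy(),
                      cp=df["Cp"].to_numpy(), scan_rate=scan_rate)


def write_pattern_csv(p: DiffractionPattern, path: PathLike) -> None:
    with open(path, "w") as fh:
        fh.write(f"# region={p.region}\n")
        for w in p.warnings:
            fh.write(f"# warning={w}\n")
        fh.write("s_invA,intensity\n")
        for s, y in zip(p.s, p.intensity):
            fh.write(f"{s:.8g},{y:.10g}\n")


def read_pattern_csv(path: PathLike) -> DiffractionPattern:
    region, warnings, lines = "SAXD", [], []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                key, _, val = line[1:].strip().partition("=")
                if key.strip() == "region":
                    region = val.strip()
                elif key.strip() == "warning":
                    warnings.append(val.strip())
            else:
                lines.append(line)
    df = pd.read_csv(_io.StringIO("".join(lines)))
    return DiffractionPattern(s=df["s_invA"].to_numpy(),
                              intensity=df["intensity"].to_numpy(),
                              region=region, warnings=warnings)


def write_spectrum_csv(sp: Spectrum31P, path: PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("ppm,intensity\n")
        for x, y in zip(sp.ppm, sp.intensity):
            fh.write(f"{x:.8g},{y:.10g}\n")


def read_spectrum_csv(path: PathLike) -> Spectrum31P:
    df = pd.read_csv(path)
    return Spectrum31P(ppm=df["ppm"].to_numpy(), intensity=df["intensity"].to_numpy())


# ---------------------------------------------------------------------------
# NOESY volume matrix

def write_noesy_csv(t: NoesyVolumeTable, path: PathLike) -> None:
    """Matrix layout: ``tm_s=`` header line, then rows per group with a
    diagonal column and one column per ligand proton (blank where a cross
    peak is absent, e.g. on ligand rows)."""
    ligands = t.ligand_protons
    with open(path, "w") as fh:
        fh.write(f"tm_s={t.tm:g}\n")
        fh.write("group,diagonal," + ",".join(ligands) + "\n")
        for g, diag in t.diagonal.items():
            cells = []
            for lig in ligands:
                v = t.cross.get((lig, g))
                cells.append(f"{v:.10g}" if v is not None else "")
            fh.write(f"{g},{diag:.10g}," + ",".join(cells) + "\n")


def read_noesy_csv(path: PathLike) -> NoesyVolumeTable:
    with open(path) as fh:
        header = fh.readline().strip()
        if not header.startswith("tm_s="):
            raise ValueError("NOESY file must start with a 'tm_s=' line")
        tm = float(header.split("=", 1)[1])
        cols = fh.readline().strip().split(",")
        ligands = cols[2:]
        diagonal: dict[str, float] = {}
        cross: dict[tuple[str, str], float] = {}
        for line in fh:
            parts = line.rstrip("\n").split(",")
            if len(parts) < 2 or not parts[0]:
                continue
            g = parts[0]
            diagonal[g] = float(parts[1])
            for lig, cell in zip(ligands, parts[2:]):
                if cell != "":
                    cross[(lig, g)] = float(cell)
    return NoesyVolumeTable(tm=tm, diagonal=diagonal, cross=cross)


# ---------------------------------------------------------------------------
# trajectories

def _sanitize(label: str) -> str:
    return label.replace(" ", "_")


def write_xyz(t: GroupTrajectory, path: PathLike) -> None:
    """Multi-frame XYZ; the comment line carries the frame index and box.

    Atom names are the (space-sanitized) group labels, so the grouping
    survives a round trip. Masses are not part of XYZ; pass them to
    :func:`read_xyz` to restore them.
    """
    labels = t.group_labels
    n_atoms = sum(t.frames[0][g].shape[0] for g in labels)
    lx, ly, lz = t.box
    with open(path, "w") as fh:
        for i, fr in enumerate(t.frames):
            fh.write(f"{n_atoms}\n")
            fh.write(f"frame={i} box {lx:.6g} {ly:.6g} {lz:.6g} nm\n")
            for g in labels:
                name = _sanitize(g)
                for x, y, z in fr[g]:
                    fh.write(f"{name} {x:.6f} {y:.6f} {z:.6f}\n")


def read_xyz(path: PathLike,
             masses: Optional[dict[str, np.ndarray]] = None) -> GroupTrajectory:
    frames: list[dict[str, np.ndarray]] = []
    box = None
    with open(path) as fh:
        while True:
            line = fh.readline()
            if not line.strip():
                break
            n = int(line)
            comment = fh.readline().split()
            b_idx = comment.index("box")
            box = tuple(float(v) for v in comment[b_idx + 1:b_idx + 4])
            rows: dict[str, list[list[float]]] = {}
            for _ in range(n):
                name, x, y, z = fh.readline().split()
                rows.setdefault(name, []).append([float(x), float(y), float(z)])
            frames.append({g: np.array(v) for g, v in rows.items()})
    if box is None:
        raise ValueError("empty XYZ file")
    # map sanitized names back where the caller supplied mass labels
    if masses is not None:
        remap = {_sanitize(g): g for g in masses}
        frames = [{remap.get(g, g): arr for g, arr in fr.items()} for fr in frames]
        m = {g: np.asarray(masses[g], dtype=float) for g in frames[0]}
    else:
        m = {g: np.ones(arr.shape[0]) for g, arr in frames[0].items()}
    return GroupTrajectory(frames=frames, masses=m, box=box)


def write_gro(t: GroupTrajectory, path: PathLike) -> None:
    """Minimal GRO dialect: one residue per group, no velocities.

    Group labels are truncated to the 5-character residue-name field, so
    labels must stay distinct within their first five characters.
    """
    labels = t.group_labels
    short = {g: _sanitize(g)[:5] for g in labels}
    if len(set(short.values())) != len(labels):
        raise ValueError("group labels collide when truncated to 5 characters")
    lx, ly, lz = t.box
    with open(path, "w") as fh:
        for i, fr in enumerate(t.frames):
            n_atoms = sum(fr[g].shape[0] for g in labels)
            fh.write(f"frame={i}\n{n_atoms}\n")
            atom = 0
            for res, g in enumerate(labels, start=1):
                for x, y, z in fr[g]:
                    atom += 1
                    fh.write(f"{res:5d}{short[g]:<5s}{'A':>5s}{atom % 100000:5d}"
                             f"{x:8.3f}{y:8.3f}{z:8.3f}\n")
            fh.write(f"{lx:10.5f}{ly:10.5f}{lz:10.5f}\n")


def read_gro(path: PathLike,
             masses: Optional[dict[str, np.ndarray]] = None) -> GroupTrajectory:
    frames: list[dict[str, np.ndarray]] = []
    box = None
    with open(path) as fh:
        while True:
            title = fh.readline()
            if not title.strip():
                break
            n = int(fh.readline())
            rows: dict[str, list[list[float]]] = {}
            for _ in range(n):
                line = fh.readline()
                resname = line[5:10].strip()
                x, y, z = float(line[20:28]), float(line[28:36]), float(line[36:44])
                rows.setdefault(resname, []).append([x, y, z])
            box = tuple(float(v) for v in fh.readline().split()[:3])
            frames.append({g: np.array(v) for g, v in rows.items()})
    if box is None:
        raise ValueError("empty GRO file")
    if masses is not None:
        remap = {_sanitize(g)[:5]: g for g in masses}
        frames = [{remap.get(g, g): arr for g, arr in fr.items()} for fr in frames]
        m = {g: np.asarray(masses[g], dtype=float) for g in frames[0]}
    else:
        m = {g: np.ones(arr.shape[0]) for g, arr in frames[0].items()}
    return GroupTrajectory(frames=frames, masses=m, box=box)
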