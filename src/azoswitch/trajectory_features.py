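"""Multi-frame XYZ trajectories and dihedral-angle feature extraction.

The structural features feeding the flexibility analysis are the torsions
psi (rotation around the central N=N bond, defined by C-N=N-C) and phi
(rotation of each aryl ring around its C-N bond, defined by the
C(ortho)-C(ipso)-N=N torsion), together with their cosine transforms.

Because the literature uses two mutually incompatible phase conventions for
phi (planar rings described both as |cos phi| = 1 and as cos phi = 0,
depending on which four atoms define the torsion), the feature table exposes
BOTH |cos phi| and |sin phi| so either convention can be reproduced; the
column names make the transform explicit.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Frame",
    "DihedralLabel",
    "DihedralSpec",
    "read_xyz_trajectory",
    "write_xyz_trajectory",
    "dihedral",
    "feature_table",
    "detect_azo_dihedrals",
]


@dataclass
class Frame:
    """One geometry: element symbols plus Cartesian coordinates in angstrom."""

    symbols: list[str]
    coords: np.ndarray  # (n_atoms, 3)
    frame_index: int = 0
    comment: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError(f"coords must be (n, 3), got {self.coords.shape}")
        if len(self.symbols) != len(self.coords):
            raise ValueError(
                f"{len(self.symbols)} symbols but {len(self.coords)} coordinate rows"
            )
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")

    @property
    def n_atoms(self) -> int:
        return len(self.symbols)


class DihedralLabel(str, Enum):
    psi = "psi"
    phi1 = "phi1"
    phi2 = "phi2"
    custom = "custom"


@dataclass(frozen=True)
class DihedralSpec:
    """Four 1-based atom indices (a, b, c, d) defining a torsion b-c."""

    atoms: tuple[int, int, int, int]
    label: DihedralLabel = DihedralLabel.custom

    def __post_init__(self) -> None:
        if len(set(self.atoms)) != 4:
            raise ValueError(f"dihedral atoms must be distinct, got {self.atoms}")
        if any(a < 1 for a in self.atoms):
            raise ValueError(f"atom indices are 1-based, got {self.atoms}")

    @property
    def zero_based(self) -> tuple[int, int, int, int]:
        a, b, c, d = self.atoms
        return a - 1, b - 1, c - 1, d - 1


class XYZParseError(ValueError):
    pass


def read_xyz_trajectory(path: str | Path) -> list[Frame]:
    """Read a (possibly multi-frame) XYZ file.

    Frames are returned in file order; the comment line of each frame is
    preserved as metadata.  An empty file yields an empty list with a warning.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    frames: list[Frame] = []
    i = 0
    while i < len(lines):
        if not lines[i].strip():  # tolerate stray blank lines between frames
            i += 1
            continue
        try:
            n = int(lines[i].strip())
        except ValueError as exc:
            raise XYZParseError(
                f"frame {len(frames)}: expected atom count, got {lines[i]!r}"
            ) from exc
        if i + 2 + n > len(lines):
            raise XYZParseError(
                f"frame {len(frames)}: file truncated, {n} atoms declared"
            )
        comment = lines[i + 1] if i + 1 < len(lines) else ""
        symbols: list[str] = []
        coords = np.empty((n, 3))
        for j in range(n):
            parts = lines[i + 2 + j].split()
            if len(parts) < 4:
                raise XYZParseError(
                    f"frame {len(frames)}, atom {j}: malformed line {lines[i + 2 + j]!r}"
                )
            symbols.append(parts[0])
            coords[j] = [float(x) for x in parts[1:4]]
        frames.append(Frame(symbols, coords, frame_index=len(frames), comment=comment))
        i += 2 + n
    if not frames:
        logger.warning("no frames found in %s", path)
    return frames


def write_xyz_trajectory(frames: Iterable[Frame], path: str | Path) -> None:
    """Write frames as concatenated XYZ blocks (%.8f coordinates)."""
    path = Path(path)
    with path.open("w") as fh:
        for frame in frames:
            fh.write(f"{frame.n_atoms}\n{frame.comment}\n")
            for sym, (x, y, z) in zip(frame.symbols, frame.coords):
                fh.write(f"{sym} {x:.8f} {y:.8f} {z:.8f}\n")


class DegenerateGeometryError(ValueError):
    pass


def _dihedral_from_points(p: np.ndarray) -> float:
    """Signed torsion angle in degrees, in (-180, 180].

    IUPAC convention: looking from b toward c, the angle from the a-b bond to
    the c-d bond, clockwise positive.
    """
    b0 = p[0] - p[1]
    b1 = p[2] - p[1]
    b2 = p[3] - p[2]
    b1n = np.linalg.norm(b1)
    if b1n < 1e-12:
        raise DegenerateGeometryError("central bond has zero length")
    b1u = b1 / b1n
    # components of b0/b2 perpendicular to the central axis
    v = b0 - np.dot(b0, b1u) * b1u
    w = b2 - np.dot(b2, b1u) * b1u
    if np.linalg.norm(v) < 1e-10 or np.linalg.norm(w) < 1e-10:
        raise DegenerateGeometryError("three of the four atoms are collinear")
    x = np.dot(v, w)
    y = np.dot(np.cross(b1u, v), w)
    ang = math.degrees(math.atan2(y, x))
    if ang <= -180.0:
        ang += 360.0
    return ang


def dihedral(frame: Frame, spec: DihedralSpec) -> float:
    """Torsion angle for ``spec`` in ``frame``, degrees in (-180, 180]."""
    idx = spec.zero_based
    if max(idx) >= frame.n_atoms:
        raise IndexError(
            f"dihedral atoms {spec.atoms} out of range for frame with {frame.n_atoms} atoms"
        )
    return _dihedral_from_points(frame.coords[list(idx)])


def feature_table(
    frames: Sequence[Frame],
    specs: dict[str, DihedralSpec] | Sequence[DihedralSpec] | None = None,
) -> pd.DataFrame:
    """Per-frame dihedral features with cosine transforms.

    ``specs`` maps column names to dihedral specs; if a plain sequence is
    given, the spec labels are used as names; if omitted, azo dihedrals are
    auto-detected from the first frame.

    For the psi-like torsion the signed cosine ``cos_psi`` is emitted; for the
    phi-like torsions both ``abs_cos_<name>`` and ``abs_sin_<name>`` are
    emitted (the two phase conventions found in the literature).
    """
    if not frames:
        raise ValueError("feature_table requires at least one frame")
    if specs is None:
        specs = detect_azo_dihedrals(frames[0])
    if not isinstance(specs, dict):
        specs = {s.label.value: s for s in specs}

    rows = []
    for frame in frames:
        row: dict[str, float] = {"frame_index": frame.frame_index}
        for name, spec in specs.items():
            try:
                ang = dihedral(frame, spec)
            except (DegenerateGeometryError, IndexError) as exc:
                raise type(exc)(f"frame {frame.frame_index}, dihedral {name}: {exc}") from exc
            row[f"{name}_deg"] = ang
            rad = math.radians(ang)
            if spec.label is DihedralLabel.psi or name == "psi":
                row["cos_psi"] = math.cos(rad)
            else:
                row[f"abs_cos_{name}"] = abs(math.cos(rad))
                row[f"abs_sin_{name}"] = abs(math.sin(rad))
        rows.append(row)
    return pd.DataFrame(rows)


_BOND_NN = 1.40  # N=N detection cutoff, angstrom
_BOND_CN = 1.60
_BOND_CC = 1.60


def detect_azo_dihedrals(frame: Frame) -> dict[str, DihedralSpec]:
    """Locate psi/phi1/phi2 specs on an azobenzene-like topology.

    Finds the N=N pair by element and distance (< 1.4 angstrom), then the
    ipso carbon bonded to each nitrogen, then one ortho carbon on each ring.
    Returns 1-based specs; explicit specs always override this convenience.
    """
    symbols = np.array(frame.symbols)
    coords = frame.coords
    n_idx = np.flatnonzero(symbols == "N")
    nn_pair = None
    for ii, i in enumerate(n_idx):
        for j in n_idx[ii + 1 :]:
            if np.linalg.norm(coords[i] - coords[j]) < _BOND_NN:
                nn_pair = (int(i), int(j))
                break
        if nn_pair:
            break
    if nn_pair is None:
        raise ValueError("no N=N bond found (two N atoms closer than 1.4 angstrom)")
    n1, n2 = nn_pair

    def bonded_carbon(center: int, exclude: set[int], cutoff: float) -> int:
        d = np.linalg.norm(coords - coords[center], axis=1)
        cands = [
            int(i)
            for i in np.argsort(d)
            if symbols[i] == "C" and i not in exclude and 0 < d[i] < cutoff
        ]
        if not cands:
            raise ValueError(f"no carbon bonded to atom {center + 1}")
        return cands[0]

    c1 = bonded_carbon(n1, {n1, n2}, _BOND_CN)  # ipso, ring A
    c2 = bonded_carbon(n2, {n1, n2}, _BOND_CN)  # ipso, ring B
    o1 = bonded_carbon(c1, {n1, n2, c1, c2}, _BOND_CC)  # ortho, ring A
    o2 = bonded_carbon(c2, {n1, n2, c1, c2, o1}, _BOND_CC)  # ortho, ring B

    one = lambda i: i + 1  # noqa: E731 - 1-based user-facing indices
    return {
        "psi": DihedralSpec((one(c1), one(n1), one(n2), one(c2)), DihedralLabel.psi),
        "phi1": DihedralSpec((one(o1), one(c1), one(n1), one(n2)), DihedralLabel.phi1),
        "phi2": DihedralSpec((one(o2), one(c2), one(n2), one(n1)), DihedralLabel.phi2),
    }
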