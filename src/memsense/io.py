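"""Coarse-grained structure / trajectory I/O and selections.

All coordinates are stored in nm internally.  GRO files are parsed by fixed
column positions (merged fields survive); PDB coordinates are converted from
Å on read.  Only orthorhombic boxes are supported — every system this
pipeline targets (planar and quasi-1D buckled bilayers) lives in one.
Positions are wrapped into [0, L) per axis on load; analyses apply the
minimum-image convention in xy where needed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import yaml

from .errors import FormatError, InputError, ParameterError, StructuralError

__all__ = [
    "BeadFrame",
    "Trajectory",
    "SelectionSpec",
    "AnalysisConfig",
    "read_coordinates",
    "write_coordinates",
    "iterate_trajectory",
    "load_trajectory",
    "write_trajectory",
    "count_frames",
    "select",
    "wrap_positions",
]


def wrap_positions(positions: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Wrap coordinates into [0, L) along each axis."""
    return np.mod(positions, box[np.newaxis, :])


@dataclass
class BeadFrame:
    """One snapshot: positions (nm), orthorhombic box (nm) and bead metadata.

    ``molecule_ids`` groups beads into molecules (lipids, the peptide);
    ``molecule_names`` / ``bead_names`` carry the force-field naming
    (e.g. POPC / PO4) that selections match against.
    """

    positions: np.ndarray  # (N, 3) nm
    box: np.ndarray  # (3,) nm
    molecule_ids: np.ndarray  # (N,) int
    molecule_names: np.ndarray  # (N,) str
    bead_names: np.ndarray  # (N,) str
    time: float = 0.0  # ps

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.box = np.asarray(self.box, dtype=float)
        self.molecule_ids = np.asarray(self.molecule_ids)
        self.molecule_names = np.asarray(self.molecule_names, dtype=object)
        self.bead_names = np.asarray(self.bead_names, dtype=object)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise InputError("positions must have shape (N, 3)")
        n = self.positions.shape[0]
        if n < 1:
            raise InputError("a frame must contain at least one bead")
        if self.box.shape != (3,) or not np.all(self.box > 0):
            raise InputError("box must be three positive lengths (nm)")
        if not np.all(np.isfinite(self.positions)):
            raise InputError("positions must be finite")
        for name, arr in (
            ("molecule_ids", self.molecule_ids),
            ("molecule_names", self.molecule_names),
            ("bead_names", self.bead_names),
        ):
            if arr.shape != (n,):
                raise InputError(f"{name} must have length N={n}")

    @property
    def n_beads(self) -> int:
        return self.positions.shape[0]

    def wrapped(self) -> "BeadFrame":
        return dataclasses.replace(self, positions=wrap_positions(self.positions, self.box))

    def translated(self, shift: Sequence[float]) -> "BeadFrame":
        return dataclasses.replace(self, positions=self.positions + np.asarray(shift, float))


class Trajectory:
    """An ordered, metadata-consistent sequence of frames.

    Frames must share bead count and metadata; times must be strictly
    increasing.  Optionally carries a ground-truth record from the synthetic
    generators (ignored by all analyses, used only by tests and reports).
    """

    def __init__(self, frames: Sequence[BeadFrame], ground_truth: dict | None = None):
        frames = list(frames)
        if not frames:
            raise InputError("trajectory must contain at least one frame")
        first = frames[0]
        for i, fr in enumerate(frames[1:], start=1):
            if fr.n_beads != first.n_beads:
                raise StructuralError(
                    f"frame {i} has {fr.n_beads} beads, expected {first.n_beads}"
                )
            if not (
                np.array_equal(fr.molecule_ids, first.molecule_ids)
                and np.array_equal(fr.bead_names, first.bead_names)
            ):
                raise StructuralError(f"frame {i} bead metadata differs from frame 0")
        times = np.array([fr.time for fr in frames])
        if len(times) > 1 and not np.all(np.diff(times) > 0):
            raise StructuralError("frame times must be strictly increasing")
        self.frames = frames
        self.ground_truth = ground_truth or {}

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self) -> Iterator[BeadFrame]:
        return iter(self.frames)

    def __getitem__(self, i):
        return self.frames[i]

    @property
    def n_beads(self) -> int:
        return self.frames[0].n_beads


@dataclass(frozen=True)
class SelectionSpec:
    """Declarative bead selection: match by molecule and/or bead name, with an
    optional leaflet restriction resolved by head-minus-tail orientation
    (see :func:`memsense.peptide.assign_leaflets`)."""

    name: str
    molecule_names: frozenset[str] | None = None
    bead_names: frozenset[str] | None = None
    leaflet: str = "both"  # upper | lower | both

    def __post_init__(self):
        if self.leaflet not in ("upper", "lower", "both"):
            raise ParameterError(f"unknown leaflet tag {self.leaflet!r}")
        if self.molecule_names is not None:
            object.__setattr__(self, "molecule_names", frozenset(self.molecule_names))
        if self.bead_names is not None:
            object.__setattr__(self, "bead_names", frozenset(self.bead_names))


# Default Martini-style naming used to resolve leaflet tags when the caller
# does not pass explicit head/tail specs.
PHOSPHATE_BEADS = frozenset({"PO4"})
TAIL_BEAD_PREFIXES = ("C", "D")  # C*A/C*B saturated, D*A/D*B unsaturated beads


def _tail_mask(bead_names: np.ndarray) -> np.ndarray:
    return np.array(
        [str(b).startswith(TAIL_BEAD_PREFIXES) and str(b) not in ("CA",) for b in bead_names]
    )


def select(
    frame: BeadFrame,
    spec: SelectionSpec,
    leaflet_labels: dict[int, str] | None = None,
) -> np.ndarray:
    """Resolve a :class:`SelectionSpec` to a sorted index array.

    Empty selections are returned as empty arrays; downstream operations
    decide whether that is an error.  ``leaflet_labels`` (molecule_id ->
    'upper'/'lower') may be precomputed; otherwise they are derived on the
    fly with the default phosphate/tail naming.
    """
    mask = np.ones(frame.n_beads, dtype=bool)
    if spec.molecule_names is not None:
        mask &= np.isin(frame.molecule_names.astype(str), list(spec.molecule_names))
    if spec.bead_names is not None:
        mask &= np.isin(frame.bead_names.astype(str), list(spec.bead_names))
    if spec.leaflet != "both":
        if leaflet_labels is None:
            from .peptide import assign_leaflets

            leaflet_labels = assign_leaflets(frame)
        wanted = np.array(
            [leaflet_labels.get(int(m)) == spec.leaflet for m in frame.molecule_ids]
        )
        mask &= wanted
    return np.flatnonzero(mask)


# ---------------------------------------------------------------------------
# Analysis configuration
# ---------------------------------------------------------------------------


@dataclass
class AnalysisConfig:
    """All tunable parameters of the pipeline, with documented defaults.

    temperature is mandatory context for every free-energy operation (the
    Martini thermostat setting for these systems); cylinder_radius is the
    1.0 nm insertion-depth cylinder; fourier_modes the surface-fit truncation.
    """

    temperature: float = 310.0  # K
    cylinder_radius: float = 1.0  # nm
    fourier_modes: tuple[int, int] = (3, 3)
    curvature_bin_width: float = 0.005  # nm^-1
    curvature_range: tuple[float, float] = (-0.15, 0.15)  # nm^-1
    accessible_mask_threshold: float = 1e-4
    leaflet_agreement_threshold: float = 0.1
    # packing-defect detection
    defect_grid_step: float = 0.1  # nm
    defect_z_depth: float = 0.1  # nm below local phosphate level
    defect_connectivity: int = 4
    defect_bead_radius: float = 0.26  # nm (Martini bead)
    defect_a_min: float = 15.0  # Å², exponential-tail fit threshold
    # state windows (NOT taken from any publication; explicit config)
    tm_z_cut: float = 0.5  # nm
    tm_tilt_cut: float = 45.0  # deg
    ads_z_cut: float = 1.2  # nm
    seed: int = 0

    def __post_init__(self):
        if self.temperature <= 0:
            raise ParameterError("temperature must be positive")
        if self.cylinder_radius <= 0:
            raise ParameterError("cylinder_radius must be positive")
        mx, my = self.fourier_modes
        if mx < 0 or my < 0:
            raise ParameterError("fourier mode cutoffs must be >= 0")
        self.fourier_modes = (int(mx), int(my))

    @property
    def curvature_bin_edges(self) -> np.ndarray:
        lo, hi = self.curvature_range
        n = int(round((hi - lo) / self.curvature_bin_width))
        return lo + self.curvature_bin_width * np.arange(n + 1)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ParameterError(f"unknown config keys: {sorted(unknown)}")
        for key in ("fourier_modes", "curvature_range"):
            if key in data and isinstance(data[key], list):
                data[key] = tuple(data[key])
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        data["fourier_modes"] = list(self.fourier_modes)
        data["curvature_range"] = list(self.curvature_range)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)

    def to_dict(self) -> dict:
        data = dataclasses.asdict(self)
        data["fourier_modes"] = list(self.fourier_modes)
        data["curvature_range"] = list(self.curvature_range)
        return data


# ---------------------------------------------------------------------------
# Coordinate files (GRO / PDB)
# ---------------------------------------------------------------------------


def read_coordinates(path: str | Path, fmt: str | None = None) -> BeadFrame:
    """Read a single-frame GRO or PDB file into a :class:`BeadFrame`.

    Format is inferred from the suffix when not given.  PDB Å are converted
    to nm.  Triclinic boxes are rejected.
    """
    path = Path(path)
    if fmt is None:
        fmt = path.suffix.lstrip(".").lower()
    if fmt == "gro":
        return _read_gro(path)
    if fmt == "pdb":
        return _read_pdb(path)
    raise FormatError(f"unsupported coordinate format {fmt!r}", str(path))


def _parse_fixed_float(line: str, start: int, stop: int, path: str, lineno: int, what: str) -> float:
    chunk = line[start:stop]
    try:
        return float(chunk)
    except ValueError:
        raise FormatError(f"cannot parse {what} from columns {start}-{stop}", path, lineno) from None


def _read_gro(path: Path) -> BeadFrame:
    with open(path) as fh:
        lines = fh.read().splitlines()
    if len(lines) < 3:
        raise FormatError("GRO file needs title, count, atoms and box lines", str(path), len(lines))
    try:
        n = int(lines[1].strip())
    except ValueError:
        raise FormatError("cannot parse atom count", str(path), 2) from None
    if len(lines) < n + 3:
        raise FormatError(f"expected {n} atom lines plus box line", str(path), len(lines))
    title_time = 0.0
    if "t=" in lines[0]:
        try:
            title_time = float(lines[0].rsplit("t=", 1)[1].split()[0])
        except (ValueError, IndexError):
            title_time = 0.0
    pos = np.empty((n, 3))
    mol_ids = np.empty(n, dtype=int)
    mol_names = np.empty(n, dtype=object)
    bead_names = np.empty(n, dtype=object)
    for i in range(n):
        lineno = 3 + i
        line = lines[2 + i]
        if len(line) < 44:
            raise FormatError("truncated GRO atom line", str(path), lineno)
        try:
            mol_ids[i] = int(line[0:5])
        except ValueError:
            raise FormatError("cannot parse residue number", str(path), lineno) from None
        mol_names[i] = line[5:10].strip()
        bead_names[i] = line[10:15].strip()
        pos[i, 0] = _parse_fixed_float(line, 20, 28, str(path), lineno, "x")
        pos[i, 1] = _parse_fixed_float(line, 28, 36, str(path), lineno, "y")
        pos[i, 2] = _parse_fixed_float(line, 36, 44, str(path), lineno, "z")
    box_line = lines[2 + n].split()
    if len(box_line) < 3:
        raise FormatError("missing or short box line", str(path), 3 + n)
    try:
        box_vals = [float(v) for v in box_line]
    except ValueError:
        raise FormatError("cannot parse box line", str(path), 3 + n) from None
    if len(box_vals) > 3 and any(abs(v) > 1e-9 for v in box_vals[3:]):
        raise FormatError("triclinic boxes are not supported", str(path), 3 + n)
    box = np.array(box_vals[:3])
    if not np.all(box > 0):
        raise FormatError("box lengths must be positive", str(path), 3 + n)
    frame = BeadFrame(pos, box, mol_ids, mol_names, bead_names, time=title_time)
    return frame.wrapped()


def _read_pdb(path: Path) -> BeadFrame:
    pos, mol_ids, mol_names, bead_names = [], [], [], []
    box = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6]
            if rec == "CRYST1":
                a = _parse_fixed_float(line, 6, 15, str(path), lineno, "a")
                b = _parse_fixed_float(line, 15, 24, str(path), lineno, "b")
                c = _parse_fixed_float(line, 24, 33, str(path), lineno, "c")
                angles = [
                    _parse_fixed_float(line, 33, 40, str(path), lineno, "alpha"),
                    _parse_fixed_float(line, 40, 47, str(path), lineno, "beta"),
                    _parse_fixed_float(line, 47, 54, str(path), lineno, "gamma"),
                ]
                if any(abs(ang - 90.0) > 1e-6 for ang in angles):
                    raise FormatError("triclinic boxes are not supported", str(path), lineno)
                box = np.array([a, b, c]) / 10.0  # Å -> nm
            elif rec in ("ATOM  ", "HETATM"):
                if len(line.rstrip("\n")) < 54:
                    raise FormatError("truncated PDB atom line", str(path), lineno)
                bead_names.append(line[12:16].strip())
                mol_names.append(line[17:21].strip())
                try:
                    mol_ids.append(int(line[22:26]))
                except ValueError:
                    raise FormatError("cannot parse residue number", str(path), lineno) from None
                pos.append(
                    [
                        _parse_fixed_float(line, 30, 38, str(path), lineno, "x"),
                        _parse_fixed_float(line, 38, 46, str(path), lineno, "y"),
                        _parse_fixed_float(line, 46, 54, str(path), lineno, "z"),
                    ]
                )
    if not pos:
        raise FormatError("no ATOM/HETATM records found", str(path))
    if box is None:
        raise FormatError("missing CRYST1 box record", str(path))
    frame = BeadFrame(
        np.asarray(pos) / 10.0,  # Å -> nm
        box,
        np.asarray(mol_ids),
        np.asarray(mol_names, dtype=object),
        np.asarray(bead_names, dtype=object),
    )
    return frame.wrapped()


def write_coordinates(frame: BeadFrame, path: str | Path, fmt: str | None = None) -> None:
    """Write a frame as GRO (nm, 3 decimals) or PDB (Å, 3 decimals)."""
    path = Path(path)
    if fmt is None:
        fmt = path.suffix.lstrip(".").lower()
    if fmt == "gro":
        with open(path, "w") as fh:
            fh.write(f"memsense frame t= {frame.time:.3f}\n{frame.n_beads:d}\n")
            for i in range(frame.n_beads):
                x, y, z = frame.positions[i]
                fh.write(
                    f"{int(frame.molecule_ids[i]) % 100000:5d}"
                    f"{str(frame.molecule_names[i]):<5.5s}"
                    f"{str(frame.bead_names[i]):>5.5s}"
                    f"{(i + 1) % 100000:5d}{x:8.3f}{y:8.3f}{z:8.3f}\n"
                )
            fh.write(f"{frame.box[0]:10.5f}{frame.box[1]:10.5f}{frame.box[2]:10.5f}\n")
    elif fmt == "pdb":
        with open(path, "w") as fh:
            a, b, c = frame.box * 10.0
            fh.write(f"CRYST1{a:9.3f}{b:9.3f}{c:9.3f}{90.0:7.2f}{90.0:7.2f}{90.0:7.2f} P 1\n")
            for i in range(frame.n_beads):
                x, y, z = frame.positions[i] * 10.0
                fh.write(
                    f"ATOM  {(i + 1) % 100000:5d} {str(frame.bead_names[i]):<4.4s}"
                    f"{str(frame.molecule_names[i]):<4.4s} "
                    f"{int(frame.molecule_ids[i]) % 10000:4d}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}\n"
                )
            fh.write("END\n")
    else:
        raise FormatError(f"unsupported coordinate format {fmt!r}", str(path))


# ---------------------------------------------------------------------------
# Trajectories (XTC / TRR via MDAnalysis)
# ---------------------------------------------------------------------------


def iterate_trajectory(
    traj_path: str | Path,
    topology_path: str | Path,
    stride: int = 1,
) -> Iterator[BeadFrame]:
    """Stream frames from an XTC/TRR file, one :class:`BeadFrame` at a time.

    Bead metadata comes from the GRO/PDB topology; memory use is independent
    of trajectory length.
    """
    import MDAnalysis as mda

    top = read_coordinates(topology_path)
    try:
        u = mda.Universe(str(topology_path), str(traj_path))
    except (ValueError, OSError, IOError) as exc:
        raise StructuralError(f"cannot open trajectory {traj_path}: {exc}") from exc
    if len(u.atoms) != top.n_beads:
        raise StructuralError(
            f"topology has {top.n_beads} beads but trajectory frames have {len(u.atoms)}"
        )
    for ts in u.trajectory[::stride]:
        dims = ts.dimensions
        if dims is None or not np.all(dims[:3] > 0):
            raise FormatError("trajectory frame lacks a box", str(traj_path))
        if any(abs(ang - 90.0) > 1e-4 for ang in dims[3:6]):
            raise FormatError("triclinic boxes are not supported", str(traj_path))
        box = np.asarray(dims[:3], dtype=float) / 10.0
        frame = BeadFrame(
            np.asarray(ts.positions, dtype=float) / 10.0,
            box,
            top.molecule_ids,
            top.molecule_names,
            top.bead_names,
            time=float(ts.time),
        )
        yield frame.wrapped()


def count_frames(traj_path: str | Path, topology_path: str | Path) -> int:
    """Independent frame-count scan (used to cross-check streamed iteration)."""
    import MDAnalysis as mda

    u = mda.Universe(str(topology_path), str(traj_path))
    return len(u.trajectory)


def load_trajectory(
    traj_path: str | Path, topology_path: str | Path, stride: int = 1
) -> Trajectory:
    """Materialize a streamed trajectory into memory."""
    return Trajectory(list(iterate_trajectory(traj_path, topology_path, stride=stride)))


def write_trajectory(traj: Trajectory, traj_path: str | Path, topology_path: str | Path) -> None:
    """Write a trajectory as topology GRO + XTC/TRR, plus a JSON ground-truth
    sidecar if the trajectory carries one."""
    import MDAnalysis as mda

    first = traj.frames[0]
    write_coordinates(first, topology_path, "gro")
    n = first.n_beads
    u = mda.Universe.empty(n, trajectory=True)
    with mda.Writer(str(traj_path), n) as w:
        for fr in traj.frames:
            u.atoms.positions = fr.positions * 10.0
            u.dimensions = [*(fr.box * 10.0), 90.0, 90.0, 90.0]
            u.trajectory.ts.time = fr.time
            w.write(u.atoms)
    if traj.ground_truth:
        sidecar = Path(str(traj_path) + ".truth.json")
        with open(sidecar, "w") as fh:
            json.dump(_jsonable(traj.ground_truth), fh, indent=2)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


# ---------------------------------------------------------------------------
# Tabular results
# ---------------------------------------------------------------------------


def write_table(df, path: str | Path, metadata: dict | None = None) -> None:
    """CSV with '#'-prefixed metadata lines followed by a header row."""
    with open(path, "w") as fh:
        for key, val in (metadata or {}).items():
            fh.write(f"# {key}: {val}\n")
        df.to_csv(fh, index=False)


def read_table(path: str | Path):
    import pandas as pd

    return pd.read_csv(path, comment="#")
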