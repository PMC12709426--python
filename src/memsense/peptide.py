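"""Per-frame peptide observables and state assignment.

Insertion depth is the z-distance between the peptide center of mass and
the mean z of the phosphate beads of the peptide's leaflet within a lateral
cylinder (default radius 1.0 nm, minimum image in xy), signed so that
positive always means deeper — below the headgroups, toward the membrane
core — on either leaflet.  Tilt (CV2) is the angle between the peptide's
principal axis (oriented first→last bead) and +z; CV1 is the signed
z-distance between peptide and membrane centers of mass.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import AnalysisError, InputError, StructuralError
from .io import (
    AnalysisConfig,
    BeadFrame,
    SelectionSpec,
    Trajectory,
    _tail_mask,
    select,
)

__all__ = [
    "FrameDepth",
    "DepthSeries",
    "OrientationState",
    "assign_leaflets",
    "insertion_depth",
    "mean_depth",
    "tilt_angle",
    "com_distance_cv1",
    "classify_state",
    "peptide_com",
]

DEFAULT_PHOSPHATE = SelectionSpec("phosphates", bead_names=frozenset({"PO4"}))
DEFAULT_PEPTIDE = SelectionSpec("peptide", molecule_names=frozenset({"PEP"}))


def _unwrap_chain(frame: BeadFrame, idx: np.ndarray) -> np.ndarray:
    """Unwrap a bead chain by minimum-imaging consecutive differences.

    Walking the chain bond by bond is robust even when the molecule's total
    extent exceeds half the box (a straight 21-bead peptide does), where
    min-imaging against a single reference bead would fold it."""
    pos = frame.positions[idx]
    diffs = np.diff(pos, axis=0)
    diffs -= frame.box[np.newaxis, :] * np.round(diffs / frame.box[np.newaxis, :])
    return np.vstack([pos[0], pos[0] + np.cumsum(diffs, axis=0)])


def _unwrapped_com(frame: BeadFrame, idx: np.ndarray) -> np.ndarray:
    return _unwrap_chain(frame, idx).mean(axis=0)


def peptide_com(frame: BeadFrame, peptide_spec: SelectionSpec = DEFAULT_PEPTIDE) -> np.ndarray:
    idx = select(frame, peptide_spec)
    if len(idx) == 0:
        raise InputError("peptide selection is empty")
    return _unwrapped_com(frame, idx)


def assign_leaflets(
    frame: BeadFrame,
    phosphate_spec: SelectionSpec = DEFAULT_PHOSPHATE,
    tail_spec: SelectionSpec | None = None,
) -> dict[int, str]:
    """Label each lipid 'upper' or 'lower' by the sign of its head-minus-tail
    z vector (head COM above tail COM → upper).

    This per-lipid rule survives buckled geometries where a global z cut
    fails.  Lipids are the molecules owning at least one phosphate bead; a
    lipid without tail beads is a structural error.
    """
    head_idx = select(frame, phosphate_spec)
    if len(head_idx) == 0:
        raise InputError("phosphate selection is empty")
    if tail_spec is not None:
        tail_of = np.zeros(frame.n_beads, dtype=bool)
        tail_of[select(frame, tail_spec)] = True
    else:
        tail_of = _tail_mask(frame.bead_names)

    def group_mean_z(bead_indices: np.ndarray) -> dict[int, float]:
        ids = frame.molecule_ids[bead_indices]
        z = frame.positions[bead_indices, 2]
        uniq, inv = np.unique(ids, return_inverse=True)
        sums = np.zeros(len(uniq))
        np.add.at(sums, inv, z)
        counts = np.bincount(inv)
        return {int(m): s / c for m, s, c in zip(uniq, sums, counts)}

    head_z = group_mean_z(head_idx)
    lipid_ids = set(head_z)
    tail_beads = np.flatnonzero(
        tail_of & np.isin(frame.molecule_ids, np.fromiter(lipid_ids, dtype=int))
    )
    tail_z = group_mean_z(tail_beads) if len(tail_beads) else {}
    labels: dict[int, str] = {}
    for mol in lipid_ids:
        if mol not in tail_z:
            raise StructuralError(f"lipid {mol} has no tail beads")
        labels[mol] = "upper" if head_z[mol] > tail_z[mol] else "lower"
    return labels


@dataclass(frozen=True)
class FrameDepth:
    """Insertion depth of one frame; invalid when the cylinder was empty."""

    depth: float  # nm, NaN when invalid
    n_phosphates: int
    time: float = 0.0

    @property
    def valid(self) -> bool:
        return self.n_phosphates > 0 and np.isfinite(self.depth)


def insertion_depth(
    frame: BeadFrame,
    peptide_spec: SelectionSpec = DEFAULT_PEPTIDE,
    phosphate_spec: SelectionSpec = DEFAULT_PHOSPHATE,
    leaflet: str = "upper",
    radius: float = 1.0,
) -> FrameDepth:
    """Depth = (mean z of the leaflet's phosphates within ``radius`` of the
    peptide COM in xy) - (peptide COM z), sign-flipped on the lower leaflet.

    Frames whose cylinder contains no phosphate are flagged (NaN), never
    silently averaged.
    """
    com = peptide_com(frame, peptide_spec)
    labels = assign_leaflets(frame, phosphate_spec)
    idx = select(frame, phosphate_spec)
    in_leaflet = np.array([labels.get(int(m)) == leaflet for m in frame.molecule_ids[idx]])
    idx = idx[in_leaflet]
    if len(idx) == 0:
        raise InputError(f"no phosphates on the {leaflet} leaflet")
    dx = frame.positions[idx, 0] - com[0]
    dy = frame.positions[idx, 1] - com[1]
    dx -= frame.box[0] * np.round(dx / frame.box[0])
    dy -= frame.box[1] * np.round(dy / frame.box[1])
    near = dx**2 + dy**2 <= radius**2
    n = int(near.sum())
    if n == 0:
        return FrameDepth(np.nan, 0, frame.time)
    plane_z = float(frame.positions[idx[near], 2].mean())
    direction = 1.0 if leaflet == "upper" else -1.0
    return FrameDepth(direction * (plane_z - com[2]), n, frame.time)


@dataclass
class DepthSeries:
    """Per-frame depths (per replicate) and their summary statistics."""

    per_replicate: list[np.ndarray]  # valid + invalid (NaN) frame depths
    n_invalid: list[int]
    leaflet: str
    mean: float = 0.0
    sd: float = 0.0
    replicate_means: np.ndarray = field(default_factory=lambda: np.array([]))

    @property
    def n_replicates(self) -> int:
        return len(self.per_replicate)


def mean_depth(
    trajectories: Trajectory | list[Trajectory],
    peptide_spec: SelectionSpec = DEFAULT_PEPTIDE,
    phosphate_spec: SelectionSpec = DEFAULT_PHOSPHATE,
    leaflet: str = "upper",
    radius: float = 1.0,
    stride_ps: float | None = None,
) -> DepthSeries:
    """Mean insertion depth over all valid frames of one or more replicate
    trajectories.

    With several replicates the reported mean is the mean of replicate means
    and the sd their sample standard deviation; a single replicate reports
    the over-frames standard deviation instead.  ``stride_ps`` subsamples
    frames to the given time interval before averaging.
    """
    if isinstance(trajectories, Trajectory):
        trajectories = [trajectories]
    per_rep: list[np.ndarray] = []
    n_invalid: list[int] = []
    for traj in trajectories:
        frames = traj.frames
        if stride_ps is not None:
            t0 = frames[0].time
            frames = [
                fr
                for fr in frames
                if abs((fr.time - t0) / stride_ps - round((fr.time - t0) / stride_ps)) < 1e-6
            ]
        depths = np.array(
            [
                insertion_depth(fr, peptide_spec, phosphate_spec, leaflet, radius).depth
                for fr in frames
            ]
        )
        per_rep.append(depths)
        n_invalid.append(int(np.sum(~np.isfinite(depths))))
    rep_means = np.array([np.nanmean(d) if np.any(np.isfinite(d)) else np.nan for d in per_rep])
    if np.all(~np.isfinite(rep_means)):
        raise AnalysisError("all frames invalid: no phosphates in any cylinder")
    rep_means = rep_means[np.isfinite(rep_means)]
    mean = float(rep_means.mean())
    if len(rep_means) > 1:
        sd = float(rep_means.std(ddof=1))
    else:
        pooled = np.concatenate(per_rep)
        sd = float(np.nanstd(pooled, ddof=0))
    return DepthSeries(per_rep, n_invalid, leaflet, mean, sd, rep_means)


def tilt_angle(
    frame: BeadFrame, backbone_spec: SelectionSpec = DEFAULT_PEPTIDE
) -> float:
    """Angle (deg, in [0, 180]) between the peptide axis and +z.

    The axis is the principal component of the backbone bead cloud (robust
    to bead jitter), oriented from the first to the last bead so that 0° and
    180° are distinguishable — the orientation matters for CV2.
    """
    idx = select(frame, backbone_spec)
    if len(idx) < 2:
        raise InputError("need at least two backbone beads")
    pos = _unwrap_chain(frame, idx)
    centered = pos - pos.mean(axis=0)
    cov = centered.T @ centered
    if np.allclose(cov, 0.0):
        raise AnalysisError("degenerate peptide: all backbone beads coincide")
    evals, evecs = np.linalg.eigh(cov)
    axis = evecs[:, -1]
    head_to_tail = pos[-1] - pos[0]
    if np.dot(axis, head_to_tail) < 0:
        axis = -axis
    cos = np.clip(axis[2] / np.linalg.norm(axis), -1.0, 1.0)
    return float(np.degrees(np.arccos(cos)))


def com_distance_cv1(
    frame: BeadFrame,
    peptide_spec: SelectionSpec = DEFAULT_PEPTIDE,
    membrane_spec: SelectionSpec | None = None,
) -> float:
    """CV1: signed z-distance between peptide COM and membrane COM (nm).

    The membrane defaults to every bead not matched by the peptide spec."""
    pep = select(frame, peptide_spec)
    if len(pep) == 0:
        raise InputError("peptide selection is empty")
    if membrane_spec is None:
        mem = np.setdiff1d(np.arange(frame.n_beads), pep)
    else:
        mem = select(frame, membrane_spec)
    if len(mem) == 0:
        raise InputError("membrane selection is empty")
    return float(_unwrapped_com(frame, pep)[2] - frame.positions[mem, 2].mean())


@dataclass(frozen=True)
class OrientationState:
    """(CV1, CV2) of one frame plus its state label."""

    cv1: float  # nm
    cv2: float  # deg
    label: str


def classify_state(cv1: float, cv2: float, config: AnalysisConfig | None = None) -> str:
    """Total classification of the (CV1, CV2) plane into
    transmembrane / adsorbed_upper / adsorbed_lower / inserted.

    transmembrane: |CV1| <= tm_z_cut and the tilt within tm_tilt_cut of
    either membrane normal; adsorbed: |CV1| beyond ads_z_cut; inserted
    otherwise.  The windows are explicit configuration (they are not
    derived from any reference data) and partition the plane.
    """
    cfg = config or AnalysisConfig()
    if not 0.0 <= cv2 <= 180.0:
        raise InputError("cv2 must be in [0, 180] degrees")
    if abs(cv1) <= cfg.tm_z_cut and min(cv2, 180.0 - cv2) <= cfg.tm_tilt_cut:
        return "transmembrane"
    if cv1 > cfg.ads_z_cut:
        return "adsorbed_upper"
    if cv1 < -cfg.ads_z_cut:
        return "adsorbed_lower"
    return "inserted"
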