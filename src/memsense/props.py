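"""Bilayer characterization: area per lipid, tail order parameters, density
profiles, lipid packing defects, and peptide-centred local maps.

Defect detection follows the conventional interfacial grid scan: the leaflet
is rasterized in xy, each cell is probed from the solvent side, and a cell
counts as a defect cell when the first bead encountered below the local
phosphate level (minus a depth threshold) is an acyl-chain bead, or when no
bead shadows the cell at all (a void).  Connected defect cells are merged
and their areas, in Å^2, follow an exponential law whose characteristic
constant is fitted on the tail by maximum likelihood.  The constants are
parameter-dependent (grid step, depth, bead radius) and every report echoes
the parameters used.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import AnalysisError, InputError, StructuralError
from .io import BeadFrame, SelectionSpec, Trajectory, select

__all__ = [
    "DefectSizeSample",
    "OrderProfile",
    "area_per_lipid",
    "scc_order",
    "scc_of_vectors",
    "density_profile",
    "detect_defects",
    "defect_constant",
    "defect_constant_loglinear",
    "local_maps",
]

A2_PER_NM2 = 100.0
HEAD_BEADS = frozenset({"NC3", "PO4", "GL1", "GL2"})


@dataclass
class DefectSizeSample:
    """Defect areas (Å^2) with detection parameters and, once fitted, the
    exponential defect-area constant π and its CI."""

    areas: np.ndarray
    params: dict = field(default_factory=dict)
    per_frame: list | None = None
    pi: float | None = None
    ci: float | None = None
    degenerate: bool = False
    ground_truth: dict = field(default_factory=dict)

    def __post_init__(self):
        self.areas = np.asarray(self.areas, dtype=float)

    def fit(self, a_min: float = 15.0) -> tuple[float, float]:
        self.pi, self.ci = defect_constant(self.areas, a_min=a_min)
        self.degenerate = self.pi == 0.0
        self.params["a_min"] = a_min
        return self.pi, self.ci


@dataclass
class OrderProfile:
    """Per-bond S_CC = <(3 cos^2 θ - 1)/2> with θ between the tail bond and
    the membrane normal (+z for planar systems)."""

    s_cc: np.ndarray  # per bond index
    bonds: list[tuple[str, str]]
    leaflet: str = "both"
    n_samples: int = 0

    def __post_init__(self):
        self.s_cc = np.asarray(self.s_cc, dtype=float)
        if np.any(self.s_cc < -0.5 - 1e-9) or np.any(self.s_cc > 1.0 + 1e-9):
            raise AnalysisError("S_CC out of the [-0.5, 1] range")


def area_per_lipid(traj: Trajectory, n_per_leaflet: int) -> tuple[float, float]:
    """Projected area per lipid, Å^2: per-frame Lx*Ly / n_per_leaflet,
    returned as (mean, sd) over frames."""
    if n_per_leaflet <= 0:
        raise InputError("n_per_leaflet must be positive")
    apl = np.array(
        [fr.box[0] * fr.box[1] / n_per_leaflet * A2_PER_NM2 for fr in traj.frames]
    )
    return float(apl.mean()), float(apl.std(ddof=0))


def scc_of_vectors(vectors: np.ndarray) -> float:
    """P2 of the angle between bond vectors and +z, averaged over vectors."""
    v = np.asarray(vectors, dtype=float)
    norms = np.linalg.norm(v, axis=1)
    if np.any(norms == 0):
        raise InputError("zero-length bond vector")
    cos = v[:, 2] / norms
    return float(np.mean(1.5 * cos**2 - 0.5))


def _lipid_bead_positions(frame: BeadFrame, bead_name: str, mol_ids: np.ndarray) -> np.ndarray:
    """Positions of the named bead for each molecule id in mol_ids (order
    preserved); StructuralError if any molecule lacks the bead."""
    mask = frame.bead_names.astype(str) == bead_name
    ids = frame.molecule_ids[mask]
    lookup = {int(m): i for m, i in zip(ids, np.flatnonzero(mask))}
    try:
        idx = [lookup[int(m)] for m in mol_ids]
    except KeyError as exc:
        raise StructuralError(f"lipid {exc.args[0]} is missing bead {bead_name!r}") from None
    return frame.positions[idx]


def scc_order(
    traj: Trajectory,
    tail_bead_names: tuple[str, ...] = ("C1A", "C2A", "C3A"),
    leaflet: str = "both",
) -> OrderProfile:
    """Tail order profile averaged over lipids and frames.

    ``tail_bead_names`` lists consecutive tail beads in chain order; bonds
    are the consecutive pairs.  The membrane normal is +z (planar systems).
    """
    from .peptide import assign_leaflets

    bonds = list(zip(tail_bead_names[:-1], tail_bead_names[1:]))
    if not bonds:
        raise InputError("need at least two tail beads to define a bond")
    sums = np.zeros(len(bonds))
    count = 0
    for frame in traj.frames:
        first = frame.bead_names.astype(str) == tail_bead_names[0]
        mol_ids = np.unique(frame.molecule_ids[first])
        if leaflet != "both":
            labels = assign_leaflets(frame)
            mol_ids = np.array([m for m in mol_ids if labels.get(int(m)) == leaflet])
        if len(mol_ids) == 0:
            continue
        per_bead = {bn: _lipid_bead_positions(frame, bn, mol_ids) for bn in tail_bead_names}
        for j, (b1, b2) in enumerate(bonds):
            v = per_bead[b2] - per_bead[b1]
            # minimum image in xy (tails never span half the box in z)
            for ax in (0, 1):
                v[:, ax] -= frame.box[ax] * np.round(v[:, ax] / frame.box[ax])
            cos = v[:, 2] / np.linalg.norm(v, axis=1)
            sums[j] += np.sum(1.5 * cos**2 - 0.5)
        count += len(mol_ids)
    if count == 0:
        raise AnalysisError("no lipids matched the order-parameter selection")
    return OrderProfile(sums / count, bonds, leaflet=leaflet, n_samples=count)


def density_profile(
    traj: Trajectory,
    group_specs: dict[str, SelectionSpec],
    bin_width: float = 0.1,
    bead_mass: float = 72.0,
) -> pd.DataFrame:
    """Frame-averaged partial mass density vs z (amu/nm^3), membrane COM
    recentred to z = 0 each frame to remove drift."""
    if bin_width <= 0:
        raise InputError("bin_width must be positive")
    lz = max(fr.box[2] for fr in traj.frames)
    nbins = int(np.ceil(lz / bin_width))
    edges = -lz / 2.0 + bin_width * np.arange(nbins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    out = {name: np.zeros(nbins) for name in group_specs}
    for frame in traj.frames:
        com_z = float(np.mean(frame.positions[:, 2]))
        vol = frame.box[0] * frame.box[1] * bin_width
        for name, spec in group_specs.items():
            idx = select(frame, spec)
            if len(idx) == 0:
                continue
            z = frame.positions[idx, 2] - com_z
            counts, _ = np.histogram(z, bins=edges)
            out[name] += counts * bead_mass / vol
    n = len(traj.frames)
    data = {"z_nm": centers}
    data.update({name: vals / n for name, vals in out.items()})
    return pd.DataFrame(data)


def _defect_mask(
    frame: BeadFrame,
    leaflet: str,
    grid_step: float,
    z_depth: float,
    bead_radius: float,
    head_beads: frozenset[str],
) -> tuple[np.ndarray, float]:
    """Boolean defect-cell mask on the xy grid, and the cell area in Å^2."""
    from .peptide import assign_leaflets

    labels = assign_leaflets(frame)
    direction = 1.0 if leaflet == "upper" else -1.0
    lipid_mask = np.array(
        [labels.get(int(m)) == leaflet for m in frame.molecule_ids]
    )
    if not np.any(lipid_mask):
        raise InputError(f"frame has no lipids on the {leaflet} leaflet")
    names = frame.bead_names.astype(str)
    po4 = lipid_mask & (names == "PO4")
    # signed height: larger s = closer to this leaflet's solvent
    s_all = direction * frame.positions[:, 2]
    s_cut = float(np.mean(s_all[po4])) - z_depth

    lx, ly = frame.box[0], frame.box[1]
    nx = max(1, int(round(lx / grid_step)))
    ny = max(1, int(round(ly / grid_step)))
    step_x, step_y = lx / nx, ly / ny

    covered_above = np.zeros((nx, ny), dtype=bool)
    below_s = np.full((nx, ny), -np.inf)
    below_is_tail = np.zeros((nx, ny), dtype=bool)

    rx = int(np.ceil(bead_radius / step_x))
    ry = int(np.ceil(bead_radius / step_y))
    ox, oy = np.meshgrid(np.arange(-rx, rx + 1), np.arange(-ry, ry + 1), indexing="ij")
    ox, oy = ox.ravel(), oy.ravel()

    idx = np.flatnonzero(lipid_mask)
    order = np.argsort(s_all[idx])  # process bottom-up so ties resolve to topmost
    for i in idx[order]:
        x, y = frame.positions[i, 0], frame.positions[i, 1]
        ci = int(np.floor(x / step_x))
        cj = int(np.floor(y / step_y))
        cxs = (ci + ox) % nx
        cys = (cj + oy) % ny
        # distance from each candidate cell center to the bead axis (min image)
        dx = (cxs + 0.5) * step_x - x
        dy = (cys + 0.5) * step_y - y
        dx -= lx * np.round(dx / lx)
        dy -= ly * np.round(dy / ly)
        hit = dx**2 + dy**2 <= bead_radius**2
        if not np.any(hit):
            continue
        hx, hy = cxs[hit], cys[hit]
        s = s_all[i]
        if s >= s_cut:
            covered_above[hx, hy] = True
        else:
            newer = s >= below_s[hx, hy]
            tail = names[i] not in head_beads
            below_s[hx[newer], hy[newer]] = s
            below_is_tail[hx[newer], hy[newer]] = tail
    void = ~np.isfinite(below_s) | (below_s == -np.inf)
    defect = ~covered_above & (void | below_is_tail)
    return defect, step_x * step_y * A2_PER_NM2


def detect_defects(
    frame: BeadFrame,
    leaflet: str = "upper",
    grid_step: float = 0.1,
    z_depth: float = 0.1,
    connectivity: int = 4,
    bead_radius: float = 0.26,
    head_beads: frozenset[str] = HEAD_BEADS,
) -> np.ndarray:
    """Packing-defect areas (Å^2) of one leaflet of one frame.

    Defect cells are merged with 4- (or 8-) connectivity, periodically in
    both lateral directions.
    """
    if connectivity not in (4, 8):
        raise InputError("connectivity must be 4 or 8")
    mask, cell_area = _defect_mask(frame, leaflet, grid_step, z_depth, bead_radius, head_beads)
    if not np.any(mask):
        return np.array([])
    structure = (
        np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]]) if connectivity == 4 else np.ones((3, 3))
    )
    labels, nlab = ndimage.label(mask, structure=structure)
    # merge components across the periodic boundaries (union-find)
    parent = np.arange(nlab + 1)

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra

    for a, b in zip(labels[0, :], labels[-1, :]):
        if a and b:
            union(a, b)
    for a, b in zip(labels[:, 0], labels[:, -1]):
        if a and b:
            union(a, b)
    roots = np.array([find(l) for l in range(nlab + 1)])
    merged = roots[labels]
    ids, counts = np.unique(merged[merged > 0], return_counts=True)
    return counts * cell_area


def defect_constant(areas: np.ndarray, a_min: float = 15.0) -> tuple[float, float]:
    """Exponential defect-area constant π (Å^2) by tail maximum likelihood.

    For A >= a_min, P(A) ∝ exp(-A/π), so the MLE is π = mean(A - a_min) and
    its CI is π/sqrt(n).  By memorylessness the estimate is a_min-invariant
    for truly exponential data.  All-equal areas are a degenerate fit:
    a warning is emitted and π = 0 is returned with CI 0.
    """
    areas = np.asarray(areas, dtype=float)
    tail = areas[areas >= a_min] - a_min
    if len(tail) < 50:
        raise AnalysisError(
            f"insufficient data: {len(tail)} areas >= {a_min} Å² (need >= 50)"
        )
    if np.ptp(tail) == 0.0:
        warnings.warn("degenerate defect-area fit: all areas equal", stacklevel=2)
        return 0.0, 0.0
    pi = float(np.mean(tail))
    return pi, pi / np.sqrt(len(tail))


def defect_constant_loglinear(
    areas: np.ndarray, a_min: float = 15.0, bin_width: float = 5.0
) -> tuple[float, float]:
    """Cross-check fit: least squares of log counts vs bin center; returns
    (π, standard error of π)."""
    areas = np.asarray(areas, dtype=float)
    tail = areas[areas >= a_min]
    if len(tail) < 50:
        raise AnalysisError("insufficient data for the log-linear cross-check")
    nbins = max(3, int(np.ceil((tail.max() - a_min) / bin_width)))
    counts, edges = np.histogram(tail, bins=nbins, range=(a_min, a_min + nbins * bin_width))
    centers = 0.5 * (edges[:-1] + edges[1:])
    keep = counts > 0
    if keep.sum() < 3:
        raise AnalysisError("too few occupied bins for the log-linear cross-check")
    x, y = centers[keep], np.log(counts[keep])
    n = len(x)
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    se_slope = np.sqrt(np.sum(resid**2) / max(n - 2, 1) / np.sum((x - x.mean()) ** 2))
    if slope >= 0:
        raise AnalysisError("log-linear fit slope is non-negative; tail is not exponential")
    pi = -1.0 / slope
    return float(pi), float(se_slope * pi**2)


def local_maps(
    traj: Trajectory,
    peptide_spec: SelectionSpec,
    radial_edges: np.ndarray,
    tail_bead_names: tuple[str, ...] = ("C1A", "C2A", "C3A"),
) -> pd.DataFrame:
    """Local membrane thickness and tail order vs lateral distance from the
    peptide COM (xy minimum image), averaged over frames.

    Thickness is the difference of local mean phosphate z between the two
    leaflets per radial bin; empty bins are NaN-flagged, never interpolated.
    """
    from .peptide import assign_leaflets

    radial_edges = np.asarray(radial_edges, dtype=float)
    nb = len(radial_edges) - 1
    sum_up = np.zeros(nb)
    sum_lo = np.zeros(nb)
    cnt_up = np.zeros(nb)
    cnt_lo = np.zeros(nb)
    scc_sum = np.zeros(nb)
    scc_cnt = np.zeros(nb)
    bonds = list(zip(tail_bead_names[:-1], tail_bead_names[1:]))
    for frame in traj.frames:
        pep = select(frame, peptide_spec)
        if len(pep) == 0:
            raise InputError("peptide selection is empty")
        com = frame.positions[pep].mean(axis=0)
        labels = assign_leaflets(frame)
        names = frame.bead_names.astype(str)
        po4 = np.flatnonzero(names == "PO4")
        dx = frame.positions[po4, 0] - com[0]
        dy = frame.positions[po4, 1] - com[1]
        dx -= frame.box[0] * np.round(dx / frame.box[0])
        dy -= frame.box[1] * np.round(dy / frame.box[1])
        r = np.sqrt(dx**2 + dy**2)
        which = np.digitize(r, radial_edges) - 1
        leaf = np.array([labels.get(int(m)) for m in frame.molecule_ids[po4]])
        for b in range(nb):
            in_bin = which == b
            up = in_bin & (leaf == "upper")
            lo = in_bin & (leaf == "lower")
            sum_up[b] += frame.positions[po4[up], 2].sum()
            cnt_up[b] += up.sum()
            sum_lo[b] += frame.positions[po4[lo], 2].sum()
            cnt_lo[b] += lo.sum()
        # local order: lipids whose phosphate falls in the bin
        for b in range(nb):
            mols = np.unique(frame.molecule_ids[po4[which == b]])
            if len(mols) == 0:
                continue
            try:
                per_bead = {bn: _lipid_bead_positions(frame, bn, mols) for bn in tail_bead_names}
            except StructuralError:
                continue
            for b1, b2 in bonds:
                v = per_bead[b2] - per_bead[b1]
                cos = v[:, 2] / np.linalg.norm(v, axis=1)
                scc_sum[b] += np.sum(1.5 * cos**2 - 0.5)
                scc_cnt[b] += len(mols)
    with np.errstate(invalid="ignore", divide="ignore"):
        thickness = sum_up / cnt_up - sum_lo / cnt_lo
        scc = scc_sum / scc_cnt
    return pd.DataFrame(
        {
            "r_nm": 0.5 * (radial_edges[:-1] + radial_edges[1:]),
            "thickness_nm": thickness,
            "s_cc": scc,
            "n_phosphates": cnt_up + cnt_lo,
        }
    )
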