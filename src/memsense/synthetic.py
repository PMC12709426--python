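"""Synthetic coarse-grained bilayer/peptide systems with known ground truth.

Every downstream stage (surface fitting, depth, PMF post-processing, defect
statistics, curvature reweighting) can be exercised on the outputs of this
module without any external data.  Generators emulate:

* planar bilayers — two jittered phosphate lattices with choline and tail
  beads, box area set by the target area per lipid;
* quasi-1D buckled bilayers — both leaflets displaced by a single-mode
  sinusoid h(x) = A sin(2*pi*x/lambda), whose mean curvature is known in
  closed form and whose Gaussian curvature is identically zero;
* peptide placements at prescribed depth and tilt on either leaflet;
* curvature-biased surface positions with density proportional to
  dA * exp(a*H), the test harness for the reweighting stage;
* smooth 2D free-energy surfaces with programmed adsorbed/transmembrane
  minima and barrier;
* exponential packing-defect area samples.

All generators are deterministic under a fixed seed, and each attaches the
parameters needed to predict the downstream estimate in closed form.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from .errors import ParameterError
from .io import BeadFrame, Trajectory
from .pmf import FES2D
from .props import DefectSizeSample

__all__ = [
    "SyntheticBilayerParams",
    "true_mean_curvature",
    "gen_planar_bilayer",
    "gen_buckled_bilayer",
    "place_peptide",
    "gen_peptide_trajectory",
    "sample_biased_positions",
    "gen_fes2d",
    "gen_defect_areas",
]

A2_PER_NM2 = 100.0  # 1 nm^2 = 100 Å^2


@dataclass
class SyntheticBilayerParams:
    """Geometry and noise parameters of a generated bilayer.

    target_apl is in Å^2 (the reporting unit for areas); all lengths in nm.
    A buckle is a single sine mode along x with amplitude A and wavelength
    lambda; lambda defaults to the box length Lx so the surface stays
    box-periodic.  Thermal roughness is modelled as independent Gaussian
    jitter: per-lipid in xy, per-bead in z.
    """

    n_per_leaflet: int = 92
    target_apl: float = 65.0  # Å^2
    thickness: float = 4.0  # nm, phosphate-plane separation
    jitter_xy: float = 0.0  # nm sd
    jitter_z: float = 0.0  # nm sd
    buckle_amplitude: float = 0.0  # nm
    buckle_wavelength: float | None = None  # nm; None -> Lx
    lipid_name: str = "POPC"
    n_tail_beads: int = 3
    n_frames: int = 1
    frame_interval: float = 400.0  # ps
    solvent_margin: float = 3.0  # nm of empty space per side along z
    thinning_amplitude: float = 0.0  # nm total thickness reduction at box center
    thinning_sigma: float = 1.0  # nm
    seed: int = 0

    def __post_init__(self):
        if self.n_per_leaflet < 1:
            raise ParameterError("n_per_leaflet must be >= 1")
        if self.target_apl <= 0:
            raise ParameterError("target_apl must be positive")
        if self.thickness <= 0:
            raise ParameterError("thickness must be positive")
        if self.buckle_amplitude < 0:
            raise ParameterError("buckle amplitude must be >= 0")
        if self.buckle_wavelength is not None and self.buckle_wavelength <= 0:
            raise ParameterError("buckle wavelength must be positive")

    def lattice(self) -> tuple[int, int, float, float]:
        """(nx, ny, Lx, Ly): lattice shape and lateral box lengths.

        Lx*Ly / n_per_leaflet equals target_apl exactly.  If a buckle
        wavelength is given it pins Lx = lambda (one full period per box).
        """
        area_nm2 = self.n_per_leaflet * self.target_apl / A2_PER_NM2
        if self.buckle_wavelength is not None:
            lx = float(self.buckle_wavelength)
            ly = area_nm2 / lx
        else:
            lx = ly = float(np.sqrt(area_nm2))
        nx = max(1, int(np.round(np.sqrt(self.n_per_leaflet * lx / ly))))
        ny = int(np.ceil(self.n_per_leaflet / nx))
        return nx, ny, lx, ly


def true_mean_curvature(x, amplitude: float, wavelength: float, leaflet: str = "upper"):
    """Closed-form Monge-gauge mean curvature of h(x) = A sin(2*pi*x/lambda).

    H(x) = -A k^2 sin(kx) / (2 (1 + A^2 k^2 cos^2(kx))^{3/2}), k = 2*pi/lambda,
    negated for the lower leaflet (shared sign convention with the fitter).
    """
    k = 2.0 * np.pi / wavelength
    kx = k * np.asarray(x, dtype=float)
    h = -amplitude * k**2 * np.sin(kx) / (2.0 * (1.0 + amplitude**2 * k**2 * np.cos(kx) ** 2) ** 1.5)
    return -h if leaflet == "lower" else h


def _build_frame(params: SyntheticBilayerParams, rng: np.random.Generator, time: float) -> BeadFrame:
    nx, ny, lx, ly = params.lattice()
    n = params.n_per_leaflet
    lz = params.thickness + 2.0 * (params.solvent_margin + 1.0)
    zc = lz / 2.0

    sites = np.arange(nx * ny)[:n]
    sx = (sites % nx + 0.5) * lx / nx
    sy = (sites // nx + 0.5) * ly / ny

    amp = params.buckle_amplitude
    lam = params.buckle_wavelength if params.buckle_wavelength is not None else lx
    if amp > 0 and amp >= lam / 4.0:
        raise ParameterError(f"buckle amplitude {amp} must be < wavelength/4 = {lam / 4.0}")

    positions, mol_ids, mol_names, bead_names = [], [], [], []
    mol_id = 0
    beads_per_lipid = 2 + params.n_tail_beads
    for leaflet, direction in (("upper", +1.0), ("lower", -1.0)):
        jx = rng.normal(0.0, params.jitter_xy, n) if params.jitter_xy > 0 else np.zeros(n)
        jy = rng.normal(0.0, params.jitter_xy, n) if params.jitter_xy > 0 else np.zeros(n)
        x = np.mod(sx + jx, lx)
        y = np.mod(sy + jy, ly)
        buckle = amp * np.sin(2.0 * np.pi * x / lam)
        half = params.thickness / 2.0
        if params.thinning_amplitude != 0.0:
            r2 = (x - lx / 2.0) ** 2 + (y - ly / 2.0) ** 2
            half = half - 0.5 * params.thinning_amplitude * np.exp(
                -r2 / (2.0 * params.thinning_sigma**2)
            )
        z_head = zc + buckle + direction * np.broadcast_to(half, x.shape)
        z_mid = zc + buckle
        for i in range(n):
            mol_id += 1
            jz = (
                rng.normal(0.0, params.jitter_z, beads_per_lipid)
                if params.jitter_z > 0
                else np.zeros(beads_per_lipid)
            )
            zh = float(z_head[i])
            # choline sits 0.3 nm outward of the phosphate
            positions.append([x[i], y[i], zh + direction * 0.3 + jz[0]])
            bead_names.append("NC3")
            positions.append([x[i], y[i], zh + jz[1]])
            bead_names.append("PO4")
            for t in range(params.n_tail_beads):
                frac = (t + 1.0) / (params.n_tail_beads + 1.0)
                zt = zh + frac * (float(z_mid[i]) - zh)
                positions.append([x[i], y[i], zt + jz[2 + t]])
                bead_names.append(f"C{t + 1}A")
            mol_ids.extend([mol_id] * beads_per_lipid)
            mol_names.extend([params.lipid_name] * beads_per_lipid)

    frame = BeadFrame(
        np.asarray(positions),
        np.array([lx, ly, lz]),
        np.asarray(mol_ids),
        np.asarray(mol_names, dtype=object),
        np.asarray(bead_names, dtype=object),
        time=time,
    )
    return frame.wrapped()


def _ground_truth(params: SyntheticBilayerParams) -> dict:
    nx, ny, lx, ly = params.lattice()
    lam = params.buckle_wavelength if params.buckle_wavelength is not None else lx
    return {
        "kind": "bilayer",
        "params": dataclasses.asdict(params),
        "box_xy": [lx, ly],
        "apl": params.target_apl,
        "thickness": params.thickness,
        "buckle_amplitude": params.buckle_amplitude,
        "buckle_wavelength": lam,
        "gaussian_curvature": 0.0,
    }


def gen_planar_bilayer(params: SyntheticBilayerParams) -> Trajectory:
    """Flat bilayer: phosphate lattices at z = center +/- thickness/2 with
    optional jitter; box area fixed by the target area per lipid."""
    planar = dataclasses.replace(params, buckle_amplitude=0.0)
    rng = np.random.default_rng(planar.seed)
    frames = [
        _build_frame(planar, rng, time=i * planar.frame_interval) for i in range(planar.n_frames)
    ]
    return Trajectory(frames, ground_truth=_ground_truth(planar))


def gen_buckled_bilayer(params: SyntheticBilayerParams) -> Trajectory:
    """Buckled bilayer: both leaflets ride h(x) = A sin(2*pi*x/lambda).

    With A = 0 this is bit-identical to :func:`gen_planar_bilayer` under the
    same seed.  Requires A < lambda/4 (gentle, single-valued buckle).
    """
    nx, ny, lx, ly = params.lattice()
    lam = params.buckle_wavelength if params.buckle_wavelength is not None else lx
    if params.buckle_amplitude >= lam / 4.0:
        raise ParameterError(
            f"buckle amplitude {params.buckle_amplitude} nm must be < lambda/4 = {lam / 4.0} nm"
        )
    rng = np.random.default_rng(params.seed)
    frames = [
        _build_frame(params, rng, time=i * params.frame_interval) for i in range(params.n_frames)
    ]
    return Trajectory(frames, ground_truth=_ground_truth(params))


def place_peptide(
    frame: BeadFrame,
    leaflet: str,
    depth: float,
    tilt: float,
    n_backbone: int = 21,
    center_xy: tuple[float, float] | None = None,
    spacing: float = 0.35,
    peptide_name: str = "PEP",
) -> BeadFrame:
    """Append a model peptide (collinear backbone beads) to a frame.

    The peptide COM sits exactly ``depth`` nm below the local phosphate
    plane of ``leaflet`` (toward the membrane core; the plane is the mean z
    of that leaflet's phosphates within a 1 nm cylinder around the lateral
    placement point), with its axis tilted ``tilt`` degrees from +z in the
    xz plane.  Helical geometry is irrelevant to COM/tilt observables and
    is not modelled.
    """
    if leaflet not in ("upper", "lower"):
        raise ParameterError("leaflet must be 'upper' or 'lower'")
    from .peptide import assign_leaflets

    lx, ly, lz = frame.box
    x0, y0 = center_xy if center_xy is not None else (lx / 2.0, ly / 2.0)
    labels = assign_leaflets(frame)
    is_po4 = frame.bead_names.astype(str) == "PO4"
    in_leaflet = np.array([labels.get(int(m)) == leaflet for m in frame.molecule_ids])
    sel = is_po4 & in_leaflet
    if not np.any(sel):
        raise ParameterError(f"frame has no phosphates on the {leaflet} leaflet")
    pos = frame.positions[sel]
    dx = pos[:, 0] - x0
    dy = pos[:, 1] - y0
    dx -= lx * np.round(dx / lx)
    dy -= ly * np.round(dy / ly)
    near = dx**2 + dy**2 <= 1.0**2
    plane_z = float(np.mean(pos[near, 2])) if np.any(near) else float(np.mean(pos[:, 2]))
    direction = 1.0 if leaflet == "upper" else -1.0
    com_z = plane_z - direction * depth  # positive depth -> toward the core

    tilt_rad = np.radians(tilt)
    axis = np.array([np.sin(tilt_rad), 0.0, np.cos(tilt_rad)])
    offsets = (np.arange(n_backbone) - (n_backbone - 1) / 2.0) * spacing
    bead_pos = np.array([x0, y0, com_z]) + offsets[:, None] * axis[None, :]
    if np.any(bead_pos[:, 2] < 0) or np.any(bead_pos[:, 2] > lz):
        raise ParameterError("peptide would exit the box along z")
    bead_pos[:, 0] = np.mod(bead_pos[:, 0], lx)
    bead_pos[:, 1] = np.mod(bead_pos[:, 1], ly)

    pep_id = int(np.max(frame.molecule_ids)) + 1
    return BeadFrame(
        np.vstack([frame.positions, bead_pos]),
        frame.box.copy(),
        np.concatenate([frame.molecule_ids, np.full(n_backbone, pep_id)]),
        np.concatenate([frame.molecule_names, np.full(n_backbone, peptide_name, dtype=object)]),
        np.concatenate([frame.bead_names, np.full(n_backbone, "BB", dtype=object)]),
        time=frame.time,
    )


def gen_peptide_trajectory(
    params: SyntheticBilayerParams,
    leaflet: str = "upper",
    depth_mean: float = 0.3,
    depth_sd: float = 0.0,
    tilt: float = 90.0,
    n_frames: int | None = None,
    seed: int | None = None,
) -> Trajectory:
    """Bilayer + peptide trajectory with per-frame depth drawn from
    N(depth_mean, depth_sd^2); the generating depths are recorded as ground
    truth for the insertion-depth stage."""
    n_frames = params.n_frames if n_frames is None else n_frames
    seed = params.seed if seed is None else seed
    base = dataclasses.replace(params, n_frames=n_frames, seed=seed)
    membrane = (
        gen_buckled_bilayer(base) if base.buckle_amplitude > 0 else gen_planar_bilayer(base)
    )
    rng = np.random.default_rng(np.random.SeedSequence([seed, 7]))
    depths = (
        rng.normal(depth_mean, depth_sd, n_frames) if depth_sd > 0 else np.full(n_frames, depth_mean)
    )
    frames = [
        place_peptide(fr, leaflet, float(depths[i]), tilt) for i, fr in enumerate(membrane.frames)
    ]
    gt = dict(membrane.ground_truth)
    gt.update(
        {
            "peptide_leaflet": leaflet,
            "depth_mean": depth_mean,
            "depth_sd": depth_sd,
            "tilt": tilt,
            "frame_depths": depths.tolist(),
        }
    )
    return Trajectory(frames, ground_truth=gt)


def sample_biased_positions(
    surface_params: dict,
    bias: float,
    n: int,
    seed: int = 0,
) -> tuple[np.ndarray, dict]:
    """(x, y) samples over a buckled surface with density proportional to
    dA * exp(bias * H), by rejection sampling.

    ``surface_params`` needs 'amplitude', 'wavelength' and 'box_xy'
    (as produced by the bilayer generators' ground truth).  ``bias`` has
    units of nm (it multiplies a curvature).  Returns the samples and a
    ground-truth record carrying the bias coefficient.
    """
    if n < 1:
        raise ParameterError("need n >= 1 samples")
    amp = float(surface_params["amplitude"] if "amplitude" in surface_params
                else surface_params["buckle_amplitude"])
    lam = float(surface_params.get("wavelength") or surface_params["buckle_wavelength"])
    lx, ly = surface_params["box_xy"]
    rng = np.random.default_rng(seed)
    k = 2.0 * np.pi / lam

    def density(x):
        hx = amp * k * np.cos(k * x)
        area = np.sqrt(1.0 + hx**2)
        H = true_mean_curvature(x, amp, lam, "upper")
        return area * np.exp(bias * H)

    grid = np.linspace(0.0, lx, 4096, endpoint=False)
    dmax = float(np.max(density(grid))) * 1.0001

    out = np.empty((n, 2))
    filled = 0
    while filled < n:
        m = max(2 * (n - filled), 1024)
        x = rng.uniform(0.0, lx, m)
        u = rng.uniform(0.0, dmax, m)
        keep = x[u < density(x)]
        take = min(len(keep), n - filled)
        out[filled : filled + take, 0] = keep[:take]
        filled += take
    out[:, 1] = rng.uniform(0.0, ly, n)
    truth = {"bias": bias, "amplitude": amp, "wavelength": lam, "box_xy": [lx, ly]}
    return out, truth


def _bump(u: np.ndarray) -> np.ndarray:
    """C1 compact bump: cos^2(pi u / 2) on |u| <= 1, zero outside."""
    u = np.asarray(u, dtype=float)
    out = np.zeros_like(u)
    inside = np.abs(u) <= 1.0
    out[inside] = np.cos(np.pi * u[inside] / 2.0) ** 2
    return out


def gen_fes2d(
    ddg: float,
    barrier: float,
    cv1_range: tuple[float, float] = (-3.0, 3.0),
    cv2_grid: np.ndarray | None = None,
    temperature: float = 310.0,
    n_cv1: int = 241,
    well_center: float = 1.8,
    well_width: float = 0.6,
    tilt_k: float = 0.002,  # kJ/mol/deg^2
    asymmetry: float = 0.0,  # kJ/mol added to the upper-leaflet adsorbed well
) -> FES2D:
    """Smooth double-well free-energy surface with programmed ΔΔG and barrier.

    The 1D marginal is specified first as a plateau at ``barrier`` carved by
    compact cosine-squared wells: adsorbed wells at cv1 = ±well_center with
    minimum 0 (the +side raised by ``asymmetry``), a transmembrane well at
    cv1 = 0 with minimum ``ddg``.  Because the wells have disjoint support
    the programmed state free energies are exact, and the added harmonic
    cv2 term is cv1-independent, so Boltzmann marginalization shifts the
    whole profile by an exact constant: the recovered ΔΔG equals ``ddg`` to
    quadrature accuracy.
    """
    if barrier < max(0.0, ddg):
        raise ParameterError("barrier must be >= max(0, ddg)")
    if cv2_grid is None:
        cv2_grid = np.linspace(0.0, 180.0, 91)
    cv1 = np.linspace(cv1_range[0], cv1_range[1], n_cv1)
    w, za = well_width, well_center
    g = (
        barrier
        - barrier * _bump((cv1 + za) / w)
        - (barrier - asymmetry) * _bump((cv1 - za) / w)
        - (barrier - ddg) * _bump(cv1 / w)
    )
    values = g[:, None] + 0.5 * tilt_k * (np.asarray(cv2_grid) - 90.0) ** 2
    fes = FES2D(cv1, np.asarray(cv2_grid, dtype=float), values, temperature)
    fes.metadata.update(
        {
            "synthetic": True,
            "ddg": ddg,
            "barrier": barrier,
            "well_center": za,
            "well_width": w,
            "tilt_k": tilt_k,
            "asymmetry": asymmetry,
        }
    )
    return fes


def gen_defect_areas(
    pi_const: float, n: int, seed: int = 0, a_min: float = 0.0
) -> DefectSizeSample:
    """Exponential defect-area samples: a_min + Exp(mean = pi_const), in Å^2.

    By memorylessness the tail fit recovers pi_const for any fit threshold
    at or above a_min.
    """
    if pi_const <= 0:
        raise ParameterError("pi_const must be positive")
    if n < 1:
        raise ParameterError("need n >= 1 samples")
    rng = np.random.default_rng(seed)
    areas = a_min + rng.exponential(pi_const, n)
    return DefectSizeSample(
        areas=areas,
        params={"generator": "exponential", "a_min": a_min},
        ground_truth={"pi": pi_const, "a_min": a_min},
    )
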