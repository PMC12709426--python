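"""Monge-gauge membrane surface reconstruction and curvature.

The leaflet surface is a single-valued, box-periodic height field h(x, y)
expanded in a truncated real 2D Fourier series

    h(x, y) = sum_{i,j} c_ij * phi_i(x) * psi_j(y),

with phi the tensor basis {1, cos(2*pi*m*x/Lx), sin(2*pi*m*x/Lx)} up to mode
cutoff Mx (and likewise in y).  Coefficients are fitted to phosphate bead
positions by linear least squares; all derivatives — and hence mean,
Gaussian and principal curvatures — follow analytically.

Sign convention: for the upper leaflet the Monge-gauge mean curvature is
reported as-is (height measured along +z); for the lower leaflet H is
negated, so that for both leaflets the sign of H at the peptide's position
is comparable across leaflets of a buckled bilayer.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .distributions import CurvatureDistribution
from .errors import FitError, ParameterError

__all__ = [
    "SurfaceModel",
    "CurvaturePoint",
    "fit_surface",
    "curvature_at",
    "curvature_field",
    "accessible_curvature",
]

_TWO_PI = 2.0 * np.pi


def _basis_1d(u: np.ndarray, L: float, M: int, deriv: int = 0) -> np.ndarray:
    """Value (deriv=0) or x-derivative of given order of the 1D basis
    [1, cos(k u), sin(k u), cos(2k u), sin(2k u), ...], shape (len(u), 2M+1)."""
    u = np.atleast_1d(np.asarray(u, dtype=float))
    out = np.empty((len(u), 2 * M + 1))
    out[:, 0] = 1.0 if deriv == 0 else 0.0
    for m in range(1, M + 1):
        k = _TWO_PI * m / L
        ku = k * u
        c, s = np.cos(ku), np.sin(ku)
        if deriv == 0:
            fc, fs = c, s
        elif deriv == 1:
            fc, fs = -k * s, k * c
        elif deriv == 2:
            fc, fs = -(k**2) * c, -(k**2) * s
        else:  # pragma: no cover - not used beyond 2nd order
            raise ValueError("derivative order > 2 not supported")
        out[:, 2 * m - 1] = fc
        out[:, 2 * m] = fs
    return out


@dataclass
class SurfaceModel:
    """Fitted periodic height field for one leaflet of one frame."""

    box: tuple[float, float]  # (Lx, Ly) nm
    modes: tuple[int, int]  # (Mx, My)
    coefficients: np.ndarray  # (2Mx+1, 2My+1)
    residual_rms: float = 0.0  # nm
    leaflet: str = "upper"
    time: float = 0.0

    def __post_init__(self):
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        mx, my = self.modes
        expected = (2 * mx + 1, 2 * my + 1)
        if self.coefficients.shape != expected:
            raise ParameterError(
                f"coefficient array must have shape {expected}, got {self.coefficients.shape}"
            )
        if self.residual_rms < 0:
            raise ParameterError("residual RMS must be >= 0")

    # -- evaluation ---------------------------------------------------------

    def _eval(self, x, y, dx: int = 0, dy: int = 0) -> np.ndarray:
        bx = _basis_1d(x, self.box[0], self.modes[0], deriv=dx)
        by = _basis_1d(y, self.box[1], self.modes[1], deriv=dy)
        return np.einsum("ni,ij,nj->n", bx, self.coefficients, by)

    def height(self, x, y) -> np.ndarray:
        return self._eval(x, y)

    def gradient(self, x, y) -> tuple[np.ndarray, np.ndarray]:
        return self._eval(x, y, dx=1), self._eval(x, y, dy=1)

    def hessian(self, x, y) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return (
            self._eval(x, y, dx=2),
            self._eval(x, y, dx=1, dy=1),
            self._eval(x, y, dy=2),
        )

    # -- serialization ------------------------------------------------------

    def to_json(self, path: str | Path) -> None:
        data = {
            "box": list(self.box),
            "modes": list(self.modes),
            "coefficients": self.coefficients.tolist(),
            "residual_rms": self.residual_rms,
            "leaflet": self.leaflet,
            "time": self.time,
        }
        with open(path, "w") as fh:
            json.dump(data, fh)

    @classmethod
    def from_json(cls, path: str | Path) -> "SurfaceModel":
        with open(path) as fh:
            data = json.load(fh)
        return cls(
            box=tuple(data["box"]),
            modes=tuple(data["modes"]),
            coefficients=np.asarray(data["coefficients"]),
            residual_rms=data["residual_rms"],
            leaflet=data["leaflet"],
            time=data["time"],
        )


@dataclass(frozen=True)
class CurvaturePoint:
    """Curvature of the fitted surface at one (x, y) point.

    H and K in nm^-1 / nm^-2; k1 >= k2 are the principal curvatures and
    area_element = sqrt(1 + |grad h|^2) >= 1 the surface measure density.
    """

    position: tuple[float, float]
    H: float
    K: float
    k1: float
    k2: float
    area_element: float


def fit_surface(
    points: np.ndarray,
    box: tuple[float, float],
    mx: int,
    my: int,
    leaflet: str = "upper",
    time: float = 0.0,
) -> SurfaceModel:
    """Least-squares fit of the truncated Fourier height field to bead
    positions (x, y, z) in nm.

    Raises :class:`FitError` when the system is underdetermined (fewer points
    than coefficients) or the design matrix is rank-deficient (e.g. all beads
    on one lattice line), reporting the condition number in the latter case.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ParameterError("points must be an (n, 3) array")
    ncoef = (2 * mx + 1) * (2 * my + 1)
    n = pts.shape[0]
    if n < ncoef:
        raise FitError(
            f"underdetermined fit: {n} points for {ncoef} coefficients (Mx={mx}, My={my})"
        )
    bx = _basis_1d(pts[:, 0], box[0], mx)
    by = _basis_1d(pts[:, 1], box[1], my)
    design = np.einsum("ni,nj->nij", bx, by).reshape(n, ncoef)
    coef, _, rank, sing = np.linalg.lstsq(design, pts[:, 2], rcond=None)
    if rank < ncoef:
        cond = sing[0] / sing[-1] if sing[-1] > 0 else np.inf
        raise FitError(
            f"rank-deficient surface fit (rank {rank} < {ncoef}, condition {cond:.3g}); "
            "reduce the mode cutoff or supply better-spread points"
        )
    resid = pts[:, 2] - design @ coef
    model = SurfaceModel(
        box=(float(box[0]), float(box[1])),
        modes=(mx, my),
        coefficients=coef.reshape(2 * mx + 1, 2 * my + 1),
        residual_rms=float(np.sqrt(np.mean(resid**2))),
        leaflet=leaflet,
        time=time,
    )
    return model


def curvature_field(model: SurfaceModel, x, y):
    """Vectorized curvature evaluation: returns (H, K, k1, k2, area_element)
    arrays, with the lower-leaflet sign convention applied to H and the
    principal curvatures."""
    hx, hy = model.gradient(x, y)
    hxx, hxy, hyy = model.hessian(x, y)
    g = 1.0 + hx**2 + hy**2
    H = ((1.0 + hy**2) * hxx - 2.0 * hx * hy * hxy + (1.0 + hx**2) * hyy) / (2.0 * g**1.5)
    K = (hxx * hyy - hxy**2) / g**2
    if model.leaflet == "lower":
        H = -H
    disc = np.maximum(H**2 - K, 0.0)  # clamp fp noise; H^2 >= K analytically
    root = np.sqrt(disc)
    return H, K, H + root, H - root, np.sqrt(g)


def curvature_at(model: SurfaceModel, x: float, y: float) -> CurvaturePoint:
    """Mean, Gaussian and principal curvatures of the surface at (x, y)."""
    H, K, k1, k2, ae = curvature_field(model, [x], [y])
    return CurvaturePoint((float(x), float(y)), float(H[0]), float(K[0]),
                          float(k1[0]), float(k2[0]), float(ae[0]))


def accessible_curvature(
    model: SurfaceModel,
    grid_nx: int,
    grid_ny: int,
    bin_edges: np.ndarray,
) -> CurvatureDistribution:
    """Area-weighted histogram of mean curvature over the surface.

    H is evaluated on a uniform (grid_nx x grid_ny) xy grid and each grid
    point contributes its local area element sqrt(1+|grad h|^2); this is the
    surface-measure distribution of curvature a freely diffusing particle
    could access.  The grid must resolve the highest fitted mode
    (nx >= 4 Mx, ny >= 4 My).
    """
    mx, my = model.modes
    if grid_nx < max(4 * mx, 1) or grid_ny < max(4 * my, 1):
        raise ParameterError(
            f"grid {grid_nx}x{grid_ny} does not resolve modes (Mx={mx}, My={my}); "
            f"need nx >= {4 * mx}, ny >= {4 * my}"
        )
    xs = (np.arange(grid_nx) + 0.5) * model.box[0] / grid_nx
    ys = (np.arange(grid_ny) + 0.5) * model.box[1] / grid_ny
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    H, _, _, _, ae = curvature_field(model, gx.ravel(), gy.ravel())
    return CurvatureDistribution.from_samples(
        H, np.asarray(bin_edges, dtype=float), kind="accessible",
        leaflet=model.leaflet, sample_weights=ae,
    )
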