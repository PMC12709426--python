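"""Free-energy landscape post-processing.

The 2D landscape ΔG(CV1, CV2) — CV1 the signed peptide–membrane COM
z-distance (nm), CV2 the peptide tilt angle (deg) — is an *input* here
(produced upstream by an adaptive-bias sampler); this module turns it into
the 1D reorientation profile and the adsorbed→transmembrane free-energy
gap:

* Boltzmann marginalization of CV2,
      G(CV1) = -RT ln( ∫ exp(-β ΔG(CV1,CV2)) dCV2 / C ),
  computed with the trapezoid rule in log space (log-sum-exp), so that
  arbitrarily offset landscapes are handled exactly;
* symmetrization across the two leaflets with per-bin error estimates from
  the half-difference of the two independent data sets;
* vertical shift so the profile minimum is zero;
* state detection (adsorbed wells, transmembrane well) and ΔΔG;
* Boltzmann inversion of unbiased density profiles as the independent
  cross-check on the biased result.

The normalization constant C only moves the profile by an additive
constant; ΔΔG is invariant to it (and to any global shift), which the test
suite asserts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.special import logsumexp

from .errors import AnalysisError, InputError, ParameterError, StateDetectionError

__all__ = [
    "GAS_CONSTANT",
    "FES2D",
    "PMF1D",
    "read_fes",
    "marginalize_cv2",
    "symmetrize",
    "shift_min_zero",
    "find_states",
    "delta_delta_g",
    "boltzmann_invert",
]

GAS_CONSTANT = 8.314462618e-3  # kJ mol^-1 K^-1


@dataclass
class FES2D:
    """Free energy on a (CV1, CV2) grid; non-finite values mark unvisited bins."""

    cv1: np.ndarray  # nm, strictly increasing
    cv2: np.ndarray  # deg, strictly increasing
    values: np.ndarray  # (n1, n2) kJ/mol
    temperature: float  # K
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.cv1 = np.asarray(self.cv1, dtype=float)
        self.cv2 = np.asarray(self.cv2, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        for name, grid in (("cv1", self.cv1), ("cv2", self.cv2)):
            if grid.ndim != 1 or len(grid) < 2 or not np.all(np.diff(grid) > 0):
                raise InputError(f"{name} grid must be 1D and strictly increasing")
        if self.values.shape != (len(self.cv1), len(self.cv2)):
            raise InputError(
                f"values must have shape ({len(self.cv1)}, {len(self.cv2)}), "
                f"got {self.values.shape}"
            )
        if self.temperature <= 0:
            raise ParameterError("temperature must be positive")

    @property
    def unvisited(self) -> np.ndarray:
        return ~np.isfinite(self.values)


@dataclass
class PMF1D:
    """1D free-energy profile along CV1 with optional state annotations."""

    cv1: np.ndarray  # nm
    G: np.ndarray  # kJ/mol; NaN = unvisited
    temperature: float
    errors: np.ndarray | None = None  # per-bin, kJ/mol
    states: dict = field(default_factory=dict)
    ddg: float | None = None
    barrier: float | None = None

    def __post_init__(self):
        self.cv1 = np.asarray(self.cv1, dtype=float)
        self.G = np.asarray(self.G, dtype=float)
        if self.cv1.ndim != 1 or not np.all(np.diff(self.cv1) > 0):
            raise InputError("cv1 grid must be 1D and strictly increasing")
        if self.G.shape != self.cv1.shape:
            raise InputError("G must match the cv1 grid")
        if self.errors is not None:
            self.errors = np.asarray(self.errors, dtype=float)
            if self.errors.shape != self.cv1.shape:
                raise InputError("errors must match the cv1 grid")

    def to_csv(self, path: str | Path, metadata: dict | None = None) -> None:
        import pandas as pd

        from .io import write_table

        meta = {"temperature_K": self.temperature}
        for label, (z, g) in self.states.items():
            meta[f"state {label}"] = f"cv1={z:.4f} nm, G={g:.4f} kJ/mol"
        if self.ddg is not None:
            meta["delta_delta_G_kJ_per_mol"] = f"{self.ddg:.4f}"
        if self.barrier is not None:
            meta["barrier_kJ_per_mol"] = f"{self.barrier:.4f}"
        meta.update(metadata or {})
        cols = {"cv1_nm": self.cv1, "G_kJ_per_mol": self.G}
        if self.errors is not None:
            cols["error_kJ_per_mol"] = self.errors
        write_table(pd.DataFrame(cols), path, meta)


def read_fes(path: str | Path, temperature: float) -> FES2D:
    """Import a tabulated landscape (columns cv1, cv2, ΔG; '#'/'@' comment
    lines ignored — the layout written by the standard `gmx awh` text dump)."""
    rows = []
    with open(path) as fh:
        for line in fh:
            s = line.strip()
            if not s or s.startswith(("#", "@")):
                continue
            parts = s.replace(",", " ").split()
            if len(parts) < 3:
                raise InputError(f"need at least 3 columns in {path}")
            rows.append([float(parts[0]), float(parts[1]), float(parts[2])])
    if not rows:
        raise InputError(f"no data rows in {path}")
    arr = np.asarray(rows)
    cv1 = np.unique(arr[:, 0])
    cv2 = np.unique(arr[:, 1])
    values = np.full((len(cv1), len(cv2)), np.nan)
    i1 = np.searchsorted(cv1, arr[:, 0])
    i2 = np.searchsorted(cv2, arr[:, 1])
    values[i1, i2] = arr[:, 2]
    return FES2D(cv1, cv2, values, temperature)


def marginalize_cv2(fes: FES2D, C: float | None = None) -> PMF1D:
    """Boltzmann-average CV2 out of the 2D landscape (unshifted result).

    C defaults to the CV2 integration range, making the argument of the
    logarithm dimensionless; since ΔΔG is C-invariant this choice is
    cosmetic.  Unvisited bins at the CV2 edges of a column are excluded
    with a warning; unvisited bins in the interior are an error because the
    trapezoid integral over the column would be meaningless.
    """
    RT = GAS_CONSTANT * fes.temperature
    if C is None:
        C = float(fes.cv2[-1] - fes.cv2[0])
    if C <= 0:
        raise ParameterError("normalization constant C must be positive")
    G1 = np.empty(len(fes.cv1))
    warned = False
    for i, z in enumerate(fes.cv1):
        col = fes.values[i]
        finite = np.isfinite(col)
        if not np.any(finite):
            raise AnalysisError(f"all CV2 bins unvisited at cv1 = {z:.4f} nm")
        lo, hi = np.flatnonzero(finite)[[0, -1]]
        if not np.all(finite[lo : hi + 1]):
            raise AnalysisError(f"unvisited CV2 bins inside the domain at cv1 = {z:.4f} nm")
        if (lo > 0 or hi < len(col) - 1) and not warned:
            warnings.warn(
                "unvisited CV2 bins at the domain edges were excluded from marginalization",
                stacklevel=2,
            )
            warned = True
        if hi - lo < 1:
            raise AnalysisError(f"fewer than 2 visited CV2 bins at cv1 = {z:.4f} nm")
        grid = fes.cv2[lo : hi + 1]
        vals = col[lo : hi + 1]
        # trapezoid weights
        w = np.empty(len(grid))
        d = np.diff(grid)
        w[0] = d[0] / 2.0
        w[-1] = d[-1] / 2.0
        w[1:-1] = (d[:-1] + d[1:]) / 2.0
        G1[i] = -RT * (logsumexp(-vals / RT, b=w) - np.log(C))
    return PMF1D(fes.cv1.copy(), G1, fes.temperature)


def symmetrize(pmf: PMF1D, interpolate: bool = False, tol: float = 1e-9) -> PMF1D:
    """Average the profile with its mirror image about CV1 = 0.

    The upper- and lower-leaflet halves are independent data sets; the
    per-bin error estimate is their half-difference |G(z) - G(-z)| / 2.
    """
    z, g = pmf.cv1, pmf.G
    if np.max(np.abs(z + z[::-1])) <= tol:
        g_rev = g[::-1]
    elif interpolate:
        zmax = min(-z[0], z[-1])
        n = len(z)
        z = np.linspace(-zmax, zmax, n if n % 2 == 1 else n + 1)
        g = np.interp(z, pmf.cv1, pmf.G)
        g_rev = g[::-1]
    else:
        raise InputError(
            "cv1 grid is not symmetric about 0; pass interpolate=True to resample"
        )
    g_sym = 0.5 * (g + g_rev)
    err = 0.5 * np.abs(g - g_rev)
    return PMF1D(z.copy(), g_sym, pmf.temperature, errors=err)


def shift_min_zero(pmf: PMF1D) -> PMF1D:
    """Vertically shift so the finite minimum of the profile is exactly zero."""
    finite = np.isfinite(pmf.G)
    if not np.any(finite):
        raise InputError("profile has no finite values")
    shift = np.min(pmf.G[finite])
    states = {k: (z, g - shift) for k, (z, g) in pmf.states.items()}
    return PMF1D(
        pmf.cv1.copy(),
        pmf.G - shift,
        pmf.temperature,
        errors=None if pmf.errors is None else pmf.errors.copy(),
        states=states,
        ddg=pmf.ddg,
        barrier=pmf.barrier,
    )


def _local_minima(G: np.ndarray) -> np.ndarray:
    """Indices of strict interior local minima."""
    return (
        np.flatnonzero((G[1:-1] < G[:-2]) & (G[1:-1] < G[2:])) + 1
        if len(G) >= 3
        else np.array([], dtype=int)
    )


def _refine_minimum(z: np.ndarray, G: np.ndarray, i: int) -> tuple[float, float]:
    """Parabolic refinement of a grid minimum over its 3-point neighborhood."""
    if i == 0 or i == len(G) - 1:
        return float(z[i]), float(G[i])
    y0, y1, y2 = G[i - 1], G[i], G[i + 1]
    denom = y0 - 2.0 * y1 + y2
    if denom <= 0:
        return float(z[i]), float(G[i])
    # uniform-spacing vertex offset in units of the grid step
    delta = 0.5 * (y0 - y2) / denom
    step = 0.5 * (z[i + 1] - z[i - 1])
    g_min = y1 - 0.125 * (y0 - y2) ** 2 / denom
    return float(z[i] + delta * step), float(g_min)


def find_states(pmf: PMF1D, tm_z_cut: float = 0.5, ads_z_cut: float = 1.2) -> dict:
    """Locate the transmembrane well (|cv1| <= tm_z_cut) and the adsorbed
    wells (|cv1| >= ads_z_cut) as refined local minima of the profile."""
    z, G = pmf.cv1, pmf.G
    finite = np.isfinite(G)
    if not np.all(finite):
        raise InputError("state detection requires a fully visited profile")
    minima = _local_minima(G)
    states: dict[str, tuple[float, float]] = {}
    tm = [i for i in minima if abs(z[i]) <= tm_z_cut]
    if not tm:
        raise StateDetectionError(
            f"no local minimum inside the transmembrane window |cv1| <= {tm_z_cut} nm "
            "(profile is monotonic there)"
        )
    i_tm = min(tm, key=lambda i: G[i])
    states["transmembrane"] = _refine_minimum(z, G, i_tm)
    for label, side in (("adsorbed_lower", -1), ("adsorbed_upper", +1)):
        cand = [i for i in minima if side * z[i] >= ads_z_cut]
        if cand:
            i_best = min(cand, key=lambda i: G[i])
            states[label] = _refine_minimum(z, G, i_best)
    if not any(k.startswith("adsorbed") for k in states):
        raise StateDetectionError(
            f"no local minimum inside the adsorbed window |cv1| >= {ads_z_cut} nm"
        )
    return states


def delta_delta_g(pmf: PMF1D, tm_z_cut: float = 0.5, ads_z_cut: float = 1.2) -> float:
    """ΔΔG = G(transmembrane minimum) - G(adsorbed global minimum), kJ/mol.

    Positive values mean the adsorbed state is favoured.  Invariant to the
    marginalization constant C and to global shifts of the landscape.
    Annotates the profile's ``states``, ``ddg`` and ``barrier`` fields.
    """
    states = find_states(pmf, tm_z_cut=tm_z_cut, ads_z_cut=ads_z_cut)
    ads = min(
        (v for k, v in states.items() if k.startswith("adsorbed")), key=lambda t: t[1]
    )
    tm = states["transmembrane"]
    ddg = tm[1] - ads[1]
    # barrier: highest point between the two minima, relative to the adsorbed one
    z, G = pmf.cv1, pmf.G
    lo, hi = sorted((ads[0], tm[0]))
    between = (z >= lo) & (z <= hi)
    barrier = float(np.max(G[between]) - ads[1]) if np.any(between) else None
    pmf.states = states
    pmf.ddg = float(ddg)
    pmf.barrier = barrier
    return float(ddg)


def boltzmann_invert(
    density: np.ndarray, cv1: np.ndarray, temperature: float
) -> PMF1D:
    """G = -RT ln(ρ / ρ_max) from an equilibrium density histogram.

    Zero-count bins become NaN (flagged unvisited), never -inf.  The result
    already has min(G) = 0 by construction.
    """
    density = np.asarray(density, dtype=float)
    if np.any(density < 0):
        raise InputError("density must be non-negative")
    rho_max = density.max()
    if rho_max <= 0:
        raise InputError("density is identically zero")
    RT = GAS_CONSTANT * temperature
    with np.errstate(divide="ignore"):
        G = np.where(density > 0, -RT * np.log(density / rho_max), np.nan)
    return PMF1D(np.asarray(cv1, dtype=float), G, temperature)
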