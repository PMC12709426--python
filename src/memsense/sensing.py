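"""Curvature-preference statistics.

A peptide diffusing on a buckled leaflet samples curvatures in proportion
to both its intrinsic preference and the amount of surface available at
each curvature.  The geometric part is removed by dividing the sampled
curvature histogram by the accessible (area-weighted) one and
renormalizing; the reweighted distribution is the peptide's curvature
preference, its weighted mean the "mean sensed curvature".  Agreement
between the two leaflets' distributions (total-variation distance) is the
convergence diagnostic, and the link to insertion depth is quantified by a
Pearson correlation plus two-sample slope tests between membranes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .distributions import CurvatureDistribution
from .errors import AnalysisError, InputError
from .io import AnalysisConfig, SelectionSpec, Trajectory, select
from .surface import curvature_field, fit_surface

__all__ = [
    "CurvatureDistribution",
    "SensingSummary",
    "sample_peptide_curvature",
    "reweight",
    "log_slope",
    "mean_sensed_curvature",
    "leaflet_agreement",
    "depth_curvature_correlation",
    "slope_difference_test",
]


def sample_peptide_curvature(
    traj: Trajectory,
    phosphate_spec: SelectionSpec,
    peptide_spec: SelectionSpec,
    config: AnalysisConfig,
    leaflet: str = "upper",
) -> tuple[np.ndarray, int]:
    """Per-frame mean curvature of the leaflet surface at the peptide COM.

    Each frame's leaflet surface is fitted independently from its phosphate
    beads and evaluated at the peptide's (x, y); the leaflet sign convention
    makes upper- and lower-leaflet samples directly comparable.  Returns
    (samples, n_skipped) where skipped frames had a failed surface fit.
    """
    from .errors import FitError
    from .peptide import assign_leaflets, peptide_com

    mx, my = config.fourier_modes
    samples = []
    skipped = 0
    for frame in traj.frames:
        pep = select(frame, peptide_spec)
        if len(pep) == 0:
            raise InputError("peptide selection is empty")
        labels = assign_leaflets(frame, phosphate_spec)
        phos = select(frame, phosphate_spec)
        mine = np.array([labels.get(int(m)) == leaflet for m in frame.molecule_ids[phos]])
        phos = phos[mine]
        if len(phos) == 0:
            raise InputError(f"no phosphates on the {leaflet} leaflet")
        try:
            model = fit_surface(
                frame.positions[phos],
                (frame.box[0], frame.box[1]),
                mx,
                my,
                leaflet=leaflet,
                time=frame.time,
            )
        except FitError:
            skipped += 1
            continue
        com = peptide_com(frame, peptide_spec)
        H, _, _, _, _ = curvature_field(model, [com[0] % frame.box[0]], [com[1] % frame.box[1]])
        samples.append(float(H[0]))
    return np.asarray(samples), skipped


def reweight(
    sampled: CurvatureDistribution,
    accessible: CurvatureDistribution,
    mask_threshold: float = 1e-4,
) -> CurvatureDistribution:
    """Divide the sampled distribution by the accessible one, bin by bin.

    Bins whose accessible weight falls below ``mask_threshold`` are masked
    (division blow-up guard) and reported via a warning when they carried
    sampled weight; the result is renormalized over unmasked bins.
    """
    if sampled.kind != "sampled" or accessible.kind != "accessible":
        raise InputError("reweight expects (sampled, accessible) distributions")
    if not sampled.same_binning(accessible):
        raise InputError("sampled and accessible distributions must share binning")
    mask = sampled.mask | accessible.mask | (accessible.weights < mask_threshold)
    lost = float(np.sum(sampled.weights[mask]))
    if lost > 0:
        warnings.warn(
            f"{int(np.sum(mask & (sampled.weights > 0)))} bins with sampled weight were "
            f"masked (accessible weight < {mask_threshold}); {lost:.3g} of the sampled "
            "probability discarded",
            stacklevel=2,
        )
    w = np.zeros_like(sampled.weights)
    ok = ~mask
    w[ok] = sampled.weights[ok] / accessible.weights[ok]
    total = w.sum()
    if total <= 0:
        raise AnalysisError("disjoint supports: no bin survives the accessible mask")
    return CurvatureDistribution(
        sampled.bin_edges,
        w / total,
        "reweighted",
        leaflet=sampled.leaflet,
        n_samples=sampled.n_samples,
        mask=mask,
    )


def log_slope(dist: CurvatureDistribution, min_weight: float = 0.0) -> float:
    """Slope of log(weight) vs bin-center curvature over occupied unmasked
    bins — for an exp(a*H)-biased sampler this recovers the bias a (nm)."""
    ok = (~dist.mask) & (dist.weights > min_weight)
    if ok.sum() < 3:
        raise AnalysisError("too few occupied bins for a log-slope fit")
    slope, _ = np.polyfit(dist.centers[ok], np.log(dist.weights[ok]), 1)
    return float(slope)


def mean_sensed_curvature(reweighted: CurvatureDistribution) -> float:
    """Weighted mean of the reweighted distribution, nm^-1."""
    if reweighted.kind != "reweighted":
        raise InputError("mean sensed curvature is defined on the reweighted distribution")
    ok = ~reweighted.mask
    return float(np.sum(reweighted.weights[ok] * reweighted.centers[ok]))


def leaflet_agreement(
    dist_upper: CurvatureDistribution, dist_lower: CurvatureDistribution
) -> float:
    """Total-variation distance in [0, 1] between the two leaflets'
    distributions; small values indicate converged sampling."""
    if not dist_upper.same_binning(dist_lower):
        raise InputError("leaflet distributions must share binning")
    wu = np.where(dist_upper.mask, 0.0, dist_upper.weights)
    wl = np.where(dist_lower.mask, 0.0, dist_lower.weights)
    return float(0.5 * np.sum(np.abs(wu - wl)))


def depth_curvature_correlation(pairs: np.ndarray) -> tuple[float, float]:
    """Pearson correlation (r, two-sided p) between per-peptide insertion
    depth and mean sensed curvature."""
    pairs = np.asarray(pairs, dtype=float)
    if pairs.ndim != 2 or pairs.shape[1] != 2 or pairs.shape[0] < 3:
        raise InputError("need at least 3 (depth, curvature) pairs")
    x, y = pairs[:, 0], pairs[:, 1]
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise AnalysisError("undefined correlation: zero variance in depth or curvature")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def _ols_slope(x: np.ndarray, y: np.ndarray) -> tuple[float, float, int]:
    """(slope, SE of slope, n) of an ordinary least-squares line."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 3:
        raise InputError("need at least 3 points per series")
    sxx = np.sum((x - x.mean()) ** 2)
    if sxx == 0:
        raise AnalysisError("degenerate x-variance in slope fit")
    slope = np.sum((x - x.mean()) * (y - y.mean())) / sxx
    resid = y - (y.mean() + slope * (x - x.mean()))
    se = np.sqrt(np.sum(resid**2) / (n - 2) / sxx) if n > 2 else 0.0
    return float(slope), float(se), n


@dataclass(frozen=True)
class SlopeTest:
    slope_a: float
    se_a: float
    slope_b: float
    se_b: float
    t: float
    df: float
    p: float


def slope_difference_test(
    series_a: tuple[np.ndarray, np.ndarray], series_b: tuple[np.ndarray, np.ndarray]
) -> SlopeTest:
    """Two-sample t-test on the difference of OLS slopes.

    t = (b_A - b_B) / sqrt(SE_A^2 + SE_B^2) with Welch-Satterthwaite degrees
    of freedom; two-sided p.  Identical series give t = 0, p = 1.
    """
    ba, sa, na = _ols_slope(*series_a)
    bb, sb, nb = _ols_slope(*series_b)
    denom = np.sqrt(sa**2 + sb**2)
    if denom == 0:
        if ba == bb:
            return SlopeTest(ba, sa, bb, sb, 0.0, np.inf, 1.0)
        return SlopeTest(ba, sa, bb, sb, np.inf if ba > bb else -np.inf, np.inf, 0.0)
    t = (ba - bb) / denom
    dfa, dfb = na - 2, nb - 2
    df = (sa**2 + sb**2) ** 2 / (sa**4 / dfa + sb**4 / dfb)
    p = 2.0 * stats.t.sf(abs(t), df)
    return SlopeTest(ba, sa, bb, sb, float(t), float(df), float(p))


@dataclass
class SensingSummary:
    """Per peptide x membrane sensing results, ready for JSON export."""

    entries: list[dict] = field(default_factory=list)
    correlations: dict[str, tuple[float, float]] = field(default_factory=dict)

    def add(
        self,
        peptide: str,
        membrane: str,
        mean_curvature: float,
        depth: float,
        agreement: float | None = None,
        converged: bool | None = None,
    ) -> None:
        self.entries.append(
            {
                "peptide": peptide,
                "membrane": membrane,
                "mean_sensed_curvature_per_nm": mean_curvature,
                "insertion_depth_nm": depth,
                "leaflet_agreement": agreement,
                "converged": converged,
            }
        )

    def correlation_for(self, membrane: str) -> tuple[float, float]:
        pairs = np.array(
            [
                (e["insertion_depth_nm"], e["mean_sensed_curvature_per_nm"])
                for e in self.entries
                if e["membrane"] == membrane
            ]
        )
        r, p = depth_curvature_correlation(pairs)
        self.correlations[membrane] = (r, p)
        return r, p

    def to_dict(self) -> dict:
        return {"entries": self.entries, "correlations": self.correlations}
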