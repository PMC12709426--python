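"""Binned curvature distributions shared by the surface and sensing stages."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InputError

__all__ = ["CurvatureDistribution"]


@dataclass
class CurvatureDistribution:
    """Normalized histogram of mean curvature (nm^-1).

    ``kind`` records provenance: 'sampled' (peptide positions), 'accessible'
    (area-weighted surface measure), or 'reweighted' (sampled / accessible).
    ``mask`` marks bins excluded from normalization (e.g. bins where the
    accessible weight is too small to divide by).
    """

    bin_edges: np.ndarray  # (nbins+1,) nm^-1
    weights: np.ndarray  # (nbins,) normalized over unmasked bins
    kind: str  # sampled | accessible | reweighted
    leaflet: str = "both"
    n_samples: int = 0
    mask: np.ndarray = field(default=None)  # True = excluded

    def __post_init__(self):
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if self.kind not in ("sampled", "accessible", "reweighted"):
            raise InputError(f"unknown distribution kind {self.kind!r}")
        if self.bin_edges.ndim != 1 or len(self.bin_edges) < 2:
            raise InputError("need at least one bin")
        if not np.all(np.diff(self.bin_edges) > 0):
            raise InputError("bin edges must be strictly increasing")
        if self.weights.shape != (len(self.bin_edges) - 1,):
            raise InputError("weights length must match bin count")
        if self.mask is None:
            self.mask = np.zeros(len(self.weights), dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
        if np.any(self.weights[~self.mask] < -1e-12):
            raise InputError("weights must be non-negative")

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def active(self) -> np.ndarray:
        """Indices of unmasked bins."""
        return np.flatnonzero(~self.mask)

    def normalized(self) -> "CurvatureDistribution":
        w = self.weights.copy()
        w[self.mask] = 0.0
        total = w.sum()
        if total <= 0:
            raise InputError("cannot normalize an all-zero distribution")
        return CurvatureDistribution(
            self.bin_edges, w / total, self.kind, self.leaflet, self.n_samples, self.mask.copy()
        )

    def same_binning(self, other: "CurvatureDistribution") -> bool:
        return self.bin_edges.shape == other.bin_edges.shape and np.allclose(
            self.bin_edges, other.bin_edges
        )

    @classmethod
    def from_samples(
        cls,
        samples: np.ndarray,
        bin_edges: np.ndarray,
        kind: str = "sampled",
        leaflet: str = "both",
        sample_weights: np.ndarray | None = None,
    ) -> "CurvatureDistribution":
        samples = np.asarray(samples, dtype=float)
        counts, _ = np.histogram(samples, bins=bin_edges, weights=sample_weights)
        total = counts.sum()
        if total <= 0:
            raise InputError("no samples fall inside the histogram range")
        return cls(bin_edges, counts / total, kind, leaflet, n_samples=len(samples))
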