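"""Population statistics: percent-positive counts and cell-cycle fractions.

DNA-content histograms are decomposed into a three-component model — a
Gaussian 2N (G1) peak, a Gaussian 4N (G2) peak constrained near twice the G1
mean, and an S-phase plateau between the peaks broadened by the G1 width —
by bounded least squares; phase fractions are the component masses divided by
the total.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

__all__ = [
    "DnaHistogram",
    "PhaseFractions",
    "PopulationCounts",
    "percent_positive",
    "estimate_phase_fractions",
]


@dataclass(frozen=True)
class DnaHistogram:
    bin_edges: np.ndarray  # increasing, len = n_bins + 1
    counts: np.ndarray  # non-negative ints, len = n_bins

    def __post_init__(self) -> None:
        edges = np.asarray(self.bin_edges, dtype=float)
        counts = np.asarray(self.counts)
        if np.any(np.diff(edges) <= 0):
            raise ValueError("bin_edges must be strictly increasing")
        if counts.size != edges.size - 1:
            raise ValueError("len(counts) must equal len(bin_edges) - 1")
        if np.any(counts < 0):
            raise ValueError("counts must be non-negative")
        if counts.sum() <= 0:
            raise ValueError("histogram must contain at least one cell")
        object.__setattr__(self, "bin_edges", edges)
        object.__setattr__(self, "counts", counts.astype(float))

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


@dataclass(frozen=True)
class PhaseFractions:
    g1: float
    s: float
    g2: float

    def __post_init__(self) -> None:
        for name in ("g1", "s", "g2"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} fraction {v} outside [0, 1]")
        if abs(self.g1 + self.s + self.g2 - 1.0) > 1e-6:
            raise ValueError("fractions must sum to 1")

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.g1, self.s, self.g2)


@dataclass(frozen=True)
class PopulationCounts:
    positive: int
    total: int

    def __post_init__(self) -> None:
        if self.total <= 0:
            raise ValueError("total must be positive")
        if not 0 <= self.positive <= self.total:
            raise ValueError("positive must be in [0, total]")


def percent_positive(counts: PopulationCounts) -> float:
    """100 * positive / total."""
    return 100.0 * counts.positive / counts.total


def _int_norm_cdf(x: np.ndarray, loc: float, scale: float) -> np.ndarray:
    """Antiderivative of the normal CDF: integral of Phi((t-loc)/scale) dt."""
    z = (x - loc) / scale
    return scale * (z * stats.norm.cdf(z) + stats.norm.pdf(z))


def _model_bin_masses(
    edges: np.ndarray,
    mu: float,
    sigma1: float,
    sigma2: float,
    g: float,
    masses: np.ndarray,
) -> np.ndarray:
    """Expected counts per bin of the three-component mixture."""
    mu2 = g * mu
    g1 = np.diff(stats.norm.cdf(edges, mu, sigma1)) * masses[0]
    g2 = np.diff(stats.norm.cdf(edges, mu2, sigma2)) * masses[2]
    # S phase: uniform on [mu, mu2] convolved with N(0, sigma1); bin mass is
    # the difference of integrated CDFs divided by the plateau width.
    width = mu2 - mu
    s_cdf_int = _int_norm_cdf(edges, mu, sigma1) - _int_norm_cdf(
        edges, mu2, sigma1
    )
    s = np.diff(s_cdf_int) / width * masses[1]
    return g1 + s + g2


def estimate_phase_fractions(hist: DnaHistogram) -> PhaseFractions:
    """Fit the G1/S/G2 mixture to a DNA-content histogram.

    The G1 mean is initialized at the histogram's dominant mode; the G2 peak
    position is constrained to [1.9, 2.1] times the fitted G1 mean.
    """
    counts = hist.counts
    if np.count_nonzero(counts) < 2:
        raise ValueError(
            "degenerate histogram: fewer than two nonzero bins; "
            "cannot separate cell-cycle phases"
        )
    edges = hist.bin_edges
    centers = hist.centers
    total = hist.total

    mu0 = float(centers[np.argmax(counts)])
    if mu0 <= 0:
        mu0 = float(centers[counts > 0][0])
    sigma0 = max(0.05 * mu0, float(np.diff(edges).mean()))

    # theta = (mu, sigma1, sigma2, g, m_g1, m_s, m_g2)
    theta0 = np.array(
        [mu0, sigma0, 2 * sigma0, 2.0, 0.6 * total, 0.2 * total, 0.2 * total]
    )
    lower = np.array(
        [0.5 * mu0, 1e-3 * mu0, 1e-3 * mu0, 1.9, 0.0, 0.0, 0.0]
    )
    upper = np.array(
        [1.5 * mu0, 0.5 * mu0, 0.5 * mu0, 2.1, total, total, total]
    )

    def residuals(theta: np.ndarray) -> np.ndarray:
        mu, s1, s2, g = theta[:4]
        masses = theta[4:]
        return _model_bin_masses(edges, mu, s1, s2, g, masses) - counts

    fit = optimize.least_squares(
        residuals, theta0, bounds=(lower, upper), method="trf"
    )
    masses = np.clip(fit.x[4:], 0.0, None)
    if masses.sum() <= 0:
        raise RuntimeError("mixture fit collapsed to zero mass")
    fracs = masses / masses.sum()
    return PhaseFractions(g1=float(fracs[0]), s=float(fracs[1]), g2=float(fracs[2]))
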