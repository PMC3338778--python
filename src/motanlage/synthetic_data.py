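"""Synthetic-data generators with known ground truth.

Every input the analysis pipeline consumes can be produced here: 2-D cell
trajectories from a two-state (run/pause) persistent random walk, per-cell
focal-adhesion scenes and rendered intensity images, per-genotype expression
replicates and DNA-content histograms.  All generators are pure functions of
their parameters and a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .track_metrics import Track

__all__ = [
    "MotilityParams",
    "TrackSet",
    "AdhesionScene",
    "ExpressionSpec",
    "DnaHistogramSpec",
    "simulate_tracks",
    "preset_params",
    "PRESETS",
    "simulate_adhesion_scene",
    "render_puncta_image",
    "simulate_expression",
    "simulate_dna_histogram",
]


@dataclass(frozen=True)
class MotilityParams:
    """Two-state run/pause kinetics of a simulated cell.

    ``p_move_to_pause`` / ``p_pause_to_move`` are per-interval switching
    probabilities; while moving, step length is ``speed * dt`` with speed
    drawn from N(speed_mean, speed_sd) truncated at 0 and heading deviating
    from the previous heading by a von Mises angle of concentration
    ``turn_kappa`` (0 = isotropic).  Paused intervals displace by Gaussian
    positional jitter of SD ``pause_jitter_um`` per axis.
    """

    p_move_to_pause: float
    p_pause_to_move: float
    speed_mean: float
    speed_sd: float
    turn_kappa: float
    group_label: str = "custom"
    pause_jitter_um: float = 0.1

    def __post_init__(self) -> None:
        for name in ("p_move_to_pause", "p_pause_to_move"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        if self.speed_mean < 0:
            raise ValueError(f"speed_mean must be >= 0, got {self.speed_mean}")
        if self.speed_sd < 0:
            raise ValueError(f"speed_sd must be >= 0, got {self.speed_sd}")
        if self.turn_kappa < 0:
            raise ValueError(f"turn_kappa must be >= 0, got {self.turn_kappa}")
        if self.pause_jitter_um < 0:
            raise ValueError(
                f"pause_jitter_um must be >= 0, got {self.pause_jitter_um}"
            )

    @property
    def stationary_moving_fraction(self) -> float:
        """Long-run fraction of intervals spent moving."""
        denom = self.p_move_to_pause + self.p_pause_to_move
        if denom == 0:
            return 1.0  # absorbing in whatever state it starts; moving by default
        return self.p_pause_to_move / denom


@dataclass(frozen=True)
class TrackSet:
    """A cohort of tracks sharing sampling interval and length."""

    tracks: tuple[Track, ...]
    dt_min: float
    n_points: int
    seed: int

    def __post_init__(self) -> None:
        for t in self.tracks:
            if t.n_points != self.n_points or t.dt_min != self.dt_min:
                raise ValueError(
                    "all tracks in a TrackSet must share dt_min and n_points"
                )

    @property
    def total_time_min(self) -> float:
        return (self.n_points - 1) * self.dt_min


# Calibrated per-genotype presets.  Switching probabilities set the long-run
# moving fraction (time budget); speed_mean sets total distance; turn_kappa
# shapes directional persistence.  Constants were fit with
# scripts/calibrate_presets.py against the published cohort summaries
# (5 cells, 25 samples, 5-min interval).
PRESETS: dict[str, MotilityParams] = {
    "WT": MotilityParams(
        p_move_to_pause=0.10,
        p_pause_to_move=0.30,
        speed_mean=0.581,
        speed_sd=0.15,
        turn_kappa=1.0,
        group_label="WT",
    ),
    "HET": MotilityParams(
        p_move_to_pause=0.05,
        p_pause_to_move=0.30,
        speed_mean=0.713,
        speed_sd=0.18,
        turn_kappa=0.6,
        group_label="HET",
    ),
    "MUT": MotilityParams(
        p_move_to_pause=0.305,
        p_pause_to_move=0.295,
        speed_mean=0.365,
        speed_sd=0.09,
        turn_kappa=2.0,
        group_label="MUT",
    ),
}


def preset_params(group: str) -> MotilityParams:
    """Calibrated motility parameters for one of the WT/HET/MUT genotypes."""
    try:
        return PRESETS[group]
    except KeyError:
        raise KeyError(
            f"unknown group {group!r}; expected one of {sorted(PRESETS)}"
        ) from None


def simulate_tracks(
    params: MotilityParams,
    n_cells: int,
    n_points: int = 25,
    dt_min: float = 5.0,
    seed: int = 0,
) -> TrackSet:
    """Simulate a cohort of run-and-pause persistent random walks.

    Each track starts at the origin.  The initial motion state is drawn from
    the two-state chain's stationary distribution and the initial heading is
    uniform on the circle.  Identical arguments (including seed) give
    bit-identical output.
    """
    if n_cells <= 0:
        raise ValueError(f"n_cells must be positive, got {n_cells}")
    if n_points <= 0:
        raise ValueError(f"n_points must be positive, got {n_points}")
    if dt_min <= 0:
        raise ValueError(f"dt_min must be positive, got {dt_min}")

    rng = np.random.default_rng(seed)
    n_steps = n_points - 1
    positions = np.zeros((n_cells, n_points, 2))
    moving = rng.random(n_cells) < params.stationary_moving_fraction
    heading = rng.uniform(-np.pi, np.pi, size=n_cells)

    for step in range(n_steps):
        # state transition for this interval
        u = rng.random(n_cells)
        next_moving = np.where(
            moving, u >= params.p_move_to_pause, u < params.p_pause_to_move
        )
        moving = next_moving

        turns = rng.vonmises(0.0, params.turn_kappa, size=n_cells)
        speeds = rng.normal(params.speed_mean, params.speed_sd, size=n_cells)
        np.clip(speeds, 0.0, None, out=speeds)
        jitter = rng.normal(0.0, params.pause_jitter_um, size=(n_cells, 2))

        heading = np.where(moving, heading + turns, heading)
        step_len = speeds * dt_min
        move_disp = step_len[:, None] * np.column_stack(
            (np.cos(heading), np.sin(heading))
        )
        disp = np.where(moving[:, None], move_disp, jitter)
        positions[:, step + 1] = positions[:, step] + disp

    tracks = tuple(
        Track(track_id=f"{params.group_label}_{i:04d}",
              positions=positions[i], dt_min=dt_min)
        for i in range(n_cells)
    )
    return TrackSet(tracks=tracks, dt_min=dt_min, n_points=n_points, seed=seed)


# ---------------------------------------------------------------------------
# Focal-adhesion scenes


@dataclass(frozen=True)
class AdhesionScene:
    """A cell's puncta with a known polarity axis and true edge counts."""

    cell_id: str
    centroid: np.ndarray  # (2,) um
    polarity_axis: np.ndarray  # (2,) unit vector
    puncta: tuple[tuple[np.ndarray, float], ...]  # ((x, y) um, area um^2)
    truth_counts: tuple[int, int]  # (leading, trailing)

    def __post_init__(self) -> None:
        axis = np.asarray(self.polarity_axis, dtype=float)
        norm = np.linalg.norm(axis)
        if not np.isclose(norm, 1.0, atol=1e-9):
            raise ValueError("polarity_axis must have unit norm")
        for _, area in self.puncta:
            if not area > 0:
                raise ValueError("puncta areas must be positive")
        object.__setattr__(self, "centroid", np.asarray(self.centroid, float))
        object.__setattr__(self, "polarity_axis", axis)


def simulate_adhesion_scene(
    count_leading: int,
    count_trailing: int,
    size_mean_um: float,
    size_sd_um: float,
    seed: int = 0,
    cell_id: str = "cell",
    cell_radius_um: float = 15.0,
) -> AdhesionScene:
    """Place puncta on either side of a random polarity axis.

    Sizes are equivalent diameters drawn from N(size_mean_um, size_sd_um)
    truncated below at 0.2 um; stored areas are pi * (d/2)^2.  Puncta are kept
    at least 1 um off the axis so the leading/trailing partition is
    unambiguous.
    """
    if count_leading < 0 or count_trailing < 0:
        raise ValueError("puncta counts must be non-negative")
    if size_mean_um <= 0 or size_sd_um < 0:
        raise ValueError("size_mean_um must be > 0 and size_sd_um >= 0")

    rng = np.random.default_rng(seed)
    theta = rng.uniform(0, 2 * np.pi)
    axis = np.array([np.cos(theta), np.sin(theta)])
    perp = np.array([-axis[1], axis[0]])
    centroid = np.zeros(2)

    puncta: list[tuple[np.ndarray, float]] = []
    for count, sign in ((count_leading, 1.0), (count_trailing, -1.0)):
        for _ in range(count):
            along = sign * rng.uniform(1.0, cell_radius_um)
            across = rng.uniform(-cell_radius_um, cell_radius_um)
            pos = centroid + along * axis + across * perp
            diam = max(0.2, rng.normal(size_mean_um, size_sd_um))
            area = np.pi * (diam / 2.0) ** 2
            puncta.append((pos, float(area)))

    return AdhesionScene(
        cell_id=cell_id,
        centroid=centroid,
        polarity_axis=axis,
        puncta=tuple(puncta),
        truth_counts=(count_leading, count_trailing),
    )


def render_puncta_image(
    scene: AdhesionScene,
    pixel_size_um: float = 0.2,
    psf_sigma_um: float = 0.3,
    noise_sd: float = 0.0,
    seed: int = 0,
    margin_um: float = 5.0,
) -> np.ndarray:
    """Render a scene as a 2-D intensity grid.

    Each punctum becomes an isotropic Gaussian blob whose integrated
    intensity is proportional to its area; Gaussian read noise of SD
    ``noise_sd`` is added everywhere.  Row index maps to y, column to x.
    """
    if pixel_size_um <= 0:
        raise ValueError(f"pixel_size_um must be positive, got {pixel_size_um}")
    if psf_sigma_um <= 0:
        raise ValueError(f"psf_sigma_um must be positive, got {psf_sigma_um}")

    if scene.puncta:
        pts = np.array([p for p, _ in scene.puncta])
        lo = pts.min(axis=0) - margin_um
        hi = pts.max(axis=0) + margin_um
    else:
        lo = scene.centroid - margin_um
        hi = scene.centroid + margin_um

    nx = max(8, int(np.ceil((hi[0] - lo[0]) / pixel_size_um)))
    ny = max(8, int(np.ceil((hi[1] - lo[1]) / pixel_size_um)))
    x = lo[0] + (np.arange(nx) + 0.5) * pixel_size_um
    y = lo[1] + (np.arange(ny) + 0.5) * pixel_size_um
    xx, yy = np.meshgrid(x, y)  # shape (ny, nx)

    image = np.zeros((ny, nx))
    two_s2 = 2.0 * psf_sigma_um**2
    for (px, py), area in scene.puncta:
        amp = area / (np.pi * two_s2)  # integrated intensity == area
        image += amp * np.exp(-((xx - px) ** 2 + (yy - py) ** 2) / two_s2)
    image *= pixel_size_um**2  # per-pixel integrated signal

    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        image = image + rng.normal(0.0, noise_sd, size=image.shape)
    return image


def image_origin(scene: AdhesionScene, margin_um: float = 5.0) -> np.ndarray:
    """Lower-left corner (um) of the grid render_puncta_image produces."""
    if scene.puncta:
        pts = np.array([p for p, _ in scene.puncta])
        return pts.min(axis=0) - margin_um
    return scene.centroid - margin_um


# ---------------------------------------------------------------------------
# Expression replicates


@dataclass(frozen=True)
class ExpressionSpec:
    """Per-gene group means and replicate noise for three genotypes.

    ``genes`` holds (name, wt_mean, het_mean, mut_mean, noise_sd) tuples.
    With probability ``outlier_rate`` one replicate per gene x genotype is
    multiplied by a corruption factor drawn outside [0.5, 2].
    """

    genes: tuple[tuple[str, float, float, float, float], ...]
    n_replicates: int = 3
    outlier_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.n_replicates < 2:
            raise ValueError("n_replicates must be >= 2")
        if not 0.0 <= self.outlier_rate <= 1.0:
            raise ValueError("outlier_rate must be in [0, 1]")
        for name, wt, het, mut, sd in self.genes:
            if min(wt, het, mut) < 0 or sd < 0:
                raise ValueError(f"gene {name!r}: means and noise_sd must be >= 0")


GENOTYPES = ("WT", "HET", "MUT")


def simulate_expression(spec: ExpressionSpec, seed: int = 0):
    """Long-format replicate table: columns gene, genotype, replicate, value.

    Returns a pandas DataFrame.  Corrupted replicates are multiplied by a
    factor log-uniform in [2, 5] or its reciprocal (both outside [0.5, 2]).
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    rows = []
    for name, wt, het, mut, sd in spec.genes:
        for genotype, mean in zip(GENOTYPES, (wt, het, mut)):
            values = rng.normal(mean, sd, size=spec.n_replicates)
            np.clip(values, 0.0, None, out=values)
            if rng.random() < spec.outlier_rate:
                idx = int(rng.integers(spec.n_replicates))
                factor = np.exp(rng.uniform(np.log(2.0), np.log(5.0)))
                if rng.random() < 0.5:
                    factor = 1.0 / factor
                values[idx] *= factor
            for rep, v in enumerate(values):
                rows.append((name, genotype, rep, float(v)))
    return pd.DataFrame(rows, columns=["gene", "genotype", "replicate", "value"])


# ---------------------------------------------------------------------------
# DNA-content histograms


@dataclass(frozen=True)
class DnaHistogramSpec:
    """Mixture spec for a propidium-iodide style DNA-content histogram."""

    fractions: tuple[float, float, float]  # (g1, s, g2)
    cv: float = 0.05
    n_cells: int = 10_000
    g2_position: float = 2.0
    g1_mean: float = 100.0

    def __post_init__(self) -> None:
        f = self.fractions
        if len(f) != 3 or min(f) < 0:
            raise ValueError("fractions must be three non-negative numbers")
        if abs(sum(f) - 1.0) > 1e-9:
            raise ValueError(f"fractions must sum to 1, got {sum(f)}")
        if self.cv < 0:
            raise ValueError("cv must be >= 0")
        if self.n_cells <= 0:
            raise ValueError("n_cells must be positive")
        if self.g2_position <= 1.0:
            raise ValueError("g2_position must exceed 1")


def simulate_dna_histogram(
    spec: DnaHistogramSpec, seed: int = 0, n_bins: int = 200
):
    """Draw per-cell DNA content and bin it into a histogram.

    G1 cells: N(mu, cv*mu).  G2 cells: N(g2_position*mu, cv*g2_position*mu).
    S cells: uniform between the two peak means, broadened by additive
    Gaussian noise of SD cv*mu (the 2N peak width).
    Returns a :class:`motanlage.cell_population.DnaHistogram`.
    """
    from .cell_population import DnaHistogram

    rng = np.random.default_rng(seed)
    mu = spec.g1_mean
    mu2 = spec.g2_position * mu
    sigma1 = spec.cv * mu

    counts = rng.multinomial(spec.n_cells, spec.fractions)
    g1 = rng.normal(mu, max(sigma1, 1e-12), size=counts[0])
    s = rng.uniform(mu, mu2, size=counts[1]) + rng.normal(
        0.0, max(sigma1, 1e-12), size=counts[1]
    )
    g2 = rng.normal(mu2, max(spec.cv * mu2, 1e-12), size=counts[2])
    content = np.concatenate([g1, s, g2])

    hi = mu2 * (1.0 + max(6.0 * spec.cv, 0.05))
    edges = np.linspace(0.0, hi, n_bins + 1)
    binned, _ = np.histogram(content, bins=edges)
    return DnaHistogram(bin_edges=edges, counts=binned)
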