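"""Focal-adhesion puncta quantification.

Detect puncta in an intensity image by absolute thresholding and
8-connectivity component labeling, split them into leading/trailing edges by
projection onto a per-cell polarity axis, classify maturity by equivalent
diameter, and summarize counts and sizes per cell and per group.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from skimage import measure

from ._util import round_half_away_from_zero

__all__ = [
    "Punctum",
    "CellAdhesionProfile",
    "GroupAdhesionSummary",
    "detect_puncta",
    "partition_edges",
    "classify_maturity",
    "profile_cell",
    "group_adhesion_summary",
    "LEADING",
    "TRAILING",
]

LEADING = "leading"
TRAILING = "trailing"


@dataclass(frozen=True)
class Punctum:
    """A detected adhesion point: centroid position and area in um."""

    position: np.ndarray  # (2,) um, (x, y)
    area_um2: float

    def __post_init__(self) -> None:
        if not self.area_um2 > 0:
            raise ValueError(f"area must be positive, got {self.area_um2}")
        object.__setattr__(self, "position", np.asarray(self.position, float))

    @property
    def equivalent_diameter_um(self) -> float:
        """Diameter of the circle with the same area."""
        return math.sqrt(4.0 * self.area_um2 / math.pi)


@dataclass(frozen=True)
class CellAdhesionProfile:
    cell_id: str
    puncta: tuple[Punctum, ...]
    edge_of: tuple[str, ...]  # per-punctum LEADING | TRAILING

    def __post_init__(self) -> None:
        if len(self.puncta) != len(self.edge_of):
            raise ValueError("edge_of must label every punctum")
        for e in self.edge_of:
            if e not in (LEADING, TRAILING):
                raise ValueError(f"unknown edge label {e!r}")

    @property
    def count_leading(self) -> int:
        return sum(1 for e in self.edge_of if e == LEADING)

    @property
    def count_trailing(self) -> int:
        return sum(1 for e in self.edge_of if e == TRAILING)

    def _sizes(self, edge: str | None) -> list[float]:
        return [
            p.equivalent_diameter_um
            for p, e in zip(self.puncta, self.edge_of)
            if edge is None or e == edge
        ]

    @property
    def mean_size_leading_um(self) -> float:
        sizes = self._sizes(LEADING)
        return float(np.mean(sizes)) if sizes else float("nan")

    @property
    def mean_size_trailing_um(self) -> float:
        sizes = self._sizes(TRAILING)
        return float(np.mean(sizes)) if sizes else float("nan")

    @property
    def mean_size_um(self) -> float:
        sizes = self._sizes(None)
        return float(np.mean(sizes)) if sizes else float("nan")


def detect_puncta(
    image: np.ndarray,
    pixel_size_um: float,
    threshold: float,
    min_area_um2: float = 0.0,
    origin_um: tuple[float, float] = (0.0, 0.0),
) -> list[Punctum]:
    """Threshold, label 8-connected components, measure centroid and area.

    Components smaller than ``min_area_um2`` are discarded.  Pixel (row, col)
    maps to position (origin + (col + 0.5, row + 0.5) * pixel_size).
    """
    if pixel_size_um <= 0:
        raise ValueError(f"pixel_size_um must be positive, got {pixel_size_um}")
    image = np.asarray(image, dtype=float)
    mask = image > threshold
    labeled = measure.label(mask, connectivity=2)
    px_area = pixel_size_um**2
    puncta = []
    for region in measure.regionprops(labeled):
        area = region.area * px_area
        if area < min_area_um2:
            continue
        row, col = region.centroid
        pos = (
            origin_um[0] + (col + 0.5) * pixel_size_um,
            origin_um[1] + (row + 0.5) * pixel_size_um,
        )
        puncta.append(Punctum(position=np.asarray(pos), area_um2=float(area)))
    return puncta


def partition_edges(
    puncta: Sequence[Punctum],
    centroid: Sequence[float],
    polarity_axis: Sequence[float],
) -> list[str]:
    """Leading iff (position - centroid) . axis > 0; exact zeros -> trailing.

    The axis is normalized internally; a zero axis is rejected.
    """
    axis = np.asarray(polarity_axis, dtype=float)
    norm = np.linalg.norm(axis)
    if norm == 0:
        raise ValueError("polarity axis must have nonzero norm")
    axis = axis / norm
    centroid = np.asarray(centroid, dtype=float)
    labels = []
    for p in puncta:
        proj = float((p.position - centroid) @ axis)
        labels.append(LEADING if proj > 0 else TRAILING)
    return labels


def classify_maturity(p: Punctum) -> str:
    """nascent (< 1 um), mature (2-10 um) or intermediate by diameter."""
    d = p.equivalent_diameter_um
    if d < 1.0:
        return "nascent"
    if 2.0 <= d <= 10.0:
        return "mature"
    return "intermediate"


def profile_cell(
    cell_id: str,
    puncta: Sequence[Punctum],
    centroid: Sequence[float],
    polarity_axis: Sequence[float],
) -> CellAdhesionProfile:
    """Partition a cell's puncta into edges and bundle the per-cell profile."""
    labels = partition_edges(puncta, centroid, polarity_axis)
    return CellAdhesionProfile(
        cell_id=cell_id, puncta=tuple(puncta), edge_of=tuple(labels)
    )


@dataclass(frozen=True)
class GroupAdhesionSummary:
    """Totals and per-cell mean +/- SEM of counts and sizes, overall and per edge.

    ``display`` values are rounded half-away-from-zero at the precision used
    in summary tables (integer counts, 2-decimal sizes).
    """

    n_cells: int
    total: int
    total_leading: int
    total_trailing: int
    mean_count: float
    sem_count: float
    mean_count_leading: float
    sem_count_leading: float
    mean_count_trailing: float
    sem_count_trailing: float
    mean_size_um: float
    sem_size_um: float
    mean_size_leading_um: float
    mean_size_trailing_um: float

    @property
    def display_mean_count(self) -> int:
        return int(round_half_away_from_zero(self.mean_count))

    @property
    def display_mean_count_leading(self) -> int:
        return int(round_half_away_from_zero(self.mean_count_leading))

    @property
    def display_mean_count_trailing(self) -> int:
        return int(round_half_away_from_zero(self.mean_count_trailing))


def _mean_sem(values: np.ndarray) -> tuple[float, float]:
    if values.size == 0:
        return float("nan"), float("nan")
    mean = float(values.mean())
    if values.size < 2:
        return mean, float("nan")
    return mean, float(values.std(ddof=1) / math.sqrt(values.size))


def group_adhesion_summary(
    cells: Sequence[CellAdhesionProfile],
) -> GroupAdhesionSummary:
    """Aggregate per-cell profiles into group totals and mean +/- SEM."""
    if not cells:
        raise ValueError("need at least one cell profile")
    counts = np.array([len(c.puncta) for c in cells], dtype=float)
    counts_lead = np.array([c.count_leading for c in cells], dtype=float)
    counts_trail = np.array([c.count_trailing for c in cells], dtype=float)
    sizes = np.array(
        [c.mean_size_um for c in cells if len(c.puncta) > 0], dtype=float
    )
    sizes_lead = np.array(
        [c.mean_size_leading_um for c in cells if c.count_leading > 0]
    )
    sizes_trail = np.array(
        [c.mean_size_trailing_um for c in cells if c.count_trailing > 0]
    )

    mean_count, sem_count = _mean_sem(counts)
    mean_cl, sem_cl = _mean_sem(counts_lead)
    mean_ct, sem_ct = _mean_sem(counts_trail)
    mean_size, sem_size = _mean_sem(sizes)

    return GroupAdhesionSummary(
        n_cells=len(cells),
        total=int(counts.sum()),
        total_leading=int(counts_lead.sum()),
        total_trailing=int(counts_trail.sum()),
        mean_count=mean_count,
        sem_count=sem_count,
        mean_count_leading=mean_cl,
        sem_count_leading=sem_cl,
        mean_count_trailing=mean_ct,
        sem_count_trailing=sem_ct,
        mean_size_um=mean_size,
        sem_size_um=sem_size,
        mean_size_leading_um=float(np.mean(sizes_lead)) if sizes_lead.size else float("nan"),
        mean_size_trailing_um=float(np.mean(sizes_trail)) if sizes_trail.size else float("nan"),
    )
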