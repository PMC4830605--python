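"""The phenotypic stem-ness index: distance to the HSC centroid.

On a co-embedded map, CD34+ CD38lo/- hematopoietic stem cells serve as a
common reference point.  A cell's HSC distance (HSCD) is the Euclidean
distance sqrt((x2-x1)^2 + (y2-y1)^2) between its map coordinates and the
centroid (coordinate-wise mean) of the reference HSCs; a population's
HSCD is the mean over its cells.  Across samples, the median and IQR of
population distances quantify inter-sample heterogeneity, and the change
in mean subpopulation distance between timepoints quantifies the
phenotypic shift away from (positive) or toward (negative) stem cells.

Distances are only defined within one co-embedded map: reference and
test populations must share a coordinate system, and mixing maps raises.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from ._stats import interp_quartiles
from .embedding import EmbeddingResult
from .io import BlastmapError, ParameterError
from .populations import PopulationAssignment

logger = logging.getLogger(__name__)


class ReferenceMissingError(BlastmapError):
    """No event carries the requested reference label."""


class MapMismatchError(BlastmapError):
    """Coordinates and centroid come from different embeddings."""


@dataclass(frozen=True)
class Centroid:
    x: float
    y: float
    map_id: str = ""

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise ParameterError("centroid coordinates must be finite")


@dataclass(frozen=True)
class DistanceSummary:
    """Per-population mean HSC distances plus cross-sample spread.

    ``per_population`` rows are (population, n_cells, mean_distance);
    ``per_sample_values`` rows are (sample_id, population, mean_distance).
    ``median``/``iqr`` summarise the per-sample values (linear-interpolation
    quartiles; lower median).
    """

    per_population: tuple[tuple[str, int, float], ...]
    per_sample_values: tuple[tuple[str, str, float], ...] = ()
    median: float = float("nan")
    iqr: float = float("nan")

    def mean_distance(self, population: str) -> float:
        for name, _, d in self.per_population:
            if name == population:
                return d
        raise KeyError(population)

    @property
    def population_means(self) -> np.ndarray:
        return np.array([d for _, _, d in self.per_population])


def reference_centroid(
    emb: EmbeddingResult, ref_labels: PopulationAssignment, ref_name: str = "HSC"
) -> Centroid:
    """Centroid of the reference population: mean x and mean y."""
    mask = ref_labels.mask(ref_name)
    if not mask.any():
        raise ReferenceMissingError(
            f"no event labeled {ref_name!r}; cannot place the reference centroid"
        )
    mean = emb.coords[mask].mean(axis=0)
    return Centroid(x=float(mean[0]), y=float(mean[1]), map_id=emb.map_id)


def cell_distance(coord, c: Centroid) -> float:
    """Euclidean distance from one map coordinate to the centroid."""
    x1, y1 = float(coord[0]), float(coord[1])
    return math.hypot(c.x - x1, c.y - y1)


def _check_map(emb: EmbeddingResult, c: Centroid) -> None:
    if c.map_id and emb.map_id and c.map_id != emb.map_id:
        raise MapMismatchError(
            "centroid and coordinates come from different embeddings; "
            "distances require one co-embedded map"
        )


def cell_distances(emb: EmbeddingResult, c: Centroid) -> np.ndarray:
    """Vectorised HSC distance of every event on the map."""
    _check_map(emb, c)
    d = emb.coords - np.array([c.x, c.y])
    return np.hypot(d[:, 0], d[:, 1])


def population_distance(
    emb: EmbeddingResult,
    labels: PopulationAssignment,
    population: str,
    c: Centroid,
) -> tuple[float, int]:
    """Mean HSC distance over a population's cells, with the cell count."""
    _check_map(emb, c)
    mask = labels.mask(population)
    n = int(mask.sum())
    if n == 0:
        raise ParameterError(f"population {population!r} has no cells")
    return float(cell_distances(emb, c)[mask].mean()), n


def distance_summary(
    emb: EmbeddingResult,
    labels: PopulationAssignment,
    c: Centroid,
    populations: list[str] | None = None,
    sample_ids: np.ndarray | None = None,
) -> DistanceSummary:
    """Summarise HSC distances per population (and per sample when given)."""
    pops = populations if populations is not None else labels.population_names
    per_population = []
    for p in pops:
        mean_d, n = population_distance(emb, labels, p, c)
        per_population.append((p, n, mean_d))
    per_sample: list[tuple[str, str, float]] = []
    if sample_ids is not None:
        sample_ids = np.asarray(sample_ids)
        dists = cell_distances(emb, c)
        for sid in sorted({str(s) for s in sample_ids}):
            s_mask = sample_ids.astype(str) == sid
            for p in pops:
                m = s_mask & labels.mask(p)
                if m.any():
                    per_sample.append((sid, p, float(dists[m].mean())))
    values = [v for _, _, v in per_sample] or [d for _, _, d in per_population]
    med, iqr = heterogeneity_summary(values)
    return DistanceSummary(
        per_population=tuple(per_population),
        per_sample_values=tuple(per_sample),
        median=med,
        iqr=iqr,
    )


def heterogeneity_summary(values) -> tuple[float, float]:
    """Median and IQR (Q3 - Q1) of per-sample population distances."""
    v = np.asarray(list(values), dtype=float)
    if v.size == 0:
        raise ParameterError("heterogeneity summary of empty input")
    if v.size == 1:
        return float(v[0]), 0.0
    # same linear-interpolation convention for the median and the quartiles
    q1, q3 = interp_quartiles(v)
    return float(np.quantile(v, 0.5, method="linear")), q3 - q1


def distance_shift(
    day0: DistanceSummary, day14: DistanceSummary, cell_weighted: bool = False
) -> float:
    """Mean change in HSC distance between timepoints (positive = away).

    By default the unweighted mean of per-subpopulation mean distances is
    compared; ``cell_weighted=True`` weights each subpopulation by its
    cell count instead.
    """
    for s, name in ((day0, "day0"), (day14, "day14")):
        if not s.per_population:
            raise ParameterError(f"{name} summary is empty")

    def agg(s: DistanceSummary) -> float:
        d = s.population_means
        if not cell_weighted:
            return float(d.mean())
        w = np.array([n for _, n, _ in s.per_population], dtype=float)
        return float((d * w).sum() / w.sum())

    return agg(day14) - agg(day0)
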