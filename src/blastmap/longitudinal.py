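"""Longitudinal tracking: blast-area occupancy, subpopulation abundance,
median marker profiles, marker shifts and marker variability.

Treatment response reads out as the regression or persistence of cells
inside the leukemic blast area over time, and — after joint regating of
pre/post blasts — as the redistribution of blasts across numbered
subpopulations, the change in median marker expression on the arcsinh
scale, and the per-marker spread of subpopulation medians.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._stats import lower_median, sample_sd
from .embedding import EmbeddingResult
from .io import EventMatrix, PanelMismatchError, ParameterError
from .populations import UNASSIGNED, BlastArea, PopulationAssignment
from .embedding import _grid_cell_of

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SubpopulationProfile:
    """One blast subpopulation: median phenotype + per-timepoint abundance."""

    subpop_id: str
    median_expression: np.ndarray
    abundance: dict[str, float]


@dataclass(frozen=True)
class MarkerShift:
    """Post-minus-pre change in a marker's median (arcsinh units)."""

    marker: str
    delta_median: float
    sd_across_subpops: float | None = None

    def __post_init__(self) -> None:
        if self.sd_across_subpops is not None and self.sd_across_subpops < 0:
            raise ParameterError("sd must be non-negative")


# ---------------------------------------------------------------------------
# blast-area occupancy
# ---------------------------------------------------------------------------

def blast_area_occupancy(
    series: list[tuple[str, np.ndarray]], area: BlastArea
) -> pd.DataFrame:
    """Per-sample fraction of events inside/outside the blast area.

    Each event is mapped to its nearest grid cell (coordinates outside
    the extent are clipped to the border); it is "inside" when that cell
    belongs to a member island of the area.
    """
    if area.is_empty:
        logger.warning("blast area is empty: all occupancy fractions are 0")
    rows = []
    shape = area.grid_mask.shape
    for sample_id, coords in series:
        coords = np.asarray(coords, dtype=float)
        if coords.size == 0:
            raise ParameterError(f"sample {sample_id!r} has no events")
        ix, iy = _grid_cell_of(coords, area.grid_extent, shape)
        inside = float(area.grid_mask[ix, iy].mean()) if not area.is_empty else 0.0
        rows.append((sample_id, inside, 1.0 - inside))
    return pd.DataFrame(rows, columns=["sample_id", "fraction_inside",
                                       "fraction_outside"])


# ---------------------------------------------------------------------------
# abundance table
# ---------------------------------------------------------------------------

def abundance_table(
    labels: PopulationAssignment, timepoint_of_event, timepoints=None
) -> pd.DataFrame:
    """Fraction of each timepoint's blasts in every subpopulation.

    Rows are subpopulation labels (plus an ``unassigned`` row when
    present), columns are timepoints; each column sums to 1.  By default
    the timepoints are those observed per event, in order of appearance.
    """
    tp = np.asarray(timepoint_of_event)
    if tp.shape[0] != len(labels):
        raise ParameterError("timepoint_of_event length must equal event count")
    if timepoints is None:
        timepoints = list(dict.fromkeys(tp.tolist()))  # stable order
    lab = labels.labels

    def sort_key(name: str):
        return (name == UNASSIGNED, len(name), name)  # "2" < "10"; unassigned last

    subpops = sorted({str(x) for x in lab}, key=sort_key)
    table = {}
    for t in timepoints:
        t_mask = tp == t
        n = int(t_mask.sum())
        if n == 0:
            raise ParameterError(f"timepoint {t!r} has zero blasts")
        table[t] = [float((lab[t_mask] == s).sum()) / n for s in subpops]
    df = pd.DataFrame(table, index=pd.Index(subpops, name="subpopulation"))
    return df


def designate_persisters(abund: pd.DataFrame, pre: str, post: str) -> tuple[set, set]:
    """Split subpopulations into dominant (pre-weighted) and persister sets.

    A subpopulation is a persister region when its share of post-treatment
    blasts exceeds its share of pre-treatment blasts; the unassigned row
    is excluded from both sets.
    """
    dominant, persister = set(), set()
    for s in abund.index:
        if s == UNASSIGNED:
            continue
        (persister if abund.loc[s, post] > abund.loc[s, pre] else dominant).add(s)
    return dominant, persister


def persistence_report(
    abund: pd.DataFrame, dominant_set: set, persister_set: set,
    pre: str, post: str,
) -> tuple[float, float]:
    """Summed occupancy of the persister regions at both timepoints."""
    if dominant_set & persister_set:
        raise ParameterError("dominant and persister sets overlap: "
                             f"{sorted(dominant_set & persister_set)}")
    ids = [s for s in abund.index if s != UNASSIGNED]
    if set(ids) != (dominant_set | persister_set):
        raise ParameterError("sets must partition the subpopulation ids")
    rows = sorted(persister_set)
    pre_occ = float(abund.loc[rows, pre].sum()) if rows else 0.0
    post_occ = float(abund.loc[rows, post].sum()) if rows else 0.0
    return pre_occ, post_occ


# ---------------------------------------------------------------------------
# median profiles
# ---------------------------------------------------------------------------

def median_profiles(
    m: EventMatrix, labels: PopulationAssignment,
    abundance: pd.DataFrame | None = None,
) -> list[SubpopulationProfile]:
    """Per-subpopulation, per-marker median expression (lower median).

    Empty subpopulations are skipped with a warning.  When an abundance
    table is supplied, its rows are attached to the profiles.
    """
    if m.scale != "arcsinh":
        raise ParameterError("median profiles expect arcsinh-scale input")
    profiles = []
    names = [s for s in labels.population_names]
    for s in names:
        mask = labels.mask(s)
        if not mask.any():
            logger.warning("subpopulation %r is empty; skipped", s)
            continue
        med = np.array([lower_median(col) for col in m.values[mask].T])
        ab = {} if abundance is None or s not in abundance.index else \
            {str(c): float(abundance.loc[s, c]) for c in abundance.columns}
        profiles.append(SubpopulationProfile(subpop_id=s, median_expression=med,
                                             abundance=ab))
    return profiles


def profiles_to_frame(profiles: list[SubpopulationProfile], marker_names) -> pd.DataFrame:
    """Heatmap matrix: subpopulations x markers."""
    return pd.DataFrame(
        [p.median_expression for p in profiles],
        index=pd.Index([p.subpop_id for p in profiles], name="subpopulation"),
        columns=list(marker_names),
    )


# ---------------------------------------------------------------------------
# marker shift
# ---------------------------------------------------------------------------

def marker_shift(
    pre: EventMatrix | list[SubpopulationProfile],
    post: EventMatrix | list[SubpopulationProfile],
    pre_weights: dict | None = None,
    post_weights: dict | None = None,
    marker_names=None,
) -> list[MarkerShift]:
    """Post-minus-pre change in median marker expression (arcsinh units).

    With event matrices the medians are pooled over all blast cells at
    each timepoint (the default aggregation); with subpopulation profiles
    the per-subpopulation medians are averaged with the supplied
    abundance weights.  A change of +0.7 means the marker's median rose
    by 0.7 arcsinh units after treatment.
    """
    if isinstance(pre, EventMatrix) != isinstance(post, EventMatrix):
        raise ParameterError("pre and post must both be matrices or both profiles")
    if isinstance(pre, EventMatrix):
        if pre.panel.names != post.panel.names:
            raise PanelMismatchError("pre and post use different marker panels")
        markers = pre.panel.names
        pre_med = np.array([lower_median(c) for c in pre.values.T])
        post_med = np.array([lower_median(c) for c in post.values.T])
        return [MarkerShift(marker=mk, delta_median=float(d))
                for mk, d in zip(markers, post_med - pre_med)]

    def weighted(profiles: list[SubpopulationProfile], weights: dict | None):
        mat = np.vstack([p.median_expression for p in profiles])
        if weights is None:
            w = np.ones(len(profiles))
        else:
            w = np.array([float(weights[p.subpop_id]) for p in profiles])
        if w.sum() <= 0:
            raise ParameterError("weights must have positive sum")
        return (mat * w[:, None]).sum(axis=0) / w.sum(), mat

    if not pre or not post:
        raise ParameterError("profile lists must be non-empty")
    if pre[0].median_expression.shape != post[0].median_expression.shape:
        raise PanelMismatchError("pre and post profiles cover different markers")
    pre_agg, pre_mat = weighted(pre, pre_weights)
    post_agg, post_mat = weighted(post, post_weights)
    all_mat = np.vstack([pre_mat, post_mat])
    sds = (np.std(all_mat, axis=0, ddof=1) if all_mat.shape[0] >= 2
           else np.zeros(all_mat.shape[1]))
    names = (list(marker_names) if marker_names is not None
             else [f"marker_{i}" for i in range(all_mat.shape[1])])
    return [MarkerShift(marker=nm, delta_median=float(d),
                        sd_across_subpops=float(s))
            for nm, d, s in zip(names, post_agg - pre_agg, sds)]


# ---------------------------------------------------------------------------
# marker SD ranking
# ---------------------------------------------------------------------------

def marker_sd_ranking(
    profiles: list[SubpopulationProfile], marker_names
) -> list[tuple[str, float]]:
    """Markers ranked by the spread of their subpopulation medians.

    The standard deviation (n-1 denominator) of each marker across all
    subpopulation median vectors, in descending order; ties break on the
    marker name so the ranking is stable.
    """
    if len(profiles) < 2:
        raise ParameterError("SD ranking needs at least two subpopulations")
    mat = np.vstack([p.median_expression for p in profiles])
    marker_names = list(marker_names)
    if mat.shape[1] != len(marker_names):
        raise PanelMismatchError("profile length does not match marker names")
    sds = [sample_sd(mat[:, j]) for j in range(mat.shape[1])]
    return sorted(zip(marker_names, sds), key=lambda t: (-t[1], t[0]))
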