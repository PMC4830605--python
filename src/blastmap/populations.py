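"""Population identity assignment and leukemic blast area definition.

Identities come from three provenances: threshold gates on markers (the
CD34+ CD38lo/- stem-cell gate), matching each density island's median
marker profile to reference immunophenotypes, or imported labels.  The
"leukemic blast area" is the region of the map occupied by a patient's
blasts at diagnosis; it is the anchor for longitudinal tracking.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .embedding import (EmbeddingParams, EmbeddingResult, IslandPartition,
                        density_islands, fit_embedding)
from .io import EventMatrix, PanelMismatchError, ParameterError, pool_samples
from ._stats import lower_median

logger = logging.getLogger(__name__)

UNASSIGNED = "unassigned"

DEFAULT_HSC_GATE_THRESHOLDS = {"CD34": ("gt", 1.0), "CD38": ("le", 0.8)}
DEFAULT_MIN_BLAST_FRAC = 0.5
DEFAULT_MAX_MATCH_DIST = 5.0


@dataclass(frozen=True)
class GatePredicate:
    marker: str
    op: str  # "gt" (strict) | "le" (inclusive)
    threshold: float

    def __post_init__(self) -> None:
        if self.op not in ("gt", "le"):
            raise ParameterError(f"gate op must be gt|le, got {self.op!r}")


@dataclass(frozen=True)
class GateRule:
    """Conjunction of per-marker threshold predicates, e.g. the HSC gate."""

    name: str
    predicates: tuple[GatePredicate, ...]

    def __post_init__(self) -> None:
        if not self.predicates:
            raise ParameterError("gate rule needs at least one predicate")


def hsc_gate(thresholds: dict | None = None) -> GateRule:
    """The CD34+ CD38lo/- hematopoietic stem-cell gate (arcsinh units)."""
    thresholds = thresholds or DEFAULT_HSC_GATE_THRESHOLDS
    preds = tuple(
        GatePredicate(marker=m, op=op, threshold=t)
        for m, (op, t) in thresholds.items()
    )
    return GateRule(name="HSC", predicates=preds)


@dataclass(frozen=True)
class PopulationAssignment:
    """Per-event population label with provenance (rule | island | imported)."""

    labels: np.ndarray
    provenance: str

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels, dtype=object)
        object.__setattr__(self, "labels", lab)
        if self.provenance not in ("rule", "island", "imported"):
            raise ParameterError(f"unknown provenance {self.provenance!r}")

    def __len__(self) -> int:
        return len(self.labels)

    def mask(self, name: str) -> np.ndarray:
        return self.labels == name

    @property
    def population_names(self) -> list[str]:
        return sorted({str(x) for x in self.labels if x != UNASSIGNED})


def imported_labels(labels) -> PopulationAssignment:
    return PopulationAssignment(labels=np.asarray(labels, dtype=object),
                                provenance="imported")


# ---------------------------------------------------------------------------
# rule gating
# ---------------------------------------------------------------------------

def gate_by_rule(m: EventMatrix, rule: GateRule) -> PopulationAssignment:
    """Label events passing every predicate; ties at `gt` thresholds fail.

    `gt` is strict and `le` inclusive so that gate counts are
    bit-reproducible.
    """
    if m.scale != "arcsinh":
        raise ParameterError("gating expects arcsinh-scale input")
    keep = np.ones(m.n_events, dtype=bool)
    for p in rule.predicates:
        col = m.column(p.marker)  # raises PanelMismatchError for unknown marker
        keep &= (col > p.threshold) if p.op == "gt" else (col <= p.threshold)
    labels = np.where(keep, rule.name, UNASSIGNED).astype(object)
    return PopulationAssignment(labels=labels, provenance="rule")


# ---------------------------------------------------------------------------
# island -> reference-profile matching
# ---------------------------------------------------------------------------

def match_islands_to_references(
    part: IslandPartition,
    m: EventMatrix,
    refs: list[tuple[str, np.ndarray]],
    max_dist: float = DEFAULT_MAX_MATCH_DIST,
) -> PopulationAssignment:
    """Assign each island the identity of its nearest reference profile.

    An island is characterised by its per-marker median expression; it is
    matched to the reference immunophenotype at minimum Euclidean
    distance in marker space, or left unassigned when every reference is
    farther than ``max_dist``.  Events inherit their island's label.
    """
    if not refs:
        raise ParameterError("no reference profiles given")
    if part.n_islands == 0:
        raise ParameterError("empty island partition: no islands to match")
    ref_names = [r[0] for r in refs]
    ref_mat = np.vstack([np.asarray(r[1], dtype=float) for r in refs])
    if ref_mat.shape[1] != m.values.shape[1]:
        raise PanelMismatchError(
            f"reference profiles have {ref_mat.shape[1]} markers, panel has "
            f"{m.values.shape[1]}"
        )
    labels = np.full(m.n_events, UNASSIGNED, dtype=object)
    for isl in range(part.n_islands):
        idx = part.members(isl)
        if idx.size == 0:
            continue
        med = np.apply_along_axis(lower_median, 0, m.values[idx])
        d = np.sqrt(((ref_mat - med) ** 2).sum(axis=1))
        best = float(d.min())
        if best > max_dist:
            continue
        winners = sorted(ref_names[i] for i in np.flatnonzero(d == best))
        if len(winners) > 1:
            logger.warning("island %d equidistant from %s; choosing %r",
                           isl, winners, winners[0])
        labels[idx] = winners[0]
    return PopulationAssignment(labels=labels, provenance="island")


# ---------------------------------------------------------------------------
# leukemic blast area
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BlastArea:
    """Map region occupied by diagnostic blasts: islands + grid mask."""

    member_islands: frozenset[int]
    grid_mask: np.ndarray
    grid_extent: tuple[float, float, float, float]

    @property
    def is_empty(self) -> bool:
        return not bool(self.member_islands)


def define_blast_area(
    part: IslandPartition,
    day0_labels: PopulationAssignment,
    blast_label: str = "blast",
    day0_mask: np.ndarray | None = None,
    min_blast_frac: float = DEFAULT_MIN_BLAST_FRAC,
) -> BlastArea:
    """Define the blast area from the islands diagnostic blasts occupy.

    An island is included when, among its Day 0 occupants (``day0_mask``;
    all events by default), strictly more than ``min_blast_frac`` carry
    ``blast_label``.  The grid mask marks the member islands' cells.
    """
    if day0_mask is None:
        day0_mask = np.ones(len(day0_labels), dtype=bool)
    day0_mask = np.asarray(day0_mask, dtype=bool)
    if not day0_mask.any():
        raise ParameterError("no Day 0 events present in the partition")
    labels = day0_labels.labels
    members: set[int] = set()
    for isl in range(part.n_islands):
        occ = (part.island_id == isl) & day0_mask
        n_occ = int(occ.sum())
        if n_occ == 0:
            continue
        frac = float((labels[occ] == blast_label).sum()) / n_occ
        if frac > min_blast_frac:
            members.add(isl)
    mask = np.isin(part.label_grid - 1, sorted(members))
    if not members:
        logger.warning("no island exceeds min_blast_frac=%.2f; blast area is empty",
                       min_blast_frac)
        mask = np.zeros_like(part.density_grid, dtype=bool)
    return BlastArea(member_islands=frozenset(members), grid_mask=mask,
                     grid_extent=part.grid_extent)


# ---------------------------------------------------------------------------
# joint Day 0 / Day 14 blast regating
# ---------------------------------------------------------------------------

def regate_joint_blasts(
    day0_blasts: EventMatrix,
    day14_blasts: EventMatrix,
    params: EmbeddingParams | None = None,
    outlier_pct: float = 10.0,
    step_pct: float = 2.0,
    grid_size: int = 256,
    bandwidth_scale: float | None = None,
) -> tuple[EmbeddingResult, PopulationAssignment]:
    """Re-embed pooled Day 0 + Day 14 blasts and number their islands.

    Each density island of the joint map becomes a numbered blast
    subpopulation.  Numbering mirrors the dominant-then-persister layout:
    islands are ordered by descending share of Day 0 blasts, ties broken
    by descending share of Day 14 blasts, and labeled "1", "2", ...

    Joint blast maps pack many similar-sized, closely related clusters,
    so the island bandwidth defaults to a finer 0.3 x Scott here (island
    label purity against synthetic truth improves materially over the
    map-wide default).
    """
    if day0_blasts.n_events == 0 or day14_blasts.n_events == 0:
        raise ParameterError("both blast matrices must be non-empty")
    pooled, source = pool_samples([day0_blasts, day14_blasts])
    emb = fit_embedding(pooled, params, source_sample_index=source)
    if bandwidth_scale is None:
        bandwidth_scale = 0.3
    part = density_islands(emb, outlier_pct=outlier_pct, step_pct=step_pct,
                           grid_size=grid_size, bandwidth_scale=bandwidth_scale)
    if part.n_islands < 2:
        logger.warning("joint regating found %d island(s); proceeding",
                       part.n_islands)
    n0 = day0_blasts.n_events
    n14 = day14_blasts.n_events
    occ = []
    for isl in range(part.n_islands):
        in_isl = part.island_id == isl
        day0_share = float(in_isl[:n0].sum()) / n0
        day14_share = float(in_isl[n0:].sum()) / n14
        occ.append((isl, day0_share, day14_share))
    order = sorted(occ, key=lambda t: (-t[1], -t[2], t[0]))
    rename = {isl: str(rank + 1) for rank, (isl, _, _) in enumerate(order)}
    labels = np.array(
        [rename.get(int(i), UNASSIGNED) if i >= 0 else UNASSIGNED
         for i in part.island_id],
        dtype=object,
    )
    return emb, PopulationAssignment(labels=labels, provenance="island")


def blast_percentage(labels: PopulationAssignment, blast_label: str = "blast") -> float:
    """Blast-labeled share of all events, in percent."""
    if len(labels) == 0:
        raise ParameterError("empty assignment")
    return 100.0 * float(np.mean(labels.labels == blast_label))
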