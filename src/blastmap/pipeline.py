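"""End-to-end orchestration: configuration, staged runs, tabular reports.

Two analysis archetypes cover the workflow:

* :func:`clearance_analysis` — co-embed a longitudinal sample series,
  partition the map into density islands, identify populations from
  reference immunophenotypes, define the leukemic blast area from the
  diagnostic sample and track its occupancy over time, plus HSC-distance
  summaries on the same map.
* :func:`refractory_analysis` — jointly re-embed Day 0 + Day 14 blasts,
  regate subpopulations, tabulate abundances, persister occupancy,
  median profiles, marker shifts, marker variability, and the mean
  HSC-distance shift on a co-embedding with healthy marrow.

:func:`run_pipeline` wires either archetype to a :class:`RunConfig`,
writes every table as CSV with a conventions header, and emits a
machine-readable manifest; re-running a config byte-reproduces the CSVs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .embedding import EmbeddingParams, density_islands, embedding_to_frame, \
    fit_embedding
from .io import (DEFAULT_COFACTOR, EventMatrix, MarkerPanel, ParameterError,
                 arcsinh_transform, pool_samples, read_events, subsample_equal)
from .longitudinal import (abundance_table, blast_area_occupancy,
                           designate_persisters, marker_shift,
                           marker_sd_ranking, median_profiles,
                           persistence_report, profiles_to_frame)
from .populations import (BlastArea, PopulationAssignment, blast_percentage,
                          define_blast_area, gate_by_rule, hsc_gate,
                          imported_labels, match_islands_to_references,
                          regate_joint_blasts)
from .stemness import (DistanceSummary, distance_shift, distance_summary,
                       reference_centroid)
from .synthetic import (BLAST, blast_profile, default_panel,
                        healthy_marrow_spec, scenario_blood_series,
                        scenario_refractory, scenario_remission)

logger = logging.getLogger(__name__)

CONVENTIONS = {
    "median_rule": "lower order statistic for even counts",
    "quantile_rule": "linear interpolation between order statistics",
    "sd_denominator": "n-1",
    "distance": "Euclidean on co-embedded t-SNE axes",
}

SCENARIOS = ("remission", "refractory", "blood_series")


@dataclass
class RunConfig:
    """Everything a run needs; the seed is mandatory for reproducibility."""

    seed: int
    scenario: str | None = None            # one of SCENARIOS, or None
    input_paths: tuple[str, ...] = ()      # FCS/CSV event files (ordered by time)
    panel_path: str | None = None          # needed with input_paths
    out_dir: str = "blastmap_run"
    cofactor: float = DEFAULT_COFACTOR
    target_n: int = 5000
    n_per_sample: int = 3000               # scenario generation size
    perplexity: float = 30.0
    iterations: int = 1000
    outlier_pct: float = 10.0
    step_pct: float = 2.0
    grid_size: int = 256
    bandwidth_scale: float = 0.4
    regate_bandwidth_scale: float = 0.3
    min_blast_frac: float = 0.5
    max_match_dist: float = 5.0
    hsc_thresholds: dict = field(
        default_factory=lambda: {"CD34": ("gt", 1.0), "CD38": ("le", 0.8)})

    def validate(self) -> None:
        if self.scenario is None and not self.input_paths:
            raise ParameterError("config needs a scenario or input_paths")
        if self.scenario is not None and self.scenario not in SCENARIOS:
            raise ParameterError(f"unknown scenario {self.scenario!r}")
        if self.input_paths:
            if self.panel_path is None:
                raise ParameterError("input_paths require a panel_path")
            if not Path(self.panel_path).exists():
                raise ParameterError(f"panel file not found: {self.panel_path}")
            for p in self.input_paths:
                if not Path(p).exists():
                    raise ParameterError(f"input file not found: {p}")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        if "input_paths" in raw:
            raw["input_paths"] = tuple(raw["input_paths"])
        return cls(**raw)

    @property
    def embedding_params(self) -> EmbeddingParams:
        return EmbeddingParams(perplexity=self.perplexity,
                               iterations=self.iterations, seed=self.seed)


# ---------------------------------------------------------------------------
# reference profiles
# ---------------------------------------------------------------------------

def reference_profiles(panel: MarkerPanel) -> list[tuple[str, np.ndarray]]:
    """Canonical immunophenotypes: 9 healthy populations + the AML blast."""
    spec = healthy_marrow_spec(panel)
    refs = [(p.name, p.mean_expr) for p in spec.populations]
    refs.append((BLAST, blast_profile(panel)))
    return refs


# ---------------------------------------------------------------------------
# clearance archetype
# ---------------------------------------------------------------------------

def clearance_analysis(
    samples: list[EventMatrix],
    cfg: RunConfig,
    diagnostic_index: int = 0,
) -> dict:
    """Track blast-area occupancy over a co-embedded longitudinal series.

    The blast area is anchored on the sample at ``diagnostic_index``
    (Day 0 by convention).  Returns embeddings, island labels, the blast
    area, per-sample occupancy/blast-percentage tables and an
    HSC-distance summary on the shared map.
    """
    subsampled = subsample_equal(samples, cfg.target_n, cfg.seed)
    pooled, source = pool_samples(subsampled)
    emb = fit_embedding(pooled, cfg.embedding_params, source_sample_index=source)
    part = density_islands(emb, cfg.outlier_pct, cfg.step_pct, cfg.grid_size,
                           cfg.bandwidth_scale)
    refs = reference_profiles(pooled.panel)
    labels = match_islands_to_references(part, pooled, refs, cfg.max_match_dist)

    day0_mask = source == diagnostic_index
    area = define_blast_area(part, labels, blast_label=BLAST,
                             day0_mask=day0_mask,
                             min_blast_frac=cfg.min_blast_frac)
    sample_ids = [s.sample_meta.sample_id or f"sample{i}"
                  for i, s in enumerate(subsampled)]
    series = [(sid, emb.coords[source == i]) for i, sid in enumerate(sample_ids)]
    occupancy = blast_area_occupancy(series, area)

    blast_pct = pd.DataFrame({
        "sample_id": sample_ids,
        "blast_pct": [blast_percentage(
            PopulationAssignment(labels.labels[source == i], labels.provenance),
            BLAST) for i in range(len(sample_ids))],
    })

    hsc = gate_by_rule(pooled, hsc_gate(cfg.hsc_thresholds))
    summary = None
    if hsc.mask("HSC").any():
        centroid = reference_centroid(emb, hsc, "HSC")
        summary = distance_summary(
            emb, labels, centroid,
            sample_ids=np.asarray(sample_ids, dtype=object)[source])
    else:
        logger.warning("no events pass the HSC gate; distance summary skipped")

    return {
        "samples": subsampled, "pooled": pooled, "source": source,
        "embedding": emb, "partition": part, "labels": labels,
        "blast_area": area, "occupancy": occupancy, "blast_pct": blast_pct,
        "distance_summary": summary, "sample_ids": sample_ids,
    }


# ---------------------------------------------------------------------------
# refractory archetype
# ---------------------------------------------------------------------------

def refractory_analysis(
    day0_blasts: EventMatrix,
    day14_blasts: EventMatrix,
    cfg: RunConfig,
    healthy_marrow: EventMatrix | None = None,
) -> dict:
    """Joint Day 0 / Day 14 blast regating and longitudinal statistics."""
    emb, subpops = regate_joint_blasts(
        day0_blasts, day14_blasts, cfg.embedding_params,
        outlier_pct=cfg.outlier_pct, step_pct=cfg.step_pct,
        grid_size=cfg.grid_size, bandwidth_scale=cfg.regate_bandwidth_scale)
    n0 = day0_blasts.n_events
    timepoint = np.array(["day0"] * n0 + ["day14"] * day14_blasts.n_events)
    abund = abundance_table(subpops, timepoint)
    dominant, persister = designate_persisters(abund, "day0", "day14")
    pre_occ, post_occ = persistence_report(abund, dominant, persister,
                                           "day0", "day14")

    pooled, _ = pool_samples([day0_blasts, day14_blasts])
    profiles = median_profiles(pooled, subpops, abund)
    heatmap = profiles_to_frame(profiles, pooled.panel.names)
    shifts = marker_shift(day0_blasts, day14_blasts)
    sd_ranking = marker_sd_ranking(profiles, pooled.panel.names) \
        if len(profiles) >= 2 else []

    shift = None
    stem_summaries: tuple[DistanceSummary, DistanceSummary] | None = None
    if healthy_marrow is not None:
        shift, stem_summaries = _stem_shift_with_marrow(
            day0_blasts, day14_blasts, subpops, dominant, persister,
            healthy_marrow, cfg)

    return {
        "embedding": emb, "subpops": subpops, "abundance": abund,
        "dominant": dominant, "persister": persister,
        "persister_pre_occupancy": pre_occ,
        "persister_post_occupancy": post_occ,
        "profiles": profiles, "heatmap": heatmap, "marker_shift": shifts,
        "sd_ranking": sd_ranking, "distance_shift": shift,
        "distance_summaries": stem_summaries,
    }


def _stem_shift_with_marrow(day0_blasts, day14_blasts, subpops, dominant,
                            persister, healthy_marrow, cfg):
    """Map blast subpopulations with healthy marrow and measure the mean
    change in HSC distance (dominant Day 0 subsets vs persisting Day 14
    subsets), positive = away from stem cells."""
    pooled, source = pool_samples([healthy_marrow, day0_blasts, day14_blasts])
    emb = fit_embedding(pooled, cfg.embedding_params, source_sample_index=source)
    hsc = gate_by_rule(pooled, hsc_gate(cfg.hsc_thresholds))
    centroid = reference_centroid(emb, hsc, "HSC")
    n_h = healthy_marrow.n_events
    labels = np.full(pooled.n_events, "healthy", dtype=object)
    labels[n_h:] = subpops.labels
    joint = imported_labels(labels)
    n0 = day0_blasts.n_events
    is_day0 = np.zeros(pooled.n_events, dtype=bool)
    is_day0[n_h:n_h + n0] = True

    def one_side(pop_set, mask):
        rows = []
        masked = imported_labels(np.where(mask, labels, "other"))
        for p in sorted(pop_set):
            if (masked.labels == p).any():
                from .stemness import population_distance

                d, n = population_distance(emb, masked, p, centroid)
                rows.append((p, n, d))
        return DistanceSummary(per_population=tuple(rows))

    s0 = one_side(dominant, is_day0)
    s14 = one_side(persister, ~is_day0 & (np.arange(pooled.n_events) >= n_h))
    if not s0.per_population or not s14.per_population:
        logger.warning("distance shift unavailable: a side has no subpopulations")
        return None, None
    return distance_shift(s0, s14), (s0, s14)


# ---------------------------------------------------------------------------
# report writing
# ---------------------------------------------------------------------------

def write_table(df: pd.DataFrame, path: Path, cfg: RunConfig,
                index: bool = True) -> None:
    """CSV with a commented metadata header naming the conventions used."""
    with open(path, "w", newline="") as fh:
        for k, v in CONVENTIONS.items():
            fh.write(f"# {k}: {v}\n")
        fh.write(f"# seed: {cfg.seed}\n# blastmap_version: {__version__}\n")
        df.to_csv(fh, index=index)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(cfg: RunConfig) -> Path:
    """Execute the configured analysis end to end into ``cfg.out_dir``.

    Stages: load/generate -> transform -> subsample -> embed -> islands ->
    gate -> stemness -> longitudinal -> report.  All CSV outputs carry a
    conventions header; the JSON manifest records parameters, stages and
    output checksums.  Identical configs byte-reproduce every CSV.
    """
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_handler = logging.FileHandler(out / "run.log", mode="w")
    log_handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("blastmap")
    root.addHandler(log_handler)
    root.setLevel(logging.INFO)
    stages: list[str] = []
    manifest = {
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in dataclasses.asdict(cfg).items()},
        "version": __version__,
        "conventions": CONVENTIONS,
        "stages": stages,
        "outputs": {},
    }
    try:
        if cfg.scenario == "refractory":
            _run_refractory(cfg, out, stages)
        else:
            _run_clearance(cfg, out, stages)
        stages.append("report")
    except Exception as exc:
        manifest["failed_stage"] = f"after {stages[-1] if stages else 'start'}: {exc}"
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise
    finally:
        root.removeHandler(log_handler)
        log_handler.close()
    manifest["outputs"] = {p.name: _sha256(p) for p in sorted(out.glob("*.csv"))}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out


def _load_series(cfg: RunConfig):
    if cfg.scenario == "remission":
        samples, _ = scenario_remission(cfg.seed, cfg.n_per_sample)
    elif cfg.scenario == "blood_series":
        samples, _ = scenario_blood_series(cfg.seed, cfg.n_per_sample)
    else:
        panel = MarkerPanel.from_csv(cfg.panel_path)
        samples = [arcsinh_transform(read_events(p, panel), cfg.cofactor)
                   for p in cfg.input_paths]
    return samples


def _run_clearance(cfg: RunConfig, out: Path, stages: list[str]) -> None:
    samples = _load_series(cfg)
    stages.append("load")
    res = clearance_analysis(samples, cfg)
    stages += ["subsample", "embed", "islands", "gate"]
    write_table(embedding_to_frame(res["embedding"], res["partition"]),
                out / "embedding.csv", cfg, index=False)
    lab = pd.DataFrame({"event_id": np.arange(len(res["labels"].labels)),
                        "label": res["labels"].labels})
    write_table(lab, out / "labels.csv", cfg, index=False)
    write_table(res["occupancy"], out / "occupancy.csv", cfg, index=False)
    write_table(res["blast_pct"], out / "blast_percentage.csv", cfg, index=False)
    stages.append("longitudinal")
    if res["distance_summary"] is not None:
        s = res["distance_summary"]
        per_pop = pd.DataFrame(s.per_population,
                               columns=["population", "n_cells", "mean_distance"])
        write_table(per_pop, out / "stemness.csv", cfg, index=False)
        cohort = pd.DataFrame(
            [("population_vs_HSC", len(s.per_sample_values), s.median, s.iqr)],
            columns=["comparison", "n_values", "median", "iqr"])
        write_table(cohort, out / "stemness_cohort.csv", cfg, index=False)
    stages.append("stemness")


def _run_refractory(cfg: RunConfig, out: Path, stages: list[str]) -> None:
    [day0, day14], _ = scenario_refractory(cfg.seed, cfg.n_per_sample)
    spec = healthy_marrow_spec(day0.panel)
    from .synthetic import generate_sample

    marrow, _ = generate_sample(spec, "marrow", cfg.n_per_sample, cfg.seed + 1)
    stages.append("load")
    res = refractory_analysis(day0, day14, cfg, healthy_marrow=marrow)
    stages += ["embed", "islands", "gate"]
    write_table(res["abundance"], out / "abundance.csv", cfg)
    write_table(res["heatmap"], out / "median_profiles.csv", cfg)
    shifts = pd.DataFrame([(s.marker, s.delta_median) for s in res["marker_shift"]],
                          columns=["marker", "delta_median"])
    write_table(shifts, out / "marker_shift.csv", cfg, index=False)
    sd = pd.DataFrame(res["sd_ranking"], columns=["marker", "sd_across_subpops"])
    write_table(sd, out / "sd_ranking.csv", cfg, index=False)
    pers = pd.DataFrame(
        [(",".join(sorted(res["persister"])), res["persister_pre_occupancy"],
          res["persister_post_occupancy"])],
        columns=["persister_subpops", "pre_occupancy", "post_occupancy"])
    write_table(pers, out / "persistence.csv", cfg, index=False)
    stages.append("longitudinal")
    if res["distance_shift"] is not None:
        df = pd.DataFrame([(res["distance_shift"],)], columns=["mean_hsc_distance_shift"])
        write_table(df, out / "distance_shift.csv", cfg, index=False)
    stages.append("stemness")


# ---------------------------------------------------------------------------
# optional figures
# ---------------------------------------------------------------------------

def plot_contour_map(part, path: Path) -> None:
    """Shaded density contours of the map (outliers start at the lowest
    level, each further level lighter), written as PNG/SVG."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    xmin, xmax, ymin, ymax = part.grid_extent
    fig, ax = plt.subplots(figsize=(5, 5))
    levels = list(part.contour_levels) + [part.density_grid.max()]
    ax.contourf(part.density_grid.T, levels=levels, cmap="viridis",
                extent=(xmin, xmax, ymin, ymax), origin="lower")
    ax.set_xlabel("viSNE axis 1")
    ax.set_ylabel("viSNE axis 2")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
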