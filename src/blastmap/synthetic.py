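"""Seeded synthetic mass-cytometry samples with known ground truth.

The generator emulates 27-marker bone-marrow / peripheral-blood
mononuclear samples: a mixture of populations, each drawn per marker
from a truncated-at-zero normal in arcsinh space around a canonical
immunophenotype, with a small per-marker dropout probability replacing
values by near-zero noise.  Longitudinal scenarios reproduce the two
clinical archetypes the analysis is built to detect — remission (blasts
clear the marrow and blood) and refractory disease (rare "persister"
subpopulations expand at Day 14 with shifted stem-cell markers
CD34 +0.7, CD38 +0.9, CD184 +0.6 and reduced CD117/CD123).

Every scenario returns a :class:`TruthBundle` so downstream estimates
can be scored against the generating parameters without external files.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
import numpy as np
from scipy.stats import truncnorm

from .io import (DEFAULT_COFACTOR, EventMatrix, MarkerPanel, ParameterError,
                 SampleMeta)

DROPOUT_SD = 0.1

BLAST = "blast"

# diagnostic AML blast immunophenotype (arcsinh-15 units); CD34 bright,
# CD38 intermediate, myeloid antigens high, CD45 dim, HLA-DR low,
# aberrant dim CD7/CD56
_BLAST_PROFILE = {
    "CD34": 3.0, "CD38": 1.2, "CD33": 3.2, "CD13": 3.0, "CD117": 1.6,
    "CD123": 0.9, "HLA-DR": 1.0, "CD45": 1.3, "CD15": 1.0, "CD11b": 0.8,
    "CD64": 0.8, "CD71": 0.8, "CD184": 1.0, "CD56": 1.5, "CD7": 1.5,
}

# the Day-14 persister phenotype relative to the diagnostic blast:
# stem-cell markers up, LSC-associated CD117/CD123 down
PERSISTER_SHIFTS = {"CD34": +0.7, "CD38": +0.9, "CD184": +0.6,
                    "CD117": -0.8, "CD123": -0.6}

# distinguishing signatures of the 13 refractory blast subpopulations
# (none touches a marker involved in the persister shift)
_SUBPOP_SIGNATURES: dict[str, dict[str, float]] = {
    "dom1": {"CD90": +2.2},
    "dom2": {"HLA-DR": +2.5},
    "dom3": {"CD61": +2.5},
    "dom4": {"CD62L": +2.5},
    "dom5": {"CD33": -2.5},
    "dom6": {"CD15": +2.0, "CD11b": +1.8},
    "per1": {"CD56": +2.0},
    "per2": {"CD7": +2.0},
    "per3": {"CD64": +2.5},
    "per4": {"CD45RA": +2.5},
    "per5": {"CD14": +2.2, "CD11c": +1.6},
    "per6": {"CD71": +2.2, "CD16": +1.6},
    "per7": {"HLA-DR": +2.5, "CD61": +2.5},
}

# per-timepoint shares of total blasts: 6 dominant subpopulations carry
# 0.91 at diagnosis; 7 persisters are each 0.6%-1.8% at Day 0 and
# 2.3%-20% at Day 14, summing to 0.88
_REFRACTORY_DAY0 = {
    "dom1": 0.30, "dom2": 0.22, "dom3": 0.15, "dom4": 0.12, "dom5": 0.07,
    "dom6": 0.05,
    "per1": 0.018, "per2": 0.016, "per3": 0.014, "per4": 0.013,
    "per5": 0.012, "per6": 0.009, "per7": 0.008,
}
_REFRACTORY_DAY14 = {
    "dom1": 0.040, "dom2": 0.030, "dom3": 0.020, "dom4": 0.015, "dom5": 0.010,
    "dom6": 0.005,
    "per1": 0.200, "per2": 0.170, "per3": 0.150, "per4": 0.130,
    "per5": 0.110, "per6": 0.097, "per7": 0.023,
}

# remission archetype: marrow blasts 60% at diagnosis, cleared through
# blood timepoints to a 2% recovery marrow
REMISSION_TIMEPOINTS = (
    ("day0_marrow", 0, "marrow", 0.60),
    ("day2_blood", 2, "blood", 0.45),
    ("day5_blood", 5, "blood", 0.25),
    ("day8_blood", 8, "blood", 0.10),
    ("day14_marrow", 14, "marrow", 0.05),
    ("recovery_marrow", 28, "marrow", 0.02),
)

# peripheral-blood regression series
BLOOD_SERIES_TIMEPOINTS = (
    ("day0_blood", 0, "blood", 0.70),
    ("day2_blood", 2, "blood", 0.50),
    ("day5_blood", 5, "blood", 0.25),
    ("day8_blood", 8, "blood", 0.10),
    ("day14_blood", 14, "blood", 0.04),
)


@dataclass(frozen=True)
class PopulationSpec:
    name: str
    mean_expr: np.ndarray          # arcsinh units, one per marker
    sd_expr: np.ndarray
    dropout_prob: np.ndarray       # per-marker probability in [0, 1]
    abundance: dict[str, float]    # timepoint label -> fraction

    def __post_init__(self) -> None:
        for arr, what in ((self.mean_expr, "mean"), (self.sd_expr, "sd"),
                          (self.dropout_prob, "dropout")):
            a = np.asarray(arr, dtype=float)
            if not np.all(np.isfinite(a)):
                raise ParameterError(f"{what} vector must be finite")
        if np.any(np.asarray(self.sd_expr) < 0):
            raise ParameterError("sd_expr must be non-negative")
        d = np.asarray(self.dropout_prob)
        if np.any((d < 0) | (d > 1)):
            raise ParameterError("dropout_prob must lie in [0, 1]")


@dataclass(frozen=True)
class Timepoint:
    label: str
    day: int
    tissue: str


@dataclass(frozen=True)
class SyntheticSpec:
    """Declarative description of populations and timepoints."""

    panel: MarkerPanel
    populations: tuple[PopulationSpec, ...]
    timepoints: tuple[Timepoint, ...]

    def __post_init__(self) -> None:
        for tp in self.timepoints:
            total = sum(p.abundance.get(tp.label, 0.0) for p in self.populations)
            if abs(total - 1.0) > 1e-9:
                raise ParameterError(
                    f"abundances at timepoint {tp.label!r} sum to {total}, not 1"
                )

    def timepoint(self, label: str) -> Timepoint:
        for tp in self.timepoints:
            if tp.label == label:
                return tp
        raise ParameterError(f"timepoint {label!r} not in spec")

    def profile(self, name: str) -> np.ndarray:
        for p in self.populations:
            if p.name == name:
                return p.mean_expr
        raise ParameterError(f"population {name!r} not in spec")


@dataclass(frozen=True)
class TruthBundle:
    """Generator ground truth for scoring downstream estimates."""

    labels: dict[str, np.ndarray]            # sample_id -> per-event label
    profiles: dict[str, np.ndarray]          # population -> mean vector
    params: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# sampling
# ---------------------------------------------------------------------------

def generate_sample(
    spec: SyntheticSpec, timepoint: str, n: int, seed: int,
    patient_id: str = "synthetic",
) -> tuple[EventMatrix, TruthBundle]:
    """Draw one sample of ``n`` events at a timepoint, with truth labels.

    Event populations follow the timepoint's abundance distribution;
    expression is truncated-at-zero normal per marker in arcsinh space,
    with a ``dropout_prob`` chance of replacement by near-zero noise
    ``|N(0, 0.1)|``.  Deterministic for a given seed.
    """
    if n <= 0:
        raise ParameterError("n must be positive")
    tp = spec.timepoint(timepoint)
    rng = np.random.default_rng(seed)
    names = [p.name for p in spec.populations]
    probs = np.array([p.abundance.get(timepoint, 0.0) for p in spec.populations])
    counts = rng.multinomial(n, probs)
    n_markers = len(spec.panel)
    values = np.empty((n, n_markers))
    labels = np.empty(n, dtype=object)
    row = 0
    for pop, k in zip(spec.populations, counts):
        if k == 0:
            continue
        block = np.empty((k, n_markers))
        for j in range(n_markers):
            mu, sd = float(pop.mean_expr[j]), float(pop.sd_expr[j])
            if sd == 0:
                block[:, j] = mu
            else:
                a = (0.0 - mu) / sd
                block[:, j] = truncnorm.rvs(a, np.inf, loc=mu, scale=sd,
                                            size=k, random_state=rng)
            dp = float(pop.dropout_prob[j])
            if dp > 0:
                drop = rng.random(k) < dp
                if drop.any():
                    block[drop, j] = np.abs(rng.normal(0.0, DROPOUT_SD,
                                                       drop.sum()))
        values[row: row + k] = block
        labels[row: row + k] = pop.name
        row += k
    # shuffle so event order carries no population information
    perm = rng.permutation(n)
    values, labels = values[perm], labels[perm]
    m = EventMatrix(
        values=values, panel=spec.panel, scale="arcsinh",
        cofactor=DEFAULT_COFACTOR,
        sample_meta=SampleMeta(patient_id=patient_id, tissue=tp.tissue,
                               day=tp.day, sample_id=timepoint),
    )
    truth = TruthBundle(
        labels={timepoint: labels},
        profiles={p.name: p.mean_expr for p in spec.populations},
        params={"abundance": {p.name: p.abundance.get(timepoint, 0.0)
                              for p in spec.populations}},
    )
    return m, truth


# ---------------------------------------------------------------------------
# canonical specs
# ---------------------------------------------------------------------------

def _data_path(name: str):
    return resources.files("blastmap").joinpath("data", name)


def default_panel() -> MarkerPanel:
    """The 27-antibody AML immunophenotyping panel (editable CSV fixture)."""
    with resources.as_file(_data_path("panel.csv")) as p:
        return MarkerPanel.from_csv(p)


def _load_healthy_profiles(panel: MarkerPanel):
    rows = []
    with resources.as_file(_data_path("healthy_marrow_profiles.csv")) as p:
        with open(p, newline="") as fh:
            for row in csv.DictReader(fh):
                rows.append(row)
    pops = []
    for row in rows:
        mean = np.array([float(row[nm]) for nm in panel.names])
        pops.append((row["population"], float(row["abundance"]),
                     float(row["sd"]), float(row["dropout"]), mean))
    return pops


def healthy_marrow_spec(panel: MarkerPanel | None = None) -> SyntheticSpec:
    """Healthy bone-marrow mononuclear mixture: 9 canonical populations.

    HSC (CD34+ CD38lo), early progenitors (CD34+ CD38+, nearest HSC and
    with the largest dispersion — the most heterogeneous population),
    maturing myeloid, monocytes, dendritic cells, NK, CD4+/CD8+ T and B
    cells.  Profiles live in an editable CSV fixture.
    """
    panel = panel or default_panel()
    n_mk = len(panel)
    pops = []
    for name, ab, sd, do, mean in _load_healthy_profiles(panel):
        pops.append(PopulationSpec(
            name=name, mean_expr=mean,
            sd_expr=np.full(n_mk, sd),
            dropout_prob=np.full(n_mk, do),
            abundance={"marrow": ab},
        ))
    return SyntheticSpec(
        panel=panel, populations=tuple(pops),
        timepoints=(Timepoint("marrow", 0, "marrow"),),
    )


def blast_profile(panel: MarkerPanel | None = None,
                  signature: dict[str, float] | None = None,
                  persister: bool = False) -> np.ndarray:
    """Diagnostic blast profile, optionally persister-shifted/signed."""
    panel = panel or default_panel()
    vec = np.full(len(panel), 0.1)
    prof = dict(_BLAST_PROFILE)
    if persister:
        for mk, dv in PERSISTER_SHIFTS.items():
            prof[mk] = prof.get(mk, 0.1) + dv
    for mk, v in prof.items():
        vec[panel.index(mk)] = v
    for mk, dv in (signature or {}).items():
        vec[panel.index(mk)] = max(vec[panel.index(mk)] + dv, 0.05)
    return vec


# ---------------------------------------------------------------------------
# longitudinal scenarios
# ---------------------------------------------------------------------------

def _mixture_spec(panel: MarkerPanel, timepoints, blast_sd=0.35,
                  blast_profile_vec=None) -> SyntheticSpec:
    """Healthy background + one blast population with per-timepoint fractions."""
    n_mk = len(panel)
    healthy = _load_healthy_profiles(panel)
    tps = tuple(Timepoint(lbl, day, tissue) for lbl, day, tissue, _ in timepoints)
    blast_frac = {lbl: bf for lbl, _, _, bf in timepoints}
    pops = []
    for name, ab, sd, do, mean in healthy:
        pops.append(PopulationSpec(
            name=name, mean_expr=mean, sd_expr=np.full(n_mk, sd),
            dropout_prob=np.full(n_mk, do),
            abundance={lbl: ab * (1.0 - bf) for lbl, bf in blast_frac.items()},
        ))
    bvec = blast_profile_vec if blast_profile_vec is not None else blast_profile(panel)
    pops.append(PopulationSpec(
        name=BLAST, mean_expr=bvec, sd_expr=np.full(n_mk, blast_sd),
        dropout_prob=np.full(n_mk, 0.03),
        abundance=dict(blast_frac),
    ))
    return SyntheticSpec(panel=panel, populations=tuple(pops), timepoints=tps)


def _series(spec: SyntheticSpec, timepoints, n_per_sample, seed, patient_id):
    rng = np.random.default_rng(seed)
    samples, labels = [], {}
    for lbl, _, _, _ in timepoints:
        m, truth = generate_sample(spec, lbl, n_per_sample,
                                   int(rng.integers(2 ** 31)), patient_id)
        samples.append(m)
        labels[lbl] = truth.labels[lbl]
    return samples, labels


def scenario_remission(
    seed: int, n_per_sample: int = 3000, panel: MarkerPanel | None = None
) -> tuple[list[EventMatrix], TruthBundle]:
    """Marrow/blood series of a patient whose induction clears the blasts.

    Day 0 marrow is 60% blast; blood blasts decline over Days 2-8; the
    Day 14 marrow is 5% and the recovery marrow 2% blast with healthy
    populations restored.
    """
    panel = panel or default_panel()
    spec = _mixture_spec(panel, REMISSION_TIMEPOINTS)
    samples, labels = _series(spec, REMISSION_TIMEPOINTS, n_per_sample, seed,
                              "remission_patient")
    truth = TruthBundle(
        labels=labels,
        profiles={p.name: p.mean_expr for p in spec.populations},
        params={"blast_fraction": {lbl: bf for lbl, _, _, bf in REMISSION_TIMEPOINTS}},
    )
    return samples, truth


def scenario_blood_series(
    seed: int, n_per_sample: int = 3000, panel: MarkerPanel | None = None
) -> tuple[list[EventMatrix], TruthBundle]:
    """Peripheral-blood series with blasts regressing from 70% to 4%."""
    panel = panel or default_panel()
    spec = _mixture_spec(panel, BLOOD_SERIES_TIMEPOINTS)
    samples, labels = _series(spec, BLOOD_SERIES_TIMEPOINTS, n_per_sample, seed,
                              "blood_patient")
    truth = TruthBundle(
        labels=labels,
        profiles={p.name: p.mean_expr for p in spec.populations},
        params={"blast_fraction": {lbl: bf for lbl, _, _, bf in
                                   BLOOD_SERIES_TIMEPOINTS}},
    )
    return samples, truth


def refractory_spec(panel: MarkerPanel | None = None,
                    subpop_sd: float = 0.3) -> SyntheticSpec:
    """13 blast subpopulations of a refractory patient (Day 0 / Day 14).

    Six dominant subpopulations carry 91% of diagnostic blasts; seven
    persisters (0.6-1.8% each at Day 0) expand to 2.3-20% each at
    Day 14, together 88%.  Persister profiles carry the canonical
    stem-marker shifts and so lie farther from the HSC immunophenotype
    than the diagnostic blasts.
    """
    panel = panel or default_panel()
    n_mk = len(panel)
    pops = []
    for name, sig in _SUBPOP_SIGNATURES.items():
        vec = blast_profile(panel, signature=sig,
                            persister=name.startswith("per"))
        pops.append(PopulationSpec(
            name=name, mean_expr=vec, sd_expr=np.full(n_mk, subpop_sd),
            dropout_prob=np.full(n_mk, 0.02),
            abundance={"day0": _REFRACTORY_DAY0[name],
                       "day14": _REFRACTORY_DAY14[name]},
        ))
    return SyntheticSpec(
        panel=panel, populations=tuple(pops),
        timepoints=(Timepoint("day0", 0, "marrow"),
                    Timepoint("day14", 14, "marrow")),
    )


def scenario_refractory(
    seed: int, n_blasts: int = 5000, panel: MarkerPanel | None = None
) -> tuple[list[EventMatrix], TruthBundle]:
    """Day 0 and Day 14 gated-blast samples of the refractory archetype."""
    panel = panel or default_panel()
    spec = refractory_spec(panel)
    rng = np.random.default_rng(seed)
    day0, t0 = generate_sample(spec, "day0", n_blasts,
                               int(rng.integers(2 ** 31)), "refractory_patient")
    day14, t14 = generate_sample(spec, "day14", n_blasts,
                                 int(rng.integers(2 ** 31)), "refractory_patient")
    persisters = sorted(n for n in _SUBPOP_SIGNATURES if n.startswith("per"))
    truth = TruthBundle(
        labels={"day0": t0.labels["day0"], "day14": t14.labels["day14"]},
        profiles={p.name: p.mean_expr for p in spec.populations},
        params={
            "abundance_day0": dict(_REFRACTORY_DAY0),
            "abundance_day14": dict(_REFRACTORY_DAY14),
            "persisters": persisters,
            "marker_shifts": dict(PERSISTER_SHIFTS),
        },
    )
    return [day0, day14], truth
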