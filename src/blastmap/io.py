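"""Reading, writing and preprocessing of event-level mass-cytometry data.

Event data live in an :class:`EventMatrix` (events x markers) on either the
raw ion-count scale or the log-like ``arcsinh(x / cofactor)`` scale that is
standard for mass cytometry (cofactor 15 by default).  Files are read from
FCS 3.0/3.1 (list mode, float data) or from plain CSV with a marker-name
header; the marker panel itself is a small CSV table.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Sequence

import numpy as np

logger = logging.getLogger(__name__)

DEFAULT_COFACTOR = 15.0
DEFAULT_SUBSAMPLE_N = 5000


# ---------------------------------------------------------------------------
# errors
# ---------------------------------------------------------------------------

class BlastmapError(Exception):
    """Base class for all package errors."""


class PanelMismatchError(BlastmapError):
    """A required marker/channel could not be resolved in a file or panel."""


class FormatError(BlastmapError):
    """A file could not be parsed in the declared format."""


class ScaleStateError(BlastmapError):
    """An operation was applied to data on the wrong intensity scale."""


class ParameterError(BlastmapError, ValueError):
    """An argument is outside its admissible range."""


class DataError(BlastmapError):
    """Input values violate an invariant (NaN, negative raw counts...)."""


# ---------------------------------------------------------------------------
# marker panel
# ---------------------------------------------------------------------------

class MarkerCategory(str, Enum):
    BLAST_ID = "blast_id"
    LINEAGE = "lineage"
    OTHER = "other"


@dataclass(frozen=True)
class Marker:
    name: str
    channel_id: str
    category: MarkerCategory


@dataclass(frozen=True)
class MarkerPanel:
    """Ordered antibody panel: marker name, mass channel and category."""

    markers: tuple[Marker, ...]

    def __post_init__(self) -> None:
        if not self.markers:
            raise ParameterError("panel must contain at least one marker")
        names = [m.name for m in self.markers]
        if len(set(names)) != len(names):
            raise ParameterError("marker names must be unique")

    def __len__(self) -> int:
        return len(self.markers)

    @property
    def names(self) -> list[str]:
        return [m.name for m in self.markers]

    def index(self, name: str) -> int:
        for i, m in enumerate(self.markers):
            if m.name == name:
                return i
        raise PanelMismatchError(f"marker {name!r} not in panel")

    @classmethod
    def from_csv(cls, path: str | Path) -> "MarkerPanel":
        markers = []
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh):
                markers.append(
                    Marker(
                        name=row["marker_name"].strip(),
                        channel_id=row["channel_id"].strip(),
                        category=MarkerCategory(row["category"].strip()),
                    )
                )
        return cls(tuple(markers))

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["marker_name", "channel_id", "category"])
            for m in self.markers:
                w.writerow([m.name, m.channel_id, m.category.value])


# ---------------------------------------------------------------------------
# event matrix
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SampleMeta:
    patient_id: str = "unknown"
    tissue: str = "marrow"  # "blood" | "marrow"
    day: int = 0
    induction_round: int = 1
    sample_id: str = ""

    def __post_init__(self) -> None:
        if self.tissue not in ("blood", "marrow"):
            raise ParameterError(f"tissue must be blood|marrow, got {self.tissue!r}")
        if self.day < 0 or self.induction_round < 1:
            raise ParameterError("day must be >= 0 and induction_round >= 1")


@dataclass(frozen=True)
class EventMatrix:
    """Events x markers expression table with scale bookkeeping.

    ``scale`` is ``"raw"`` (non-negative ion counts) or ``"arcsinh"``
    (``asinh(raw / cofactor)``); ``labels``, when present, holds one
    population name per event.
    """

    values: np.ndarray
    panel: MarkerPanel
    scale: str = "raw"
    cofactor: float | None = None
    sample_meta: SampleMeta = field(default_factory=SampleMeta)
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        object.__setattr__(self, "values", v)
        if v.ndim != 2:
            raise DataError("values must be a 2-D events x markers matrix")
        if v.shape[1] != len(self.panel):
            raise DataError(
                f"matrix has {v.shape[1]} columns but panel has {len(self.panel)} markers"
            )
        if self.scale not in ("raw", "arcsinh"):
            raise ParameterError(f"unknown scale {self.scale!r}")
        if not np.all(np.isfinite(v)):
            raise DataError("expression values must be finite")
        if self.labels is not None:
            lab = np.asarray(self.labels, dtype=object)
            if lab.shape[0] != v.shape[0]:
                raise DataError("labels length must equal event count")
            object.__setattr__(self, "labels", lab)

    @property
    def n_events(self) -> int:
        return self.values.shape[0]

    def column(self, marker: str) -> np.ndarray:
        return self.values[:, self.panel.index(marker)]

    def take(self, idx: np.ndarray) -> "EventMatrix":
        """Row subset preserving metadata (and labels, when present)."""
        lab = None if self.labels is None else self.labels[idx]
        return replace(self, values=self.values[idx], labels=lab)


def pool_samples(samples: Sequence[EventMatrix]) -> tuple[EventMatrix, np.ndarray]:
    """Vertically concatenate samples sharing one panel and scale.

    Returns the pooled matrix and a per-event integer giving the index of
    the source sample, which downstream co-embedding keeps track of.
    """
    if not samples:
        raise ParameterError("no samples to pool")
    first = samples[0]
    for s in samples[1:]:
        if s.panel.names != first.panel.names:
            raise PanelMismatchError("samples use different panels")
        if s.scale != first.scale:
            raise ScaleStateError("samples are on different scales")
    values = np.vstack([s.values for s in samples])
    source = np.concatenate(
        [np.full(s.n_events, i, dtype=np.int64) for i, s in enumerate(samples)]
    )
    if all(s.labels is not None for s in samples):
        labels = np.concatenate([s.labels for s in samples])
    else:
        labels = None
    pooled = EventMatrix(
        values=values,
        panel=first.panel,
        scale=first.scale,
        cofactor=first.cofactor,
        sample_meta=replace(first.sample_meta, sample_id="pooled"),
        labels=labels,
    )
    return pooled, source


# ---------------------------------------------------------------------------
# arcsinh transform
# ---------------------------------------------------------------------------

def arcsinh_transform(m: EventMatrix, cofactor: float = DEFAULT_COFACTOR) -> EventMatrix:
    """Apply the element-wise ``asinh(x / cofactor)`` transform.

    The transform is the standard variance-stabilising, log-like scaling
    for mass cytometry.  It is strictly monotone, so per-marker rank order
    of events is preserved.  Re-transforming an already transformed matrix
    is refused.
    """
    if cofactor <= 0:
        raise ParameterError(f"cofactor must be positive, got {cofactor}")
    if m.scale != "raw":
        raise ScaleStateError("matrix is already on the arcsinh scale")
    return replace(m, values=np.arcsinh(m.values / cofactor), scale="arcsinh",
                   cofactor=float(cofactor))


def inverse_arcsinh(m: EventMatrix) -> EventMatrix:
    """Recover raw-scale intensities: ``sinh(x) * cofactor``."""
    if m.scale != "arcsinh":
        raise ScaleStateError("matrix is not on the arcsinh scale")
    if m.cofactor is None:
        raise ScaleStateError("matrix does not record its cofactor")
    return replace(m, values=np.sinh(m.values) * m.cofactor, scale="raw")


# ---------------------------------------------------------------------------
# equal-count subsampling
# ---------------------------------------------------------------------------

def subsample_equal(
    samples: Sequence[EventMatrix], target_n: int = DEFAULT_SUBSAMPLE_N, seed: int = 0
) -> list[EventMatrix]:
    """Randomly sample the same number of events from each file.

    Each sample with at least ``target_n`` events is reduced to exactly
    ``target_n`` events drawn without replacement; a sample with fewer
    events is kept whole (small files are used in full).  Row order within
    each sample is preserved and the draw is deterministic for a seed.
    """
    if target_n <= 0:
        raise ParameterError(f"target_n must be positive, got {target_n}")
    if not samples:
        raise ParameterError("no samples given")
    rng = np.random.default_rng(seed)
    out = []
    for s in samples:
        if s.n_events <= target_n:
            out.append(s)
        else:
            idx = np.sort(rng.choice(s.n_events, size=target_n, replace=False))
            out.append(s.take(idx))
    return out


# ---------------------------------------------------------------------------
# CSV read/write
# ---------------------------------------------------------------------------

def write_csv(m: EventMatrix, path: str | Path) -> None:
    """Write events as CSV with a header row of marker names."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(m.panel.names)
        for row in m.values:
            w.writerow([repr(float(x)) for x in row])


def _read_csv_events(path: Path, panel: MarkerPanel) -> np.ndarray:
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise FormatError(f"{path}: empty CSV") from None
        header = [h.strip() for h in header]
        col_of: dict[str, int] = {}
        for mk in panel.markers:
            if mk.name in header:
                col_of[mk.name] = header.index(mk.name)
            elif mk.channel_id in header:
                col_of[mk.name] = header.index(mk.channel_id)
            else:
                raise PanelMismatchError(
                    f"panel mismatch: channel {mk.name!r} absent from {path}"
                )
        rows = []
        for row in reader:
            if not row:
                continue
            try:
                rows.append([float(row[col_of[n]]) for n in panel.names])
            except (ValueError, IndexError) as exc:
                raise FormatError(f"{path}: unparseable CSV row: {row!r}") from exc
    return np.asarray(rows, dtype=np.float64).reshape(len(rows), len(panel))


# ---------------------------------------------------------------------------
# FCS 3.1 read/write (list mode, float32)
# ---------------------------------------------------------------------------
# Minimal but standard-conformant subset: HEADER + primary TEXT segment with
# '/' delimiter, $DATATYPE F or D, $MODE L, little- or big-endian $BYTEORD.
# Channel resolution prefers $PnS (stain = marker name), falling back to
# $PnN (short channel name).

_FCS_DELIM = "/"


def write_fcs(m: EventMatrix, path: str | Path) -> None:
    """Write an FCS 3.1 file (list mode, float32 data segment)."""
    n_par = len(m.panel)
    n_tot = m.n_events
    data = np.asarray(m.values, dtype="<f4").tobytes(order="C")

    def text_segment(begin_data: int, end_data: int) -> bytes:
        pairs = [
            ("$BEGINANALYSIS", "0"), ("$ENDANALYSIS", "0"),
            ("$BEGINSTEXT", "0"), ("$ENDSTEXT", "0"),
            ("$BEGINDATA", str(begin_data)), ("$ENDDATA", str(end_data)),
            ("$BYTEORD", "1,2,3,4"), ("$DATATYPE", "F"),
            ("$MODE", "L"), ("$NEXTDATA", "0"),
            ("$TOT", str(n_tot)), ("$PAR", str(n_par)),
        ]
        for i, mk in enumerate(m.panel.markers, start=1):
            pairs += [
                (f"$P{i}N", mk.channel_id), (f"$P{i}S", mk.name),
                (f"$P{i}B", "32"), (f"$P{i}E", "0,0"), (f"$P{i}R", "262144"),
            ]
        body = _FCS_DELIM + _FCS_DELIM.join(f"{k}{_FCS_DELIM}{v}" for k, v in pairs) + _FCS_DELIM
        return body.encode("ascii")

    # offsets depend on TEXT length; digit widths are padded stable by
    # computing with generous placeholders first
    text = text_segment(10 ** 9, 10 ** 9)
    text_begin = 58
    text_end = text_begin + len(text) - 1
    data_begin = text_end + 1
    data_end = data_begin + len(data) - 1
    text2 = text_segment(data_begin, data_end)
    while len(text2) != len(text):  # re-pad if offset digit count changed
        text = text2
        text_end = text_begin + len(text) - 1
        data_begin = text_end + 1
        data_end = data_begin + len(data) - 1
        text2 = text_segment(data_begin, data_end)

    header = b"FCS3.1    " + b"".join(
        f"{v:>8d}".encode("ascii")
        for v in (text_begin, text_end, data_begin, data_end, 0, 0)
    )
    assert len(header) == 58
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(text2)
        fh.write(data)


def _parse_fcs_text(raw: bytes) -> dict[str, str]:
    try:
        txt = raw.decode("latin-1")
    except UnicodeDecodeError as exc:  # pragma: no cover - latin-1 never fails
        raise FormatError("undecodable TEXT segment") from exc
    if not txt:
        raise FormatError("empty TEXT segment")
    delim = txt[0]
    # delimiter escaping (doubled delimiters) is not used by this writer;
    # split directly and tolerate a trailing delimiter
    parts = txt.strip(delim).split(delim)
    if len(parts) % 2 == 1:
        parts = parts[:-1]
    return {parts[i].strip(): parts[i + 1] for i in range(0, len(parts), 2)}


def read_fcs(path: str | Path, panel: MarkerPanel) -> np.ndarray:
    """Read the primary data segment of an FCS 3.0/3.1 file.

    Returns the event matrix with columns ordered per ``panel``.
    """
    path = Path(path)
    with open(path, "rb") as fh:
        blob = fh.read()
    if len(blob) < 58 or not blob[:6].startswith(b"FCS3"):
        raise FormatError(f"{path}: not an FCS 3.x file")
    try:
        offs = [int(blob[10 + 8 * i: 18 + 8 * i]) for i in range(4)]
    except ValueError as exc:
        raise FormatError(f"{path}: malformed FCS header offsets") from exc
    text_begin, text_end, data_begin, data_end = offs
    kw = _parse_fcs_text(blob[text_begin: text_end + 1])
    if data_begin == 0:
        data_begin = int(kw.get("$BEGINDATA", 0))
        data_end = int(kw.get("$ENDDATA", 0))
    try:
        n_tot = int(kw["$TOT"])
        n_par = int(kw["$PAR"])
        datatype = kw["$DATATYPE"].strip().upper()
        byteord = kw["$BYTEORD"].strip()
    except KeyError as exc:
        raise FormatError(f"{path}: missing required FCS keyword {exc}") from exc
    if kw.get("$MODE", "L").strip().upper() != "L":
        raise FormatError(f"{path}: only list-mode FCS is supported")
    if datatype not in ("F", "D"):
        raise FormatError(f"{path}: unsupported $DATATYPE {datatype!r}")
    endian = "<" if byteord.startswith("1") else ">"
    itemsize = 4 if datatype == "F" else 8
    expected = n_tot * n_par * itemsize
    raw = blob[data_begin: data_begin + expected]
    if len(raw) < expected:
        raise FormatError(f"{path}: truncated data segment")
    arr = np.frombuffer(raw, dtype=f"{endian}f{itemsize}").reshape(n_tot, n_par)

    # resolve panel markers against $PnS (stain) then $PnN (short name)
    short = [kw.get(f"$P{i}N", "").strip() for i in range(1, n_par + 1)]
    stain = [kw.get(f"$P{i}S", "").strip() for i in range(1, n_par + 1)]
    cols = []
    for mk in panel.markers:
        if mk.name in stain:
            cols.append(stain.index(mk.name))
        elif mk.channel_id in short:
            cols.append(short.index(mk.channel_id))
        elif mk.name in short:
            cols.append(short.index(mk.name))
        else:
            raise PanelMismatchError(
                f"panel mismatch: channel {mk.name!r} absent from {path}"
            )
    return np.asarray(arr[:, cols], dtype=np.float64)


# ---------------------------------------------------------------------------
# unified entry point
# ---------------------------------------------------------------------------

def read_events(
    path: str | Path,
    panel: MarkerPanel,
    format: str | None = None,
    sample_meta: SampleMeta | None = None,
) -> EventMatrix:
    """Read an event file (FCS or CSV) as a raw-scale :class:`EventMatrix`.

    ``format`` defaults to the file suffix (``.fcs`` / ``.csv``).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = path.suffix.lstrip(".").lower()
    if format == "fcs":
        values = read_fcs(path, panel)
    elif format == "csv":
        values = _read_csv_events(path, panel)
    else:
        raise ParameterError(f"unknown format {format!r} (expected fcs or csv)")
    return EventMatrix(
        values=values,
        panel=panel,
        scale="raw",
        sample_meta=sample_meta or SampleMeta(sample_id=path.stem),
    )
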