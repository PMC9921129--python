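"""Plain-text I/O for chromatogram traces, peak tables and analyte libraries.

Traces are two-column CSV (``time_min,intensity``) with optional ``#``-prefixed
metadata lines of the form ``# key: value``.  Peak tables are TSV.  Analyte
libraries are packaged TSV fixtures carrying, per column, the expected
retention time, calculated/literature retention indices, enantiomer-group
membership, internal-standard flag and calibration range of every analyte.

All readers reject malformed input (with a line number where applicable)
rather than silently coercing it; all writers emit files their own readers
accept losslessly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "Chromatogram",
    "Peak",
    "PeakTable",
    "LibraryEntry",
    "AnalyteLibrary",
    "TraceFormatError",
    "LibraryError",
    "read_trace",
    "write_trace",
    "read_peak_table",
    "write_peak_table",
    "load_library",
    "load_default_library",
]

#: Relative tolerance on the uniformity of the time axis.
_SPACING_RTOL = 1e-6


class TraceFormatError(ValueError):
    """Raised when a trace file violates the two-column text format."""


class LibraryError(ValueError):
    """Raised when an analyte-library file violates its invariants."""


@dataclass
class Chromatogram:
    """A uniformly sampled time (minutes) vs detector-intensity trace."""

    time: np.ndarray
    intensity: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.time.ndim != 1 or self.intensity.ndim != 1:
            raise TraceFormatError("time and intensity must be 1-D vectors")
        if self.time.size != self.intensity.size:
            raise TraceFormatError(
                f"length mismatch: {self.time.size} time stamps vs "
                f"{self.intensity.size} intensities"
            )
        if self.time.size < 2:
            raise TraceFormatError("a trace needs at least two samples")
        if not (np.isfinite(self.time).all() and np.isfinite(self.intensity).all()):
            raise TraceFormatError("trace contains non-finite values")
        dt = np.diff(self.time)
        if np.any(dt <= 0):
            bad = int(np.argmax(dt <= 0)) + 2
            raise TraceFormatError(f"time stamps not strictly increasing at row {bad}")
        mean_dt = float(dt.mean())
        if np.max(np.abs(dt - mean_dt)) > _SPACING_RTOL * mean_dt:
            raise TraceFormatError("time axis is not uniformly spaced (1 ppm tolerance)")

    @property
    def n_points(self) -> int:
        return int(self.time.size)

    @property
    def sampling_interval(self) -> float:
        """Sample spacing in minutes."""
        return float(self.time[1] - self.time[0])


@dataclass
class Peak:
    """One integrated chromatographic feature.

    ``area`` is the baseline-corrected trapezoid area in intensity·minutes —
    the peak area (PA) used for internal-standard ratios and for the
    enantiomeric-excess computation.  ``fwhm`` is the half-height width used
    by the Ph. Eur. resolution formula.
    """

    apex_time: float
    height: float = 0.0
    area: float = 0.0
    fwhm: float = 0.0
    start_time: float = math.nan
    end_time: float = math.nan
    snr: float = math.inf
    assigned_analyte: str | None = None
    ambiguous: bool = False


@dataclass
class PeakTable:
    """Peaks from one chromatogram, sorted by apex time."""

    peaks: list[Peak]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.peaks = sorted(self.peaks, key=lambda p: p.apex_time)

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self):
        return iter(self.peaks)

    def get(self, analyte: str) -> Peak | None:
        """Return the peak assigned to *analyte*, or None."""
        for p in self.peaks:
            if p.assigned_analyte == analyte:
                return p
        return None

    @property
    def assigned(self) -> list[Peak]:
        return [p for p in self.peaks if p.assigned_analyte is not None]

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {
                "apex_min": p.apex_time,
                "height": p.height,
                "area": p.area,
                "fwhm_min": p.fwhm,
                "start_min": p.start_time,
                "end_min": p.end_time,
                "snr": p.snr,
                "analyte": p.assigned_analyte if p.assigned_analyte is not None else "",
            }
            for p in self.peaks
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "apex_min",
                "height",
                "area",
                "fwhm_min",
                "start_min",
                "end_min",
                "snr",
                "analyte",
            ],
        )


def write_trace(chrom: Chromatogram, path: str | Path) -> None:
    """Write *chrom* as ``time_min,intensity`` CSV with ``# key: value`` header lines."""
    path = Path(path)
    with path.open("w") as fh:
        for key, value in chrom.metadata.items():
            fh.write(f"# {key}: {value}\n")
        fh.write("time_min,intensity\n")
        for t, y in zip(chrom.time, chrom.intensity):
            # shortest repr that round-trips float64 exactly
            fh.write(f"{float(t)!r},{float(y)!r}\n")


def read_trace(path: str | Path) -> Chromatogram:
    """Read a two-column trace file written by :func:`write_trace`."""
    path = Path(path)
    metadata: dict = {}
    times: list[float] = []
    values: list[float] = []
    header_seen = False
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if ":" in body:
                    key, _, value = body.partition(":")
                    metadata[key.strip()] = value.strip()
                continue
            if not header_seen:
                cols = [c.strip() for c in line.split(",")]
                if cols != ["time_min", "intensity"]:
                    raise TraceFormatError(
                        f"{path}:{lineno}: expected header 'time_min,intensity', got {line!r}"
                    )
                header_seen = True
                continue
            cells = line.split(",")
            if len(cells) != 2:
                raise TraceFormatError(f"{path}:{lineno}: expected 2 columns, got {len(cells)}")
            try:
                times.append(float(cells[0]))
                values.append(float(cells[1]))
            except ValueError as exc:
                raise TraceFormatError(f"{path}:{lineno}: non-numeric cell ({exc})") from None
    if not header_seen:
        raise TraceFormatError(f"{path}: missing 'time_min,intensity' header")
    try:
        return Chromatogram(np.array(times), np.array(values), metadata)
    except TraceFormatError as exc:
        raise TraceFormatError(f"{path}: {exc}") from None


def write_peak_table(table: PeakTable, path: str | Path) -> None:
    path = Path(path)
    df = table.to_dataframe()
    with path.open("w") as fh:
        for key, value in table.metadata.items():
            fh.write(f"# {key}: {value}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.10g")


def read_peak_table(path: str | Path) -> PeakTable:
    path = Path(path)
    metadata: dict = {}
    with path.open() as fh:
        lines = fh.readlines()
    body_start = 0
    for i, line in enumerate(lines):
        if line.startswith("#"):
            text = line.lstrip("#").strip()
            if ":" in text:
                key, _, value = text.partition(":")
                metadata[key.strip()] = value.strip()
            body_start = i + 1
        else:
            break
    df = pd.read_csv(path, sep="\t", skiprows=body_start)
    peaks = [
        Peak(
            apex_time=float(r.apex_min),
            height=float(r.height),
            area=float(r.area),
            fwhm=float(r.fwhm_min),
            start_time=float(r.start_min),
            end_time=float(r.end_min),
            snr=float(r.snr),
            assigned_analyte=(None if pd.isna(r.analyte) or r.analyte == "" else str(r.analyte)),
        )
        for r in df.itertuples()
    ]
    return PeakTable(peaks, metadata)


@dataclass(frozen=True)
class LibraryEntry:
    """One analyte on one column."""

    name: str
    compound: str
    column_id: str
    rt_min: float
    ri_cal: float | None = None
    ri_lit: float | None = None
    enantiomer_group: str | None = None
    elution_rank: int | None = None
    is_internal_standard: bool = False
    range_low: float | None = None
    range_high: float | None = None


@dataclass
class AnalyteLibrary:
    """Per-column expected retention times and analyte annotations."""

    entries: list[LibraryEntry]

    def __post_init__(self) -> None:
        seen: set[tuple[str, str]] = set()
        for e in self.entries:
            key = (e.name, e.column_id)
            if key in seen:
                raise LibraryError(f"duplicate library entry {key}")
            seen.add(key)
        for column in self.columns():
            standards = [e for e in self.entries_for(column) if e.is_internal_standard]
            if len(standards) != 1:
                raise LibraryError(
                    f"column {column!r} must declare exactly one internal standard, "
                    f"found {len(standards)}"
                )
            for group, members in self.groups(column).items():
                ranks = [e.elution_rank for e in members]
                if sorted(ranks) != list(range(1, len(members) + 1)):
                    raise LibraryError(
                        f"group {group!r} on {column!r}: elution ranks must be 1..k, got {ranks}"
                    )
                rts = [e.rt_min for e in members]
                if len(set(rts)) != len(rts):
                    raise LibraryError(f"group {group!r} on {column!r}: duplicate retention times")

    def columns(self) -> list[str]:
        out: list[str] = []
        for e in self.entries:
            if e.column_id not in out:
                out.append(e.column_id)
        return out

    def entries_for(self, column_id: str) -> list[LibraryEntry]:
        sub = [e for e in self.entries if e.column_id == column_id]
        if not sub:
            raise LibraryError(f"no library entries for column {column_id!r}")
        return sorted(sub, key=lambda e: e.rt_min)

    def internal_standard(self, column_id: str) -> LibraryEntry:
        for e in self.entries_for(column_id):
            if e.is_internal_standard:
                return e
        raise LibraryError(f"no internal standard for column {column_id!r}")

    def groups(self, column_id: str) -> dict[str, list[LibraryEntry]]:
        """Enantiomer/diastereomer groups, members sorted by elution rank."""
        out: dict[str, list[LibraryEntry]] = {}
        for e in self.entries:
            if e.column_id == column_id and e.enantiomer_group:
                out.setdefault(e.enantiomer_group, []).append(e)
        for members in out.values():
            members.sort(key=lambda e: e.elution_rank or 0)
        return out

    def compounds(self, column_id: str) -> dict[str, list[LibraryEntry]]:
        """Map compound key -> library entries (isomers in elution order)."""
        out: dict[str, list[LibraryEntry]] = {}
        for e in self.entries_for(column_id):
            out.setdefault(e.compound, []).append(e)
        return out

    def entry(self, name: str, column_id: str) -> LibraryEntry:
        for e in self.entries:
            if e.name == name and e.column_id == column_id:
                return e
        raise LibraryError(f"analyte {name!r} not in library for column {column_id!r}")


def _opt_float(value) -> float | None:
    if value is None or (isinstance(value, float) and math.isnan(value)) or value == "":
        return None
    return float(value)


def load_library(path: str | Path) -> AnalyteLibrary:
    """Load an analyte library from delimited text (one row per analyte per column)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {
        "compound",
        "name",
        "column_id",
        "rt_min",
        "ri_cal",
        "ri_lit",
        "enantiomer_group",
        "elution_rank",
        "is_internal_standard",
        "range_low_mg_ml",
        "range_high_mg_ml",
    }
    missing = required - set(df.columns)
    if missing:
        raise LibraryError(f"{path}: missing columns {sorted(missing)}")
    entries = []
    for r in df.itertuples():
        entries.append(
            LibraryEntry(
                name=r.name,
                compound=r.compound,
                column_id=r.column_id,
                rt_min=float(r.rt_min),
                ri_cal=_opt_float(r.ri_cal),
                ri_lit=_opt_float(r.ri_lit),
                enantiomer_group=r.enantiomer_group or None,
                elution_rank=(int(r.elution_rank) if r.elution_rank else None),
                is_internal_standard=bool(int(r.is_internal_standard)),
                range_low=_opt_float(r.range_low_mg_ml),
                range_high=_opt_float(r.range_high_mg_ml),
            )
        )
    return AnalyteLibrary(entries)


def load_default_library(column_id: str) -> AnalyteLibrary:
    """Load the packaged library fixture for ``polar_wax`` or ``chiral_cd``."""
    if column_id not in ("polar_wax", "chiral_cd"):
        raise LibraryError(
            f"unknown column {column_id!r}; packaged libraries: polar_wax, chiral_cd"
        )
    ref = resources.files("rosegc.data").joinpath(f"{column_id}.tsv")
    with resources.as_file(ref) as p:
        return load_library(p)
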