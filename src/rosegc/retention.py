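"""Temperature-programmed retention indices from an n-alkane ladder.

The van den Dool–Kratz index interpolates linearly in retention time between
the two bracketing alkane rungs:

    RI(t) = 100·n + 100·(n' − n)·(t − t_n)/(t_n' − t_n)

for consecutive rungs (n, t_n) and (n', t_n').  The logarithmic (isothermal
Kovats) variant is deliberately not implemented: both runs of this method
are temperature-programmed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import AnalyteLibrary, PeakTable

__all__ = [
    "AlkaneLadder",
    "AnalyteAnnotation",
    "compute_retention_index",
    "annotate_ri",
]


@dataclass
class AlkaneLadder:
    """(carbon number, retention time) rungs of a homologous alkane series."""

    rungs: list[tuple[int, float]]
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.rungs) < 2:
            raise ValueError("a ladder needs at least two rungs")
        carbons = [c for c, _ in self.rungs]
        rts = [t for _, t in self.rungs]
        if any(b <= a for a, b in zip(carbons, carbons[1:])):
            raise ValueError("carbon numbers must be strictly increasing")
        if any(b <= a for a, b in zip(rts, rts[1:])):
            raise ValueError("ladder retention times must be strictly increasing")

    @property
    def carbons(self) -> np.ndarray:
        return np.array([c for c, _ in self.rungs], dtype=float)

    @property
    def retention_times(self) -> np.ndarray:
        return np.array([t for _, t in self.rungs], dtype=float)

    def thin(self, step: int = 2) -> "AlkaneLadder":
        """Keep every *step*-th rung (always keeping the last one)."""
        rungs = self.rungs[::step]
        if rungs[-1] != self.rungs[-1]:
            rungs.append(self.rungs[-1])
        return AlkaneLadder(rungs)


def compute_retention_index(rt: float, ladder: AlkaneLadder) -> float:
    """van den Dool–Kratz retention index of a peak at *rt* minutes.

    Strictly increasing and continuous in *rt*; exactly 100·n at each rung.
    Retention times outside the ladder are rejected (no extrapolation).
    """
    rts = ladder.retention_times
    carbons = ladder.carbons
    if rt < rts[0] or rt > rts[-1]:
        raise ValueError(
            f"retention time {rt:.3f} min outside ladder range "
            f"[{rts[0]:.3f}, {rts[-1]:.3f}] min"
        )
    i = int(np.searchsorted(rts, rt, side="right")) - 1
    i = min(i, len(rts) - 2)
    frac = (rt - rts[i]) / (rts[i + 1] - rts[i])
    return float(100.0 * (carbons[i] + frac * (carbons[i + 1] - carbons[i])))


@dataclass
class AnalyteAnnotation:
    """Calculated vs literature retention index for one assigned analyte."""

    analyte: str
    ri_calculated: float | None
    ri_literature: float | None
    ri_delta: float | None
    outlier: bool = False
    computable: bool = True


def annotate_ri(
    peak_table: PeakTable,
    ladder: AlkaneLadder,
    library: AnalyteLibrary,
    ri_tolerance: float = 15.0,
) -> list[AnalyteAnnotation]:
    """Annotate every assigned peak with its RI and the literature delta.

    Deltas beyond *ri_tolerance* are flagged as outliers — this is what
    surfaces the known literature mismatches (e.g. citronellyl acetate on the
    wax column).  Peaks outside the ladder are marked not computable.
    """
    column = peak_table.metadata.get("column_id")
    annotations: list[AnalyteAnnotation] = []
    for peak in peak_table.assigned:
        entry = library.entry(peak.assigned_analyte, column)
        try:
            ri_calc = compute_retention_index(peak.apex_time, ladder)
        except ValueError:
            annotations.append(
                AnalyteAnnotation(entry.name, None, entry.ri_lit, None, computable=False)
            )
            continue
        delta = abs(ri_calc - entry.ri_lit) if entry.ri_lit is not None else None
        annotations.append(
            AnalyteAnnotation(
                entry.name,
                ri_calc,
                entry.ri_lit,
                delta,
                outlier=(delta is not None and delta > ri_tolerance),
            )
        )
    return annotations
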