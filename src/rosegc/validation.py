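"""Accuracy, precision, recovery and method-agreement statistics.

Implements the ICH-style validation summary of the rose-oil method: bias as
percent deviation of the mean from nominal; intra-day imprecision RSD_R as
the pooled within-day relative standard deviation; inter-day (total)
imprecision RSD_T as the relative standard deviation over all measurements;
spike recovery RE = (spiked − unspiked)/spike × 100 with the ±20% acceptance
window; QC stability classification against a ±20% deviation limit; and
Bland–Altman agreement (bias and 1.96·SD limits) between the polar- and
chiral-column quantifications.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ValidationSummary",
    "SpikeExperiment",
    "BlandAltmanResult",
    "bias_pct",
    "rsd_r",
    "rsd_t",
    "recovery_effect",
    "recovery_acceptable",
    "qc_stability",
    "bland_altman",
    "bland_altman_plot",
    "summarize_level",
]


@dataclass
class ValidationSummary:
    """Bias and imprecision of one analyte at one QC level."""

    analyte: str
    level: str
    bias_pct: float
    rsd_r_pct: float
    rsd_t_pct: float
    n_days: int
    n_replicates: int

    def within_window(self, limit_pct: float) -> bool:
        return (
            abs(self.bias_pct) <= limit_pct
            and self.rsd_r_pct <= limit_pct
            and self.rsd_t_pct <= limit_pct
        )


def bias_pct(measurements, nominal: float) -> float:
    """Accuracy as bias: (mean − nominal)/nominal × 100 (signed %)."""
    values = np.asarray(list(measurements), dtype=float)
    if values.size == 0:
        raise ValueError("bias needs at least one measurement")
    if nominal <= 0:
        raise ValueError("nominal concentration must be positive")
    return float((values.mean() - nominal) / nominal * 100.0)


def _as_days(batch) -> list[np.ndarray]:
    days = [np.asarray(day, dtype=float) for day in batch]
    if any(d.size == 0 for d in days):
        raise ValueError("every day needs at least one measurement")
    return days


def rsd_r(batch) -> float:
    """Intra-day imprecision: pooled within-day SD / grand mean × 100.

    *batch* is an iterable of per-day measurement sequences; each day needs
    at least two replicates.
    """
    days = _as_days(batch)
    if any(d.size < 2 for d in days):
        raise ValueError("intra-day RSD needs >= 2 replicates per day")
    grand = float(np.concatenate(days).mean())
    num = sum((d.size - 1) * d.var(ddof=1) for d in days)
    dof = sum(d.size - 1 for d in days)
    pooled_sd = float(np.sqrt(num / dof))
    return pooled_sd / grand * 100.0


def rsd_t(batch) -> float:
    """Inter-day (total) imprecision: SD of all measurements / grand mean × 100."""
    days = _as_days(batch)
    if len(days) < 2:
        raise ValueError("inter-day RSD needs measurements from >= 2 days")
    values = np.concatenate(days)
    return float(values.std(ddof=1) / values.mean() * 100.0)


def summarize_level(
    analyte: str, level: str, batch, nominal: float
) -> ValidationSummary:
    """Bias, RSD_R and RSD_T of one analyte/level from per-day replicates."""
    days = _as_days(batch)
    if len(days) < 2 or any(d.size < 2 for d in days):
        raise ValueError("validation summary needs >= 2 days and >= 2 replicates per day")
    values = np.concatenate(days)
    return ValidationSummary(
        analyte=analyte,
        level=level,
        bias_pct=bias_pct(values, nominal),
        rsd_r_pct=rsd_r(days),
        rsd_t_pct=rsd_t(days),
        n_days=len(days),
        n_replicates=int(days[0].size),
    )


@dataclass
class SpikeExperiment:
    """A spiking run: measured unspiked/spiked concentrations and the spike."""

    conc_spiked_sample: float
    conc_sample: float
    conc_spiking: float

    def __post_init__(self) -> None:
        if self.conc_spiking <= 0:
            raise ValueError("spiking concentration must be positive")


def recovery_effect(exp: SpikeExperiment) -> float:
    """Recovery effect RE = (spiked − unspiked)/spike × 100 (%)."""
    return (exp.conc_spiked_sample - exp.conc_sample) / exp.conc_spiking * 100.0


def recovery_acceptable(re_pct: float, limit_pct: float = 20.0) -> bool:
    """A run is acceptable when RE deviates from 100% by at most *limit_pct*."""
    return abs(re_pct - 100.0) <= limit_pct


def qc_stability(
    series, nominal: float, limit_pct: float = 20.0
) -> list[tuple[float, float, bool]]:
    """Classify dated QC measurements against a deviation limit.

    *series* is an iterable of (time, value) pairs; returns
    (time, deviation %, passed) per point.
    """
    points = list(series)
    if len(points) < 2:
        raise ValueError("QC stability needs at least two time points")
    if nominal <= 0:
        raise ValueError("nominal must be positive")
    out = []
    for when, value in points:
        dev = (value - nominal) / nominal * 100.0
        out.append((when, float(dev), abs(dev) <= limit_pct))
    return out


@dataclass
class BlandAltmanResult:
    """Agreement between two quantification methods for one analyte."""

    analyte: str
    bias: float  # mean difference, mg/mL
    loa_low: float
    loa_high: float
    sd_diff: float
    n_samples: int
    fraction_within_loa: float


def bland_altman(pairs, analyte: str = "") -> BlandAltmanResult:
    """Bland–Altman analysis of paired measurements (method A, method B).

    Differences d = A − B; bias = mean(d); 95% limits of agreement
    bias ± 1.96·SD(d) with the sample (n−1) standard deviation.
    """
    arr = np.asarray(list(pairs), dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("pairs must be (method_A, method_B) tuples")
    if arr.shape[0] < 3:
        raise ValueError("Bland–Altman needs at least 3 pairs")
    d = arr[:, 0] - arr[:, 1]
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    lo, hi = bias - 1.96 * sd, bias + 1.96 * sd
    within = float(np.mean((d >= lo) & (d <= hi))) if sd > 0 else 1.0
    return BlandAltmanResult(
        analyte=analyte,
        bias=bias,
        loa_low=float(lo),
        loa_high=float(hi),
        sd_diff=sd,
        n_samples=int(arr.shape[0]),
        fraction_within_loa=within,
    )


def bland_altman_plot(result: BlandAltmanResult, pairs, path) -> None:
    """Write the classic difference-vs-mean agreement plot to *path*."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    arr = np.asarray(list(pairs), dtype=float)
    means = arr.mean(axis=1)
    diffs = arr[:, 0] - arr[:, 1]
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(means, diffs, color="k", s=18)
    ax.axhline(result.bias, color="red", linestyle=":", label="bias")
    ax.axhline(result.loa_low, color="blue", linestyle=":", label="95% LoA")
    ax.axhline(result.loa_high, color="blue", linestyle=":")
    ax.set_xlabel("mean concentration [mg/mL]")
    ax.set_ylabel("difference A − B [mg/mL]")
    ax.set_title(result.analyte or "method agreement")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
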