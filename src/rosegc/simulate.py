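"""Synthetic GC-FID chromatograms with known ground truth.

The generator emulates the two analytical runs of the rose-oil method — a
polar wax column and a cyclodextrin (chiral) column — by placing one
Gaussian (optionally exponentially-modified Gaussian) peak per analyte at
the library retention time, with area proportional to concentration, plus
white detector noise and a slow sinusoidal baseline drift.  Retention times
come from the packaged library; the temperature program is recorded as
metadata only and never simulated physically.

Sample presets encode the composition patterns that distinguish authentic
*Rosa damascena* oil from a *Pelargonium graveolens* (geranium) adulterant:
nerol/geraniol dominance, a strong (−)-rose-oxide excess, single-isomer
citronellyl acetate and β-damascenone in rose oil versus a 0.15 excess of
(+)-rose oxide, both citronellyl acetate enantiomers, both β-damascenone
diastereomers and no farnesol in geranium oil.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import yaml
from scipy.stats import exponnorm

from .io import AnalyteLibrary, Chromatogram, load_default_library
from .retention import AlkaneLadder

__all__ = [
    "ColumnMethod",
    "PeakShapeModel",
    "SampleSpec",
    "POLAR_WAX",
    "CHIRAL_CD",
    "DEFAULT_FWHM",
    "SPLIT_RATIO",
    "IS_MOLAR_MASS",
    "PROFILES",
    "make_sample_spec",
    "default_shape",
    "simulate_chromatogram",
    "simulate_alkane_ladder",
    "simulate_validation_batch",
    "ValidationInjection",
]

#: Molar mass of the internal standard cis-3-hexen-1-ol, g/mol.
IS_MOLAR_MASS = 100.16

_FWHM_TO_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))  # ≈ 2.3548


@dataclass(frozen=True)
class ColumnMethod:
    """Acquisition settings of one GC-FID run (program text is metadata only)."""

    column_id: str
    run_time: float  # minutes
    sampling_rate: float = 5.0  # points per second
    temperature_program: str = ""

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.run_time <= 0:
            raise ValueError("run_time must be positive")

    def time_axis(self) -> np.ndarray:
        n = int(round(self.run_time * 60.0 * self.sampling_rate)) + 1
        return np.arange(n) / (self.sampling_rate * 60.0)


POLAR_WAX = ColumnMethod(
    "polar_wax",
    run_time=60.0,
    sampling_rate=5.0,
    temperature_program="45 °C held 15 min, +5 °C/min to 220 °C, held 9 min (DB-wax)",
)
CHIRAL_CD = ColumnMethod(
    "chiral_cd",
    run_time=65.0,
    sampling_rate=5.0,
    temperature_program="60 °C held 2 min, +2 °C/min to 180 °C, held 3 min (BGB 178 30% CD)",
)

#: Default half-height peak widths per column, minutes.
DEFAULT_FWHM = {"polar_wax": 0.04, "chiral_cd": 0.03}

#: Split ratios of the two injection methods (used for the ng-on-column conversion).
SPLIT_RATIO = {"polar_wax": 50.0, "chiral_cd": 60.0}


@dataclass(frozen=True)
class PeakShapeModel:
    """Peak shape used for simulation.

    ``response_factor`` is detector area per (mg/mL) of injected analyte; the
    default 1.0 treats all analytes as having equal FID response, a documented
    simplification.  ``emg_tau`` is the exponential tail constant of the EMG
    shape (0 selects a pure Gaussian).
    """

    shape: str = "gaussian"
    fwhm: float = 0.04
    emg_tau: float = 0.0
    response_factor: float = 1.0

    def __post_init__(self) -> None:
        if self.shape not in ("gaussian", "emg"):
            raise ValueError("shape must be 'gaussian' or 'emg'")
        if self.fwhm <= 0:
            raise ValueError("fwhm must be positive")
        if self.emg_tau < 0:
            raise ValueError("emg_tau must be >= 0")

    @property
    def sigma(self) -> float:
        return self.fwhm / _FWHM_TO_SIGMA

    def profile(self, t: np.ndarray, rt: float, area: float) -> np.ndarray:
        """Unit-area shape at *rt* scaled to *area*, evaluated on *t*."""
        sigma = self.sigma
        if self.shape == "gaussian" or self.emg_tau == 0.0:
            return area * np.exp(-0.5 * ((t - rt) / sigma) ** 2) / (sigma * np.sqrt(2 * np.pi))
        k = self.emg_tau / sigma
        return area * exponnorm.pdf(t, k, loc=rt, scale=sigma)


def default_shape(column_id: str, **overrides) -> PeakShapeModel:
    return PeakShapeModel(fwhm=DEFAULT_FWHM[column_id], **overrides)


@dataclass
class SampleSpec:
    """Composition and noise model of one simulated injection.

    ``concentrations`` maps compound keys (library ``compound`` column) to
    mg/mL in the injected solution.  ``enantiomer_fractions`` maps an
    enantiomer-group name to the fraction of the group total assigned to the
    first-eluting isomer.  Identical spec + seed yields a bit-identical trace.
    """

    profile_name: str = "custom"
    concentrations: dict[str, float] = field(default_factory=dict)
    enantiomer_fractions: dict[str, float] = field(default_factory=dict)
    is_concentration_mm: float = 10.0
    noise_sd: float = 1e-4
    drift_amplitude: float = 5e-3
    drift_period: float | None = None  # minutes; None -> 2 × run time (half sinusoid)
    seed: int = 0

    def __post_init__(self) -> None:
        for name, c in self.concentrations.items():
            if c < 0:
                raise ValueError(f"negative concentration for {name!r}")
        for group, f in self.enantiomer_fractions.items():
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"enantiomer fraction for {group!r} must be in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SampleSpec":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


# Preset compositions, mg/mL in the injected solution.  Authentic rose oil is
# dominated by nerol/geraniol/citronellol; the geranium adulterant is
# citronellol-rich, poor in geraniol/eugenol/methyleugenol and farnesol-free.
_AUTHENTIC_CONC = {
    "alpha_pinene": 0.02,
    "camphene": 0.004,
    "beta_pinene": 0.004,
    "alpha_terpinene": 0.004,
    "limonene": 0.004,
    "p_cymene": 0.004,
    "rose_oxide": 0.05,
    "linalool": 0.012,
    "beta_caryophyllene": 0.05,
    "beta_damascenone": 0.06,
    "citronellyl_acetate": 0.02,
    "citral": 0.012,
    "neryl_acetate": 0.02,
    "geranyl_acetate": 0.05,
    "citronellol": 0.30,
    "nerol": 0.35,
    "phenylethanol": 0.08,
    "geraniol": 0.45,
    "methyleugenol": 0.02,
    "eugenol": 0.02,
    "farnesol": 0.05,
}

# First-eluting-isomer fractions.  On the chiral column (+)-rose oxide elutes
# first: authentic oil is strongly biased to the later (−) form, while the
# adulterant shows EE = 0.15 toward (+), i.e. a 0.575/0.425 split — the unique
# solution of the excess formula (a−b)/(a+b) = 0.15.
_AUTHENTIC_FRAC = {
    "camphene": 0.5,
    "rose_oxide": 0.02,
    "linalool": 0.12,
    "citral": 0.6,
    "citronellol": 0.9,
    "citronellyl_acetate": 1.0,
    "beta_damascenone": 1.0,
}

_ADULTERANT_CONC = dict(
    _AUTHENTIC_CONC,
    citronellol=0.45,
    geraniol=0.12,
    nerol=0.05,
    citronellyl_acetate=0.025,
    beta_damascenone=0.08,
    phenylethanol=0.02,
    eugenol=0.003,
    methyleugenol=0.003,
    farnesol=0.0,
)

_ADULTERANT_FRAC = {
    "camphene": 0.5,
    "rose_oxide": 0.575,
    "linalool": 0.3,
    "citral": 0.6,
    "citronellol": 0.65,
    "citronellyl_acetate": 0.575,
    "beta_damascenone": 0.6,
}

PROFILES = {
    "authentic_rose": (_AUTHENTIC_CONC, _AUTHENTIC_FRAC),
    "geranium_adulterant": (_ADULTERANT_CONC, _ADULTERANT_FRAC),
    "custom": ({k: 0.0 for k in _AUTHENTIC_CONC}, {k: 0.5 for k in _AUTHENTIC_FRAC}),
}


def make_sample_spec(profile: str, seed: int) -> SampleSpec:
    """Build a :class:`SampleSpec` from a named preset."""
    if profile not in PROFILES:
        raise ValueError(
            f"unknown profile {profile!r}; valid presets: {sorted(PROFILES)}"
        )
    conc, frac = PROFILES[profile]
    return SampleSpec(
        profile_name=profile,
        concentrations=dict(conc),
        enantiomer_fractions=dict(frac),
        # the bare 'custom' preset is a true blank: no internal standard either
        is_concentration_mm=0.0 if profile == "custom" else 10.0,
        seed=int(seed),
    )


def _is_concentration_mg_ml(spec: SampleSpec) -> float:
    return spec.is_concentration_mm * IS_MOLAR_MASS / 1000.0


def _add_peak(y: np.ndarray, t: np.ndarray, shape: PeakShapeModel, rt: float, area: float) -> None:
    # evaluate only on a local window: ±8σ plus the EMG tail
    half = 8.0 * shape.sigma + 8.0 * shape.emg_tau
    dt = t[1] - t[0]
    lo = max(0, int((rt - half) / dt))
    hi = min(t.size, int((rt + half) / dt) + 1)
    if hi > lo:
        y[lo:hi] += shape.profile(t[lo:hi], rt, area)


def simulate_chromatogram(
    spec: SampleSpec,
    method: ColumnMethod,
    shapes: PeakShapeModel | None = None,
    library: AnalyteLibrary | None = None,
    rt_shift: float = 0.0,
    rf_factors: dict[str, float] | None = None,
) -> Chromatogram:
    """Render one injection of *spec* on *method*'s column.

    ``rt_shift`` (minutes, additive) and ``rf_factors`` (per-entry
    multiplicative response scaling) expose the day/injection effects used by
    :func:`simulate_validation_batch`.
    """
    library = library or load_default_library(method.column_id)
    shapes = shapes or default_shape(method.column_id)
    compounds = library.compounds(method.column_id)
    max_rt = max(e.rt_min for e in library.entries_for(method.column_id))
    if method.run_time < max_rt + 2.0:
        raise ValueError(
            f"run_time {method.run_time} min too short for library (needs ≥ {max_rt + 2.0})"
        )
    rf_factors = rf_factors or {}

    t = method.time_axis()
    y = np.zeros_like(t)

    amounts = dict(spec.concentrations)
    is_entry = library.internal_standard(method.column_id)
    amounts[is_entry.compound] = _is_concentration_mg_ml(spec)

    for compound, conc in amounts.items():
        if conc == 0.0:
            continue
        if compound not in compounds:
            raise ValueError(
                f"analyte {compound!r} absent from the {method.column_id!r} library"
            )
        entries = compounds[compound]
        if len(entries) == 1:
            parts = [(entries[0], 1.0)]
        elif len(entries) == 2:
            group = entries[0].enantiomer_group
            f = spec.enantiomer_fractions.get(group, 0.5)
            parts = [(entries[0], f), (entries[1], 1.0 - f)]
        else:
            raise ValueError(f"compound {compound!r} has >2 isomers; groups must be binary")
        for entry, part in parts:
            if part == 0.0:
                continue
            area = conc * part * shapes.response_factor * rf_factors.get(entry.name, 1.0)
            _add_peak(y, t, shapes, entry.rt_min + rt_shift, area)

    period = spec.drift_period if spec.drift_period is not None else 2.0 * method.run_time
    if spec.drift_amplitude:
        y += spec.drift_amplitude * np.sin(2.0 * np.pi * t / period)
    if spec.noise_sd:
        rng = np.random.default_rng(spec.seed)
        y += rng.normal(0.0, spec.noise_sd, t.size)

    meta = {
        "sample_id": spec.profile_name,
        "column_id": method.column_id,
        "seed": spec.seed,
        "profile": spec.profile_name,
    }
    return Chromatogram(t, y, meta)


# Invented end anchors extending the printed (RT, RI) pairs so the alkane
# ladder can bracket the full analyte range; see docs/methods.md.
_ANCHOR_LOW = {"polar_wax": (2.2, 790.0), "chiral_cd": (4.0, 770.0)}
_ANCHOR_HIGH = {"polar_wax": (52.0, 2310.0), "chiral_cd": (63.0, 1920.0)}


def _ri_anchors(library: AnalyteLibrary, column_id: str) -> tuple[np.ndarray, np.ndarray]:
    pairs = [
        (e.rt_min, e.ri_cal)
        for e in library.entries_for(column_id)
        if e.ri_cal is not None
    ]
    pairs.sort()
    pairs = [_ANCHOR_LOW[column_id]] + pairs + [_ANCHOR_HIGH[column_id]]
    rt = np.array([p[0] for p in pairs])
    ri = np.array([p[1] for p in pairs])
    if np.any(np.diff(rt) <= 0) or np.any(np.diff(ri) <= 0):
        raise ValueError("retention-index anchors must be strictly increasing")
    return rt, ri


def simulate_alkane_ladder(
    method: ColumnMethod,
    carbon_range: tuple[int, int] | None = None,
    library: AnalyteLibrary | None = None,
    shapes: PeakShapeModel | None = None,
    area: float = 1.0,
    noise_sd: float = 0.0,
) -> tuple[Chromatogram, AlkaneLadder]:
    """Simulate a homologous n-alkane series on *method*'s column.

    Rung retention times are obtained by inverting the library's
    (retention time, calculated RI) pairs, so an alkane with carbon number n
    sits exactly at retention index 100·n.  If the requested range does not
    bracket every library analyte, a warning is attached to the ladder.
    """
    if carbon_range is None:
        carbon_range = {"polar_wax": (8, 22), "chiral_cd": (8, 19)}[method.column_id]
    n_min, n_max = carbon_range
    if n_min >= n_max:
        raise ValueError("carbon_range must satisfy n_min < n_max")
    library = library or load_default_library(method.column_id)
    shapes = shapes or default_shape(method.column_id)

    anchor_rt, anchor_ri = _ri_anchors(library, method.column_id)
    carbons = list(range(n_min, n_max + 1))
    ris = np.array([100.0 * n for n in carbons])
    if ris[0] < anchor_ri[0] or ris[-1] > anchor_ri[-1]:
        raise ValueError(
            f"carbon range C{n_min}–C{n_max} outside the invertible RI range "
            f"[{anchor_ri[0]:.0f}, {anchor_ri[-1]:.0f}]"
        )
    rts = np.interp(ris, anchor_ri, anchor_rt)
    ladder = AlkaneLadder(list(zip(carbons, rts.tolist())))

    analyte_rts = [
        e.rt_min for e in library.entries_for(method.column_id) if not e.is_internal_standard
    ]
    if min(analyte_rts) < rts[0] or max(analyte_rts) > rts[-1]:
        ladder.warnings.append(
            f"ladder C{n_min}–C{n_max} does not bracket all library analytes "
            f"(analyte RTs span {min(analyte_rts):.2f}–{max(analyte_rts):.2f} min)"
        )

    t = method.time_axis()
    y = np.zeros_like(t)
    for rt in rts:
        _add_peak(y, t, shapes, float(rt), area)
    if noise_sd:
        y += np.random.default_rng(0).normal(0.0, noise_sd, t.size)
    chrom = Chromatogram(t, y, {"sample_id": f"alkane_C{n_min}-C{n_max}", "column_id": method.column_id})
    return chrom, ladder


@dataclass
class ValidationInjection:
    """One chromatogram of a validation batch plus its ground truth."""

    day: int
    level: str
    replicate: int
    truth: dict[str, float]  # compound -> nominal mg/mL injected
    chromatogram: Chromatogram


def simulate_validation_batch(
    levels: dict[str, dict[str, float]] | list[dict[str, float]],
    days: int,
    replicates: int,
    seed: int,
    method: ColumnMethod = POLAR_WAX,
    library: AnalyteLibrary | None = None,
    shapes: PeakShapeModel | None = None,
    day_rt_sd: float = 0.005,
    day_rf_sd: float = 0.03,
    injection_rf_sd: float = 0.02,
    noise_sd: float = 1e-4,
    enantiomer_fractions: dict[str, float] | None = None,
) -> list[ValidationInjection]:
    """Simulate a multi-day calibration/QC batch.

    Day effects are a common additive retention-time shift (sd ``day_rt_sd``
    min) and an independent multiplicative lognormal response factor per
    analyte (sd ``day_rf_sd``); each injection adds another per-analyte
    lognormal factor (sd ``injection_rf_sd``) and fresh detector noise, so
    the within-day spread is smaller than the total spread in expectation.
    """
    if days < 1 or replicates < 1:
        raise ValueError("days and replicates must be >= 1")
    if isinstance(levels, list):
        levels = {f"level_{i + 1}": m for i, m in enumerate(levels)}
    library = library or load_default_library(method.column_id)
    entry_names = [e.name for e in library.entries_for(method.column_id)]

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    out: list[ValidationInjection] = []
    for day in range(1, days + 1):
        rt_shift = rng.normal(0.0, day_rt_sd) if day_rt_sd else 0.0
        day_rf = {
            name: float(np.exp(rng.normal(0.0, day_rf_sd))) if day_rf_sd else 1.0
            for name in entry_names
        }
        for level_name, conc_map in levels.items():
            for rep in range(1, replicates + 1):
                inj_rf = {
                    name: day_rf[name]
                    * (float(np.exp(rng.normal(0.0, injection_rf_sd))) if injection_rf_sd else 1.0)
                    for name in entry_names
                }
                spec = SampleSpec(
                    profile_name=f"{level_name}_d{day}_r{rep}",
                    concentrations=dict(conc_map),
                    enantiomer_fractions=dict(enantiomer_fractions or {}),
                    noise_sd=noise_sd,
                    seed=int(rng.integers(2**31)),
                )
                chrom = simulate_chromatogram(
                    spec, method, shapes=shapes, library=library,
                    rt_shift=rt_shift, rf_factors=inj_rf,
                )
                out.append(ValidationInjection(day, level_name, rep, dict(conc_map), chrom))
    return out
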