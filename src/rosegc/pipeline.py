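"""End-to-end studies wiring simulation → detection → calibration → statistics.

These are the reusable building blocks behind the command-line interface:
fixture traces built from the packaged retention-time libraries, the
multi-day validation study with its bias/RSD summaries, the two-column
Bland–Altman comparison, and the chiral marker study on the sample presets.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import calibration as cal
from . import markers as mk
from . import validation as vs
from .io import AnalyteLibrary, Chromatogram, PeakTable, load_default_library, load_library
from .peaks import assign_analytes, detect_peaks, estimate_baseline
from .retention import annotate_ri
from .simulate import (
    CHIRAL_CD,
    POLAR_WAX,
    ColumnMethod,
    PeakShapeModel,
    SampleSpec,
    default_shape,
    make_sample_spec,
    simulate_alkane_ladder,
    simulate_chromatogram,
    simulate_validation_batch,
)

__all__ = [
    "METHODS",
    "method_for",
    "build_library_trace",
    "process_trace",
    "response_ratios",
    "calibration_levels",
    "qc_levels",
    "entry_nominals",
    "fit_curves_from_batch",
    "run_calibration",
    "ValidationStudyResult",
    "run_validation_study",
    "run_bland_altman_study",
    "run_marker_study",
    "RunConfig",
    "run_pipeline",
]

METHODS = {"polar_wax": POLAR_WAX, "chiral_cd": CHIRAL_CD}


def method_for(column_id: str) -> ColumnMethod:
    try:
        return METHODS[column_id]
    except KeyError:
        raise ValueError(f"unknown column {column_id!r}; choose from {sorted(METHODS)}") from None


def build_library_trace(
    column_id: str,
    fwhm: float | None = None,
    area: float = 1.0,
    library: AnalyteLibrary | None = None,
) -> Chromatogram:
    """Noiseless trace with one equal-area Gaussian peak per library row."""
    library = library or load_default_library(column_id)
    method = method_for(column_id)
    shape = default_shape(column_id) if fwhm is None else PeakShapeModel(fwhm=fwhm)
    t = method.time_axis()
    y = np.zeros_like(t)
    sigma = shape.sigma
    for e in library.entries_for(column_id):
        y += area * np.exp(-0.5 * ((t - e.rt_min) / sigma) ** 2) / (sigma * np.sqrt(2 * np.pi))
    return Chromatogram(t, y, {"sample_id": f"{column_id}_library_fixture", "column_id": column_id})


def process_trace(
    chrom: Chromatogram,
    library: AnalyteLibrary | None = None,
    min_snr: float = 10.0,
    rt_tolerance: float = 0.05,
) -> PeakTable:
    """Baseline → detection → assignment; annotates the IS name in metadata."""
    column = chrom.metadata.get("column_id")
    library = library or load_default_library(column)
    baseline = estimate_baseline(chrom)
    table = detect_peaks(chrom, baseline, min_snr=min_snr)
    table = assign_analytes(table, library, rt_tolerance=rt_tolerance)
    table.metadata["internal_standard"] = library.internal_standard(column).name
    return table


def response_ratios(table: PeakTable, library: AnalyteLibrary) -> dict[str, float]:
    """Area ratio to the internal standard for every assigned analyte."""
    column = table.metadata.get("column_id")
    is_name = library.internal_standard(column).name
    is_peak = table.get(is_name)
    if is_peak is None or is_peak.area <= 0:
        raise ValueError("internal-standard peak missing from the assigned table")
    return {
        p.assigned_analyte: p.area / is_peak.area
        for p in table.assigned
        if p.assigned_analyte != is_name
    }


def calibration_levels(
    library: AnalyteLibrary, column_id: str, n_levels: int = 6
) -> list[dict[str, float]]:
    """Six serial-dilution calibration levels spanning each compound's range."""
    compounds = library.compounds(column_id)
    levels: list[dict[str, float]] = []
    for i in range(n_levels):
        frac = i / (n_levels - 1)
        level = {}
        for compound, entries in compounds.items():
            e = entries[0]
            if e.is_internal_standard or e.range_low is None:
                continue
            level[compound] = float(e.range_low * (e.range_high / e.range_low) ** frac)
        levels.append(level)
    return levels


def qc_levels(library: AnalyteLibrary, column_id: str) -> dict[str, dict[str, float]]:
    """QC_low/QC_med/QC_high concentration maps inside the calibration range."""
    compounds = library.compounds(column_id)
    out = {"QC_low": {}, "QC_med": {}, "QC_high": {}}
    for compound, entries in compounds.items():
        e = entries[0]
        if e.is_internal_standard or e.range_low is None:
            continue
        out["QC_low"][compound] = float(min(2.0 * e.range_low, e.range_high))
        out["QC_med"][compound] = float(np.sqrt(e.range_low * e.range_high))
        out["QC_high"][compound] = float(0.8 * e.range_high)
    return out


def entry_nominals(
    conc_map: dict[str, float],
    library: AnalyteLibrary,
    column_id: str,
    enantiomer_fractions: dict[str, float] | None = None,
) -> dict[str, float]:
    """Per-library-entry nominal concentration implied by a compound map.

    Stereoisomer groups split the compound total by the enantiomer fraction
    (default 0.5 each, the racemic standard used for calibration mixes).
    """
    fractions = enantiomer_fractions or {}
    out: dict[str, float] = {}
    for compound, conc in conc_map.items():
        entries = library.compounds(column_id).get(compound)
        if entries is None:
            raise ValueError(f"analyte {compound!r} absent from the {column_id!r} library")
        if len(entries) == 1:
            out[entries[0].name] = conc
        else:
            f = fractions.get(entries[0].enantiomer_group, 0.5)
            out[entries[0].name] = conc * f
            out[entries[1].name] = conc * (1.0 - f)
    return out


def fit_curves_from_batch(
    injections,
    library: AnalyteLibrary,
    column_id: str,
    min_snr: float = 10.0,
    rt_tolerance: float = 0.05,
) -> dict[str, cal.CalibrationCurve]:
    """Fit one IS-normalised curve per library entry from calibration injections."""
    from .simulate import SPLIT_RATIO

    mc = cal.mass_conversion_for(SPLIT_RATIO[column_id])
    is_name = library.internal_standard(column_id).name
    points: dict[str, list[tuple[float, float, float]]] = {}
    for inj in injections:
        table = process_trace(inj.chromatogram, library, min_snr=min_snr, rt_tolerance=rt_tolerance)
        is_peak = table.get(is_name)
        if is_peak is None:
            raise ValueError(f"internal standard not detected in {inj.level} day {inj.day}")
        nominals = entry_nominals(inj.truth, library, column_id)
        for name, conc in nominals.items():
            peak = table.get(name)
            if peak is None:
                continue
            points.setdefault(name, []).append((conc, peak.area, is_peak.area))
    return {
        name: cal.fit_calibration(pts, analyte=name, mass_conversion=mc)
        for name, pts in points.items()
    }


def run_calibration(
    column_id: str,
    seed: int,
    library: AnalyteLibrary | None = None,
    noise_sd: float = 1e-4,
    day_rt_sd: float = 0.0,
    day_rf_sd: float = 0.0,
    injection_rf_sd: float = 0.0,
) -> dict[str, cal.CalibrationCurve]:
    """Simulate a six-level calibration run and fit all curves (jitter-free by default)."""
    library = library or load_default_library(column_id)
    method = method_for(column_id)
    levels = {f"Cal_{i + 1}": m for i, m in enumerate(calibration_levels(library, column_id))}
    batch = simulate_validation_batch(
        levels, days=1, replicates=1, seed=seed, method=method, library=library,
        day_rt_sd=day_rt_sd, day_rf_sd=day_rf_sd, injection_rf_sd=injection_rf_sd,
        noise_sd=noise_sd,
    )
    return fit_curves_from_batch(batch, library, column_id)


@dataclass
class ValidationStudyResult:
    summaries: list[vs.ValidationSummary]
    curves: dict[str, cal.CalibrationCurve]
    nominals: dict[str, dict[str, float]]  # level -> entry -> nominal mg/mL

    def worst(self) -> dict[str, float]:
        return {
            "max_abs_bias_pct": max(abs(s.bias_pct) for s in self.summaries),
            "max_rsd_r_pct": max(s.rsd_r_pct for s in self.summaries),
            "max_rsd_t_pct": max(s.rsd_t_pct for s in self.summaries),
        }


def run_validation_study(
    seed: int,
    column_id: str = "polar_wax",
    days: int = 5,
    replicates: int = 2,
    day_rt_sd: float = 0.005,
    day_rf_sd: float = 0.03,
    injection_rf_sd: float = 0.02,
    noise_sd: float = 1e-4,
) -> ValidationStudyResult:
    """Full accuracy/precision study on simulated QC batches.

    Calibration standards are injected once per level on every study day and
    pooled into a single six-level fit (one calibration serving the whole
    study); QC_low/med/high are injected ``replicates`` times on each of
    ``days`` days with day and injection effects.  Every QC injection is
    re-detected, assigned, IS-normalised and inverted through its curve;
    summaries carry bias, RSD_R and RSD_T.
    """
    library = load_default_library(column_id)
    method = method_for(column_id)
    ss = np.random.SeedSequence(seed)
    cal_seed, qc_seed = (int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(2))

    cal_levels = {f"Cal_{i + 1}": m for i, m in enumerate(calibration_levels(library, column_id))}
    cal_batch = simulate_validation_batch(
        cal_levels, days=days, replicates=1, seed=cal_seed, method=method,
        library=library, day_rt_sd=day_rt_sd, day_rf_sd=day_rf_sd,
        injection_rf_sd=injection_rf_sd, noise_sd=noise_sd,
    )
    curves = fit_curves_from_batch(cal_batch, library, column_id)
    qc = qc_levels(library, column_id)
    batch = simulate_validation_batch(
        qc, days=days, replicates=replicates, seed=qc_seed, method=method,
        library=library, day_rt_sd=day_rt_sd, day_rf_sd=day_rf_sd,
        injection_rf_sd=injection_rf_sd, noise_sd=noise_sd,
    )

    # measured concentration per (level, entry, day)
    measured: dict[tuple[str, str], dict[int, list[float]]] = {}
    for inj in batch:
        table = process_trace(inj.chromatogram, library)
        ratios = response_ratios(table, library)
        for name, ratio in ratios.items():
            curve = curves.get(name)
            if curve is None:
                continue
            measured.setdefault((inj.level, name), {}).setdefault(inj.day, []).append(
                curve.invert(ratio)
            )

    nominals = {level: entry_nominals(m, library, column_id) for level, m in qc.items()}
    summaries = []
    for (level, name), by_day in sorted(measured.items()):
        days_sorted = [by_day[d] for d in sorted(by_day)]
        summaries.append(
            vs.summarize_level(name, level, days_sorted, nominals[level][name])
        )
    return ValidationStudyResult(summaries, curves, nominals)


#: Compounds quantified on both columns as single (non-stereoisomer) peaks —
#: the majors compared between the two methods.
BLAND_ALTMAN_COMPOUNDS = [
    "nerol",
    "geraniol",
    "phenylethanol",
    "neryl_acetate",
    "geranyl_acetate",
    "eugenol",
]


def run_bland_altman_study(
    seed: int,
    n_samples: int = 10,
    compounds: list[str] | None = None,
    noise_sd: float = 1e-4,
    injection_rf_sd: float = 0.02,
    sample_spread_sd: float = 0.3,
) -> dict[str, tuple[vs.BlandAltmanResult, list[tuple[float, float]]]]:
    """Quantify simulated oils on both columns and compare by Bland–Altman.

    Each sample's true composition is drawn lognormally around the midpoint
    of the overlapping calibration ranges; the same truth is injected on both
    columns with independent injection effects and noise, quantified through
    each column's own calibration, and the paired concentrations compared.
    """
    compounds = compounds or BLAND_ALTMAN_COMPOUNDS
    libs = {c: load_default_library(c) for c in METHODS}
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    curves = {
        c: run_calibration(c, int(rng.integers(2**31)), libs[c], noise_sd=noise_sd)
        for c in METHODS
    }

    mids = {}
    for compound in compounds:
        lo = max(libs[c].compounds(c)[compound][0].range_low for c in METHODS)
        hi = min(libs[c].compounds(c)[compound][0].range_high for c in METHODS)
        mids[compound] = float(np.sqrt(lo * hi)), lo, hi

    concs_by_column: dict[str, dict[str, list[float]]] = {
        c: {k: [] for k in compounds} for c in METHODS
    }
    for _ in range(n_samples):
        truth = {}
        for compound, (mid, lo, hi) in mids.items():
            truth[compound] = float(np.clip(mid * np.exp(rng.normal(0, sample_spread_sd)), lo, hi))
        for column in METHODS:
            library = libs[column]
            entry_names = [e.name for e in library.entries_for(column)]
            inj_rf = {
                name: float(np.exp(rng.normal(0.0, injection_rf_sd))) for name in entry_names
            }
            spec = SampleSpec(
                profile_name="ba_sample",
                concentrations=truth,
                noise_sd=noise_sd,
                seed=int(rng.integers(2**31)),
            )
            chrom = simulate_chromatogram(spec, method_for(column), library=library, rf_factors=inj_rf)
            table = process_trace(chrom, library)
            ratios = response_ratios(table, library)
            for compound in compounds:
                name = library.compounds(column)[compound][0].name
                concs_by_column[column][compound].append(curves[column][name].invert(ratios[name]))

    out = {}
    for compound in compounds:
        pairs = list(zip(concs_by_column["polar_wax"][compound], concs_by_column["chiral_cd"][compound]))
        out[compound] = (vs.bland_altman(pairs, analyte=compound), pairs)
    return out


def run_marker_study(profile: str, seed: int, with_quant: bool = False):
    """Simulate a preset oil on the chiral column and evaluate its markers.

    Returns (MarkerReport, pairs, assigned PeakTable).  With ``with_quant``
    a calibration is simulated as well so marker gating and the
    citronellol/geraniol ratio use quantified concentrations.
    """
    library = load_default_library("chiral_cd")
    spec = make_sample_spec(profile, seed)
    chrom = simulate_chromatogram(spec, CHIRAL_CD, library=library)
    table = process_trace(chrom, library)
    pairs = mk.pair_isomers(table, library)
    quant = None
    if with_quant:
        curves = run_calibration("chiral_cd", seed + 1, library)
        quant = cal.quantify(table, curves, dilution_factor=1.0)
    report = mk.marker_report(pairs, quant_results=quant)
    return report, pairs, table


@dataclass
class RunConfig:
    """Serializable configuration of one reproducible pipeline run."""

    column: str = "polar_wax"
    profile: str = "authentic_rose"
    seed: int = 0
    min_snr: float = 10.0
    rt_tolerance: float = 0.05
    ri_tolerance: float = 15.0
    dilution_factor: float = 1.0
    library_path: str | None = None  # None -> packaged fixture
    output_dir: str = "rosegc_run"
    marker_rules: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "column": self.column,
            "profile": self.profile,
            "seed": self.seed,
            "min_snr": self.min_snr,
            "rt_tolerance": self.rt_tolerance,
            "ri_tolerance": self.ri_tolerance,
            "dilution_factor": self.dilution_factor,
            "library_path": self.library_path,
            "output_dir": self.output_dir,
            "marker_rules": self.marker_rules,
        }

    def config_hash(self) -> str:
        blob = yaml.safe_dump(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        unknown = set(data) - set(cls().to_dict())
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def validate(self) -> None:
        if self.column not in METHODS:
            raise ValueError(f"unknown column {self.column!r}")
        if self.library_path is not None and not Path(self.library_path).exists():
            raise ValueError(f"library path {self.library_path!r} does not exist")


def run_pipeline(config: RunConfig) -> Path:
    """Execute simulate → detect → RI → calibrate → quantify (→ markers).

    Writes peak table, RI annotations, calibration curves, quantification and
    (on the chiral column) the marker report into the run directory; every
    file carries the config hash.  Returns the run directory path.
    """
    from .io import write_peak_table, write_trace

    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    tag = config.config_hash()
    log: list[str] = [f"config_hash: {tag}", f"seed: {config.seed}"]

    library = (
        load_library(config.library_path) if config.library_path else load_default_library(config.column)
    )
    method = method_for(config.column)
    spec = make_sample_spec(config.profile, config.seed)
    chrom = simulate_chromatogram(spec, method, library=library)
    chrom.metadata["config_hash"] = tag
    write_trace(chrom, outdir / "trace.csv")
    log.append(f"simulated {config.profile} on {config.column}")

    table = process_trace(chrom, library, min_snr=config.min_snr, rt_tolerance=config.rt_tolerance)
    table.metadata["config_hash"] = tag
    write_peak_table(table, outdir / "peaks.tsv")
    log.append(f"detected {len(table)} peaks, {len(table.assigned)} assigned")

    ladder_chrom, ladder = simulate_alkane_ladder(method, library=library)
    write_trace(ladder_chrom, outdir / "alkane_ladder.csv")
    annotations = annotate_ri(table, ladder, library, ri_tolerance=config.ri_tolerance)
    with (outdir / "retention_indices.tsv").open("w") as fh:
        fh.write(f"# config_hash: {tag}\n")
        fh.write("analyte\tri_calculated\tri_literature\tri_delta\toutlier\n")
        for a in annotations:
            fh.write(
                f"{a.analyte}\t{'' if a.ri_calculated is None else f'{a.ri_calculated:.1f}'}\t"
                f"{'' if a.ri_literature is None else f'{a.ri_literature:.0f}'}\t"
                f"{'' if a.ri_delta is None else f'{a.ri_delta:.1f}'}\t{int(a.outlier)}\n"
            )

    curves = run_calibration(config.column, config.seed + 1, library)
    cal.save_curves(curves, outdir / "calibration_curves.yaml")
    quant = cal.quantify(table, curves, dilution_factor=config.dilution_factor)
    with (outdir / "quantification.tsv").open("w") as fh:
        fh.write(f"# config_hash: {tag}\n")
        fh.write("analyte\tconcentration_mg_ml\tflag\n")
        for r in quant:
            value = "" if r.concentration is None else f"{r.concentration:.6g}"
            fh.write(f"{r.analyte}\t{value}\t{r.flag}\n")
    log.append(f"quantified {sum(r.flag == 'ok' for r in quant)} analytes cleanly")

    if config.column == "chiral_cd":
        pairs = mk.pair_isomers(table, library)
        rules = config.marker_rules or None
        report = mk.marker_report(pairs, quant_results=quant, rules=rules)
        with (outdir / "marker_report.tsv").open("w") as fh:
            fh.write(f"# config_hash: {tag}\n")
            fh.write("group\tee\tmajor_isomer\tverdict\tnote\n")
            for group, f in report.findings.items():
                ee = "" if f.ee is None else f"{f.ee:.3f}"
                fh.write(f"{group}\t{ee}\t{f.major_identity or ''}\t{f.verdict}\t{f.note}\n")
        log.append(f"marker verdict: {report.overall}")

    with (outdir / "config.yaml").open("w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
    (outdir / "run.log").write_text("\n".join(log) + "\n")
    return outdir
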