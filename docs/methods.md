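# Methods

This note documents the models behind `rosegc`, the defaults and why they
were chosen, what the synthetic data does and does not emulate, and the
numerical choices a maintainer should know about.

## The measurement model

A GC-FID run is represented as a uniformly sampled time–intensity trace
(minutes vs arbitrary detector counts). Two column methods are built in:

| column      | run time | program (metadata only)                  | default FWHM |
|-------------|----------|------------------------------------------|--------------|
| `polar_wax` | 60 min   | 45 °C 15 min, +5 °C/min → 220 °C, 9 min  | 0.04 min     |
| `chiral_cd` | 65 min   | 60 °C 2 min, +2 °C/min → 180 °C, 3 min   | 0.03 min     |

Retention times are taken from the packaged per-column analyte libraries
(21 analytes + internal standard on the wax column, 29 + IS on the
cyclodextrin column); the temperature program is recorded as text and never
simulated physically. No vendor binary formats are read — traces are plain
`time_min,intensity` CSV.

## Synthetic chromatograms

Each analyte contributes one peak (per stereoisomer on the chiral column)
at its library retention time:

- **Shape** — Gaussian by default; an exponentially modified Gaussian
  (tail constant `emg_tau`) is available for asymmetry/realism tests. The
  per-column FWHM defaults (0.04 / 0.03 min) were chosen so that every
  neighbouring pair in the libraries is resolved consistently with the
  method's reported bounds: the tightest wax-column pair
  (nerol/phenylethanol, Δ 0.17 min) gives Rs ≈ 2.5 (> 2.4) and the tightest
  chiral pair (geranyl acetate/β-caryophyllene, Δ 0.09 min) gives Rs ≈ 1.8
  (> 0.7, in fact fully resolved). The instrument's true peak widths are
  not published, so these are package choices.
- **Area** — `response_factor × concentration` (mg/mL), with
  `response_factor = 1.0` area·mL/mg for every analyte. FID response
  differences between analytes are deliberately not modelled; calibration
  then recovers a slope of ≈ 1/IS-concentration, and nothing downstream
  assumes it.
- **Internal standard** — cis-3-hexen-1-ol at 10 mM in every non-blank
  sample, converted to mg/mL with M = 100.16 g/mol.
- **Noise and drift** — additive white Gaussian noise (default SD 1e-4
  intensity units, i.e. SNR ≈ 200–9000 for preset peaks) and a slow
  sinusoidal baseline drift (default amplitude 5e-3, period = twice the run
  time, i.e. a half sinusoid over the run). The drift exercises baseline
  correction; it is not a physical column-bleed model.
- **Sampling** — 5 points/s, so the narrowest default peak carries ~9–12
  samples across its FWHM and > 30 across its base.
- **Determinism** — identical spec + seed yields a bit-identical trace;
  all randomness flows through `numpy.random.default_rng(seed)`.

### Sample presets

`authentic_rose` encodes the authentic-oil patterns: nerol/geraniol/
citronellol dominant; rose oxide split 0.02/0.98 toward the later-eluting
(−) form (EE 0.96); citronellyl acetate and β-damascenone single-isomer;
farnesol present. `geranium_adulterant` encodes the adulterant signature:
citronellol-rich and geraniol/eugenol/methyleugenol-poor; rose oxide split
0.575/0.425 toward the first-eluting (+) form — the unique solution of
(a−b)/(a+b) = 0.15; both citronellyl acetate enantiomers (excess 0.15) and
both β-damascenone diastereomers (excess 0.2); no farnesol. Absolute
concentrations (mg/mL in the injected solution) are package choices placed
inside the chiral calibration ranges; only the published qualitative
patterns and the 0.15 excess are taken from the source method. `custom` is
a true blank (no analytes, no IS).

### Multi-day validation batches

`simulate_validation_batch` adds, per day, a common retention-time shift
(normal, SD 0.005 min) and an independent lognormal response factor per
analyte (SD 3%); each injection adds another per-analyte lognormal factor
(SD 2%) plus fresh noise. Because the IS jitters independently, the
analyte/IS ratio carries ≈ √(2²+2²) ≈ 3% within-day and ≈ 5% total
relative spread — comfortably inside the method's ±20% (wax) and ±15%
(chiral) acceptance windows, and with RSD_T ≥ RSD_R in expectation by
construction.

## Peak processing

- **Baseline** — iteratively reweighted Whittaker smoothing (second-
  difference penalty, λ = 1e9 at 5 points/s, 15 iterations): points whose
  residual exceeds 3 robust SDs are down-weighted to 1e-6, so the smoother
  follows drift and the noise floor but not peaks. At λ = 1e9 the effective
  smoothing half-width (~λ^¼ ≈ 180 samples ≈ 0.6 min) is ~15× the widest
  default peak yet far below the drift scale; baseline error against the
  generator's known drift is < 2e-5 (a fifth of the default noise SD).
- **Noise estimate** — 1.4826 × MAD of the first differences / √2,
  insensitive to peaks and drift.
- **Detection** — local maxima of a Savitzky–Golay-smoothed corrected
  signal (quadratic, window ≈ ¼ of `min_fwhm`, ≥ 5 samples) with
  prominence ≥ max(`min_snr` × noise SD, 1e-6 × signal maximum). The
  relative floor defines "zero" on noiseless traces; 1e-6 sits three
  orders below the smallest real peak of any packaged scenario. Defaults:
  `min_snr` 10, `min_fwhm` 0.01 min. Detection is complete and exact on the
  noiseless library fixtures (22 and 30 peaks) and stable down to SNR ≈ 50.
- **Boundaries** — nearest flanking valley (argmin between adjacent
  apexes) or baseline return (3 × noise SD crossing), whichever is closer
  to the apex; fused neighbours split at the valley, no tangent skimming.
  Area is the trapezoid of the corrected signal between boundaries; for an
  isolated simulated Gaussian it matches amplitude·σ·√(2π) within 0.5%.
- **Apex refinement** — 3-point parabolic interpolation on the smoothed
  signal (sub-sample accuracy; fixture apexes match library RTs within
  0.01 min).
- **Assignment** — greedy one-to-one nearest matching within
  `rt_tolerance` (default 0.05 min, an order above the simulated day
  jitter), ties broken toward the earlier-eluting analyte; analytes whose
  only candidates were taken by competitors are flagged ambiguous,
  unmatched analytes reported absent.

## Retention indices

Only the temperature-programmed (van den Dool–Kratz, linear) form is
implemented; the runs are temperature-programmed so the isothermal
logarithmic Kovats variant does not apply. RI is exactly 100·n at each
rung, continuous and strictly monotone between rungs, and retention times
outside the ladder are rejected rather than extrapolated.

The alkane ladder itself is synthesized by inverting the library's
(retention time, calculated RI) pairs, linearly in RI with one invented
anchor appended at each end, so that each rung C_n sits exactly at index
100·n. A caveat: the published RT↔RI pairs of the wax column are not
jointly consistent with *any* single ladder under linear interpolation
(the index rises ~167 units across 0.81 min between linalool and
β-caryophyllene, ten times the neighbouring rate), so recomputed indices
deviate from the tabulated ones by up to ~35 units in that kinked region.
The two genuine literature outliers — citronellyl acetate (Δ ≈ 187) and
geraniol (Δ ≈ 58) — remain by far the largest deltas and are what the
default `ri_tolerance` of 15 index units is designed to surface. No
literature matching is attempted on the chiral column (no published chiral
RI values).

## Calibration and quantification

The response is the area ratio analyte/IS; the curve is unweighted OLS of
ratio on concentration over six serial-dilution levels spanning each
analyte's published range (no weighting scheme is published, and σ is the
regression residual SD on n−2 degrees of freedom — the commonest reading
of the ICH "standard deviation of the response"). LoD = 3.3·σ/S and
LoQ = 10·σ/S (ratio exactly 10/3.3) are converted to ng on column as
`mg/mL × injection volume (1 µL) × 1000 / split ratio` (1:50 wax, 1:60
chiral); the conversion convention is recorded in the curve and
overridable, since the published ng values do not state theirs.

Quantification inverts the curve and multiplies by the dilution factor
(1:10 for minor, 1:500 for major components). Below-LoQ results carry no
numeric value; above-range results are flagged and `select_dilution`
replaces them with the higher-dilution measurement. In the full validation
study, calibration standards are injected once per level on each study day
and pooled into a single fit — the single up-front calibration the method
relies on; pooling across days keeps the intercept noise of the unweighted
fit from inflating low-QC bias.

## Validation statistics and method agreement

Bias, RSD_R (pooled within-day SD over grand mean) and RSD_T (total SD
over grand mean) are computed per analyte and QC level from ≥ 2 days × ≥ 2
replicates. RSD_T is deliberately the *total* relative SD rather than a
between-day ANOVA component: the inter-day wording is ambiguous, the total
form is always defined, and it is the conservative (larger) choice.
Recovery RE uses the spiked−unspiked difference over the spike with a
±20% acceptance band; QC stability classifies each dated point against
±20% of nominal (not against the day-1 measurement). Bland–Altman limits
use the sample (n−1) SD and a fixed 1.96 multiplier, require ≥ 3 pairs,
and report the fraction of differences inside the limits.

The packaged two-column comparison (`run_bland_altman_study`) draws ten
sample compositions lognormally (SD 30%) around the midpoint of the
overlapping calibration ranges, injects the same truth on both columns
with independent 2% injection effects, quantifies each through its own
column's calibration and compares the six compounds that appear as single
peaks on both columns (nerol, geraniol, phenylethanol, neryl acetate,
geranyl acetate, eugenol).

## Chiral markers

EE/DE is reported unsigned in [0, 1] with an explicit major-isomer label
(elution rank from the library; optical labels are only asserted where
published, i.e. (+)-rose oxide elutes before (−)). A group with both areas
zero is indeterminate, not racemic. Marker rules are configuration, since
the source observations are qualitative: rose oxide flags when the major
isomer is the first-eluting (+) form; citronellyl acetate and
β-damascenone flag when EE ≤ 0.90 ("both isomers present") and read
consistent when EE ≥ 0.98 ("single isomer"), with the band in between
indeterminate. When quantification results are supplied, markers whose
peaks are below LoQ are reported indeterminate rather than judged from
noise-level areas.

## Problem sizes and limitations

The multi-day validation study runs at the method's own design size —
6 calibration levels and 3 QC levels over 5 days with duplicate QC
injections, 21 analytes on the wax column (66 chromatograms of 18 001
points) — in about two seconds; the Bland–Altman study uses 10 samples ×
2 columns plus two calibration runs.

What passing tests do *not* show about real data: the generator has no
co-eluting interferents beyond the library, no analyte-specific FID
response, no peak-shape drift or column ageing, no carry-over, and
retention times come from the library rather than from a retention model —
so the pipeline's robustness to matrix effects and to RT drift beyond the
simulated 0.005 min/day is untested. The published per-analyte bias/RSD
values are not reproducible from the outside because the underlying
instrument data are not deposited; the simulated study instead verifies
that the pipeline's statistics fall inside the published acceptance
windows under the stated variability model. Stereoisomer ratios changing
with storage conditions are out of scope, as is any species-classification
model.
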