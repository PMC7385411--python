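# Methods

## The scientific problem

Flowers that rely on a pollinator active only in a brief daily window are
expected to concentrate costly signals — here floral volatiles — in that
window. Testing this requires (a) quantifying what the blend is
(discrete, compound-resolved GC-MS sampling), (b) resolving when each
volatile rises, peaks, and falls (continuous multi-day ion time series),
and (c) a statistic that compares emission timing with the pollinator's
activity distribution on a common clock. The package implements all
three stages plus a synthetic-data generator with retained ground truth,
so every stage is testable without access to instrument data.

All within-day times are expressed in **hours relative to the dark
(light-to-dark) transition**, which is aligned with local sunset when
chamber data are compared with field observations. The default light
schedule is light-on 05:00, dark-on 17:00 (12 h photoperiod).

## GC-MS quantification

- **Retention index**: linear van den Dool–Kratz interpolation on a
  C7–C30 n-alkane ladder; RI of alkane C_n is exactly 100·n; retention
  times outside the ladder raise an error rather than extrapolate.
- **Calibration**: per authentic standard, ordinary least squares of
  log₁₀(response) on log₁₀(mass). The log–log form is essential because
  the curves span four decades of mass (1–1000 ng); untransformed least
  squares would be dominated by the top decade. Each compound class maps
  to a chemically nearest standard; the mapping is a required
  configuration table with a documented default (aliphatics →
  (Z)-hex-3-en-1-ol, benzenoids → benzaldehyde dimethyl acetate,
  monoterpenes → linalool, irregular terpenes → (E,E)-farnesol, other →
  β-caryophyllene).
- **Emission rate** = inverse-calibrated trapped mass / (sampling
  duration × open flowers), in ng·flower⁻¹·h⁻¹. Zero responses give rate
  0; "present" everywhere below means rate strictly > 0.
- **Inclusion rules** (all strict inequalities): spectral match > 0.75,
  maximum abundance across samples > 120,000 counts, occurrence in more
  than one sample.
- **Contaminants**: per compound, a one-sided Welch *t*-test of floral >
  ambient-control rates, Benjamini–Hochberg adjusted across compounds;
  compounds not significantly exceeding controls at the adjusted 0.05
  level are removed. One-sided is the right direction here: a compound
  *suppressed* in floral samples relative to controls is still not
  floral. Compounds on an explicit exclusion list (wound volatiles such
  as (Z)-hex-3-en-1-ol) are removed regardless of significance. A
  compound absent from the control table is tested against control level
  0 and flagged in the report.
- **Blend statistics**: relative proportion of compound *j* is its mean
  rate over the group's summed mean rates, computed over all included
  compounds; Shannon *H* = −Σ p ln p is per sample on that sample's own
  relative rates (all-zero samples → missing). Species totals are
  compared with a Mann–Whitney test, exact when both groups are tie-free
  and small enough to enumerate, otherwise the tie-corrected normal
  approximation with continuity correction.

## Constrained ordination (CAP / dbRDA)

Bray–Curtis dissimilarities are computed on square-root-transformed
rates (the transform reduces the strong right skew of emission data;
pairs of all-zero samples get distance 0 by convention). PCoA uses
Gower double-centering; axes with negative eigenvalues — possible
because Bray–Curtis is non-Euclidean — are dropped and their magnitude
reported as imaginary inertia, with no Lingoes/Cailliez correction
(corrections change pseudo-F, so the choice is stated rather than
silent). All positive-eigenvalue axes enter the constrained analysis by
default (exposed as a parameter).

`CAP.fit()` centers the patsy design matrix (the intercept is thereby
absorbed), projects the PCoA coordinates onto it via QR, and
eigendecomposes fitted and residual variation separately into canonical
and MDS axes. Inertia is conserved: constrained + residual + imaginary
= total PCoA inertia (checked in tests at 1e-8). Per-term sums of
squares are sequential (Type I); the permutation test permutes response
rows freely — no block structure is assumed — and reports
p = (exceedances + 1)/(n_perm + 1) with 99,999 permutations by default.
Compound scores are correlations of the (transformed, centered)
compound columns with the canonical axes; sign and ordering are the
interpretable content. The implementation was cross-checked against an
independent distance-based RDA implementation on a frozen fixture
(per-term SS and F agree to ≥ 4 decimals).

Ion-trace structure uses column-centered PCA (SVD) after dropping ions
whose maximum signal does not exceed 0.001 counts·s⁻¹·flower⁻¹, and
WPGMA (McQuitty) clustering of 1 − Pearson r distances among max-scaled
traces; constant traces have undefined correlation and are flagged and
placed at the maximal distance 2; labels are pre-sorted so merge ties
resolve deterministically.

## The diel pulse model

Each ion × plant × day window (light-on to next light-on plus a 6 h
tail, so pulses decaying after midnight are not truncated; partial
first/last windows dropped) is fitted with

    y(t) = b(t) + A·g(t),   g rising as exp(−((t_peak−t)/s_r)^k_r),
                            falling as exp(−((t−t_peak)/s_f)^k_f)

with b(t) a logistic blend from b_pre to b_post (center t_peak, scale
s_r + s_f). The form has exactly the degrees of freedom the analysis
needs — different rise and fall slopes, different baselines before and
after the peak — with monotone rise and fall and k ≥ 1.

**Estimation.** Bounded nonlinear least squares with *inverse-signal
weights* (1/max(median-smoothed y, 5% of window max)): the generator's
noise model — and volatile data generally — is multiplicative, so
relative residuals are the efficient objective; fixing the weights from
the data keeps the problem an ordinary bounded least squares. Starting
points come from a deterministic grid (peak every 2 h plus the window
argmax; shapes k ∈ {1, 2, 4}); the six cheapest starts are polished and
the best kept, so fits are exactly reproducible with no random
restarts. A fit is degenerate when the window is flat (range below 3×
the MAD of first differences) and non-converged when the residual SD
exceeds half the amplitude or a structural bound (peak at a window
edge, scale/shape at a limit) is hit. Argmax ties break to the earliest
time.

**Cardinal times.** The baseline-free pulse A·g is integrated on a
1-min grid over a support wide enough that g < 1e-8 at the edges;
t_start and t_end are where the normalized cumulative area crosses
0.5% and 99.5% — the central 99% of modelled pulse area — and t_max =
t_peak. Degenerate fits yield missing cardinal times, not zeros.

**Identifiability.** The curvature of g at the peak scales as
(t − t_peak)^(k−2): for k ≤ 2 the maximum is locally quadratic and its
time is statistically well determined; for k > 2 the top flattens and
t_peak becomes weakly identified — at 5% multiplicative noise the
estimate scatters by ±15 min or more no matter the estimator, and for
plateau-shaped pulses (k ≈ 4, the morning class below) by an hour.
This is a property of the data-generating shape, not of the optimizer
(truth-started fits land on the same optimum). Consequently the
peak-recovery guarantee (and the acceptance suite's recovery run) is
stated for pulses with curved maxima; plateau pulses are still fitted,
classified, and overlapped, but their t_max carries wide uncertainty.

**Timing classes** from the onset (t_start) relative to the schedule,
tolerance 0.5 h: morning = onset within tolerance of light-on; dark =
onset at or after the dark transition; afternoon = in between;
otherwise unclassified (reported). **Diel ratio** = mean signal in the
evening window (dark + 2 to + 3 h) over the day window (dark − 5 to
− 4 h); a zero day mean reports an infinite ratio with a flag.

## Synchrony: densities and areal overlap

Moth visits (offsets from terrain-corrected sunset, pooled across dates
without per-date weighting) and emission traces are converted to
unit-area densities on a circular 24 h grid: 4-min steps, each grid
point receiving the count (or smoothed signal) in a half-open 16-min
window centered on it, then one global normalization to area 1. The
sliding windows act as a moving-average density estimate; a point mass
therefore occupies one 16-min window (four grid bins). The circular
domain prevents truncation of pulses spanning midnight.

Areal overlap O(f, g) = Σ min(fᵢ, gᵢ)·Δt ∈ [0, 1]; symmetric; 1 iff
the densities coincide on the grid. The null expectation is the
overlap with the flat line at 1/24 h⁻¹ (unit area over the cycle),
representing either a uniform distribution of peak times or a volatile
emitted at a constant rate; it is invariant to circular shifts of the
observed density. The aggregate synchrony metric overlaps the density
of fitted peak times (across ions, days, plants) with the visit
density; the per-ion table overlaps each plant-day trace separately
and summarizes mean ± SD per ion. A constant-emission trace's overlap
equals the flat-line null exactly, by construction.

## Solar geometry

Solar position uses the NOAA low-precision approximations (geometric
mean longitude and anomaly, equation of center, apparent longitude,
mean obliquity, equation of time), good to ~0.1° of elevation across
1900–2100. Standard sunset is the descending crossing of −0.833°
(refraction + solar semidiameter); terrain sunset replaces the
threshold with the ridge's elevation angle toward the sunset azimuth —
a single scalar, not a horizon profile — and is found by bracketed
root-finding from solar noon. Terrain sunset is monotone nonincreasing
in ridge angle, and an impossible ridge (sun never above it) raises an
error.

## Synthetic data: what it emulates, and what it does not

The generator's defaults are the study conditions:

- **Blends**: per-compound occurrence probabilities and mean nonzero
  emission rates for the two species come from the packaged 40-compound
  table; day-phase emission is scaled by 0.6 (evening emissions run
  1.5–1.8× day); per-sample rates are log-normal around the species
  mean (CV 0.3 by default); occurrence is Bernoulli. Compounds that
  occur but whose tabulated mean rounds to 0.00 emit at 0.005
  ng·flower⁻¹·h⁻¹ (half the table's printed resolution). Designated
  contaminants appear in ambient controls (n = 19) at levels at or
  above floral samples. Calibration fixtures: C7–C30 ladder with mild
  programmed-temperature curvature; 7 standards × 4 decades of mass
  with proportional response (~10⁵ counts/ng, so major compounds clear
  the 120,000-count inclusion threshold and trace ones may not).
- **Ion traces**: one pulse per ion per day from the same functional
  form the fitter assumes, classes keyed to the light transitions
  (morning: onset at light-on, plateau shape k 3–5; afternoon: onset
  0–6 h before dark, peak 0–2.5 h after; dark: onset at dark, peak
  1–3 h after; afternoon/dark shapes draw k in [1.3, 2.1] so modelled
  maxima are locally quadratic — see Identifiability). The rise scale
  is solved by bisection so the 0.5%-area onset lands in the class
  window. Pulse noise is multiplicative log-normal (signals are
  positive and heteroscedastic); baseline noise is additive, truncated
  at 0; optional geometric day-to-day amplitude decay emulates
  inflorescence aging. Between-day amplitude correlation within a
  plant is exposed as a parameter defaulting to 0 (no empirical value
  is available to set it).
- **Visits**: truncated normal, mean 1.1 h, SD 0.4 h, support 0.2–1.6 h
  after sunset, round-robin across dates — a parametric stand-in chosen
  because only summary statistics of real visit times are available.

Passing tests on these data show the pipeline recovers known truth
under the stated noise; they do not show robustness to what the
generator omits: multi-modal days, instrument drift, retention-time
misalignment, correlated compound noise, weather-driven emission
variation, or gradual (non-step) light transitions.

## Numerical choices and defaults

| parameter | default | units | note |
|---|---|---|---|
| match threshold | 0.75 | fraction | strict > |
| abundance threshold | 120,000 | counts | strict > |
| occurrence reporting threshold | 0.20 | fraction of either species | strict > |
| contaminant alpha | 0.05 | — | BH-adjusted, one-sided |
| transform before Bray–Curtis | sqrt | — | |
| permutations | 99,999 | — | p = (k+1)/(n+1) |
| grid step / window | 4 / 16 | min | densities and binning |
| area quantiles | 0.005 / 0.995 | — | cardinal times |
| timing tolerance | 0.5 | h | classification |
| evening / day ratio windows | +2..+3 / −5..−4 | h rel. dark | |
| sunset convention | −0.833 | deg | refraction + semidiameter |

Degenerate inputs are reported, not silently zeroed: all-zero samples
give missing Shannon values, degenerate fits give missing cardinal
times, all-zero traces give overlap 0 with a flag, zero day-window
means give flagged infinite ratios.

Problem sizes in the test and acceptance runs (180 fitted ion-days
across 3 seeds, 500 null simulations at 999 permutations, 2,000-visit
densities) were chosen as the smallest sizes at which the binomial and
recovery bounds being checked are sharp.

## Known limitations

- Single pulse per day: genuinely bimodal days are mis-modelled by
  design (the fit absorbs the smaller mode into baseline or tail).
- Day windows extend 6 h past light-on of the next day, so a
  morning-class pulse's window contains the *next* day's rise; the
  dual-baseline model absorbs most of this, but it contributes to the
  wide uncertainty of plateau-pulse peak times.
- The per-ion overlap treats each plant-day independently and then
  summarizes; averaging traces across days before overlapping is a
  defensible alternative that would narrow the spread.
- The flat-line null depends only on the visit density, not on the
  number of ions; it is a reference value, not a significance test.
- Compound scores use one of several defensible scalings (correlation
  with canonical axes); magnitudes are not comparable across software
  that scales scores differently, but signs and rank order are.
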