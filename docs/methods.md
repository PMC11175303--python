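# Methods

## Measurement model

Each measurement consists of eight chronofrequency curves, one per coated
14.0 MHz quartz resonator. Sorption of headspace volatiles lowers the
resonator frequency (Sauerbrey regime), so curves are negative-going; all
analytical responses are reported as positive magnitudes of −ΔF.

Two gas-input modes are represented. In the *injected* mode a fixed
headspace volume enters a closed cell; the record spans 80 s, with a
quasi-plateau reached during the first 40 s and a slow first-order
relaxation afterwards (time constant 400 s, a closed-cell equilibration
scale). In the *frontal* mode the cell is fed continuously for 40 s and
then purged; the record spans 120 s with exponential desorption after the
40 s breakpoint. Frontal signals are amplified by a per-sensor gain in
[3, 6]. The sorption branch in both modes is first-order,
ΔF(t) = ΔF_plateau·(1 − e^(−t/τ_s)), with per-sensor τ_s of 8–18 s.

## Synthetic study generator

The generator reproduces the design of the study it emulates: 14 raw-milk
specimens from five farms plus two artificial standards, each measured in
triplicate (48 measurements per mode), three specimens per day across six
days, with three water-vapor reference measurements per day; the same
specimens measured again after ultrasound treatment; and four held-out
specimens whose true lg counts equal the published test-set reference
values, so the prediction table is directly comparable in scale.

VOC emission is log-linear: for each class (acids, alcohols, ketones,
aldehydes, esters, water),

    c = max(0, c0 + a·lgQ + b·lgY + d·lgM + e·fat + f·protein) · e^N(0, s²)

in mmol/dm³. Acids and aldehydes track the total bacterial count, alcohols
and esters the yeasts, ketones the molds; fat and protein contribute small
matrix terms. Ultrasound treatment doubles the yeast/mold coefficients
(b, d), standing in for increased volatile emission after cell disruption.
This is the simplest structure consistent with microbial VOC production; it
does not model metabolic interactions, species composition (two specimens
with equal counts but different microflora emit identically), storage-time
kinetics, or saturation. Passing tests therefore demonstrate that the
*pipeline* recovers lg counts when the emission model holds — not that the
emission model is true of real milk.

Sensor response slopes (Hz per mmol/dm³) are anchored to the published
characterisation: for acids, alcohols and ketones they invert the printed
limits of determination via slope = 3.3σ/LOD with σ the sensor's point
noise; aldehydes reuse the ketone (carbonyl) slopes and esters half the
mean of alcohol/ketone slopes, since no dedicated LOD rows exist for those
classes. The printed LOD and Ks tables are mutually inconsistent under a
single linear response with one blank SD, so they are kept as *separate*
anchors: LOD-derived slopes drive calibration-series simulation, Ks-derived
water slopes drive selectivity checks, and the water-class sensitivities of
the milk simulation (100–200 Hz per mmol/dm³) are chosen independently so
the daily water-vapor reference signals are large (≈200–400 Hz).

Noise model and chosen magnitudes:

* per-point curve noise: the sensor's characterised noise (1–11 Hz);
* replicate scatter: lognormal, 8 % per VOC class for milk (puts the
  replicate CVs of the calculated parameters in the observed 5–20 % band),
  1 % for water references (keeps day-normalized water signals inside the
  observed 0.95–1.05 band — a 4 % scatter, sometimes quoted for this
  purpose, mathematically cannot: the ratio SD would be ≈3.3 %);
* day-level drift: a 3 % lognormal per-(sensor, day) sensitivity factor
  shared by all of a day's measurements — exactly the component the daily
  water normalization removes — plus an in-record baseline ramp derived
  from the characterised 180-day drift, which is negligible within a
  120 s record, as physically expected.

## Preprocessing

Curves are smoothed with a Savitzky–Golay filter (window 3, degree 1 — a
centered 3-point moving average). Endpoints are handled by the edge
polynomial fit rather than mirror padding: mirroring distorts the ends of
any non-even signal, and the defining property of the filter — exact
reproduction of polynomials up to its degree — then fails at the
boundaries. Responses and whole curves are divided by the same-day,
same-sensor arithmetic mean of the water-reference signals. Curves are
linearly resampled to 78 points over the full record; 78 is reverse-
engineered from the fixed matrix width 701 = 8×78 + 8 + 69. Block scaling
autoscales curve-point and max-signal columns and centers calculated-
parameter columns only; zero-variance scaled columns are excluded with a
warning, and missing entries are imputed with training-column means before
scaling.

## Calculated-parameter catalogue (version v1)

The exact published formula list for the 69 parameters is not available;
the catalogue is *reconstructed* from the named families: 28 pairwise
max-signal ratios A_i/j over the C(8,2) unordered sensor pairs, 28
sorption-area ratios, 8 kinetic parameters β_i (response at half the 40 s
sorption window over the maximal response; in [0, 1] for monotone
sorption), and 5 array aggregates (summed normalized response, summed
normalized area, mean β, max/min response ratio, and δ-similarity of the
unit-mean response profile to the flat water profile). Ratios, β and
aggregates 3–5 are invariant to a common per-measurement gain — the
computational content of the frontal-vs-injected comparability claim —
which is asserted exactly on noiseless simulations. Ratio denominators
below 1 Hz (raw) propagate as missing values. The catalogue is versioned so
an alternative list can be swapped in if the original becomes available.

The similarity parameter is the bounded, symmetric L1 overlap
δ = 100·(1 − Σ|a−b| / Σ(|a|+|b|)) ∈ [0, 100], with δ = 100 only for
identical profiles; the original reference formula is unavailable, so this
is a documented reconstruction, as is the coincidence criterion
|x − ref| ≤ k·CV·|ref| (default k = 3).

## Regression

PLS1 is fitted by NIPALS on block-scaled features with a centered response;
the algorithm is deterministic (no random initialisation) and at full rank
coincides with least squares, which the tests verify against an independent
pseudo-inverse oracle and against scikit-learn's NIPALS implementation.

Model checking uses full (leave-one-out) cross-validation with the scaling
re-learned inside every fold; the factor count minimises the RMSEP curve,
ties broken toward fewer factors (cap 10). Variable selection iterates:
fit, drop variables with |b| below the 0.25 quantile or with variable
leverage above 2(f+1)/n, refit. Two numerical choices matter here and were
made after observing degenerate behaviour of the naive rules:

* *leverage safeguard*: normalized-loading leverage is rescaled so its mean
  is (f+1)/n (making the cutoff "twice the average" for any matrix shape),
  and a variable whose coefficient is in the top half is never removed for
  leverage alone — in PLS1 the most informative variables necessarily
  dominate the loadings, and an unguarded leverage rule deletes exactly
  them;
* *stop rule*: iteration continues while the CV RMSEP stays within 15 % of
  the best seen (CV error at n ≈ 48 fluctuates by that much between
  refits); the returned mask is the most parsimonious one within tolerance,
  a one-SE-style rule. Hard-stopping at the first non-improvement leaves
  most uninformative variables in place.

Metrics: RMSEP from the LOO residuals, R² on the LOO predictions,
Δ% = 100·RMSEP/max(y_train). The Δ% definition reproduces the published
4.9 (total count, RMSEP 0.390 / lg 7.99) and 12 (yeast, 0.535 / lg 4.53);
the published mold row would give 18.7 rather than the printed 17, a known
inconsistency of that reconstruction.

Prediction deviations are RMSEP·√(1 + h) with h the new sample's leverage
in score space, so deviations are never below the RMSEP. The RMSEP used
for deviations is re-estimated by *leave-one-specimen-out* cross-validation
when replicate groups are supplied: record-level LOO keeps a specimen's
sibling replicates in training and underestimates the error for a genuinely
new specimen. Yeast and mold models are trained on the ultrasound-treated
measurement set, the total count on the untreated set.

## Limit of determination and related quantities

LOD = k·σ_blank/slope with k = 3.3 (the calibration line anchored at the
blank mean, intersected with the blank + 3.3σ threshold). The estimator's
consistency is tested at 1000 blank replicates. Sauerbrey mass uses
Δm = −Δf·A·√(ρ_q μ_q)/(2F₀²) with configurable electrode area (default
0.2 cm²) and standard AT-cut quartz constants; since only F₀ = 14.0 MHz is
characterised, coating masses are magnitude anchors, not exact targets.
lg-scale values back-transform to CFU as center 10^lg with half-range
(10^(lg+sd) − 10^(lg−sd))/2.

## Problem sizes and determinism

The default study runs 16 specimens × 3 replicates × 2 treatment states
plus 4 test specimens and 18 water references (~150 measurements of 8
curves each), and trains three variable-selected models with LOO CV — a few
seconds per seed on one CPU. A single master seed is split into per-stage
seeds (day gains, water, milk, ultrasound, test) via `SeedSequence.spawn`,
so a rerun with the same seed reproduces every artifact bitwise.

## Known limitations

* The catalogue, δ formula and coincidence criterion are reconstructions of
  unavailable originals; profile subsets for farm comparison are a config
  choice with no claim of fidelity to the published figures.
* Deviations are calibrated for new specimens drawn from the study
  population. Specimens with an independent correlation structure among the
  three indicators show larger errors than the specimen-out RMSEP predicts,
  because the model legitimately exploits the population's inter-indicator
  correlations; coverage of ±deviation on such specimens drops toward ~60 %.
* The emission model is population-level and steady-state; no species
  effects, no adsorption isotherms beyond first-order kinetics, no coating
  aging.
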