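# Methods

This note documents the models implemented in `driftccs`, the parameter
choices behind them, what the synthetic data generator does and does not
emulate, and the numerical conventions a maintainer needs to know.

## Physical model

All calibration modes rest on the low-field Mason–Schamp relation between
an ion's reduced mobility K0 (normalised to 273.15 K, 760 Torr) and its
collision cross section Ω with the buffer gas:

    Ω = (3 z e / 16 N0) · sqrt(2π / (μ k T)) · (1 / K0)

with μ = mI·mB/(mI+mB) the ion–neutral reduced mass, N0 the Loschmidt
number density, k the Boltzmann constant, T the drift-gas temperature.
Constants are pinned to CODATA values (k = 1.380649e-23 J/K,
e = 1.602176634e-19 C, N0 = 2.6867801e25 m⁻³,
1 Da = 1.66053906660e-27 kg); buffer-gas masses default to N₂ = 28.0134 Da
and He = 4.002602 Da and are user-overridable. The ion mass is
mI = mz·z ∓ z·mₑ (mₑ = 5.48579909e-4 Da; minus for positive, plus for
negative polarity). The electron-mass correction is below the precision of
any reported CCS but is fixed so that results are deterministic and
polarity-consistent.

Unit contract throughout: arrival times ms, drift length cm, pressure
Torr, temperature °C at I/O boundaries and K internally, K0 cm²/(V·s),
CCS Å², masses Da. The low-field assumption (mobility independent of field
strength) is taken as given; high-field corrections and
temperature-dependent collision-integral models are out of scope.

## Stepped-field regression

The per-field regressor is

    x_n = 1000 · L² · (273.15/760) · P_n / (T_n,K · V_n)

so that tA = x/K0 + t0 holds exactly in the package's units; the factor
1000 converts seconds to milliseconds so the fitted slope is 1/K0 with K0
in cm²/(V·s). Temperature enters the regressor per field rather than being
factored out: with per-field T the relation stays exact when the drift
temperature drifts across fields. The representative temperature for the
final Mason–Schamp step is the mean of the per-field temperatures over the
fields used in the accepted combination.

Candidate features per field are the m/z matches within the ppm tolerance
(default 20 ppm), capped at the top `max_rank` (default 3) by intensity;
ties break by lower arrival time then lower m/z so the search is
deterministic. Every combination of one candidate per field is fitted by
unweighted ordinary least squares; fits with r² ≥ `r2_threshold` (default
0.99) and positive slope are kept and reported as conformers, sorted by
descending r² then summed intensity. By default combinations must span all
candidate-bearing fields; setting `min_fields` lower allows dropping
fields, implemented by adding a "skip" option per field (bounding the
search at (max_rank+1)^n_fields combinations). Two passing fits whose CCS
agree within 0.5% and that share at least half their features are
considered the same conformer and merged, keeping the higher r²; the
combination search otherwise reports near-identical duplicates whenever a
field may be skipped. Replicate statistics use the arithmetic mean and
%RSD with the n−1 standard deviation; a single replicate reports RSD 0
with a `single_replicate` flag.

## Single-field calibration

Standard mode regresses calibrant arrival times on the reduced CCS
Ω′ = (1/z)·sqrt(mI/(mI+mB))·Ω; enhanced mode regresses on
Ω″ = (P/T)·Ω′ with P, T the calibrant run's mean conditions, and converts
back using the *sample* run's mean conditions, cancelling pressure and
temperature drift between runs. When P/T is constant across runs the two
modes are algebraically identical (the ratio is absorbed into the slope).
The residual √T dependence of the true slope (the Mason–Schamp
relation carries sqrt(T) inside the mobility) is treated as constant in
both modes; over realistic laboratory drift (a few K) it is an order of
magnitude smaller than the P/T term the enhanced mode removes. Per-run P
and T are the means over that run's frame-metadata rows — the
deterministic reduction of well-recorded per-frame readings.

Calibrant matching reuses the m/z tolerance machinery (default 20 ppm,
highest-intensity feature wins per calibrant); at least two matched
calibrants are required, and a negative fitted slope is a hard calibration
failure. Unknown features default to charge 1 unless a `charge` column is
supplied — feature finders frequently omit charge, and most small-molecule
features are singly charged. Calibration-to-sample assignment picks, among
same-polarity calibrations, the closest one acquired at or after the
sample run (ties broken by run id); when none follows, the closest
preceding one is used and records carry a `calibration_fallback` flag. The
package deliberately assigns a single calibrant run per sample rather than
interpolating between the surrounding two. `tims_scan` mode is the
standard fit with scan numbers substituted for arrival times and no P/T
term. Features whose arrival time falls outside the calibrant range are
flagged `extrapolated`; arrival times at or below t0 yield `invalid`
records. Records are never dropped: output row count equals input feature
count.

## Traveling-wave calibration

Polynomial mode fits Ω′ as a degree-D polynomial of t′ = tA − t_acc by
least squares, with D+2 calibrant points required so the fit is never an
exact interpolation (degree 2 by default, allowed 1–4; degree 1 reduces
to the single-field standard fit). Power mode corrects arrival times as

    t′ = tA − C·sqrt(m/z)/1000 − t_acc

(C the Synapt EDC delay coefficient, 0 on SLIM; t_acc the SLIM
ion-accumulation time, typically 1000 ms), then proceeds in three stages:
OLS of ln Ω′ on ln t′ for the exponent X and ln Y; the doubly-corrected
time t″ = t′^X·z/√μ; and a final OLS of reference Ω on t″ for (a, b).
Both stages' r² are stored.

Two typographic ambiguities in the published rendering of this protocol
are resolved as follows, matching the de-facto TWIMS calibration
literature: the second-stage correction uses z/√μ (not z·(1/μ)), which
makes the final line dimensionally consistent with Ω′ ∝ Ω·√μ/z up to the
constant √mB; and the EDC term is C·sqrt(m/z)/1000 in ms. The reduced-CCS
normalisation uses sqrt(mI/(mI+mB)) uniformly across all modes (it differs
from √μ only by the constant √mB, which the fitted slope absorbs).

Extrapolation flagging compares the corrected time t′ against the
calibrant t′ range and is monotone by construction: any feature farther
outside the range than a flagged one is also flagged. The empirical curve
is only trusted where calibrants anchored it — CCS computed in the
extrapolation region is reported but marked.

The ΔCCS% comparison metric is 100·|Ω_a − Ω_ref|/Ω_ref, reported to two
decimals in outputs.

## Synthetic campaigns

The generator inverts each forward model with known truth, so round-trip
tests separate implementation defects from model error:

* stepped-field: tA = x_field/K0_true + t0 over the 850–1450 V, 100 V-step
  ladder of a commercial drift-tube QTOF, at 3.95 Torr, 28 °C, L =
  78.236 cm, t0 = 0.2 ms — typical values for that instrument class;
* single-field: tA = s·Ω″(run P, T) + t0 with the instrument slope s fixed
  at the nominal temperature (equivalently, K0 evaluated at nominal T),
  i.e. exactly the enhanced calibration's forward model. Campaigns
  interleave calibrant and sample runs every 10 minutes, with a calibrant
  run every k-th slot and always one at the end. Drift programs: constant,
  linear ramp, three-level step (mimicking discrete condition changes that
  produce multi-modal arrival-time distributions), and a bounded seeded
  random walk; default amplitudes ±2% pressure, ±1% temperature (Kelvin
  scale);
* traveling-wave: t′ = (Ω′/Y)^(1/X), plus accumulation-time and EDC
  offsets. Under this forward model the implied final line is exactly
  a = Y·√mB, b = 0, so those are part of the returned truth.

Arrival-time noise is multiplicative Gaussian (a fraction of tA), default
0 — a minimal model sufficient to exercise every code path. The generators
do **not** emulate peak shapes and centroiding error, isotope envelopes,
charge-state envelopes, chemical background beyond planted decoy features,
ion-intensity saturation, or correlated instrument drift within a run.
Passing round-trip tests therefore demonstrates correctness of the
calibration algebra and the selection logic under the stated conditions,
not robustness to real-data peak-finding artefacts. All generators are
pure functions of (parameters, seed).

Test problem sizes — 7-field campaigns, 5-ion calibrant ladders,
30-run drift scenarios, 100-seed noise ensembles — were chosen as the
smallest sizes at which each statistical property under test is clearly
resolved.

## Numerical choices and degenerate inputs

* All fits are unweighted OLS (`scipy.stats.linregress`,
  `numpy.polynomial.polyfit`); the calibration protocols specify plain
  least squares, and weighting would need a peak-level error model the
  inputs do not carry.
* r² for polynomial fits is 1 − SS_res/SS_tot, defined as 1 when SS_tot
  is 0 (all calibrants identical — degenerate but not undefined).
* Intensity ties in ranking and matching break by arrival time then m/z;
  calibration-assignment ties break by run id. Every ordering in the
  package is total, making workflow outputs byte-identical across reruns.
* Fewer than 2 distinct drift voltages, fewer than 2 matched calibrants,
  fewer than D+2 polynomial points, or fewer than 3 power-law points raise
  typed errors; a combination search with no passing fit returns an empty
  result (absence of a conformer is a finding, not an error).
* Timestamps are ISO-8601; naive timestamps are interpreted as UTC.
  Numeric parsing is locale-independent (period decimal separator).
* CEF input support is a minimal dialect (m/z, drift time, intensity on a
  `Location` element; schema sketch in `driftccs.io.CEF_SCHEMA_NOTE`); full
  vendor CEF is out of scope. MZmine-style CSV column names are
  configurable, defaulting to the MZmine 2 convention in which the
  retention-time column carries the IMS arrival time.

## Known limitations

* CCS is computed from feature apexes/centroids as given; arrival-time
  distribution widths and conformer-ensemble analysis are out of scope.
* Charge assignment for unknown features is a default plus an optional
  input column, not a deisotoping inference.
* The enhanced mode corrects the P/T term only; slope drift from other
  causes (gas composition, field inhomogeneity) is not modelled.
* Confidence reporting on TWIMS calibration is limited to r² and the
  extrapolation flag; no pointwise prediction bands are propagated into
  records.
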