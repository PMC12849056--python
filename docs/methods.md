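# Methods

## Signal model and conventions

A profile channel is an ordered sequence `y[0..L−1]` of detector readings
with unit spacing; the x-axis is the 0-based sample index. Time and volume
columns in instrument exports are deliberately ignored: alignment and
quantification operate on data-point position, and differences in elution
speed or sampling rate between runs are handled explicitly by the length
normalization step rather than by trusting vendor time stamps. UV and
fluorescence channels of one run are stored as corresponding rows and share
all index-based operations (regions, offsets, stretch factors); only their
baselines are independent.

The baseline is a single scalar per channel, conventionally read near the
end of the profile where the gradient has fully eluted but sucrose solution
still passes the detector. `baseline_from_index(trace, index, window)`
takes the mean of a centered window at the chosen index (window 1 = the raw
sample). Because the window shrinks symmetrically at the trace edges, a
baseline read at the literal last sample uses a single noisy reading; the
CLI and the bundled pipelines therefore default to reading it a half-window
in from the end so the full window fits. A sloped or piecewise baseline is
not offered — the subtracted level is one number per channel, and negative
areas that result from a baseline set above the signal are reported with a
warning rather than clamped, since they are user-visible evidence of a bad
baseline choice.

## Smoothing and derivatives

Smoothing is a centered moving average; the window (odd, in samples) is the
single "degree of smoothing" knob. At the edges the window shrinks
symmetrically to the largest odd width that fits, so output length equals
input length, the output never leaves the input's value range, and a
constant trace is a fixed point. Windows up to the trace length are
accepted (the shrink rule handles them). Moving-average smoothing and
baseline subtraction are both linear, so their order is irrelevant — the
pipeline exploits this and the property suite asserts it.

Curvature is the discrete second difference
`d2[i] = y[i+1] − 2y[i] + y[i−1]`, defined for `i = 1..L−2`. Its output
index `i` corresponds to input index `i+1`; the offset is exposed as
`SECOND_DIFF_OFFSET` and applied whenever derived positions (inflection
points, peak seeds) are reported, so everything downstream speaks in
original-axis indices.

## Feature detection

A sample `i` is a local minimum at resolution `r` iff `y[i] ≤ y[j]` for all
in-range `j` with `|j−i| ≤ r`, strictly for at least one `j`; maxima are
defined on `−y`, which makes the min/max duality exact by construction.
The half-window `r` is the "resolution": raising it monotonically thins the
feature set (on plateau-free traces), suppressing noise-scale wiggles.
Plateaus are reported at their leftmost index, and `snap` (the headless
analogue of clicking near a valley in an interactive plot) breaks distance
ties toward the smaller index — both choices exist purely for determinism,
so that a replayed session reproduces every selection. The sliding-window
extremum test is computed with `scipy.ndimage` min/max filters in
"nearest" mode, which matches clipped windows exactly because replicated
edge values are themselves in-range samples.

Inflection points are sign changes of the raw second difference, reported
at the left sample of the crossing pair; the resolution half-window does
not enter their definition (callers smooth first if they need noise
robustness).

## Areas and summaries

The area of a closed region `[s, e]` is `Σ (y[i] − b)`, a pure sum with no
Δx factor; units are signal × samples, and relative areas
(e.g. Polysomes/Total, the global-translation readout) are dimensionless.
The accumulation is an explicit left-to-right loop rather than a pairwise
vector sum so the value is bit-for-bit reproducible across library
versions; split additivity over `[s,m] ∪ [m+1,e]` holds to 1e-12 relative
(IEEE addition is not associative, so exact equality is not claimed).
Replicates are summarized per (condition, region, channel, normalization
mode) with mean and sample standard deviation (n−1 denominator; 0 reported
for n = 1). No hypothesis testing is performed — the per-replicate table is
exported so any downstream statistics can be applied.

## Alignment and normalization

Profiles are aligned by integer shifts only: every profile's anchor (for
mammalian profiles conventionally the monosome/disome valley) is moved to
the maximum anchor index over the set, so all offsets are non-negative and
no resampling happens at the anchor. Sub-sample alignment and nonlinear
warping are out of scope by design.

Two normalizations compensate for run-to-run variation: *adjust to
largest* rescales each profile's baseline-subtracted y so its user-defined
Total area equals the maximal Total among the profiles (stored values
become `b + f·(y−b)`, so re-quantifying with the same baseline reproduces
the reference area to float precision); *adjust to longest* stretches each
profile along x by (reference Total sample count / own Total sample count)
via linear interpolation with endpoints preserved exactly. Ties for the
reference go to the first profile in input order. Region and anchor indices
are remapped through a length change by `round(i·(L'−1)/(L−1))`, recorded
in the session.

## Gaussian deconvolution

Within a user-restricted region the signal is modeled as
`Σ_k h_k exp(−(x−μ_k)²/(2σ_k²))`. Candidate positions are the negative
local minima of the smoothed second difference of the baseline-subtracted
profile, restricted to the region: a Gaussian bump's curvature is most
negative at its mean, so each sufficiently resolved peak contributes one
negative minimum. The fit is bounded nonlinear least squares
(`scipy.optimize.least_squares`, trust-region reflective) with

- `μ_k ∈ [seed_k − τ, seed_k + τ]`, `τ = 0.01·L` where `L` is the **entire
  profile length**, even when only a sub-region is fitted;
- `σ_k ∈ [1e-6, region length]`, `h_k ∈ [1e-12, ∞)` — positivity bounds
  added for robustness, since unbounded fits of overlapping peaks routinely
  produce negative heights;
- deterministic initialisation: `μ_k` at the seed, `h_k` from the
  baseline-subtracted signal at the seed (clamped to a small positive
  floor), `σ_k` half the distance to the nearest neighboring seed (region
  length / 4 for a single seed), clamped to `[0.5, region length]`. No
  random restarts, so a fit is exactly reproducible from its session
  parameters.

Optimizer tolerances are set to 1e-12 so noiseless fits reach
near-machine-precision residuals and superfluous components collapse
cleanly. Optimizer failure never raises: the result carries
`converged=False` and the best parameters found. Peaks whose fitted height
falls below 1e-6 × the region maximum are flagged degenerate but kept, so
failure modes stay auditable. Each peak's analytic area is
`h·σ·√(2π)`; fitted curves, residuals and per-peak tables are exportable as
CSV. By default the raw baseline-subtracted signal is fitted; a switch fits
the smoothed signal instead, and the choice is recorded in the session.

Deconvolution is deliberately user-guided and region-restricted: at the
profile ends peaks deviate from symmetry and unresolved shoulders (e.g.
half-mers) distort larger peaks, so automatic whole-profile deconvolution
is a non-goal.

## Input dialects

Instrument exports are one profile per delimited text file; the dialect
(delimiter, decimal mark, header lines to skip, 1-based UV/fluorescence
column ordinals) varies by vendor software *and* by the exporting machine's
language settings — a comma decimal forces a semicolon delimiter in "CSV"
files. Decimal-comma handling is a per-field character substitution before
parsing, so results are independent of the environment locale. Parse errors
name the offending 1-based line number. The shipped presets (peaktrak,
triax, primeview, custom) are editable config data with provisional
defaults; users must verify them against their own exports, and every field
is overridable. Fixture writing uses `repr` formatting (shortest
round-trip representation), so write→read reproduces values exactly in
every dialect.

## Synthetic profiles

The generator emulates the anatomy of a mammalian polysome profile on a
1000-sample axis: a large detergent peak (h = 3.0 at index 40), 40S
(h = 0.5, σ = 10, index 180), 60S (h = 0.7, σ = 11, index 240), 80S
(h = 1.6, σ = 13, index 310), then six polysome peaks from index 420 with
geometric height decay (ratio 0.72), widths growing by 15% per peak and
spacings shrinking by 10% — heavier fractions resolve worse, which stresses
deconvolution the way real profiles do. The default baseline is 0.25 and
the default noise is i.i.d. Gaussian with sd 0.03 (1% of the tallest
peak). Named variants: *runoff* halves the polysome heights (stalled
initiation lets elongating ribosomes run off), *halfmer* inserts low
shoulders between the 80S/P1 and P1/P2 peaks, *fluorescent* adds a
fluorescence channel as a reweighted mixture riding on the monosome and
polysome peaks with its own baseline and noise. Ground truth — analytic
per-peak areas and the exact polysome/total ratio of the noiseless mixture
over stated index ranges (Total from the 40S leading flank to the profile
end, Polysomes from the monosome/disome valley to the end) — is
recomputable from the recipe alone.

What the generator does **not** emulate: autocorrelated detector noise,
baseline drift during elution (a `drift` slope exists but defaults to 0),
sucrose-density distortions, peak asymmetry, and elution-speed warping.
Passing tests therefore demonstrate correctness of the computational
pipeline under idealized Gaussian-peak conditions, not robustness to every
artifact of real gradients; on real data the user-guided region and
parameter choices carry that burden, which is why sessions record them.

## Validation benchmark sizes

The end-to-end benchmark quantifies 3 replicates × 2 conditions of
1000-sample profiles and recovers each condition's polysome/total ratio
within 2% of ground truth (observed < 1% across seeds). The deconvolution
benchmark uses three σ = 8 Gaussians (heights 1.0/0.8/1.2) at indices
170/250/330 of a 500-sample trace, region [130, 370], seeded with smoothing
window 11 and resolution half-window 35; at 1% noise, 20 independent draws
recover all positions within 0.01·L and widths/heights within 5% in ≥ 90%
of runs (observed 20/20). The large half-window matters: in the flat gaps
between peaks the signal curvature is ~0, so noise always creates shallow
negative minima there, and only resolution-scale thinning removes them —
on real profiles this is exactly the "resolution" knob a user would raise.

## Sessions and determinism

A session is a YAML document (schema_version "1.0") holding, per profile:
file path, dialect, smoothing window, per-channel baselines, anchor,
regions, condition label and normalization factors; globally: the reference
mode (largest/longest/none), the relative-area label pair, and
deconvolution specs (region, smoothing, resolution, recorded seeds, raw-vs-
smoothed switch). Export→import is lossless field for field; unknown schema
versions are rejected, never migrated silently. Every operation in the
package is deterministic given its inputs — the only randomness lives in
the synthetic generator's explicit seed — so replaying a session on the
same input files reproduces every CSV byte for byte, and the CLI writes the
fully resolved parameter set of each run to a `.log.yaml` beside its
output.

## Known limitations

- One fluorescence channel; one profile per input file; no concatenated
  single-column UV+fluorescence layouts.
- Scalar baselines only; no drift correction.
- Linear stretch/shrink only; no correlation-optimized warping.
- Gaussian peak shapes only; no exponentially modified Gaussians for
  asymmetric peaks.
- Summaries report mean/sd/n only; statistical comparisons are left to
  downstream tools via the exported CSVs.
- Dialect presets are provisional; verify against your instrument's actual
  export before trusting column assignments.
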