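# Methods

This note documents the models implemented in `synaptenacity`, the
assumptions behind them, the tunable parameters, the design choices made
where the underlying conventions were genuinely open, and the known limits
of what the synthetic data can show.

## FRAP analysis

### Photobleaching correction

Repeated imaging bleaches the whole field, so raw recovery at a bleached
punctum mixes true exchange with acquisition bleaching. The correction

    F_norm(t) = (F_t / F_0) · (F_nb0 / F_nbt)

divides the bleached punctum's series (normalised to its pre-bleach level
`F_0`) by the relative decay of the across-reference average of
non-bleached puncta (`F_nbt`, with `F_nb0` its t = 0 value). Any factor
applied per time point to *all* post-bleach series cancels algebraically;
this exact-cancellation property is the module's contract and is asserted
in the tests (bit-identically for power-of-two factors, which are exact in
IEEE-754 arithmetic, and to 1e-12 relative tolerance for generic
exponential factors, where floating-point multiplication/division round
trips can differ by an ulp).

Assumptions: references experience the same illumination history as the
bleached punctum, and references are themselves in steady state. At least
one reference is required; simulated experiments follow the convention of
using ten.

### Two-pool recovery model

    F(t) = F_bl + (1 − F_bl)·[P_f (1 − e^(−t/τ_f)) + (1 − P_f)(1 − e^(−t/τ_s))]

- `F_bl` ∈ [0, 1): normalised fluorescence immediately post-bleach (set by
  the bleaching procedure, not by exchange).
- `P_f` ∈ [0, 1]: fractional size of the rapidly exchanging pool.
- `τ_f ≤ τ_s` (minutes): fast and slow exchange time constants.
- Asymptote is 1 (full recovery to the pre-bleach level); the model is
  monotone non-decreasing in t for any admissible parameters.

The functional form is the standard two-pool convention for synaptic
scaffold FRAP: it satisfies F(0) = F_bl, full recovery at t → ∞, and P_f
as the fast-pool weight.

**Fitting.** Bounded nonlinear least squares
(`scipy.optimize.least_squares`) on the parameterisation
(`F_bl`, `P_f`, `τ_f`, `δ`) with `τ_s = τ_f(1 + δ)`, `δ ≥ 0`, which removes
fast/slow label switching. Initialisation: `F_bl` = first post-bleach
value; `τ_f` = time at half of the final recovery; `τ_s = 10 τ_f`;
`P_f = 0.5`. Up to three perturbed starts; best residual wins; tolerances
1e-12. A constant (unbleached or fully stalled) curve is returned as a
flagged fit with `P_f` undetermined (NaN) rather than a spurious optimum.
When the fitted `τ_s < 2 τ_f` the fit is flagged `well_separated=False`:
with time constants within a factor of two the two-pool split is barely
identifiable and the pool fractions should not be over-read. Approximate
parameter standard errors from the Jacobian are attached for the same
reason.

Both entry points are supported: fitting each punctum's corrected curve,
and fitting the group-average curve (the pipeline does both; averaged
curves carry pointwise n and SEM).

**Fractional recovery** is the mean of the final three normalised values —
a model-free per-punctum summary of recovery extent over the recorded
horizon (the default simulated schedule covers 3 h, sampled every 5 min for
the first hour and every 10 min thereafter).

## Content-constancy statistics

### Smoothing

The 5-point low-pass filter is implemented as an unweighted centered moving
average — the most common reading of an otherwise unspecified "5-point
low-pass filter" — with symmetric truncation at the boundaries (the window
half-width shrinks near the ends so it never becomes one-sided; the first
and last samples pass through unchanged). Width is configurable and must be
odd.

### Range over mean

    (F_max − F_min) / F̄, computed on the smoothed trace

Max, min and mean are all taken after smoothing (the smoothing exists to
keep single-frame noise out of the extremes; applying the mean to the same
series keeps the statistic exactly scale-invariant). It is also invariant
to time reversal, and zero iff the smoothed trace is constant. Reported
internally as a fraction; percent formatting happens only in report
layers.

### Similarity Index and its normalization

`SI(t)` is the cosine between the vector of punctum intensities at t = 0
and at time t, over puncta tracked across the *entire* window. Lost and
split/merge-rejected puncta are excluded from the vectors (a punctum that
drops to background would otherwise pull the angle by its zero entry
rather than by reconfiguration); lost puncta still count toward loss
rates. SI is symmetric, lies in (0, 1] for positive data, and is exactly
invariant to any shared per-time-point factor — which is why global
photobleaching does not bias it.

Even a fully reshuffled configuration retains cosine similarity when
brightnesses share a distribution, so raw SI has a neuron-specific floor.
The floor is estimated by cyclically rotating the final intensity vector
against the t = 0 vector and averaging the SI over 10 nonzero offsets
(all offsets when the vector is short; otherwise sampled uniformly without
replacement, seeded — the offset-selection rule is not dictated by the
convention the statistic comes from, so it is explicit and configurable,
and an exact `offsets=` override exists for analyses that need
reproducible rotations). The affine map

    SI_norm(t) = (SI(t) − SI_shuffled) / (1 − SI_shuffled)

is the only affine normalization sending the floor to 0 while keeping
SI(0) = 1. `SI_norm` is *not* clipped: values below 0 are possible (e.g.
when the final vector is close to a rotation of the initial one, the floor
— which averages over rotations including the one mapping it back —
exceeds the raw value), and clipping would hide that diagnostic. Raw SI
values are always emitted alongside normalized ones so the normalization
is auditable. When the floor is within 1e-12 of 1 (degenerate,
rotation-invariant vectors) the normalized curve is defined as 1 where the
raw SI is 1 and NaN elsewhere.

### Loss rate

`n_lost / (n_tracked + n_lost)` per neuron; split/merge rejections are
excluded from numerator and denominator.

### Group comparisons

Two-sample two-sided Kolmogorov–Smirnov tests (`scipy.stats.ks_2samp`):
exact method below a combined n of 30, asymptotic above. For SI decay, the
final three SI values of each neuron's curve are averaged and those
per-neuron endpoints pooled per group; range-over-mean comparisons pool
per-punctum values; loss-rate comparisons pool per-neuron rates. α = 0.05
is the reporting default. No multiple-testing correction is applied beyond
these single pairwise tests; that is a deliberate mirror of the analysis
convention the package implements, and batteries of contrasts should be
corrected by the caller.

## Synthetic data generator

The generator emulates the statistical structure of the recordings the
analysis is designed for, with independent knobs for each phenomenon:

- **Trajectory process.** Punctum i carries a setpoint `s_i(t)` performing
  a slow random walk in log space (per-step SD `reconfiguration_sd`),
  seeded from a baseline with between-punctum log-spread `size_spread_sd`
  around `mean_intensity`. The observed log-deviation from the setpoint is
  AR(1) with per-step innovation SD `fluctuation_sd` and reversion
  `exp(−reversion_rate·dt)` per step. Observed fluorescence is
  `s_i(t)·exp(x_i(t))·exp(−bleach_rate·t)` plus additive Gaussian
  measurement noise, truncated at zero. The walk drives long-term
  reconfiguration (SI decay); the AR(1) term drives short-term fluctuation
  (range over mean).
- **Size spread.** `size_spread_sd` (default 0.8 log-units) exists because
  both the SI floor and realistic images require a wide punctum-brightness
  distribution; with identical setpoints the rotation floor degenerates to
  1 and normalized SI is undefined.
- **Loss events.** Exponential waiting times with rate scaled so the
  probability of loss within the experiment equals `loss_prob` exactly;
  after its loss time a trace reports background plus noise and is flagged
  `lost` with the time recorded.
- **Bleaching** is multiplicative and identical for all puncta of a neuron
  — the regime in which SI is provably insensitive to it.
- **Determinism.** One `numpy` Generator seeded per call; identical
  parameters and seed give bit-identical traces, stacks and ground truth.

**FRAP simulation** evaluates the two-pool model on a sampling schedule,
multiplies by the acquisition-bleach factor, adds Gaussian noise, and emits
ten (or more) constant-baseline reference series under the same bleach
factor — exactly the structure the correction assumes.

**Image rendering** draws each punctum as an isotropic 2-D Gaussian (SD
`psf_sd` pixels) whose integrated intensity equals the trace value, on a
constant background with optional Gaussian pixel noise, positions laid out
on a jittered grid with ≥4·psf_sd margins (drift included) and recorded
per frame as ground truth. Spots packed closer than ~6 PSF SDs trigger a
resolvability warning but render anyway.

### Genotype presets and calibration

Presets (`wt`, `ko`, `wt_blocked`, `ko_blocked`) encode the study's
*orderings*, not mechanistic biology: the knockout gets larger
`fluctuation_sd`, `reconfiguration_sd` and `loss_prob` than wild type;
under activity blockade the fluctuation ordering reverses; blocked presets
use the receptor-imaging cadence (30-min intervals over 8 h) versus 10-min
intervals over 12 h otherwise.

Absolute magnitudes are calibration choices, fixed once: loss probabilities
use the reported loss rates (6.2% / 9.1%); fluctuation and reconfiguration
SDs were chosen so preset populations land near the reported
range-over-mean scale (wild type ~34%, knockout ~40%, blocked ~26%/23%,
with the knockout–wild-type gap sized like the larger reporter contrasts so
the ordering is robust at test scale). One structural limitation follows
from the random-walk design: a log random walk's expected path range is
≈1.6× its final displacement, so per-trace range and configuration drift
are geometrically coupled, and no parameter choice reproduces a ~33% range
over mean together with a normalized-SI endpoint as low as ~0.6 over 12 h.
With presets pinned to the range-over-mean scale, preset normalized-SI
endpoints decay only to ~0.95–0.97. Real recordings evidently contain
slow, punctum-specific *trends* (directional growth/shrinkage) that
reorder configurations more per unit of per-trace range than a memoryless
walk does; emulating that would need a persistent-drift component, which
is out of scope here. Consequences for testing: SI-related checks assert
orderings, calibration (type-I error, power), exact algebra and oracle
equivalence — never the study's SI magnitudes.

## Tracking

All measurements run on maximal intensity projections across Z. Intensity
is the mean of a 7×7-pixel box centered on integer pixel coordinates
(fixed blocks, no interpolation; sub-pixel refinement is deliberately
absent because box extraction is integer anyway). Recentering follows the
brightest local maximum within `search_radius` of the previous center,
staying put when none is found; the tracker contains no randomness.

Flagging rules operationalise qualitative conventions and are all
configurable:

- *lost*: background-subtracted box mean below `k·σ_background` for `m`
  consecutive frames (defaults k = 2, m = 3); the loss frame is the first
  of the run. Background and noise default to the median and scaled MAD of
  the first frame.
- *merged*: two track centers within `min_separation` (default: the box
  size) in the same frame; both tracks are flagged.
- *split*: a second local maximum within the search radius at least 0.6×
  as bright as the best, at least 3 px away, and at least 8·σ above
  background — the brightness condition prevents noise peaks around a
  fading punctum from masquerading as splits.

The tracker is validated by round-trip properties against rendered ground
truth (positions within 1 px, intensity correlation r > 0.98 with bright
spots and pixel noise at ~5% of the box-mean signal, downstream range over
mean within 10% of the generating traces) — it is a documented stand-in
for interactive acquisition software whose recentering algorithm is
unpublished, and the round trip, not algorithmic fidelity, is its
contract.

## Pipeline and reporting

Runs are fully determined by a `RunConfig` (mode, group assignments,
metric parameters, seed); the config, seed and package version are
serialised into every summary so reruns reproduce outputs byte-for-byte.
Exclusions (split/merge rejections, losses, traces too short for range
over mean) are counted per group and reported — nothing is dropped
silently. Machine outputs keep full-precision fractions; percentages are a
report-layer formatting choice. Simulated FRAP groups use the two-pool
generating truths (knockout: τ_f = 18 min, τ_s = 7.2 h, P_f = 0.30;
wild type: τ_f = 20 min, τ_s = 4.7 h, P_f = 0.24) with `F_bl = 0.2` as a
calibration choice for the post-bleach level, which the pool model does
not determine.

## Problem sizes

Default test and acceptance problem sizes are chosen as the smallest at
which each statistical check is stable: calibration tests use 200
replicates of 20-neuron groups (30 puncta × 25 time points each); power
checks use 25 replicates at 20 neurons/group; the acceptance script runs
40 neurons/group at the full preset size (75 puncta × 73 time points) and
30 simulated FRAP synapses/group. The imaging round trip uses 9 bright,
well-separated puncta over 40 frames on a 160×160 field.

## Known limitations

- The generator emulates trajectory *statistics*, not biology: no spine
  morphology, no receptor biophysics, no activity dependence beyond preset
  orderings; presets are qualitative encodings.
- The random-walk reconfiguration model cannot reproduce deep SI decay at
  realistic range-over-mean levels (see calibration above).
- The tracker assumes well-separated, roughly isotropic puncta and small
  per-frame drift; it is not a general particle tracker.
- KS comparisons at very small group sizes are conservative (the exact
  two-sample statistic is discrete); calibration holds in the asymptotic
  regime the analyses actually use.
- Normalized SI can exceed 1 slightly or go below 0 by construction; raw
  SI is always available for auditing.
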