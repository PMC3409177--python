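# synaptenacity

Quantifying **synaptic tenacity** — the capacity of individual synapses to
preserve their molecular content and relative size over hours — from
long-term live-imaging of fluorescently tagged synaptic proteins.

Synapses are dynamic assemblies: scaffold molecules, receptors and vesicles
continuously exchange with extrasynaptic pools and with neighbouring
synapses. Live imaging of tagged reporters (e.g. a postsynaptic scaffold
protein, a vesicle protein, or a surface glutamate-receptor subunit) in
cultured neurons yields per-punctum fluorescence trajectories over 8–12
hours, and photobleaching experiments yield exchange kinetics. This package
implements the quantitative framework for analysing such recordings, plus a
synthetic-data generator with known ground truth so the entire analysis
chain is testable without microscope data.

## What it computes

**FRAP exchange kinetics.** Recovery after photobleaching is normalised to
the pre-bleach level and corrected for ongoing acquisition photobleaching
using the average of ≥10 non-bleached reference puncta,

```
F_norm(t) = (F_t / F_0) · (F_nb0 / F_nbt)
```

then fit by bounded nonlinear least squares to a two-pool recovery model

```
F(t) = F_bl + (1 − F_bl)·[ P_f (1 − e^(−t/τ_f)) + (1 − P_f)(1 − e^(−t/τ_s)) ]
```

with `P_f` the fractional size of the rapidly exchanging pool, `τ_f ≤ τ_s`
the fast/slow time constants, and `F_bl` the normalised fluorescence
immediately after the bleach. *Fractional recovery* is the mean of the
final three normalised values.

**Content constancy.** Per punctum, *range over mean* —
`(F_max − F_min) / F̄` of the 5-point-smoothed trace — measures fluctuation
magnitude and is invariant to global scaling. Per neuron, the *Similarity
Index* `SI(t) = g₀·g_t / (‖g₀‖‖g_t‖)` (the cosine of the angle between the
punctum-intensity vectors at time 0 and time t) measures preservation of
the "synaptic configuration"; it ignores any shared factor such as
photobleaching. Raw SI is normalised to each neuron's attainable floor,
estimated by cyclically rotating the final intensity vector against the
initial one (10 rotations averaged): `SI_norm = (SI − SI_shuffled)/(1 −
SI_shuffled)`.

**Turnover.** The loss rate is the fraction of reliably tracked puncta that
clearly disappeared; puncta that split or merged are excluded everywhere.

**Comparisons.** Group contrasts (per-punctum range-over-mean pools,
per-neuron SI endpoints and loss rates) use the two-sample two-sided
Kolmogorov–Smirnov test.

**Tracking.** Multi-frame stacks are maximum-projected across Z; puncta are
measured as mean pixel values in 7×7-pixel boxes recentered per frame on
the nearest local maximum, with loss / split / merge flagging.

## Worked example

```python
import numpy as np
from synaptenacity import *

# simulate one wild-type neuron and summarise its constancy
params = genotype_presets("wt", seed=7)
records, truth = simulate_trace_population(params, "wt", n_neurons=1)
neuron = records[0]
roms = [range_over_mean(tr).percent for tr in neuron.traces_with_status(TraceStatus.TRACKED)]
curve = normalized_si_curve(neuron, seed=7)
print(f"tracked {neuron.n_tracked()} puncta, lost {neuron.n_lost()}")
print(f"range over mean: {np.mean(roms):.1f} +/- {np.std(roms, ddof=1):.1f} %")
print(f"SI floor (shuffled): {curve.si_shuffled:.3f}")
print(f"normalized SI after 12 h: {si_endpoint(curve):.3f}")
print(f"loss rate: {100*loss_rate(neuron):.1f} %")

# FRAP: simulate a bleached punctum from known pools and refit it
from synaptenacity.pipeline import FRAP_TRUTHS
rec = simulate_frap_experiment(FRAP_TRUTHS["ko"], frap_schedule(),
                               noise_sd=0.02, bleach_rate=1e-3, seed=7)
fit = fit_double_exponential(bleach_correct(rec))
print(f"fast pool {fit.p_f:.2f}, tau_f {fit.tau_f:.0f} min, tau_s {fit.tau_s/60:.1f} h")
```

prints

```
tracked 73 puncta, lost 2
range over mean: 35.6 +/- 12.6 %
SI floor (shuffled): 0.634
normalized SI after 12 h: 0.965
loss rate: 2.7 %
fast pool 0.30, tau_f 19 min, tau_s 8.5 h
```

The single neuron's range-over-mean distribution sits near the wild-type
preset's calibrated ~34% scale; 2 of 75 puncta were lost; and the FRAP fit
recovers the generating two-pool parameters (fast pool 0.30, τ_f 18 min,
τ_s 7.2 h) from a noisy, photobleaching-corrupted simulated recovery.

A command-line interface mirrors the library
(`synaptenacity simulate|track|frap-fit|constancy|compare|run`); `run`
executes the full pipeline from a YAML config and writes per-punctum /
per-neuron CSVs, a JSON summary with the config and seed embedded, and
figures.

## Layout

- `synaptenacity.synthkit` — trace-population generator, FRAP simulator, image-stack renderer, genotype presets
- `synaptenacity.frap` — bleach correction, two-pool fitting, fractional recovery, curve averaging
- `synaptenacity.constancy` — smoothing, range over mean, SI, shuffled floor, loss rate, KS comparisons
- `synaptenacity.tracking` — max projection, detection, box-mean measurement, tracking with loss/split/merge flags
- `synaptenacity.pipeline` / `synaptenacity.cli` — end-to-end orchestration and the command-line tool
- `docs/methods.md` — model assumptions, parameter meanings, calibration choices and known limitations
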