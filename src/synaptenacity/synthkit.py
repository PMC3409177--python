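"""Synthetic punctum populations, FRAP experiments, and image stacks.

Every analysis stage in this package can be exercised against data with a
known ground truth.  The generator emulates the statistical structure of
long-term live imaging of fluorescently tagged synaptic proteins:

* per-punctum intensity trajectories sampled every ``dt`` minutes over
  many hours, with multiplicative short-term fluctuations and a slow
  drift of each punctum's characteristic size (which reorders puncta
  relative to each other and thus drives Similarity-Index decay);
* a global exponential photobleaching factor shared by all puncta;
* per-punctum loss events (the punctum disappears mid-experiment);
* two-pool FRAP recovery curves with additive measurement noise;
* rendered 2-D image stacks (Gaussian spots on a noisy background) for
  the tracking module.

Trajectory model
----------------
Each punctum ``i`` carries a setpoint ``s_i(t)`` performing a slow random
walk in log space (per-step SD ``reconfiguration_sd``), around a baseline
drawn with between-punctum log-spread ``size_spread_sd``.  The observed
log-deviation from the setpoint follows a discrete mean-reverting (AR(1))
process with per-step innovation SD ``fluctuation_sd`` and reversion rate
``reversion_rate`` per minute:

    x_i(k+1) = exp(-reversion_rate * dt) * x_i(k) + fluctuation_sd * eps

    F_i(k) = s_i(k) * exp(x_i(k)) * exp(-bleach_rate * t_k) + noise, >= 0

This gives independent knobs for short-term fluctuation magnitude
(range-over-mean) and long-term reconfiguration (SI decay).
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field

import numpy as np

from .datatypes import NeuronRecord, PunctumTrace, TraceStatus
from .errors import ParameterError
from .frap import FRAPFit, FRAPRecord, recovery_model

__all__ = [
    "GeneratorParams",
    "GroundTruth",
    "ImageStack",
    "simulate_trace_population",
    "simulate_frap_experiment",
    "render_image_stack",
    "genotype_presets",
    "frap_schedule",
    "PRESET_NAMES",
]


@dataclass(frozen=True)
class GeneratorParams:
    """Parameters of the synthetic trace population.

    Units: ``dt`` minutes; ``mean_intensity`` and ``measurement_noise_sd``
    arbitrary fluorescence units (AU); ``fluctuation_sd``,
    ``reconfiguration_sd`` and ``size_spread_sd`` are dimensionless
    log-scale SDs; ``reversion_rate`` and ``bleach_rate`` per minute;
    ``loss_prob`` is the probability that a punctum is lost at some point
    within the full experiment.
    """

    n_puncta: int = 75
    n_timepoints: int = 73
    dt: float = 10.0
    mean_intensity: float = 1000.0
    fluctuation_sd: float = 0.05
    reversion_rate: float = 0.02
    reconfiguration_sd: float = 0.02
    size_spread_sd: float = 0.8
    bleach_rate: float = 3e-4
    loss_prob: float = 0.06
    measurement_noise_sd: float = 15.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_puncta < 2:
            raise ParameterError("n_puncta", "must be >= 2")
        if self.n_timepoints < 2:
            raise ParameterError("n_timepoints", "must be >= 2")
        if self.dt <= 0:
            raise ParameterError("dt", "must be > 0")
        if self.mean_intensity <= 0:
            raise ParameterError("mean_intensity", "must be > 0")
        for name in (
            "fluctuation_sd",
            "reversion_rate",
            "reconfiguration_sd",
            "size_spread_sd",
            "bleach_rate",
            "measurement_noise_sd",
        ):
            if getattr(self, name) < 0:
                raise ParameterError(name, "must be >= 0")
        if not 0.0 <= self.loss_prob <= 1.0:
            raise ParameterError("loss_prob", "must lie in [0, 1]")

    def replace(self, **kw) -> "GeneratorParams":
        return dataclasses.replace(self, **kw)


@dataclass
class GroundTruth:
    """Ground truth emitted alongside synthetic data.

    ``setpoints[n]`` is an (n_puncta, n_timepoints) array of true setpoint
    trajectories (AU, bleach-free) for neuron ``n``; ``loss_times[n]`` has
    one entry per punctum (minutes, or NaN when never lost).  ``positions``
    is filled by :func:`render_image_stack`: (n_puncta, n_frames, 2) pixel
    coordinates (row, col) per frame.
    """

    setpoints: list[np.ndarray] = field(default_factory=list)
    loss_times: list[np.ndarray] = field(default_factory=list)
    positions: np.ndarray | None = None
    seed: int | None = None


@dataclass
class ImageStack:
    """A rendered time-lapse stack: frames (T, H, W) or (T, Z, H, W)."""

    frames: np.ndarray
    frame_times: np.ndarray
    psf_sd: float
    background: float
    noise_sd: float = 0.0
    pixel_size_um: float = 0.143

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        if self.frames.ndim not in (3, 4):
            raise ValueError("frames must be (T, H, W) or (T, Z, H, W)")
        if self.frames.shape[0] != self.frame_times.size:
            raise ValueError("frame count must equal the number of frame times")
        if np.any(self.frames < 0):
            raise ValueError("intensities must be >= 0")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


def simulate_trace_population(
    params: GeneratorParams,
    genotype_label: str = "wt",
    n_neurons: int = 1,
    condition: str = "",
    experiment_id: str = "exp0",
) -> tuple[list[NeuronRecord], GroundTruth]:
    """Simulate ``n_neurons`` fields of view of punctum traces.

    Returns the records and the matching :class:`GroundTruth` (setpoint
    trajectories and loss times, aligned one-to-one with emitted traces).
    Identical ``(params, genotype_label, n_neurons)`` give bit-identical
    output.
    """
    rng = np.random.default_rng(params.seed)
    n_p, n_t = params.n_puncta, params.n_timepoints
    t = np.arange(n_t) * params.dt
    bleach = np.exp(-params.bleach_rate * t)
    rho = np.exp(-params.reversion_rate * params.dt)

    records: list[NeuronRecord] = []
    truth = GroundTruth(seed=params.seed)
    for j in range(n_neurons):
        log_s0 = np.log(params.mean_intensity) + rng.normal(0.0, params.size_spread_sd, n_p)
        # slow setpoint random walk in log space
        steps = rng.normal(0.0, params.reconfiguration_sd, (n_p, n_t - 1))
        log_s = np.concatenate([log_s0[:, None], log_s0[:, None] + np.cumsum(steps, axis=1)], axis=1)
        # mean-reverting multiplicative fluctuation around the setpoint
        x = np.zeros((n_p, n_t))
        innov = rng.normal(0.0, params.fluctuation_sd, (n_p, n_t - 1))
        for k in range(1, n_t):
            x[:, k] = rho * x[:, k - 1] + innov[:, k - 1]
        setpoints = np.exp(log_s)
        clean = setpoints * np.exp(x) * bleach[None, :]

        # exponential waiting times scaled so P(loss within experiment) = loss_prob
        loss_times = np.full(n_p, np.nan)
        horizon = t[-1] if t[-1] > 0 else params.dt
        if params.loss_prob > 0:
            lam = -np.log1p(-min(params.loss_prob, 1.0 - 1e-12)) / horizon
            waits = rng.exponential(1.0 / lam, n_p)
            lost = waits <= horizon
            loss_times[lost] = waits[lost]

        noise = (
            rng.normal(0.0, params.measurement_noise_sd, (n_p, n_t))
            if params.measurement_noise_sd > 0
            else np.zeros((n_p, n_t))
        )

        record = NeuronRecord(
            neuron_id=f"{genotype_label}_n{j}",
            genotype=genotype_label,
            condition=condition,
            dt_min=params.dt,
            experiment_id=experiment_id,
        )
        for i in range(n_p):
            F = clean[i] + noise[i]
            status = TraceStatus.TRACKED
            loss_time = None
            if np.isfinite(loss_times[i]):
                status = TraceStatus.LOST
                loss_time = float(loss_times[i])
                gone = t >= loss_time
                F = F.copy()
                F[gone] = noise[i][gone]  # background + residual noise only
            F = np.clip(F, 0.0, None)
            record.traces.append(
                PunctumTrace(punctum_id=f"p{i}", t=t.copy(), F=F, status=status, loss_time=loss_time)
            )
        records.append(record)
        truth.setpoints.append(setpoints)
        truth.loss_times.append(loss_times)
    return records, truth


def frap_schedule(total_min: float = 180.0, fine_until: float = 60.0) -> np.ndarray:
    """Post-bleach sampling schedule: 5-min intervals initially, then 10-min.

    Mirrors a 3-hour recovery recording that samples densely at first and
    more sparsely later.
    """
    fine = np.arange(0.0, fine_until + 1e-9, 5.0)
    coarse = np.arange(fine_until + 10.0, total_min + 1e-9, 10.0)
    return np.concatenate([fine, coarse])


def simulate_frap_experiment(
    true_fit: FRAPFit,
    schedule: np.ndarray,
    noise_sd: float = 0.0,
    bleach_rate: float = 0.0,
    n_reference: int = 10,
    seed: int = 0,
    f0: float = 1.0,
    punctum_id: str = "bleached0",
) -> FRAPRecord:
    """Simulate one FRAP experiment from known two-pool parameters.

    The bleached-punctum series is the recovery model evaluated on
    ``schedule``, multiplied by ``exp(-bleach_rate * t)`` (ongoing
    acquisition photobleaching) plus additive Gaussian noise; the
    ``n_reference`` non-bleached reference series are a constant baseline
    times the same bleach factor plus noise.  ``noise_sd`` is in AU on the
    same scale as ``f0``.
    """
    schedule = np.asarray(schedule, dtype=float)
    if schedule.size == 0:
        raise ParameterError("schedule", "must not be empty")
    if schedule[0] != 0.0 or (schedule.size > 1 and not np.all(np.diff(schedule) > 0)):
        raise ParameterError("schedule", "must be strictly increasing and start at 0")
    if noise_sd < 0:
        raise ParameterError("noise_sd", "must be >= 0")
    if n_reference < 10:
        raise ParameterError("n_reference", "at least 10 non-bleached reference puncta required")
    if f0 <= 0:
        raise ParameterError("f0", "must be > 0")

    rng = np.random.default_rng(seed)
    decay = np.exp(-bleach_rate * schedule)
    model = recovery_model(schedule, true_fit.f_bl, true_fit.p_f, true_fit.tau_f, true_fit.tau_s)
    F_t = f0 * model * decay + rng.normal(0.0, noise_sd, schedule.size)
    F_nb = f0 * decay[None, :] + rng.normal(0.0, noise_sd, (n_reference, schedule.size))
    # noise must not push baselines non-positive for the correction to exist
    F_t = np.clip(F_t, 0.0, None)
    F_nb = np.clip(F_nb, f0 * 1e-6, None)
    return FRAPRecord(F0=f0, t=schedule, F_t=F_t, F_nb=F_nb, punctum_id=punctum_id)


def render_image_stack(
    record: NeuronRecord,
    truth: GroundTruth,
    psf_sd: float = 1.5,
    drift_per_frame: float | tuple[float, float] = 0.0,
    background: float = 20.0,
    noise_sd: float = 0.0,
    shape: tuple[int, int] = (128, 128),
    seed: int = 0,
) -> ImageStack:
    """Render a neuron's traces as Gaussian spots on a noisy background.

    Each punctum becomes a 2-D Gaussian of SD ``psf_sd`` pixels whose
    *integrated* (background-subtracted) intensity equals the punctum's
    trace value at that frame.  Base positions are laid out on a jittered
    grid with a margin of at least ``4 * psf_sd`` from every edge at every
    frame (accounting for drift); a stack that cannot satisfy the margin
    raises, while puncta packed more tightly than ~6 PSF SDs trigger a
    resolvability warning but are rendered anyway.  Ground-truth per-frame
    positions are recorded into ``truth.positions`` (n_puncta, T, 2).
    """
    rng = np.random.default_rng(seed)
    n_p = len(record.traces)
    n_t = len(record.traces[0]) if n_p else 0
    if n_p and any(len(tr) != n_t for tr in record.traces):
        raise ValueError("all traces must share a length to be rendered")
    H, W = shape
    drift = np.asarray(
        drift_per_frame if np.ndim(drift_per_frame) else (drift_per_frame, drift_per_frame),
        dtype=float,
    )
    margin = 4.0 * psf_sd
    total_drift = drift * max(n_t - 1, 0)

    if n_p:
        lo = np.array([margin, margin]) + np.maximum(-total_drift, 0.0)
        hi = np.array([H - 1 - margin, W - 1 - margin]) - np.maximum(total_drift, 0.0)
        if np.any(hi <= lo):
            raise ValueError("frame too small for the requested margin and drift")
        g = int(np.ceil(np.sqrt(n_p)))
        rows = np.linspace(lo[0], hi[0], g)
        cols = np.linspace(lo[1], hi[1], g)
        base = np.array([(rows[i // g], cols[i % g]) for i in range(n_p)])
        spacing = min(
            (rows[1] - rows[0]) if g > 1 else np.inf, (cols[1] - cols[0]) if g > 1 else np.inf
        )
        if spacing < 6.0 * psf_sd:
            warnings.warn(
                f"puncta spaced {spacing:.1f} px apart may be unresolvable at psf_sd={psf_sd}",
                stacklevel=2,
            )
        jitter_amp = min(0.2 * spacing, 2.0) if np.isfinite(spacing) else 2.0
        base = base + rng.uniform(-jitter_amp, jitter_amp, base.shape)
        positions = base[:, None, :] + drift[None, None, :] * np.arange(n_t)[:, None]
    else:
        positions = np.zeros((0, n_t, 2))

    frame_times = record.traces[0].t if n_p else np.arange(n_t, dtype=float)
    frames = np.full((n_t, H, W), float(background))
    if noise_sd > 0:
        frames += rng.normal(0.0, noise_sd, frames.shape)
    half = int(np.ceil(4.0 * psf_sd))
    norm = 1.0 / (2.0 * np.pi * psf_sd**2)
    for f in range(n_t):
        for i, tr in enumerate(record.traces):
            amp = tr.F[f]
            if amp <= 0:
                continue
            r, c = positions[i, f]
            r0, r1 = max(int(round(r)) - half, 0), min(int(round(r)) + half + 1, H)
            c0, c1 = max(int(round(c)) - half, 0), min(int(round(c)) + half + 1, W)
            rr, cc = np.meshgrid(np.arange(r0, r1), np.arange(c0, c1), indexing="ij")
            frames[f, r0:r1, c0:c1] += (
                amp * norm * np.exp(-((rr - r) ** 2 + (cc - c) ** 2) / (2.0 * psf_sd**2))
            )
    frames = np.clip(frames, 0.0, None)
    truth.positions = positions
    return ImageStack(
        frames=frames,
        frame_times=np.asarray(frame_times, float),
        psf_sd=psf_sd,
        background=background,
        noise_sd=noise_sd,
    )


PRESET_NAMES = ("wt", "ko", "wt_blocked", "ko_blocked")

# Contrast presets.  Orderings encode the study's qualitative findings:
# knockout populations fluctuate more, reconfigure faster and lose more
# puncta than wild type, while under activity blockade the fluctuation
# ordering reverses.  Absolute magnitudes are calibration choices (see
# docs/methods.md): chosen so the wild-type population lands near a
# range-over-mean of ~33%, a normalized-SI 12-h endpoint near ~0.6 and
# the reported loss rates (6.2% WT, 9.1% KO).  Blocked presets emulate
# the receptor-imaging condition (30-min intervals over 8 h).
_PRESETS: dict[str, dict] = {
    "wt": dict(
        n_puncta=75,
        n_timepoints=73,
        dt=10.0,
        fluctuation_sd=0.030,
        reconfiguration_sd=0.018,
        loss_prob=0.062,
    ),
    "ko": dict(
        n_puncta=75,
        n_timepoints=73,
        dt=10.0,
        fluctuation_sd=0.038,
        reconfiguration_sd=0.024,
        loss_prob=0.091,
    ),
    "wt_blocked": dict(
        n_puncta=40,
        n_timepoints=17,
        dt=30.0,
        fluctuation_sd=0.090,
        reconfiguration_sd=0.022,
        loss_prob=0.062,
    ),
    "ko_blocked": dict(
        n_puncta=40,
        n_timepoints=17,
        dt=30.0,
        fluctuation_sd=0.073,
        reconfiguration_sd=0.018,
        loss_prob=0.091,
    ),
}


def genotype_presets(name: str, seed: int = 0) -> GeneratorParams:
    """Documented parameter bundles for the study's contrast groups.

    ``name`` is one of ``wt``, ``ko``, ``wt_blocked``, ``ko_blocked``.
    Presets differ only in fluctuation/reconfiguration magnitudes, loss
    probability and sampling cadence; repeated calls return identical
    bundles.
    """
    if name not in _PRESETS:
        raise ParameterError("name", f"unknown preset {name!r}; choose from {PRESET_NAMES}")
    return GeneratorParams(seed=seed, **_PRESETS[name])
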