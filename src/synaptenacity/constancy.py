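"""Content-constancy statistics for tracked synaptic puncta.

Two complementary measures quantify how well individual synapses preserve
their molecular content over hours:

* **Range over mean** — per punctum, ``(F_max - F_min) / F_mean`` of the
  smoothed fluorescence trace.  Captures instantaneous fluctuation
  magnitude; invariant to global scaling, so insensitive to expression
  level and photobleaching.
* **Similarity Index (SI)** — per neuron, the cosine of the angle between
  the vector of punctum intensities at t = 0 and at time t.  SI = 1 means
  no change in puncta brightness *relative to each other*; decay of SI
  measures reconfiguration of the "synaptic configuration".  Because the
  cosine ignores vector length, SI is unaffected by multiplying all
  intensities by a shared factor (e.g. photobleaching).

Raw SI has a neuron-specific floor: even a completely reshuffled
configuration retains some similarity when punctum brightnesses share a
distribution.  :func:`shuffled_si_floor` estimates that floor by cyclically
rotating the final intensity vector against the t = 0 vector, and
:func:`normalized_si_curve` rescales SI affinely so the floor maps to 0 and
1 stays 1, making decay curves comparable across neurons.

Group comparisons use the two-sample Kolmogorov-Smirnov test, matching the
study's statistics: per-punctum values (range over mean) or per-neuron
values (loss rates; mean of the final three SI values per curve) are pooled
per group and compared.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .datatypes import NeuronRecord, PunctumTrace, TraceStatus
from .errors import InsufficientDataError, ParameterError

__all__ = [
    "RangeOverMean",
    "SICurve",
    "KSResult",
    "smooth",
    "smooth_trace",
    "range_over_mean",
    "similarity_index",
    "shuffled_si_floor",
    "normalized_si_curve",
    "loss_rate",
    "si_endpoint",
    "compare_si_curves",
    "compare_distributions",
]


@dataclass
class RangeOverMean:
    """Range-over-mean of one punctum (computed on the smoothed trace)."""

    value: float
    f_max: float
    f_min: float
    f_mean: float

    @property
    def percent(self) -> float:
        return 100.0 * self.value


@dataclass
class SICurve:
    """Per-neuron similarity-index time series.

    ``si_raw`` holds the cosine similarities against t = 0; ``si_shuffled``
    is the scalar rotation floor estimated from the final time point;
    ``si_norm = (si_raw - si_shuffled) / (1 - si_shuffled)`` maps the floor
    to 0 while keeping SI(0) = 1.  Raw values are always kept alongside the
    normalized ones.
    """

    t: np.ndarray
    si_raw: np.ndarray
    si_shuffled: float
    si_norm: np.ndarray
    neuron_id: str = ""
    n_puncta: int = 0

    def __len__(self) -> int:
        return self.t.size


@dataclass
class KSResult:
    """Two-sample Kolmogorov-Smirnov comparison with group summaries."""

    statistic: float
    pvalue: float
    n_a: int
    n_b: int
    mean_a: float
    mean_b: float
    sd_a: float
    sd_b: float
    method: str = "auto"

    def significant(self, alpha: float = 0.05) -> bool:
        return self.pvalue <= alpha


def smooth(values: np.ndarray, width: int = 5) -> np.ndarray:
    """Centered moving average with symmetric truncation at the boundaries.

    At index ``i`` the window half-width is ``min(width // 2, i, n-1-i)``,
    so the first and last samples are returned unchanged and the window
    never becomes one-sided.
    """
    if width < 1 or width % 2 == 0:
        raise ParameterError("width", "must be odd and >= 1")
    values = np.asarray(values, dtype=float)
    n = values.size
    h = width // 2
    out = np.empty_like(values)
    for i in range(n):
        k = min(h, i, n - 1 - i)
        out[i] = values[i - k : i + k + 1].mean()
    return out


def smooth_trace(trace: PunctumTrace, width: int = 5) -> PunctumTrace:
    """Return a copy of ``trace`` with the fluorescence low-pass filtered."""
    return PunctumTrace(
        punctum_id=trace.punctum_id,
        t=trace.t.copy(),
        F=smooth(trace.F, width),
        status=trace.status,
        loss_time=trace.loss_time,
    )


def range_over_mean(trace: PunctumTrace | np.ndarray, width: int = 5) -> RangeOverMean:
    """Normalized fluorescence range ``(F_max - F_min) / F_mean``.

    The trace is smoothed first (default 5-point low-pass filter) to
    suppress measurement noise; max, min and mean are all taken on the
    smoothed series.
    """
    values = trace.F if isinstance(trace, PunctumTrace) else np.asarray(trace, dtype=float)
    if values.size < 2:
        raise InsufficientDataError("range over mean needs at least 2 time points")
    s = smooth(values, width)
    mean = float(s.mean())
    if mean <= 0:
        raise InsufficientDataError("smoothed trace mean must be positive")
    f_max, f_min = float(s.max()), float(s.min())
    return RangeOverMean(value=(f_max - f_min) / mean, f_max=f_max, f_min=f_min, f_mean=mean)


def similarity_index(g0: np.ndarray, gt: np.ndarray) -> float:
    """Cosine of the angle between two punctum-intensity vectors."""
    g0 = np.asarray(g0, dtype=float)
    gt = np.asarray(gt, dtype=float)
    if g0.shape != gt.shape:
        raise ValueError(f"vector length mismatch: {g0.shape} vs {gt.shape}")
    if g0.size < 2:
        raise InsufficientDataError("SI needs vectors of length >= 2")
    n0 = np.linalg.norm(g0)
    nt = np.linalg.norm(gt)
    if n0 == 0 or nt == 0:
        raise ValueError("SI is undefined for a zero vector")
    return float(np.dot(g0, gt) / (n0 * nt))


def shuffled_si_floor(
    g0: np.ndarray,
    g_last: np.ndarray,
    n_shuffles: int = 10,
    seed: int = 0,
    offsets: list[int] | None = None,
) -> float:
    """Minimum-attainable-SI floor from cyclic rotations of the final vector.

    Averages ``SI(g0, rotate(g_last, k))`` over ``n_shuffles`` nonzero
    offsets ``k``, sampled uniformly without replacement (all nonzero
    offsets are used when there are at most ``n_shuffles`` of them).
    ``offsets`` overrides the sampling with an explicit list of nonzero
    rotations, which makes the floor exactly reproducible in analyses that
    need it.
    """
    g0 = np.asarray(g0, dtype=float)
    g_last = np.asarray(g_last, dtype=float)
    n = g0.size
    if n < 3:
        raise InsufficientDataError("shuffled SI floor needs vectors of length >= 3")
    if offsets is None:
        all_offsets = np.arange(1, n)
        if all_offsets.size <= n_shuffles:
            chosen = all_offsets
        else:
            rng = np.random.default_rng(seed)
            chosen = rng.choice(all_offsets, size=n_shuffles, replace=False)
    else:
        chosen = np.asarray(offsets, dtype=int)
        if np.any(chosen % n == 0):
            raise ParameterError("offsets", "rotation offsets must be nonzero modulo length")
    return float(np.mean([similarity_index(g0, np.roll(g_last, int(k))) for k in chosen]))


def _full_window_matrix(record: NeuronRecord) -> tuple[np.ndarray, np.ndarray]:
    tracked = record.traces_with_status(TraceStatus.TRACKED)
    if len(tracked) < 3:
        raise InsufficientDataError(
            f"neuron {record.neuron_id}: need >= 3 full-window tracked puncta, "
            f"got {len(tracked)}"
        )
    t = tracked[0].t
    for tr in tracked[1:]:
        if not np.array_equal(tr.t, t):
            raise ValueError("tracked traces must share one time base")
    return t, np.vstack([tr.F for tr in tracked])


def normalized_si_curve(
    record: NeuronRecord, n_shuffles: int = 10, seed: int = 0
) -> SICurve:
    """Raw and floor-normalized SI time series for one neuron.

    Only puncta tracked across the entire window enter the intensity
    vectors; lost and split/merge-rejected puncta are excluded (they are
    still counted by :func:`loss_rate`).  The floor is estimated from the
    final time point and the affine normalization maps it to 0, leaving
    SI(0) = 1 unchanged.
    """
    t, M = _full_window_matrix(record)
    g0 = M[:, 0]
    si_raw = np.array([similarity_index(g0, M[:, k]) for k in range(M.shape[1])])
    floor = shuffled_si_floor(g0, M[:, -1], n_shuffles=n_shuffles, seed=seed)
    denom = 1.0 - floor
    if denom < 1e-12:
        # degenerate: rotations indistinguishable from the original
        si_norm = np.where(np.isclose(si_raw, 1.0), 1.0, np.nan)
    else:
        si_norm = (si_raw - floor) / denom
    return SICurve(
        t=t.copy(),
        si_raw=si_raw,
        si_shuffled=floor,
        si_norm=si_norm,
        neuron_id=record.neuron_id,
        n_puncta=M.shape[0],
    )


def loss_rate(record: NeuronRecord) -> float:
    """Fraction of reliably tracked puncta that clearly disappeared.

    ``n_lost / (n_tracked + n_lost)``; split/merge-rejected puncta are
    excluded from both numerator and denominator.
    """
    n_lost = record.n_lost()
    n_eligible = record.n_tracked() + n_lost
    if n_eligible == 0:
        raise InsufficientDataError(f"neuron {record.neuron_id}: no eligible puncta")
    return n_lost / n_eligible


def si_endpoint(curve: SICurve, use: str = "norm") -> float:
    """Mean of the final three SI values of one curve."""
    values = curve.si_norm if use == "norm" else curve.si_raw
    if values.size < 3:
        raise InsufficientDataError("SI endpoint needs at least 3 time points")
    return float(np.mean(values[-3:]))


def _ks(a: np.ndarray, b: np.ndarray, exact_below: int = 30) -> KSResult:
    method = "exact" if (a.size + b.size) < exact_below else "asymp"
    res = stats.ks_2samp(a, b, alternative="two-sided", method=method)
    return KSResult(
        statistic=float(res.statistic),
        pvalue=float(res.pvalue),
        n_a=int(a.size),
        n_b=int(b.size),
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        sd_a=float(a.std(ddof=1)) if a.size > 1 else 0.0,
        sd_b=float(b.std(ddof=1)) if b.size > 1 else 0.0,
        method=method,
    )


def compare_si_curves(
    group_a: list[SICurve], group_b: list[SICurve], use: str = "norm"
) -> KSResult:
    """KS comparison of SI decay between two groups of neurons.

    The final three SI values of each neuron's curve are averaged; those
    per-neuron endpoint values are pooled per group and compared with a
    two-sample two-sided Kolmogorov-Smirnov test.
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise InsufficientDataError("each group needs at least 2 SI curves")
    a = np.array([si_endpoint(c, use=use) for c in group_a])
    b = np.array([si_endpoint(c, use=use) for c in group_b])
    return _ks(a, b)


def compare_distributions(values_a, values_b) -> KSResult:
    """Two-sample KS test with per-group mean +/- SD summaries.

    The generic comparison used for range-over-mean and loss-rate value
    distributions.
    """
    a = np.asarray(list(values_a), dtype=float)
    b = np.asarray(list(values_b), dtype=float)
    if a.size < 2 or b.size < 2:
        raise InsufficientDataError("each group needs at least 2 values")
    return _ks(a, b)
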