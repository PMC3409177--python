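"""Fluorescence recovery after photobleaching (FRAP) analysis.

FRAP reports molecular exchange between a synapse and its surrounding
pools: a punctum is photobleached and the return of fluorescence is
followed over hours.  The workflow implemented here is

1. :func:`bleach_correct` — normalise the bleached-punctum series to its
   pre-bleach level and divide out ongoing acquisition photobleaching,
   estimated from the average of non-bleached reference puncta:
   ``F_norm(t) = (F_t / F0) * (F_nb0 / F_nbt)``.
2. :func:`fit_double_exponential` — fit the corrected recovery to a
   two-pool model

   ``F(t) = F_bl + (1 - F_bl) * [P_f (1 - e^(-t/tau_f))
                                 + (1 - P_f) (1 - e^(-t/tau_s))]``

   where ``F_bl`` is the normalised fluorescence immediately after the
   bleach, ``P_f`` the fractional size of the rapidly exchanging pool and
   ``tau_f <= tau_s`` the fast/slow recovery time constants.  The model
   starts at ``F_bl`` and recovers to 1 (the pre-bleach level).
3. :func:`fractional_recovery` — the mean of the final three normalised
   values, the per-punctum summary of how much fluorescence returned.
4. :func:`average_frap_curve` — pointwise mean +/- SEM across puncta
   sharing a time base.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .errors import CorrectionError, InsufficientDataError

__all__ = [
    "FRAPRecord",
    "FRAPFit",
    "RecoveryCurve",
    "recovery_model",
    "bleach_correct",
    "fit_double_exponential",
    "fractional_recovery",
    "average_frap_curve",
]


@dataclass
class FRAPRecord:
    """One FRAP experiment: a bleached punctum plus reference puncta.

    ``F0`` is the pre-bleach fluorescence of the bleached punctum; ``t``
    the post-bleach sample times (minutes, strictly increasing, starting
    at the first post-bleach frame); ``F_t`` the bleached-punctum series;
    ``F_nb`` a (n_reference, n_time) matrix of non-bleached reference
    series used to estimate ongoing acquisition photobleaching.
    """

    F0: float
    t: np.ndarray
    F_t: np.ndarray
    F_nb: np.ndarray
    punctum_id: str = "bleached0"

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.F_t = np.asarray(self.F_t, dtype=float)
        self.F_nb = np.atleast_2d(np.asarray(self.F_nb, dtype=float))
        if self.F0 <= 0:
            raise CorrectionError("pre-bleach fluorescence F0 must be positive")
        if self.t.ndim != 1 or self.F_t.shape != self.t.shape:
            raise ValueError("t and F_t must be 1-D arrays of equal length")
        if self.t.size >= 2 and not np.all(np.diff(self.t) > 0):
            raise ValueError("times must be strictly increasing")
        if self.F_nb.shape[1] != self.t.size:
            raise ValueError("reference matrix must have one column per time point")
        if np.any(self.F_nb[:, 0] <= 0):
            raise CorrectionError("all reference t=0 values must be positive")

    @property
    def n_reference(self) -> int:
        return self.F_nb.shape[0]


@dataclass
class RecoveryCurve:
    """A (possibly averaged) normalised recovery curve.

    ``value`` is dimensionless with 1 = pre-bleach level.  For averaged
    curves ``n`` counts contributing puncta per time point and ``sem`` is
    the pointwise standard error of the mean.
    """

    t: np.ndarray
    value: np.ndarray
    n: np.ndarray | None = None
    sem: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.value = np.asarray(self.value, dtype=float)
        if self.value.shape != self.t.shape:
            raise ValueError("t and value must have the same length")
        if np.any(self.value < 0):
            raise ValueError("normalised recovery values must be >= 0")

    def __len__(self) -> int:
        return self.t.size


@dataclass
class FRAPFit:
    """Fitted two-pool recovery parameters with diagnostics.

    ``converged`` is False when the optimiser failed or the curve was
    degenerate (``p_f`` is then NaN).  ``well_separated`` is False when
    tau_s < 2 * tau_f, i.e. the two pools are too close in time scale for
    the split to be trustworthy.
    """

    f_bl: float
    p_f: float
    tau_f: float
    tau_s: float
    residual_norm: float
    converged: bool
    well_separated: bool = True
    n_points: int = 0
    param_stderr: dict = field(default_factory=dict)

    def predict(self, t: np.ndarray) -> np.ndarray:
        return recovery_model(np.asarray(t, float), self.f_bl, self.p_f, self.tau_f, self.tau_s)


def recovery_model(
    t: np.ndarray, f_bl: float, p_f: float, tau_f: float, tau_s: float
) -> np.ndarray:
    """Two-pool FRAP recovery model (normalised; 1 = pre-bleach level)."""
    t = np.asarray(t, dtype=float)
    rec = p_f * (1.0 - np.exp(-t / tau_f)) + (1.0 - p_f) * (1.0 - np.exp(-t / tau_s))
    return f_bl + (1.0 - f_bl) * rec


def bleach_correct(record: FRAPRecord) -> RecoveryCurve:
    """Normalise a FRAP record and divide out ongoing photobleaching.

    Returns ``F_norm(t) = (F_t / F0) * (F_nb0 / F_nbt)`` where ``F_nbt``
    is the across-reference average fluorescence at time t and ``F_nb0``
    that average at t = 0.  Any per-time-point factor applied to all
    post-bleach series simultaneously (e.g. exponential acquisition
    photobleaching) cancels algebraically.
    """
    if record.n_reference < 1:
        raise CorrectionError("at least one non-bleached reference punctum is required")
    f_nbt = record.F_nb.mean(axis=0)
    if np.any(f_nbt <= 0):
        raise CorrectionError("reference average must stay positive at every time point")
    f_nb0 = f_nbt[0]
    value = (record.F_t / record.F0) * (f_nb0 / f_nbt)
    return RecoveryCurve(t=record.t.copy(), value=value)


def _degenerate_fit(y: np.ndarray, n: int) -> FRAPFit:
    # Constant curve: nothing recovered because nothing was bleached (or the
    # punctum never recovered at all); pools are undetermined.
    return FRAPFit(
        f_bl=float(np.clip(np.mean(y), 0.0, 1.0)),
        p_f=float("nan"),
        tau_f=float("nan"),
        tau_s=float("nan"),
        residual_norm=float(np.linalg.norm(y - np.mean(y))),
        converged=False,
        well_separated=False,
        n_points=n,
    )


def fit_double_exponential(
    curve: RecoveryCurve,
    *,
    n_starts: int = 3,
    separation_factor: float = 2.0,
    xtol: float = 1e-12,
) -> FRAPFit:
    """Bounded nonlinear least-squares fit of the two-pool recovery model.

    The slow time constant is parameterised as ``tau_s = tau_f * (1 +
    delta)`` with ``delta >= 0`` so the fast/slow labels cannot switch.
    Initialisation: ``f_bl`` = first post-bleach value, ``tau_f`` = time at
    half of the final recovery, ``tau_s = 10 tau_f``, ``p_f = 0.5``; up to
    ``n_starts`` perturbed restarts are tried when the first attempt does
    not converge, and the best residual wins.

    A fit with ``tau_s < separation_factor * tau_f`` is flagged
    ``well_separated=False``: the two pools are then barely
    distinguishable and the fast/slow split should not be over-read.
    """
    t = curve.t
    y = curve.value
    n = t.size
    if n < 6:
        raise InsufficientDataError(f"need >= 6 time points to fit two pools, got {n}")
    if float(np.ptp(y)) < 1e-9:
        return _degenerate_fit(y, n)

    def residuals(x: np.ndarray) -> np.ndarray:
        f_bl, p_f, tau_f, delta = x
        return recovery_model(t, f_bl, p_f, tau_f, tau_f * (1.0 + delta)) - y

    f_bl0 = float(np.clip(y[0], 0.0, 0.95))
    final = float(y[-1])
    half_level = f_bl0 + 0.5 * (final - f_bl0)
    above = np.nonzero(y >= half_level)[0]
    t_half = float(t[above[0]]) if above.size and t[above[0]] > 0 else float(t[-1]) / 4.0
    tau_f0 = max(t_half, 1e-3)

    lo = np.array([0.0, 0.0, 1e-6, 0.0])
    hi = np.array([1.0 - 1e-9, 1.0, 1e8, 1e8])
    starts = [
        np.array([f_bl0, 0.5, tau_f0, 9.0]),
        np.array([f_bl0, 0.3, tau_f0 * 0.3, 30.0]),
        np.array([f_bl0, 0.7, min(tau_f0 * 3.0, 1e7), 3.0]),
    ][: max(1, n_starts)]

    best = None
    for k, x0 in enumerate(starts):
        x0 = np.clip(x0, lo, hi)
        res = least_squares(residuals, x0, bounds=(lo, hi), xtol=xtol, ftol=xtol, gtol=xtol)
        if best is None or res.cost < best.cost:
            best = res
        # first start converged cleanly: no need for restarts
        if k == 0 and res.success and res.cost < 1e-20:
            break

    f_bl, p_f, tau_f, delta = best.x
    tau_s = tau_f * (1.0 + delta)
    stderr: dict = {}
    try:
        jac = best.jac
        dof = max(n - 4, 1)
        s2 = 2.0 * best.cost / dof
        cov = s2 * np.linalg.pinv(jac.T @ jac)
        for name, var in zip(("f_bl", "p_f", "tau_f", "delta"), np.diag(cov)):
            stderr[name] = float(np.sqrt(max(var, 0.0)))
    except Exception:  # pragma: no cover - singular jacobian etc.
        pass

    return FRAPFit(
        f_bl=float(f_bl),
        p_f=float(p_f),
        tau_f=float(tau_f),
        tau_s=float(tau_s),
        residual_norm=float(np.sqrt(2.0 * best.cost)),
        converged=bool(best.success),
        well_separated=bool(tau_s >= separation_factor * tau_f),
        n_points=n,
        param_stderr=stderr,
    )


def fractional_recovery(curve: RecoveryCurve) -> float:
    """Mean of the final three normalised recovery values."""
    if len(curve) < 3:
        raise InsufficientDataError("fractional recovery needs at least 3 time points")
    return float(np.mean(curve.value[-3:]))


def average_frap_curve(curves: list[RecoveryCurve]) -> RecoveryCurve:
    """Pointwise mean +/- SEM over curves sharing an identical time base."""
    if not curves:
        raise InsufficientDataError("no curves to average")
    t0 = curves[0].t
    for c in curves[1:]:
        if c.t.shape != t0.shape or not np.array_equal(c.t, t0):
            raise ValueError("all curves must share an identical time base")
    mat = np.vstack([c.value for c in curves])
    mean = mat.mean(axis=0)
    n = mat.shape[0]
    if n > 1:
        sem = mat.std(axis=0, ddof=1) / np.sqrt(n)
    else:
        sem = np.zeros_like(mean)
    return RecoveryCurve(t=t0.copy(), value=mean, n=np.full(t0.shape, n), sem=sem)
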