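"""Core in-memory containers for punctum fluorescence time series.

A *punctum* is one discrete fluorescent spot in a projected time-lapse
image, corresponding to one synaptic site.  A :class:`PunctumTrace` is the
time-ordered fluorescence record of one tracked punctum; a
:class:`NeuronRecord` bundles all traces from one neuron / field of view
together with acquisition metadata (genotype, condition, frame interval).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np


class TraceStatus(str, enum.Enum):
    """Fate of a tracked punctum over the imaging session."""

    TRACKED = "tracked"
    LOST = "lost"
    REJECTED_SPLIT_MERGE = "rejected_split_merge"


@dataclass
class PunctumTrace:
    """Fluorescence trace of a single punctum.

    Parameters
    ----------
    punctum_id
        Identifier unique within the parent neuron.
    t
        Sample times in minutes, strictly increasing.
    F
        Mean fluorescence (arbitrary units, AU) at each time, >= 0.
    status
        Whether the punctum stayed tracked for the whole session, clearly
        disappeared (``LOST``), or was rejected because it split or merged.
    loss_time
        Time (minutes) at which a lost punctum disappeared; required when
        ``status`` is ``LOST``.
    """

    punctum_id: str
    t: np.ndarray
    F: np.ndarray
    status: TraceStatus = TraceStatus.TRACKED
    loss_time: float | None = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.F = np.asarray(self.F, dtype=float)
        if self.t.ndim != 1 or self.F.shape != self.t.shape:
            raise ValueError("t and F must be 1-D arrays of equal length")
        if self.t.size >= 2 and not np.all(np.diff(self.t) > 0):
            raise ValueError("sample times must be strictly increasing")
        if np.any(self.F < 0):
            raise ValueError("fluorescence values must be non-negative")
        if isinstance(self.status, str) and not isinstance(self.status, TraceStatus):
            self.status = TraceStatus(self.status)
        if self.status is TraceStatus.LOST and self.loss_time is None:
            raise ValueError("a lost punctum must record its loss time")

    def __len__(self) -> int:
        return self.t.size


@dataclass
class NeuronRecord:
    """All punctum traces from one neuron (field of view) plus metadata."""

    neuron_id: str
    traces: list[PunctumTrace] = field(default_factory=list)
    genotype: str = "wt"
    condition: str = ""
    dt_min: float = 10.0
    experiment_id: str = "exp0"

    @property
    def duration_min(self) -> float:
        if not self.traces:
            return 0.0
        return float(self.traces[0].t[-1] - self.traces[0].t[0])

    def traces_with_status(self, status: TraceStatus) -> list[PunctumTrace]:
        return [tr for tr in self.traces if tr.status is status]

    def n_tracked(self) -> int:
        return len(self.traces_with_status(TraceStatus.TRACKED))

    def n_lost(self) -> int:
        return len(self.traces_with_status(TraceStatus.LOST))

    def n_rejected(self) -> int:
        return len(self.traces_with_status(TraceStatus.REJECTED_SPLIT_MERGE))
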