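"""Sampling grids for longitudinal post-hepatectomy studies.

A :class:`TimeGrid` holds the ordered sample labels of a longitudinal design,
their clock times in hours post-resection, and a flag marking samples drawn
before the resection itself.  The first pre-resection sample is the baseline
against which all log2 fold changes are computed.  The default grid is the
one-year LDLT donor follow-up design: one preoperative baseline plus 14
post-operative points from 5 minutes to 12 months.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

HOURS_PER_MONTH = 730.0


@dataclass(frozen=True)
class TimeGrid:
    """Ordered time points of a longitudinal sampling design.

    Parameters
    ----------
    labels
        Time-point names, baseline first.
    hours
        Clock time of each sample in hours post-resection.  Pre-resection
        samples are coded at hour 0 (the baseline) or at their clock time
        with ``pre_resection`` set.
    pre_resection
        True for samples drawn before the liver resection (the preoperative
        baseline, and optionally a post-incision / pre-resection sample).
    """

    labels: tuple[str, ...]
    hours: tuple[float, ...]
    pre_resection: tuple[bool, ...] = field(default=())

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.hours):
            raise ValueError("labels and hours must have equal length")
        pre = self.pre_resection
        if not pre:
            pre = (True,) + (False,) * (len(self.labels) - 1)
            object.__setattr__(self, "pre_resection", pre)
        if len(pre) != len(self.labels):
            raise ValueError("pre_resection flags must match labels")
        if sum(pre) < 1:
            raise ValueError("grid needs at least one pre-resection baseline")
        if len(self.labels) < 3:
            raise ValueError("grid needs at least 3 time points")
        post = [h for h, p in zip(self.hours, pre) if not p]
        if any(b <= a for a, b in zip(post, post[1:])):
            raise ValueError("post-resection hours must be strictly increasing")

    # -- indexing helpers -------------------------------------------------
    def __len__(self) -> int:
        return len(self.labels)

    @property
    def baseline_index(self) -> int:
        return int(np.argmax(self.pre_resection))

    @property
    def postop_indices(self) -> np.ndarray:
        """Indices of samples drawn after the resection, in grid order."""
        return np.flatnonzero(~np.asarray(self.pre_resection))

    @property
    def pre_resection_indices(self) -> np.ndarray:
        """Pre-resection samples other than the baseline itself."""
        idx = np.flatnonzero(np.asarray(self.pre_resection))
        return idx[idx != self.baseline_index]

    def index_of(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"unknown time point {label!r}") from None

    @property
    def hours_array(self) -> np.ndarray:
        return np.asarray(self.hours, dtype=float)


#: One-year LDLT donor follow-up design: preoperative baseline plus 14
#: post-operative samples (5 min ... 12 months; 1 month = 730 h).
DEFAULT_LABELS = (
    "Before Surgery",
    "5 min", "30 min", "1 h", "2 h", "3 h", "4 h",
    "1 d", "2 d", "3 d", "4 d", "10 d",
    "3 mo", "6 mo", "12 mo",
)

DEFAULT_HOURS = (
    0.0,
    5 / 60, 0.5, 1.0, 2.0, 3.0, 4.0,
    24.0, 48.0, 72.0, 96.0, 240.0,
    3 * HOURS_PER_MONTH, 6 * HOURS_PER_MONTH, 12 * HOURS_PER_MONTH,
)


def default_grid() -> TimeGrid:
    """The 15-point study grid (baseline + 14 post-operative samples)."""
    return TimeGrid(labels=DEFAULT_LABELS, hours=DEFAULT_HOURS)
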