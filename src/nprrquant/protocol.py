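"""Stimulation protocols: timed trains of electrical stimulation trials.

A recording is laid out as  [pre_window | S1 | I1 | S2 | I2 | ... | Sn | post_window]
where S_k are stimulation trials (burst of pulses at a fixed frequency) and
I_k the inter-stimulation intervals (ISIs).  All analysis windows downstream
(trial peaks, in-trial integrals, undershoot integrals over ISIs) are derived
from this object.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["StimTrial", "StimulationProtocol", "make_protocol"]


@dataclass(frozen=True)
class StimTrial:
    """One stimulation burst.

    Parameters
    ----------
    onset, duration : float
        Start time and length of the burst, in seconds.
    frequency : float
        Pulse frequency in Hz.
    pulse_width_ms : float
        Width of the individual pulses in milliseconds (metadata; the frame-rate
        analysis never resolves single pulses).
    """

    onset: float
    duration: float
    frequency: float
    pulse_width_ms: float = 1.0

    @property
    def offset(self) -> float:
        return self.onset + self.duration


@dataclass(frozen=True)
class StimulationProtocol:
    """Ordered, non-overlapping stimulation trials plus the recording extent."""

    trials: tuple[StimTrial, ...]
    pre_window: float
    post_window: float
    frame_interval: float = 1.0
    extent: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.pre_window < 0 or self.post_window < 0:
            raise ValueError("pre_window and post_window must be >= 0")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be > 0")
        prev_off = None
        for t in self.trials:
            if t.duration <= 0:
                raise ValueError("trial duration must be > 0")
            if t.frequency <= 0:
                raise ValueError("trial frequency must be > 0")
            if prev_off is not None and t.onset < prev_off - 1e-9:
                raise ValueError("trials must be sorted by onset and non-overlapping")
            prev_off = t.offset
        if self.extent is None:
            last = self.trials[-1].offset if self.trials else self.pre_window
            object.__setattr__(self, "extent", last + self.post_window)

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    def frame_times(self) -> np.ndarray:
        """Sample times at ``frame_interval`` covering [0, extent]."""
        n = int(np.floor(self.extent / self.frame_interval)) + 1
        return np.arange(n) * self.frame_interval

    def trial_windows(self) -> list[tuple[float, float]]:
        """[onset, offset] per trial."""
        return [(t.onset, t.offset) for t in self.trials]

    def interval_windows(self) -> list[tuple[float, float]]:
        """Inter-stimulation intervals: [offset_k, onset_{k+1}]; the last
        interval runs from the final offset to the end of the recording."""
        out = []
        for k, t in enumerate(self.trials):
            end = self.trials[k + 1].onset if k + 1 < len(self.trials) else self.extent
            out.append((t.offset, end))
        return out

    def is_stimulated(self, times: np.ndarray) -> np.ndarray:
        """Boolean mask: which of ``times`` fall within a stimulation trial."""
        times = np.asarray(times, dtype=float)
        mask = np.zeros(times.shape, dtype=bool)
        for t in self.trials:
            mask |= (times >= t.onset) & (times < t.offset)
        return mask

    def trial_frequency(self, times: np.ndarray) -> np.ndarray:
        """Stimulation frequency at each time (0 outside trials)."""
        times = np.asarray(times, dtype=float)
        f = np.zeros(times.shape, dtype=float)
        for t in self.trials:
            f[(times >= t.onset) & (times < t.offset)] = t.frequency
        return f

    def to_dict(self) -> dict:
        return {
            "trials": [
                {
                    "onset": t.onset,
                    "duration": t.duration,
                    "frequency": t.frequency,
                    "pulse_width_ms": t.pulse_width_ms,
                }
                for t in self.trials
            ],
            "pre_window": self.pre_window,
            "post_window": self.post_window,
            "frame_interval": self.frame_interval,
            "extent": self.extent,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StimulationProtocol":
        return cls(
            trials=tuple(
                StimTrial(
                    onset=t["onset"],
                    duration=t["duration"],
                    frequency=t["frequency"],
                    pulse_width_ms=t.get("pulse_width_ms", 1.0),
                )
                for t in d["trials"]
            ),
            pre_window=d["pre_window"],
            post_window=d["post_window"],
            frame_interval=d.get("frame_interval", 1.0),
            extent=d.get("extent"),
        )


def make_protocol(
    n_trials: int = 4,
    stim_duration: float = 18.0,
    interval: float = 42.0,
    frequency: float = 70.0,
    pre_window: float = 30.0,
    post_window: float = 30.0,
    frame_interval: float = 1.0,
    pulse_width_ms: float = 1.0,
) -> StimulationProtocol:
    """Build a regular repeated-burst protocol.

    Defaults reproduce the standard NMJ paradigm: four 70 Hz bursts of 18 s
    separated by 42 s intervals, 1 ms pulses, imaged at 1 frame/s.

    Trial k (1-based) starts at ``pre_window + (k-1)*(stim_duration+interval)``;
    the recording extent is ``pre_window + n*stim_duration + (n-1)*interval +
    post_window`` (``pre + post`` when there are no trials).
    """
    if n_trials < 0:
        raise ValueError("n_trials must be >= 0")
    if n_trials > 0:
        if stim_duration <= 0:
            raise ValueError("stim_duration must be > 0")
        if interval < 0:
            raise ValueError("interval must be >= 0")
        if frequency <= 0:
            raise ValueError("frequency must be > 0")
    trials = tuple(
        StimTrial(
            onset=pre_window + k * (stim_duration + interval),
            duration=stim_duration,
            frequency=frequency,
            pulse_width_ms=pulse_width_ms,
        )
        for k in range(n_trials)
    )
    if n_trials > 0:
        extent = (
            pre_window
            + n_trials * stim_duration
            + (n_trials - 1) * interval
            + post_window
        )
    else:
        extent = pre_window + post_window
    return StimulationProtocol(
        trials=trials,
        pre_window=pre_window,
        post_window=post_window,
        frame_interval=frame_interval,
        extent=extent,
    )
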