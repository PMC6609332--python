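"""Raw fluorescence -> dF/F conversion, baseline handling and ROI aggregation.

Conventions:

* dF/F is computed against the mean raw fluorescence over a pre-stimulation
  baseline window: ``dff(t) = (F(t) - F0) / F0``.
* The default baseline window runs from the recording start to 2 s before the
  first trial onset.
* A per-trial baseline correction ("corrected" traces) subtracts the mean
  dF/F over the 5 s immediately preceding each trial onset from that trial's
  samples, so peak heights are measured above the local pre-stimulation
  baseline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .protocol import StimulationProtocol
from .traces import DFFTrace, ROITraceSet

__all__ = [
    "DegenerateBaselineError",
    "default_baseline_window",
    "compute_dff",
    "compute_dff_set",
    "correct_trial_baseline",
    "AggregateTrace",
    "aggregate_mean_sem",
    "FoldChangeResult",
    "fold_change_screen",
]

BASELINE_GAP_S = 2.0  # default gap between baseline window end and first onset


class DegenerateBaselineError(ValueError):
    """Baseline window empty, too short, or with non-positive mean F."""


def default_baseline_window(protocol: StimulationProtocol) -> tuple[float, float]:
    """Recording start to 2 s before the first trial onset (whole pre-window
    when there are no trials)."""
    if protocol.n_trials == 0:
        return (0.0, protocol.extent)
    return (0.0, max(protocol.trials[0].onset - BASELINE_GAP_S, 0.0))


def compute_dff(
    frames: np.ndarray,
    f: np.ndarray,
    baseline_window: tuple[float, float],
    *,
    roi_id: str = "",
    roi_class: str = "whole",
    conditions: dict | None = None,
) -> DFFTrace:
    """dF/F of one raw series against the mean F over ``baseline_window``.

    Requires at least 3 frames in the window and a strictly positive mean.
    """
    frames = np.asarray(frames, dtype=float)
    f = np.asarray(f, dtype=float)
    lo, hi = baseline_window
    in_win = (frames >= lo) & (frames <= hi)
    if in_win.sum() < 3:
        raise DegenerateBaselineError(
            f"baseline window [{lo}, {hi}] contains {int(in_win.sum())} frames (< 3)"
        )
    f0 = float(np.mean(f[in_win]))
    if f0 <= 0:
        raise DegenerateBaselineError(f"mean baseline fluorescence {f0} <= 0")
    return DFFTrace(
        frames=frames,
        dff=(f - f0) / f0,
        baseline_value=f0,
        baseline_window=(lo, hi),
        roi_id=roi_id,
        roi_class=roi_class,
        conditions=dict(conditions or {}),
    )


def compute_dff_set(
    traces: ROITraceSet,
    baseline_window: tuple[float, float] | None = None,
    protocol: StimulationProtocol | None = None,
) -> list[DFFTrace]:
    """dF/F for every ROI in a set; the window defaults from the protocol."""
    if baseline_window is None:
        if protocol is None:
            raise ValueError("need baseline_window or protocol")
        baseline_window = default_baseline_window(protocol)
    return [
        compute_dff(
            traces.frames,
            traces.f[i],
            baseline_window,
            roi_id=traces.roi_ids[i],
            roi_class=traces.roi_classes[i],
            conditions=traces.conditions,
        )
        for i in range(traces.n_rois)
    ]


def correct_trial_baseline(
    dff: DFFTrace,
    protocol: StimulationProtocol,
    pre_span: float = 5.0,
) -> DFFTrace:
    """Per-trial baseline correction.

    Each trial is re-expressed relative to its own pre-stimulation baseline:
    the mean dF/F of the input trace over ``[onset - pre_span, onset)`` is
    subtracted from every sample in ``[onset - pre_span, next onset -
    pre_span)`` (the last trial's span extends to the end of the recording).
    Samples before the first trial's pre-span are unchanged.  After one
    application every pre-trial mean is 0, so the operation is idempotent.
    """
    out = dff.dff.copy()
    frames = dff.frames
    for k, trial in enumerate(protocol.trials):
        if trial.onset - pre_span < frames[0] - 1e-9:
            raise ValueError(
                f"trial {k + 1}: less than {pre_span} s of pre-onset recording"
            )
        pre = (frames >= trial.onset - pre_span) & (frames < trial.onset)
        if not pre.any():
            raise ValueError(
                f"trial {k + 1}: no samples in the {pre_span} s pre-onset span"
            )
        shift = float(np.mean(dff.dff[pre]))
        nxt = (protocol.trials[k + 1].onset - pre_span
               if k + 1 < protocol.n_trials else np.inf)
        span = (frames >= trial.onset - pre_span) & (frames < nxt)
        out[span] -= shift
    return dff.copy_with(out)


@dataclass
class AggregateTrace:
    """Per-frame mean and s.e.m. across a set of dF/F traces."""

    frames: np.ndarray
    mean: np.ndarray
    sem: np.ndarray
    n: int
    single_trace: bool = False  # sem reported as 0 for n = 1


def aggregate_mean_sem(traces: list[DFFTrace]) -> AggregateTrace:
    """Per-frame mean and standard error (sample sd / sqrt(n)) across ROIs."""
    if not traces:
        raise ValueError("need at least one trace")
    frames = traces[0].frames
    for t in traces[1:]:
        if not np.array_equal(t.frames, frames):
            raise ValueError("traces do not share a frame vector")
    mat = np.vstack([t.dff for t in traces])
    n = mat.shape[0]
    mean = mat.mean(axis=0)
    if n == 1:
        warnings.warn("single trace: s.e.m. reported as 0", stacklevel=2)
        sem = np.zeros_like(mean)
    else:
        sem = mat.std(axis=0, ddof=1) / np.sqrt(n)
    return AggregateTrace(frames=frames, mean=mean, sem=sem, n=n,
                          single_trace=(n == 1))


@dataclass(frozen=True)
class FoldChangeResult:
    fold: float
    passed: bool
    threshold: float


def fold_change_screen(
    signal: float, reference: float, threshold: float = 2.0
) -> FoldChangeResult:
    """Expression/function screening rule: pass iff signal/reference >= threshold."""
    if reference <= 0:
        raise ValueError("reference fluorescence must be > 0")
    fold = signal / reference
    return FoldChangeResult(fold=fold, passed=fold >= threshold,
                            threshold=threshold)
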