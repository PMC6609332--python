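"""Release read-outs from dF/F traces.

Implements the standard per-trial quantities for stimulus-evoked reporter
recordings: in-trial peak and latency, trapezoidal integrals over trials and
inter-stimulation intervals (the ISI integral is the "undershoot" when
negative), tri-phasic segmentation (rising / falling / undershoot-recovery),
normalization of peaks across a frequency titration, and the bouton vs
inter-bouton-interval contrast ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .protocol import StimulationProtocol
from .traces import DFFTrace

__all__ = [
    "TrialMetrics",
    "trial_peaks",
    "interval_integrals",
    "TrialPhases",
    "PhaseSegmentation",
    "segment_phases",
    "FrequencyResponse",
    "normalize_frequency_response",
    "BoutonIBIRatio",
    "bouton_ibi_ratio",
]


def _window_values(
    frames: np.ndarray, y: np.ndarray, lo: float, hi: float
) -> tuple[np.ndarray, np.ndarray]:
    """Samples inside [lo, hi] with values interpolated at both boundaries,
    so integrals over windows are exact for piecewise-linear traces."""
    if lo < frames[0] or hi > frames[-1]:
        raise ValueError(
            f"window [{lo}, {hi}] outside recorded extent "
            f"[{frames[0]}, {frames[-1]}]"
        )
    inner = (frames > lo) & (frames < hi)
    t = np.concatenate(([lo], frames[inner], [hi]))
    v = np.concatenate((
        [np.interp(lo, frames, y)], y[inner], [np.interp(hi, frames, y)]
    ))
    return t, v


@dataclass
class TrialMetrics:
    """Per-trial peaks/latencies and per-window integrals, in protocol order.

    ``interval_integrals`` holds one value per inter-stimulation interval
    (trial offset to next onset; the last runs to the end of the recording);
    a negative value is an undershoot.
    """

    peaks: np.ndarray = field(default_factory=lambda: np.array([]))
    latencies: np.ndarray = field(default_factory=lambda: np.array([]))
    trial_integrals: np.ndarray = field(default_factory=lambda: np.array([]))
    interval_integrals: np.ndarray = field(default_factory=lambda: np.array([]))
    trial_durations: np.ndarray = field(default_factory=lambda: np.array([]))
    interval_durations: np.ndarray = field(default_factory=lambda: np.array([]))

    @property
    def total_trial_integral(self) -> float:
        return float(np.sum(self.trial_integrals))

    @property
    def total_interval_integral(self) -> float:
        return float(np.sum(self.interval_integrals))

    def to_frame(self) -> pd.DataFrame:
        n = max(len(self.peaks), len(self.trial_integrals))
        df = pd.DataFrame({"trial": np.arange(1, n + 1)})
        for name, arr in [
            ("peak_dff", self.peaks),
            ("latency_s", self.latencies),
            ("trial_integral", self.trial_integrals),
            ("interval_integral", self.interval_integrals),
            ("trial_duration_s", self.trial_durations),
            ("interval_duration_s", self.interval_durations),
        ]:
            if len(arr):
                df[name] = arr
        # per-second variants, since window lengths can differ
        if len(self.trial_integrals) and len(self.trial_durations):
            df["trial_integral_per_s"] = self.trial_integrals / self.trial_durations
        if len(self.interval_integrals) and len(self.interval_durations):
            df["interval_integral_per_s"] = (
                self.interval_integrals / self.interval_durations
            )
        return df


def trial_peaks(dff: DFFTrace, protocol: StimulationProtocol) -> TrialMetrics:
    """In-stimulation peak dF/F and latency-to-peak for each trial.

    The peak is the maximum over [onset, offset] only (post-offset maxima are
    ignored); latency is measured from trial onset, ties resolved to the
    earliest frame.
    """
    peaks, lats, durs = [], [], []
    for lo, hi in protocol.trial_windows():
        if lo < dff.frames[0] or hi > dff.frames[-1]:
            raise ValueError(f"trial window [{lo}, {hi}] outside recording")
        sel = (dff.frames >= lo) & (dff.frames <= hi)
        vals = dff.dff[sel]
        times = dff.frames[sel]
        i = int(np.argmax(vals))  # first occurrence on ties
        peaks.append(float(vals[i]))
        lats.append(float(times[i] - lo))
        durs.append(hi - lo)
    return TrialMetrics(
        peaks=np.array(peaks),
        latencies=np.array(lats),
        trial_durations=np.array(durs),
    )


def interval_integrals(
    dff: DFFTrace, protocol: StimulationProtocol
) -> TrialMetrics:
    """Trapezoidal integrals of dF/F over trial windows and ISIs (dF/F * s)."""
    tri, tri_d = [], []
    for lo, hi in protocol.trial_windows():
        t, v = _window_values(dff.frames, dff.dff, lo, hi)
        tri.append(float(np.trapezoid(v, t)))
        tri_d.append(hi - lo)
    iv, iv_d = [], []
    for lo, hi in protocol.interval_windows():
        hi = min(hi, dff.frames[-1])
        t, v = _window_values(dff.frames, dff.dff, lo, hi)
        iv.append(float(np.trapezoid(v, t)))
        iv_d.append(hi - lo)
    return TrialMetrics(
        trial_integrals=np.array(tri),
        interval_integrals=np.array(iv),
        trial_durations=np.array(tri_d),
        interval_durations=np.array(iv_d),
    )


def trial_metrics(dff: DFFTrace, protocol: StimulationProtocol) -> TrialMetrics:
    """Peaks/latencies and integrals in one record."""
    p = trial_peaks(dff, protocol)
    i = interval_integrals(dff, protocol)
    return TrialMetrics(
        peaks=p.peaks,
        latencies=p.latencies,
        trial_integrals=i.trial_integrals,
        interval_integrals=i.interval_integrals,
        trial_durations=i.trial_durations,
        interval_durations=i.interval_durations,
    )


__all__.append("trial_metrics")


@dataclass
class TrialPhases:
    """Tri-phasic segmentation of one trial and its following interval."""

    rising: tuple[float, float] | None  # [onset, time of peak]
    falling_onset: float | None  # start of sustained post-peak decline
    undershoot_interval: tuple[float, float] | None  # within the ISI
    recovery_flag: bool  # trace re-enters [-eps, eps] before next onset
    undefined: bool = False  # degenerate (flat) trial


@dataclass
class PhaseSegmentation:
    trials: list[TrialPhases]
    smooth_span: int
    eps: float


def _moving_average(y: np.ndarray, span: int) -> np.ndarray:
    """Centered moving average; the window shrinks at the edges."""
    if span <= 1:
        return y.astype(float)
    c = np.convolve(y, np.ones(span), mode="same")
    norm = np.convolve(np.ones_like(y), np.ones(span), mode="same")
    return c / norm


def segment_phases(
    dff: DFFTrace,
    protocol: StimulationProtocol,
    smooth_span: int = 3,
    eps: float = 0.01,
) -> PhaseSegmentation:
    """Segment each trial's response into rising / falling / undershoot phases.

    Works on a ``smooth_span``-frame moving average.  Per trial:

    * rising: onset to the smoothed in-trial peak;
    * falling onset: first post-peak time from which the smoothed trace
      declines monotonically for at least 2 consecutive frames;
    * undershoot: the maximal contiguous span of the following ISI where the
      smoothed trace sits below ``-eps`` (None when it never does);
    * recovery flag: whether the trace re-enters [-eps, eps] after the
      undershoot and before the next onset.

    A flat trial (peak-to-trough span below ``eps``) is flagged undefined
    rather than raising.
    """
    sm = _moving_average(dff.dff, smooth_span)
    frames = dff.frames
    out = []
    windows = protocol.trial_windows()
    intervals = protocol.interval_windows()
    for k, (lo, hi) in enumerate(windows):
        sel = np.where((frames >= lo) & (frames <= hi))[0]
        if sel.size < 5:
            raise ValueError(f"trial {k + 1}: fewer than 5 frames")
        vals = sm[sel]
        if vals.max() - vals.min() < eps:
            out.append(TrialPhases(None, None, None, False, undefined=True))
            continue
        ipk = sel[int(np.argmax(vals))]
        rising = (lo, float(frames[ipk]))
        falling_onset = None
        for i in range(ipk, sel[-1] - 1):
            if sm[i + 1] < sm[i] and sm[i + 2] < sm[i + 1]:
                falling_onset = float(frames[i])
                break
        ilo, ihi = intervals[k]
        ihi = min(ihi, frames[-1])
        isel = np.where((frames >= ilo) & (frames < ihi))[0]
        below = sm[isel] < -eps
        undershoot = None
        if below.any():
            # maximal contiguous run below -eps
            runs, start = [], None
            for j, b in enumerate(below):
                if b and start is None:
                    start = j
                elif not b and start is not None:
                    runs.append((start, j - 1))
                    start = None
            if start is not None:
                runs.append((start, len(below) - 1))
            s, e = max(runs, key=lambda r: r[1] - r[0])
            undershoot = (float(frames[isel[s]]), float(frames[isel[e]]))
        recovery = False
        if isel.size:
            after = isel[isel >= (isel[0] if undershoot is None
                                  else np.searchsorted(frames, undershoot[1]))]
            if after.size:
                recovery = bool(np.any(np.abs(sm[after]) <= eps))
        out.append(TrialPhases(rising, falling_onset, undershoot, recovery))
    return PhaseSegmentation(trials=out, smooth_span=smooth_span, eps=eps)


@dataclass
class FrequencyResponse:
    """Peak responses across a frequency titration, as % of the reference."""

    normalized: dict[float, float]  # Hz -> percent of reference peak
    reference_frequency: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "frequency_hz": sorted(self.normalized),
                "normalized_peak_pct": [
                    self.normalized[f] for f in sorted(self.normalized)
                ],
            }
        )


def normalize_frequency_response(
    peaks_by_frequency: dict[float, float],
    reference: float = 70.0,
) -> FrequencyResponse:
    """Express each frequency's peak as a percentage of the reference peak."""
    if reference not in peaks_by_frequency:
        raise ValueError(f"reference frequency {reference} Hz not measured")
    ref = peaks_by_frequency[reference]
    if ref <= 0:
        raise ValueError("reference peak must be > 0")
    if len(set(peaks_by_frequency)) != len(peaks_by_frequency):
        raise ValueError("frequencies must be unique")
    return FrequencyResponse(
        normalized={f: 100.0 * p / ref for f, p in peaks_by_frequency.items()},
        reference_frequency=reference,
    )


@dataclass
class BoutonIBIRatio:
    """Per-trial time-averaged bouton / inter-bouton dF/F ratio."""

    ratios: np.ndarray  # NaN where undefined
    excluded_fraction: np.ndarray  # fraction of in-trial frames excluded
    undefined: np.ndarray  # True when every frame was excluded
    floor: float


def bouton_ibi_ratio(
    bouton_traces: list[DFFTrace],
    ibi_traces: list[DFFTrace],
    protocol: StimulationProtocol,
    floor: float = 0.01,
) -> BoutonIBIRatio:
    """Time-averaged ratio of mean bouton dF/F to mean inter-bouton dF/F.

    Frame ratios are computed only on in-trial frames where the inter-bouton
    mean is at least ``floor`` (near-zero denominators are excluded and the
    excluded fraction reported); the per-trial value is the mean of the
    retained frame ratios.
    """
    if not bouton_traces or not ibi_traces:
        raise ValueError("need at least one trace per class")
    frames = bouton_traces[0].frames
    for t in list(bouton_traces) + list(ibi_traces):
        if not np.array_equal(t.frames, frames):
            raise ValueError("traces do not share a frame vector")
    b_mean = np.vstack([t.dff for t in bouton_traces]).mean(axis=0)
    i_mean = np.vstack([t.dff for t in ibi_traces]).mean(axis=0)
    ratios, excl, undef = [], [], []
    for lo, hi in protocol.trial_windows():
        sel = (frames >= lo) & (frames <= hi)
        denom_ok = i_mean[sel] >= floor
        n_tot = int(sel.sum())
        n_ok = int(denom_ok.sum())
        excl.append(1.0 - n_ok / n_tot if n_tot else 1.0)
        if n_ok == 0:
            ratios.append(np.nan)
            undef.append(True)
        else:
            fr = b_mean[sel][denom_ok] / i_mean[sel][denom_ok]
            ratios.append(float(np.mean(fr)))
            undef.append(False)
    return BoutonIBIRatio(
        ratios=np.array(ratios),
        excluded_fraction=np.array(excl),
        undefined=np.array(undef),
        floor=floor,
    )
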