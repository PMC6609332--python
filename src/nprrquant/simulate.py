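"""Synthetic fluorescence traces for NPRR-style reporters and controls.

The generator is a minimal phenomenological model of stimulus-evoked dense-core
vesicle (DCV) release producing the three phases seen in NPRR recordings:

* a *rising* phase whose peak lags stimulation onset (release integrates the
  releasable pool through a clearance filter),
* a *falling* phase that begins before stimulus offset (pool depletion),
* an *undershoot* below baseline during inter-stimulation intervals, followed
  by recovery (released reporter has diffused away; the pool replenishes
  slowly from transport).

Per ROI, with normalized releasable pool ``P`` (P(0)=1), released-signal ``R``
and cumulative unreplenished release ``D``::

    drive(t) = sigmoid((f - freq_threshold) * freq_slope) * trial_gain   (in trial)
    dP/dt = -pool_depletion_rate * drive * P          during stimulation
    dP/dt = (1 - P) / pool_replenish_tau              otherwise
    dR/dt = release_gain_per_Hz * f * drive * P - R / signal_clearance_tau
    dD/dt = (release flux) - (replenish flux)         i.e. D = 1 - P
    dF/F(t) = R(t) - undershoot_coupling * D(t) + N(0, noise_sd)
    F(t) = baseline_f * (1 + dF/F(t))

A conventional cytosolic calcium indicator ("GCaMP mode") is modelled
separately with near-instantaneous saturating rise, a mild adaptation to a
plateau, and exponential decay after offset — it never undershoots.

Release-blocked ("TNT") preparations are emulated with zero release gain:
no fusion means neither signal nor pool turnover, so dF/F is pure noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .protocol import StimulationProtocol
from .traces import ROITraceSet

__all__ = [
    "TraceSimParams",
    "simulate_nprr_traces",
    "simulate_gcamp_traces",
    "nprr_dff_noiseless",
    "gcamp_dff_noiseless",
    "TYPE_III_FREQ",
    "TYPE_IB_FREQ",
    "ANP_GAIN_SCHEDULE",
    "DTK_GAIN_SCHEDULE",
]

# Frequency-drive presets: Type III motor neurons respond only to high
# stimulation frequencies; Type Ib neurons already respond at 10-20 Hz.
TYPE_III_FREQ = {"freq_threshold": 45.0, "freq_slope": 0.15}
TYPE_IB_FREQ = {"freq_threshold": 15.0, "freq_slope": 0.15}

# Descriptive per-trial gain schedules for the two reporters' published
# patterns: ANP's first peak is characteristically lower; dTK's peaks fall
# progressively across trials.
ANP_GAIN_SCHEDULE = (0.6, 0.9, 1.0, 1.0)
DTK_GAIN_SCHEDULE = (1.0, 0.8, 0.6, 0.45)


@dataclass(frozen=True)
class TraceSimParams:
    """Parameters of the release-reporter trace model.

    Defaults are tuned once to the qualitative kinetics of high-frequency NMJ
    stimulation: ~1 dF/F peak amplitude at 70 Hz, peak latency of a few
    seconds, decline before an 18 s trial ends, and an undershoot that decays
    back toward baseline within a ~40 s inter-stimulation interval.
    """

    baseline_f: float = 100.0  # raw fluorescence units
    release_gain_per_Hz: float = 0.01  # dF/F per Hz of drive at full pool
    pool_depletion_rate: float = 0.12  # 1/s, at full drive
    pool_replenish_tau: float = 12.0  # s
    signal_clearance_tau: float = 2.0  # s
    undershoot_coupling: float = 0.3  # dF/F per unit of unreplenished pool
    trial_gain_schedule: tuple[float, ...] = (1.0,)
    freq_threshold: float = 45.0  # Hz
    freq_slope: float = 0.15  # 1/Hz
    noise_sd: float = 0.02  # dF/F units
    n_rois: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.pool_depletion_rate, self.pool_replenish_tau,
               self.signal_clearance_tau) <= 0:
            raise ValueError("rates and time constants must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.baseline_f <= 0:
            raise ValueError("baseline_f must be > 0")
        if self.n_rois < 1:
            raise ValueError("n_rois must be >= 1")
        if self.release_gain_per_Hz < 0 or self.undershoot_coupling < 0:
            raise ValueError("gains must be >= 0")
        if any(g < 0 for g in self.trial_gain_schedule):
            raise ValueError("trial gains must be >= 0")

    def with_(self, **kw) -> "TraceSimParams":
        return replace(self, **kw)


def _trial_gains(params: TraceSimParams, n_trials: int) -> np.ndarray:
    g = np.asarray(params.trial_gain_schedule, dtype=float)
    if g.size == 1:
        return np.full(n_trials, g[0])
    if g.size != n_trials:
        raise ValueError(
            f"trial_gain_schedule length {g.size} does not match "
            f"{n_trials} trials (must match or be length 1)"
        )
    return g


def _sigmoid(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x))


def nprr_dff_noiseless(
    protocol: StimulationProtocol,
    params: TraceSimParams,
    substeps: int = 10,
) -> np.ndarray:
    """Noise-free dF/F of the release-reporter model at frame times.

    Fourth-order Runge-Kutta on a fixed grid of ``substeps`` sub-steps per
    frame.  Zero release gain (fusion blocked) short-circuits to an exactly
    flat trace: without fusion there is no release, hence no pool turnover
    and no undershoot.
    """
    frames = protocol.frame_times()
    if params.release_gain_per_Hz == 0.0:
        return np.zeros(frames.size)

    gains = _trial_gains(params, protocol.n_trials)
    # Per-trial drive (constant within a trial).
    trial_info = [
        (t.onset, t.offset, t.frequency,
         _sigmoid((t.frequency - params.freq_threshold) * params.freq_slope) * gains[k])
        for k, t in enumerate(protocol.trials)
    ]

    def rates(stim: tuple[float, float], P: float, R: float, D: float
              ) -> tuple[float, float, float]:
        f, drive = stim
        if drive > 0.0:
            release = params.pool_depletion_rate * drive * P
            replenish = 0.0
        else:
            release = 0.0
            replenish = (1.0 - P) / params.pool_replenish_tau
        dP = replenish - release
        dR = params.release_gain_per_Hz * f * drive * P - R / params.signal_clearance_tau
        dD = release - replenish
        return dP, dR, dD

    def stim_at(t: float) -> tuple[float, float]:
        for onset, offset, freq, drv in trial_info:
            if onset <= t < offset:
                return freq, drv
        return 0.0, 0.0

    dt = protocol.frame_interval / substeps
    n_steps = (frames.size - 1) * substeps
    P, R, D = 1.0, 0.0, 0.0
    out = np.empty(frames.size)
    out[0] = R - params.undershoot_coupling * D
    for i in range(n_steps):
        # drive is piecewise-constant; classify the whole sub-step by its
        # midpoint so stage evaluations never straddle a trial boundary
        stim = stim_at(i * dt + dt / 2)
        k1 = rates(stim, P, R, D)
        k2 = rates(stim, P + dt / 2 * k1[0], R + dt / 2 * k1[1], D + dt / 2 * k1[2])
        k3 = rates(stim, P + dt / 2 * k2[0], R + dt / 2 * k2[1], D + dt / 2 * k2[2])
        k4 = rates(stim, P + dt * k3[0], R + dt * k3[1], D + dt * k3[2])
        P += dt / 6 * (k1[0] + 2 * k2[0] + 2 * k3[0] + k4[0])
        R += dt / 6 * (k1[1] + 2 * k2[1] + 2 * k3[1] + k4[1])
        D += dt / 6 * (k1[2] + 2 * k2[2] + 2 * k3[2] + k4[2])
        if (i + 1) % substeps == 0:
            out[(i + 1) // substeps] = R - params.undershoot_coupling * D
    return out


def gcamp_dff_noiseless(
    protocol: StimulationProtocol,
    params: TraceSimParams,
    rise_tau: float = 0.3,
    adapt_tau: float = 5.0,
    plateau_frac: float = 0.9,
) -> np.ndarray:
    """Noise-free dF/F of a cytosolic calcium-indicator control.

    Saturating rise with time constant ``rise_tau`` (virtually instantaneous
    at 1 frame/s), mild adaptation toward ``plateau_frac`` of the initial
    peak, exponential decay with ``signal_clearance_tau`` after offset.
    Non-negative everywhere; amplitude scales like the reporter model's
    steady state (gain x frequency x clearance tau x drive).
    """
    frames = protocol.frame_times()
    gains = _trial_gains(params, protocol.n_trials)
    out = np.zeros(frames.size)
    carry = 0.0  # dF/F carried past each trial's offset
    last_offset = -np.inf
    for k, trial in enumerate(protocol.trials):
        drive = _sigmoid((trial.frequency - params.freq_threshold) * params.freq_slope)
        amp = (params.release_gain_per_Hz * trial.frequency
               * params.signal_clearance_tau * drive * gains[k])
        # decay of the previous trial's signal
        between = (frames >= last_offset) & (frames < trial.onset)
        out[between] = carry * np.exp(-(frames[between] - last_offset)
                                      / params.signal_clearance_tau)
        within = (frames >= trial.onset) & (frames < trial.offset)
        dt_on = frames[within] - trial.onset
        resid = carry * np.exp(-dt_on / params.signal_clearance_tau)
        out[within] = resid + amp * (1.0 - np.exp(-dt_on / rise_tau)) * (
            plateau_frac + (1.0 - plateau_frac) * np.exp(-dt_on / adapt_tau)
        )
        d_end = trial.duration
        carry = (carry * math.exp(-d_end / params.signal_clearance_tau)
                 + amp * (1.0 - math.exp(-d_end / rise_tau))
                 * (plateau_frac + (1.0 - plateau_frac) * math.exp(-d_end / adapt_tau)))
        last_offset = trial.offset
    tail = frames >= last_offset
    if np.isfinite(last_offset):
        out[tail] = carry * np.exp(-(frames[tail] - last_offset)
                                   / params.signal_clearance_tau)
    return out


def _assemble(
    dff_clean: np.ndarray,
    protocol: StimulationProtocol,
    params: TraceSimParams,
    roi_class: str,
    conditions: dict,
) -> ROITraceSet:
    rng = np.random.default_rng(params.seed)
    frames = protocol.frame_times()
    noise = (rng.normal(0.0, params.noise_sd, size=(params.n_rois, frames.size))
             if params.noise_sd > 0 else np.zeros((params.n_rois, frames.size)))
    dff = dff_clean[None, :] + noise
    f = params.baseline_f * (1.0 + dff)
    f = np.clip(f, 0.0, None)  # raw fluorescence cannot go negative
    return ROITraceSet(
        frames=frames,
        f=f,
        roi_ids=[f"roi{i:03d}" for i in range(params.n_rois)],
        roi_classes=[roi_class] * params.n_rois,
        conditions=dict(conditions),
        ground_truth={
            "dff_noiseless": dff_clean,
            "params": params,
            "protocol": protocol,
        },
    )


def simulate_nprr_traces(
    protocol: StimulationProtocol,
    params: TraceSimParams | None = None,
    roi_class: str = "bouton",
    conditions: dict | None = None,
    substeps: int = 10,
) -> ROITraceSet:
    """Simulate a release-reporter ROI trace set. Deterministic given seed."""
    params = params or TraceSimParams()
    cond = {"reporter": "NPRR"}
    cond.update(conditions or {})
    clean = nprr_dff_noiseless(protocol, params, substeps=substeps)
    return _assemble(clean, protocol, params, roi_class, cond)


def simulate_gcamp_traces(
    protocol: StimulationProtocol,
    params: TraceSimParams | None = None,
    roi_class: str = "bouton",
    conditions: dict | None = None,
) -> ROITraceSet:
    """Simulate a cytosolic calcium-indicator control trace set."""
    params = params or TraceSimParams()
    cond = {"reporter": "GCaMP6s"}
    cond.update(conditions or {})
    clean = gcamp_dff_noiseless(protocol, params)
    return _assemble(clean, protocol, params, roi_class, cond)
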