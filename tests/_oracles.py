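"""Independent brute-force oracles used by the tests.

Deliberately written from first principles, sharing no code path with the
package: a fine-step Euler integrator for the trace model, a ray-casting
point-in-polygon compartment assigner, and a permutation-enumeration
Mann-Whitney p-value.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np


def euler_trace_oracle(protocol, params, substeps: int = 1000) -> np.ndarray:
    """Forward-Euler integration of the release-reporter model on a grid
    ``substeps`` times finer than the frame clock."""
    frames = protocol.frame_times()
    if params.release_gain_per_Hz == 0.0:
        return np.zeros(frames.size)
    gains = list(params.trial_gain_schedule)
    if len(gains) == 1:
        gains = gains * protocol.n_trials
    info = []
    for k, t in enumerate(protocol.trials):
        drive = gains[k] / (
            1.0 + math.exp(-(t.frequency - params.freq_threshold) * params.freq_slope)
        )
        info.append((t.onset, t.offset, t.frequency, drive))
    dt = protocol.frame_interval / substeps
    P, R, D = 1.0, 0.0, 0.0
    out = np.empty(frames.size)
    out[0] = 0.0
    for i in range((frames.size - 1) * substeps):
        tm = i * dt + dt / 2  # classify by midpoint, as a piecewise model
        f = drive = 0.0
        for on, off, fr, drv in info:
            if on <= tm < off:
                f, drive = fr, drv
                break
        if drive > 0:
            release = params.pool_depletion_rate * drive * P
            replenish = 0.0
        else:
            release = 0.0
            replenish = (1.0 - P) / params.pool_replenish_tau
        dR = params.release_gain_per_Hz * f * drive * P - R / params.signal_clearance_tau
        P += dt * (replenish - release)
        R += dt * dR
        D += dt * (release - replenish)
        if (i + 1) % substeps == 0:
            out[(i + 1) // substeps] = R - params.undershoot_coupling * D
    return out


def point_in_polygon(px: float, py: float, poly: np.ndarray) -> bool:
    """Ray casting with an on-edge check (edges count as inside)."""
    n = len(poly)
    inside = False
    for i in range(n):
        x1, y1 = poly[i]
        x2, y2 = poly[(i + 1) % n]
        # on-segment test
        cross = (px - x1) * (y2 - y1) - (py - y1) * (x2 - x1)
        if abs(cross) < 1e-9:
            if min(x1, x2) - 1e-9 <= px <= max(x1, x2) + 1e-9 and \
               min(y1, y2) - 1e-9 <= py <= max(y1, y2) + 1e-9:
                return True
        if (y1 > py) != (y2 > py):
            xint = x1 + (py - y1) * (x2 - x1) / (y2 - y1)
            if px < xint:
                inside = not inside
    return inside


def dist_point_segment(px, py, x1, y1, x2, y2) -> float:
    dx, dy = x2 - x1, y2 - y1
    L2 = dx * dx + dy * dy
    if L2 == 0:
        return math.hypot(px - x1, py - y1)
    t = max(0.0, min(1.0, ((px - x1) * dx + (py - y1) * dy) / L2))
    return math.hypot(px - (x1 + t * dx), py - (y1 + t * dy))


def assign_compartments_oracle(ann) -> list[str]:
    """Brute-force priority assignment: dcv > membrane > cytoplasm > outside."""
    labels = []
    poly = np.asarray(ann.bouton_outline)
    n = len(poly)
    for px, py in ann.gold:
        in_dcv = any(
            math.hypot(px - cx, py - cy) <= ann.dcv_disc_radius
            for cx, cy in ann.dcv_centers
        )
        if in_dcv:
            labels.append("dcv")
            continue
        bdist = min(
            dist_point_segment(px, py, *poly[i], *poly[(i + 1) % n])
            for i in range(n)
        )
        if bdist <= ann.membrane_band_halfwidth:
            labels.append("membrane")
        elif point_in_polygon(px, py, poly):
            labels.append("cytoplasm")
        else:
            labels.append("outside")
    return labels


def mann_whitney_enumeration(a, b, sided: str = "two") -> float:
    """Exact Mann-Whitney p by enumerating every assignment of the pooled
    observations to the two groups (tie-free samples only).

    U is computed directly as the count of (a_i, b_j) pairs with a_i > b_j,
    independent of any rank formula.
    """
    a = list(map(float, a))
    b = list(map(float, b))
    pooled = a + b
    assert len(set(pooled)) == len(pooled), "oracle requires tie-free data"
    n_a = len(a)

    def u_stat(ga, gb):
        return sum(1 for x in ga for y in gb if x > y)

    u_obs = u_stat(a, b)
    idx = range(len(pooled))
    us = []
    for comb in combinations(idx, n_a):
        sa = [pooled[i] for i in comb]
        sb = [pooled[i] for i in idx if i not in comb]
        us.append(u_stat(sa, sb))
    us = np.array(us)
    total = len(us)
    if sided == "greater":
        return float((us >= u_obs).sum() / total)
    if sided == "less":
        return float((us <= u_obs).sum() / total)
    mean = len(a) * len(b) / 2
    dev = abs(u_obs - mean)
    return float(min(1.0, (np.abs(us - mean) >= dev).sum() / total))
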