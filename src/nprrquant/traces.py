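"""In-memory containers for ROI fluorescence time series and ΔF/F traces."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ROITraceSet", "DFFTrace", "ROI_CLASSES"]

ROI_CLASSES = ("bouton", "inter_bouton", "whole")


@dataclass
class ROITraceSet:
    """Raw fluorescence series for a set of ROIs sharing one frame clock.

    Attributes
    ----------
    frames : (n_frames,) float array
        Sample times in seconds, strictly increasing.
    f : (n_rois, n_frames) float array
        Raw fluorescence, arbitrary units, finite and >= 0.
    roi_ids : list of str
    roi_classes : list of str, each in {"bouton", "inter_bouton", "whole"}
    conditions : dict
        Free-form labels (reporter, intervention, cell_type, ...).
    ground_truth : dict or None
        For simulated sets: noiseless ΔF/F and generator parameters, kept as
        a sidecar for recovery tests.
    """

    frames: np.ndarray
    f: np.ndarray
    roi_ids: list[str]
    roi_classes: list[str]
    conditions: dict = field(default_factory=dict)
    ground_truth: dict | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        self.f = np.atleast_2d(np.asarray(self.f, dtype=float))
        if self.frames.ndim != 1 or np.any(np.diff(self.frames) <= 0):
            raise ValueError("frames must be a strictly increasing 1-D vector")
        if self.f.shape != (len(self.roi_ids), self.frames.size):
            raise ValueError("f must be (n_rois, n_frames)")
        if len(self.roi_classes) != len(self.roi_ids):
            raise ValueError("one roi_class per ROI required")
        for c in self.roi_classes:
            if c not in ROI_CLASSES:
                raise ValueError(f"unknown roi_class {c!r}")
        if not np.all(np.isfinite(self.f)) or np.any(self.f < 0):
            raise ValueError("fluorescence must be finite and >= 0")

    @property
    def n_rois(self) -> int:
        return len(self.roi_ids)

    def select(self, roi_class: str) -> "ROITraceSet":
        """Sub-set of ROIs of one class."""
        idx = [i for i, c in enumerate(self.roi_classes) if c == roi_class]
        return ROITraceSet(
            frames=self.frames,
            f=self.f[idx],
            roi_ids=[self.roi_ids[i] for i in idx],
            roi_classes=[self.roi_classes[i] for i in idx],
            conditions=dict(self.conditions),
            ground_truth=self.ground_truth,
        )

    def to_long(self) -> pd.DataFrame:
        """Long-form table: time_s, roi_id, roi_class, condition, F."""
        cond = ";".join(f"{k}={v}" for k, v in sorted(self.conditions.items()))
        n_f = self.frames.size
        return pd.DataFrame(
            {
                "time_s": np.tile(self.frames, self.n_rois),
                "roi_id": np.repeat(self.roi_ids, n_f),
                "roi_class": np.repeat(self.roi_classes, n_f),
                "condition": cond,
                "F": self.f.ravel(),
            }
        )

    @classmethod
    def from_long(cls, df: pd.DataFrame) -> "ROITraceSet":
        """Rebuild a trace set from the long-form table written by ``to_long``."""
        required = {"time_s", "roi_id", "roi_class", "F"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"trace table missing columns: {sorted(missing)}")
        frames = np.sort(df["time_s"].unique())
        roi_ids, roi_classes, rows = [], [], []
        for roi_id, grp in df.groupby("roi_id", sort=True):
            grp = grp.sort_values("time_s")
            if not np.array_equal(grp["time_s"].to_numpy(), frames):
                raise ValueError(f"ROI {roi_id!r} does not share the frame vector")
            roi_ids.append(str(roi_id))
            roi_classes.append(str(grp["roi_class"].iloc[0]))
            rows.append(grp["F"].to_numpy(dtype=float))
        conditions: dict = {}
        if "condition" in df.columns and len(df):
            raw = str(df["condition"].iloc[0])
            if raw and raw != "nan":
                for part in raw.split(";"):
                    if "=" in part:
                        k, v = part.split("=", 1)
                        conditions[k] = v
        return cls(
            frames=frames,
            f=np.vstack(rows) if rows else np.empty((0, frames.size)),
            roi_ids=roi_ids,
            roi_classes=roi_classes,
            conditions=conditions,
        )


@dataclass
class DFFTrace:
    """ΔF/F series for one ROI with its baseline provenance.

    ``dff(t) = (F(t) - F0) / F0`` with F0 the mean raw fluorescence over
    ``baseline_window`` (a pre-stimulation span).
    """

    frames: np.ndarray
    dff: np.ndarray
    baseline_value: float
    baseline_window: tuple[float, float]
    roi_id: str = ""
    roi_class: str = "whole"
    conditions: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        self.dff = np.asarray(self.dff, dtype=float)
        if self.frames.shape != self.dff.shape:
            raise ValueError("frames and dff must have equal length")
        if not np.all(np.isfinite(self.dff)):
            raise ValueError("dff must be finite")
        if self.baseline_value <= 0:
            raise ValueError("baseline_value must be > 0")

    def copy_with(self, dff: np.ndarray) -> "DFFTrace":
        return DFFTrace(
            frames=self.frames,
            dff=np.asarray(dff, dtype=float),
            baseline_value=self.baseline_value,
            baseline_window=self.baseline_window,
            roi_id=self.roi_id,
            roi_class=self.roi_class,
            conditions=dict(self.conditions),
        )
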