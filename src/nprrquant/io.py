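"""Readers/writers for the pipeline's text formats.

All tables are long-form delimited text with a header; nested structures
(protocols, parameters, reports) are JSON.  Times are seconds, EM
coordinates nm, areas um^2.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .protocol import StimulationProtocol
from .stereology import DensityReport, EMImageAnnotation
from .traces import DFFTrace, ROITraceSet

__all__ = [
    "write_trace_table", "read_trace_table",
    "write_protocol", "read_protocol",
    "write_annotations", "read_annotations",
    "write_json_report", "write_dff_table", "read_dff_table",
]


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_trace_table(traces: ROITraceSet, path) -> None:
    """Long-form table: time_s, roi_id, roi_class, condition, F."""
    traces.to_long().to_csv(path, index=False)


def read_trace_table(path) -> ROITraceSet:
    return ROITraceSet.from_long(pd.read_csv(path))


def write_dff_table(traces: list[DFFTrace], path) -> None:
    """Long-form dF/F table: time_s, roi_id, roi_class, dff."""
    frames = [
        pd.DataFrame(
            {
                "time_s": t.frames,
                "roi_id": t.roi_id,
                "roi_class": t.roi_class,
                "dff": t.dff,
                "baseline_value": t.baseline_value,
            }
        )
        for t in traces
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_dff_table(path) -> list[DFFTrace]:
    df = pd.read_csv(path)
    out = []
    for roi_id, grp in df.groupby("roi_id", sort=True):
        grp = grp.sort_values("time_s")
        out.append(
            DFFTrace(
                frames=grp["time_s"].to_numpy(float),
                dff=grp["dff"].to_numpy(float),
                baseline_value=float(grp["baseline_value"].iloc[0]),
                baseline_window=(np.nan, np.nan),
                roi_id=str(roi_id),
                roi_class=str(grp["roi_class"].iloc[0]),
            )
        )
    return out


def write_protocol(protocol: StimulationProtocol, path) -> None:
    Path(path).write_text(json.dumps(protocol.to_dict(), indent=2) + "\n")


def read_protocol(path) -> StimulationProtocol:
    return StimulationProtocol.from_dict(json.loads(Path(path).read_text()))


def write_annotations(annotations: list[EMImageAnnotation], path) -> None:
    payload = {"annotations": [a.to_dict() for a in annotations]}
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def read_annotations(path) -> list[EMImageAnnotation]:
    payload = json.loads(Path(path).read_text())
    return [EMImageAnnotation.from_dict(d) for d in payload["annotations"]]


def write_json_report(report, path) -> None:
    """Any dataclass / dict / DensityReport tree as JSON."""
    if isinstance(report, DensityReport):
        report = report.to_dict()
    Path(path).write_text(json.dumps(_jsonable(report), indent=2,
                                     allow_nan=True) + "\n")
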