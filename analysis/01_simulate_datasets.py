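#!/usr/bin/env python
"""Generate the synthetic study datasets every later stage analyses.

Under the standard paradigm (four 18 s bursts at 70 Hz, 42 s intervals,
1 frame/s) this writes, under results/datasets/:

* an ANP-like reporter set (first trial peak characteristically lower),
* a dTK-like reporter set (peaks declining across trials),
* a cytosolic-calcium control set,
* a release-blocked (toxin) set and its inactive-toxin control,
* synthetic immunogold micrographs at 15:1 DCV:cytoplasm contrast plus
  low-density controls.

Each trace table ships with its protocol and a ground-truth sidecar.
"""

import argparse
from pathlib import Path

import nprrquant as q
from nprrquant import io as nio

OUT = Path(__file__).resolve().parents[1] / "results" / "datasets"


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    args = ap.parse_args()
    OUT.mkdir(parents=True, exist_ok=True)

    protocol = q.make_protocol()
    nio.write_protocol(protocol, OUT / "protocol.json")

    sets = {
        "nprr_anp": dict(params=q.TraceSimParams(
            trial_gain_schedule=q.ANP_GAIN_SCHEDULE, seed=args.seed),
            sim=q.simulate_nprr_traces, cond={"reporter": "NPRR-ANP"}),
        "nprr_dtk": dict(params=q.TraceSimParams(
            trial_gain_schedule=q.DTK_GAIN_SCHEDULE, n_rois=6,
            seed=args.seed + 1),
            sim=q.simulate_nprr_traces, cond={"reporter": "NPRR-dTK"}),
        "gcamp": dict(params=q.TraceSimParams(seed=args.seed + 2),
                      sim=q.simulate_gcamp_traces,
                      cond={"reporter": "GCaMP6s"}),
        "nprr_tnt": dict(params=q.TraceSimParams(
            release_gain_per_Hz=0.0, seed=args.seed + 3),
            sim=q.simulate_nprr_traces,
            cond={"reporter": "NPRR-ANP", "intervention": "TNT"}),
        "nprr_tnt_imp": dict(params=q.TraceSimParams(seed=args.seed + 4),
                             sim=q.simulate_nprr_traces,
                             cond={"reporter": "NPRR-ANP",
                                   "intervention": "TNTimp"}),
    }
    for name, spec in sets.items():
        traces = spec["sim"](protocol, spec["params"], conditions=spec["cond"])
        nio.write_trace_table(traces, OUT / f"{name}_traces.csv")
        print(f"wrote {name}: {traces.n_rois} ROIs x {traces.frames.size} frames")

    em = q.EMSimParams(density_dcv=30.0, density_cytoplasm=2.0)
    anns = [q.simulate_em_annotation(em.with_(seed=args.seed + 100 + k))
            for k in range(20)]
    nio.write_annotations(anns, OUT / "em_annotations.json")
    ctl = q.EMSimParams(density_dcv=0.3, density_cytoplasm=0.3,
                        density_membrane_band=0.3, density_outside=0.3)
    ctl_anns = [q.simulate_em_annotation(ctl.with_(seed=args.seed + 200 + k))
                for k in range(20)]
    nio.write_annotations(ctl_anns, OUT / "em_controls.json")
    print(f"wrote {len(anns)} immunogold micrographs (15:1 contrast) "
          f"and {len(ctl_anns)} controls")


if __name__ == "__main__":
    main()
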