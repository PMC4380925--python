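#!/usr/bin/env python
"""Quantify translocation dynamics for three drug-like conditions.

Forty traces per condition (control; a ROCK-inhibitor-like condition with
higher first-peak amplitude and a clean 120-min cycle; a
microtubule-drug-like condition with damped amplitude and shorter, noisier
periods), mirroring the live-imaging protocol: 6 h at 5-min intervals.
Reports first-peak amplitude/time and the distribution of instantaneous
wavelet periods at t = 300 min.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from shapesignal import dynamics as dyn
from shapesignal import synthetic as syn

ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "results" / "dynamics"

CONDITIONS = {
    # amplitude, first-peak time, period, damping, noise
    "control": dict(amplitude=0.5, first_peak_time=30.0, period=115.0,
                    damping_timescale=150.0, noise_sd=0.03),
    "rock_inhibitor": dict(amplitude=0.8, first_peak_time=25.0, period=120.0,
                           damping_timescale=250.0, noise_sd=0.02),
    "microtubule_drug": dict(amplitude=0.25, first_peak_time=40.0, period=75.0,
                             damping_timescale=100.0, noise_sd=0.05),
}
N_TRACES = 40


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    peaks_rows = []
    traces: dict[str, list] = {}
    for ci, (cond, kw) in enumerate(CONDITIONS.items()):
        traces[cond] = []
        for i in range(N_TRACES):
            params = syn.OscillationParams(
                baseline=1.0, dt=5.0, duration=360.0, seed=1000 * ci + i, **kw)
            tr = syn.simulate_trace(params, cell_id=f"{cond}_{i:02d}", condition=cond)
            traces[cond].append(tr)
            peak = dyn.first_peak_metrics(tr)
            peaks_rows.append({"condition": cond, "cell_id": tr.cell_id,
                               "amplitude": peak.amplitude, "time": peak.time,
                               "found": peak.found})
    peaks = pd.DataFrame(peaks_rows)
    peaks.to_csv(OUT / "first_peaks.csv", index=False, float_format="%.6g")

    summary = peaks[peaks.found].groupby("condition")[["amplitude", "time"]].agg(
        ["mean", "std"])
    print("first-peak metrics (40 cells/condition):")
    print(summary.round(3).to_string())

    # mid-trace: every period in the analyzed band is outside the cone of
    # influence there; later times on a 6-h movie are edge-affected for
    # 110-120 min periods (see docs/methods.md)
    hist = dyn.period_frequency_comparison(traces, t=180.0)
    hist.to_csv(OUT / "period_frequencies_t180.csv", float_format="%.6g")
    print("\nwavelet period frequencies at t = 180 min:")
    print(hist.round(3).to_string())
    for cond in CONDITIONS:
        if hist[cond].sum() > 0:
            print(f"  modal period ({cond}): {hist[cond].idxmax():.0f} min bin")


if __name__ == "__main__":
    main()
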