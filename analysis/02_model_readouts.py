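#!/usr/bin/env python
"""Derive the model readouts from the simulated grid.

Reads results/model/summary.h5 (running 01_simulate_model.py first if it is
missing) and writes tidy CSVs: shift slopes at 100-400 ms after the jump,
slope convergence times, estimation-error half-times, and peak jump force
contrasts. Prints the headline numbers: the fast slope approaches -1 by
~300-400 ms and the slow condition needs ~70-80 ms longer; error decay
half-times order with visual uncertainty but not speed.
"""

import subprocess
import sys
from pathlib import Path

import numpy as np
import pandas as pd

from reach_ofc.experiments import (convergence_time, error_decay_halftime_ms,
                                   simulated_delta_force, simulated_slopes,
                                   slope_curve)
from reach_ofc.io import read_summary

OUT = Path(__file__).resolve().parents[1] / "results" / "model"


def main() -> None:
    if not (OUT / "summary.h5").exists():
        subprocess.check_call([sys.executable,
                               str(Path(__file__).with_name("01_simulate_model.py"))])
    s = read_summary(OUT / "summary.h5")

    slopes = simulated_slopes(s, times_after_jump_ms=(100, 200, 300, 400))
    slopes.to_csv(OUT / "slopes.csv", index=False)

    rows = []
    for (unc, speed) in sorted({(k[0], k[1]) for k in s.cells}):
        t, sl = slope_curve(s, unc, speed)
        rows.append({"uncertainty": unc, "speed": speed,
                     "convergence_ms": convergence_time(t, sl),
                     "decay_halftime_ms": error_decay_halftime_ms(s, unc, speed)})
    conv = pd.DataFrame(rows)
    conv.to_csv(OUT / "convergence.csv", index=False)

    peaks = pd.DataFrame(
        [{"uncertainty": u, "speed": sp, "peak_delta_force_N": float(np.max(np.abs(d)))}
         for (u, sp), (_, d) in simulated_delta_force(s).items()])
    peaks.to_csv(OUT / "delta_force_peaks.csv", index=False)

    fast400 = slopes.query("uncertainty=='low' and speed=='fast' and time_ms==400")
    cl = conv.set_index(["uncertainty", "speed"])
    print(f"fast/low slope at 400 ms: {fast400['slope'].iloc[0]:+.3f} (full compensation = -1)")
    print("convergence (low): fast %.0f ms, slow %.0f ms -> lag %.0f ms" % (
        cl.loc[("low", "fast"), "convergence_ms"],
        cl.loc[("low", "slow"), "convergence_ms"],
        cl.loc[("low", "slow"), "convergence_ms"] - cl.loc[("low", "fast"), "convergence_ms"]))
    for sp in ("fast", "slow"):
        hs = [float(cl.loc[(u, sp), "decay_halftime_ms"])
              for u in ("low", "medium", "high")]
        print(f"error half-times {sp} (low/med/high): "
              + "/".join(f"{h:.0f}" for h in hs) + " ms")
    print(f"tables written to {OUT}")


if __name__ == "__main__":
    main()
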