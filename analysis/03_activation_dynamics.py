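#!/usr/bin/env python
"""Amplitude-frequency trade-off during strong optogenetic activation.

Simulates activation sessions for flies spanning baseline wingbeat
frequencies 170-230 Hz, all sharing one muscle power cap.  Flies beating
slowly can raise both amplitude and frequency; flies already near the cap
must trade frequency away as amplitude rises past the ~160 deg saturation
point.  The frequency-change regression and the bounding power of the
amplitude-frequency trajectory quantify both effects.

Writes results/activation_dynamics/*.csv|json and prints the regression.
"""

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

from dnflight import io
from dnflight import opto_response as opt
from dnflight import synthetic as syn
from dnflight.aero_power import bounding_power, drosophila_morphometrics

OUT = Path(__file__).resolve().parent.parent / "results" / "activation_dynamics"
SEED = 1


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    morph = drosophila_morphometrics()
    cap = syn.default_power_cap(syn.OptoSimConfig(baseline_freq=200.0), morph)
    print(f"Shared muscle power cap: {cap:.1f} W/kg "
          "(P_mech at the saturation amplitude)")

    rows = []
    for i, f0 in enumerate(np.arange(170.0, 231.0, 10.0)):
        cfg = syn.OptoSimConfig(baseline_freq=f0, power_cap=cap, n_trials=10,
                                fs=500.0, seed=SEED + i)
        trace, _ = syn.simulate_wingbeat_session(cfg, morph)
        fly = opt.summarize_fly(
            [opt.score_trial(w) for w in opt.segment_trials(trace)],
            fly_id=f"f{int(f0)}")
        rows.append({"baseline_freq": fly.baseline_freq,
                     "delta_freq": fly.delta_freq,
                     "delta_wba": fly.delta_wba})
    flies = pd.DataFrame(rows)
    flies.to_csv(OUT / "per_fly_freq_changes.csv", index=False)

    fit = opt.freq_change_regression(flies["baseline_freq"], flies["delta_freq"])
    io.write_json_report(dataclasses.asdict(fit), OUT / "freq_regression.json")
    print(f"delta_freq vs baseline_freq: slope {fit.slope:.2f}, "
          f"zero-crossing {fit.zero_crossing:.0f} Hz (r^2={fit.r2:.2f})")
    print("Above the crossover, activation lowers wingbeat frequency: the "
          "power budget forces the trade-off.")

    # trajectory of one strongly activated fly against the bounding isoline
    cfg = syn.OptoSimConfig(baseline_freq=210.0, power_cap=cap, n_trials=10,
                            fs=500.0, seed=SEED)
    trace, _ = syn.simulate_wingbeat_session(cfg, morph)
    traj = pd.concat([opt.amp_freq_trajectory(w, morph)
                      for w in opt.segment_trials(trace)])
    traj.to_csv(OUT / "amp_freq_trajectory.csv", index=False)
    level, _ = bounding_power((traj["n_hz"].to_numpy(), traj["phi_deg"].to_numpy()),
                              morph, degrees=True)
    print(f"Bounding isoline of the observed (n, Phi) cloud: {level:.1f} W/kg")
    print(f"Wrote tables to {OUT}")


if __name__ == "__main__":
    main()
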