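#!/usr/bin/env python
"""Map muscle-power isolines in the wingbeat frequency-amplitude plane.

For a Drosophila-like morphometric parameter set, traces the curves of
constant muscle-mass-specific mechanical power P*_mech = P*_ind + P*_pro
and reports how dominant the profile term is at flight kinematics.  The
hyperbola-like shape of these curves is what forces an inverse
amplitude-frequency relationship when muscle power saturates.

Writes results/isolines/<level>w_per_kg.csv and prints a summary table.
"""

from pathlib import Path

import numpy as np

from dnflight import io
from dnflight.aero_power import drosophila_morphometrics, mechanical_power, solve_isoline

OUT = Path(__file__).resolve().parent.parent / "results" / "isolines"
LEVELS = (100.0, 150.0, 200.0, 250.0)


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    morph = drosophila_morphometrics()
    grid = np.linspace(150.0, 300.0, 100)

    print("morphometrics:", morph)
    pb = mechanical_power(212.0, 160.0, morph, degrees=True)
    print(f"\nAt a typical activated state (212 Hz, 160 deg): "
          f"P_ind={pb.P_ind:.1f}, P_pro={pb.P_pro:.1f}, P_mech={pb.P_mech:.1f} W/kg "
          f"(Re={pb.Re:.0f}, cd={pb.cd_used:.2f})")
    print(f"Profile/induced ratio {pb.P_pro / pb.P_ind:.1f}: "
          "profile drag dominates, so P_mech ~ (n*Phi)^3 and the isolines "
          "are close to n*Phi = const.\n")

    print(f"{'P (W/kg)':>9} {'points':>7} {'phi@170Hz':>10} {'phi@250Hz':>10}")
    for level in LEVELS:
        iso = solve_isoline(level, grid, morph)
        io.write_isoline_csv(iso, morph, OUT / f"{int(level)}w_per_kg.csv")
        phi_lo = np.interp(170.0, iso.n, iso.phi_deg)
        phi_hi = np.interp(250.0, iso.n, iso.phi_deg)
        print(f"{level:9.0f} {iso.n.size:7d} {phi_lo:9.1f}deg {phi_hi:9.1f}deg")
    print(f"\nWrote {len(LEVELS)} isoline tables to {OUT}")


if __name__ == "__main__":
    main()
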