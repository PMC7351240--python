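"""The two kinetic regimes: equilibrium vs non-equilibrium assembly.

Sweeps the protein export rate of the generic parallel circuit from far
below baseline up to baseline and compares the stochastic ensemble with the
deterministic (large-ensemble) solution.  Slow export gives the scaffolds
time to sample both proteins — the combinatoric 25/50/25 distribution, in
agreement with the deterministic solution (equilibrium regime).  Fast
export arrests each run in whatever the expression bursts delivered first:
the ensemble mean departs from the deterministic prediction and the
run-to-run variation changes character (non-equilibrium regime).
"""

from complexoform import run_condition

N_RUNS = 300

print(f"{'k_out multiplier':>16} {'XX%':>6} {'XY%':>6} {'YY%':>6} "
      f"{'discrepancy':>12} {'variation':>10}")
for mult in (1e-5, 1e-3, 1e-1, 1.0):
    rec = run_condition("generic", "parallel", n_runs=N_RUNS, base_seed=1,
                        rate_overrides={"k_out": 1.0 * mult})
    print(f"{mult:16g} {rec['frac_XX']*100:6.1f} {rec['frac_XY']*100:6.1f} "
          f"{rec['frac_YY']*100:6.1f} {rec['discrepancy']:12.3f} "
          f"{rec['variation']:10.3f}")

print(
    "\nDiscrepancy = sum over XX/XY/YY of |stochastic mean - deterministic|\n"
    "(scaffold fractions); variation = sum of the per-composition SDs across\n"
    "runs.  The discrepancy rises from ~0 (equilibrium) to O(1) as export\n"
    "accelerates and the assembly arrests before the pools equilibrate."
)
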