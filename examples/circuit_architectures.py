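"""How the genetic circuit architecture shapes the assembled complexoform.

Runs a stochastic ensemble for each of the four circuit architectures of
the generic two-protein model (identical nominal rates everywhere) and
prints the mean fractions of scaffolds ending XX, XY/YX and YY.  The
cascade and series circuits express protein X before Y, so they bias the
assembly toward homogeneous XX; the parallel circuit splits its runs
between XX- and YY-dominated outcomes instead of mixing.
"""

from complexoform import CircuitKind, run_condition

N_RUNS = 500  # 1000 in the full-scale experiments

print(f"{'circuit':>18} {'XX%':>6} {'XY%':>6} {'YY%':>6} {'mean T_asb':>11}")
for kind in CircuitKind:
    rec = run_condition("generic", kind, n_runs=N_RUNS, base_seed=0,
                        solve_ode=False)
    print(f"{kind.value:>18} {rec['frac_XX']*100:6.1f} {rec['frac_XY']*100:6.1f} "
          f"{rec['frac_YY']*100:6.1f} {rec['mean_t_asb']:11.1f}")

print(
    "\nXX/XY/YY are scaffold fractions averaged over completed runs; T_asb\n"
    "is the mean time (arbitrary units) until all 20 docking sites are\n"
    "occupied.  X-first circuits (cascade, series) end mostly XX; the\n"
    "parallel circuit is bimodal, so XX ~ YY with little mixed XY."
)
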