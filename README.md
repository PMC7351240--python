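# complexoform

Stochastic and deterministic simulation of how genetic circuits order the
assembly of heterogeneous protein complexes ("complexoforms").

## The problem

Many protein complexes — cellulosomes, proteasomes, pili — are built from
interchangeable subunits that compete for a limited number of docking sites
on a scaffold protein. The composition of the finished complex (its
*complexoform*) is then decided by a race: which subunit reaches a vacant
site first. Because gene expression happens in bursts of a handful of
molecules, this race is stochastic, and the wiring of the genetic circuit
that expresses the subunits (one operon, a regulatory cascade, or two
independent genes) can bias the outcome long before binding affinities come
into play.

`complexoform` models a two-protein system: proteins X and Y are
transcribed and translated through one of four circuit architectures
(**parallel**, **cascade**, **series uncoupled**, **series coupled**),
exported, and bound irreversibly to multi-site scaffolds. The same
mass-action reaction network is solved two ways:

* **exactly** — Gillespie's stochastic simulation algorithm (direct
  method), run to full scaffold occupancy, in seeded 1,000-run ensembles;
* **deterministically** — the coupled rate equations
  d[S]/dt = Σ_j ν_{js} · k_j · Π_r [R]^{ν⁻} integrated with an adaptive
  stiff solver, giving the large-ensemble (equilibrium-limit) prediction.

Comparing the two separates an **equilibrium regime** (slow kinetics: the
ensemble mean matches the deterministic 25/50/25 combinatorics) from a
**non-equilibrium regime** (fast kinetics: assembly arrests far from it),
quantified by the package's discrepancy and variation metrics, the
complexoform distribution (XX / XY / YY scaffold fractions), the time to
assembly T_asb, and single-scaffold occupancy histograms.

Two presets ship with the package: a dimensionless **generic** model
(10 two-site scaffolds) and a **cellulosome** model in SI units (one
10-site scaffoldin, all rates from literature estimates, molar rates
converted at 1 M ≡ 6·10⁸ molecules per 1 fL cell). It is a library first
(audience: systems/synthetic-biology modellers working in Python), with a
thin `complexoform` CLI for scripted runs.

## Worked example

```python
from complexoform import run_condition, CircuitKind

for kind in CircuitKind:
    rec = run_condition("generic", kind, n_runs=500, base_seed=0, solve_ode=False)
    print(f"{kind.value:>18} XX={rec['frac_XX']:.2f} XY={rec['frac_XY']:.2f} "
          f"YY={rec['frac_YY']:.2f}")
```

prints

```
          parallel XX=0.42 XY=0.15 YY=0.43
           cascade XX=0.88 XY=0.08 YY=0.05
  series_uncoupled XX=0.44 XY=0.39 YY=0.17
    series_coupled XX=0.85 XY=0.13 YY=0.01
```

Same nominal rates everywhere — only the circuit wiring differs. The
cascade and series circuits make X before Y and end mostly in homogeneous
XX scaffolds; the parallel circuit splits its runs between XX- and
YY-dominated outcomes (bimodal, XX ≈ YY) with little mixed XY; the
uncoupled operon, whose two cistrons translate concurrently, mixes the
most. Slowing any single rate (try
`rate_overrides={"k_out": 1e-5}`) drives every circuit to the combinatoric
25/50/25 equilibrium distribution.

The `examples/` directory has one narrative script per capability
(circuit architectures, the two kinetic regimes, cellulosome assembly at
physiological rates, building a custom network by hand). From a shell:

```bash
complexoform simulate --preset cellulosome --circuit cascade --n-runs 1000 --seed 1
complexoform sweep --parameter k_out --grid 1e-3,1e-2,0.1,1 --n-runs 200
complexoform properties --circuit cascade
```

Every command writes CSV outputs plus a JSON manifest (config + seed +
version) from which the run can be regenerated bit-identically.

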