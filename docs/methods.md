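# Methods

## Model overview

The package simulates the expression, transport and irreversible assembly
of two proteins, X and Y, that compete for the docking sites of a fixed
pool of scaffold proteins. Everything is a well-mixed mass-action reaction
network: species are molecule counts (unit volume, so concentration ≡
count), reactions are uni- or bimolecular, and the propensity of a
reaction is its rate constant times the product of its reactant counts.
Scaffold occupancy is tracked as unordered compositions `(nX, nY)` with
`nX + nY ≤ sites`; a state with `v` vacant sites binds external protein P
at propensity `v · k_bind · [state] · [P_ext]`, so the two-fold combinatoric
weight of mixed XY assemblies comes from site multiplicity, not from
distinct ordered species. Binding is irreversible (`k_bind_off = 0`)
throughout: the simulated quantity is the structure of the complex at the
moment assembly completes, not its long-time equilibrium with the
surrounding solution.

A run ends when every docking site is occupied — after which no reaction
can change the assembly — and records the final scaffold composition and
the completion time (the *time to assembly*, T_asb). Runs that can never
complete (extinction, or a time guard of 10⁶ time units) are retained and
flagged; by default they are excluded from composition statistics and
counted separately (all shipped experiments complete).

The same network is solved two ways from the same initial condition:

* **Stochastic** — Gillespie's exact SSA. The direct method is used
  (waiting time ~ Exp(total propensity), reaction chosen proportional to
  propensity), which is statistically identical to the first-reaction
  method but needs fewer random draws. The inner loop is compiled with
  numba over a flat array form of the network; a pure-Python
  `propensities`/`step` pair exposes the identical kinetics for inspection
  and is cross-checked against the kernel and against an exhaustively
  enumerated master equation in the test suite. Ensembles (default 1,000
  runs) derive independent per-run seeds from one base seed via
  `numpy.random.SeedSequence`, making every ensemble reproducible
  bit-for-bit.
* **Deterministic** — the amounts are treated as continuous and the
  mass-action rate equations (term-by-term the expectation of the SSA
  propensities) are integrated with LSODA at `rtol 1e-8 / atol 1e-10`.
  Integration stops early at full occupancy, defined as vacant amount
  < 10⁻⁶ of total sites; terminal compositions are stable to 4 significant
  figures under 10× tolerance tightening (tested).

## Comparison metrics

For the generic model (10 scaffolds × 2 sites), per completed run each
scaffold is XX, XY (≡ YX) or YY; the **complexoform distribution** is the
ensemble mean of these per-run fractions. **Stochastic variation** is the
sum of the three per-class sample SDs (n−1) across runs; the
**stochastic–deterministic discrepancy** is the sum of the three absolute
differences between the ensemble mean and the deterministic terminal
fractions. Absolute values are used so the discrepancy is a non-negative
regime indicator that cannot cancel across classes. For the cellulosome
model (1 scaffold × 10 sites) the per-run summary is the number of
X-occupied sites; variation is its SD, discrepancy its mean absolute
deviation from the deterministic value (in sites), and the ensemble is
summarized by an occupancy histogram over 0…10.

## Circuit architectures

All four circuits share a promoter–polymerase cycle
(`P + RNAP ⇌ P·RNAP` at `k_pro`/`k_pro_off`), two-step transcription
(initiation `k_gene` frees the promoter; completion `k_m` frees the
polymerase and yields the transcript), first-order mRNA loss, two-step
translation (a free ribosome initiates on a transcript at `k_p`,
bimolecular, and is sequestered until it releases the finished protein at
`k_elong`), first-order export (`k_out`) and loss of external protein
(`k_out_loss`). Internal and scaffold-bound protein do not decay.

* **parallel** — two independent copies of this backbone.
* **cascade** — the backbone for X; the Y promoter must first bind an
  internal X molecule (`P_Y + X_int ⇌ P_Y·X` at `k_pro`/`k_act_off`)
  before it can recruit RNAP: X's product is Y's transcription activator.
* **series (one operon)** — a single promoter; transcription is
  sequential, so the nascent transcript carries only the X cistron
  (`mRNA_X`), becoming bicistronic (`mRNA_XY`) one polymerase-traversal
  time later (`k_ext`). Decay is directional the same way: the 5′ X
  cistron is removed first (`mRNA_XY → mRNA_Y` at `k_mrna_loss`) and the
  3′ remnant disappears one traversal time after that (`k_ext`). Both
  cistrons therefore have the same mean availability — Y's window is X's
  window shifted later by ~1/`k_ext` — so the operon biases *when* each
  protein is made, never *how much*; this is what lets every circuit reach
  the combinatoric limit under slow kinetics while remaining X-biased at
  baseline.
  * **uncoupled**: independent ribosome binding sites; X translates from
    `mRNA_X`/`mRNA_XY`, Y from `mRNA_XY`/`mRNA_Y`, concurrently.
  * **coupled**: a single ribosome binding site at the 5′ cistron. Each
    initiating ribosome releases X first and then traverses the
    intercistronic junction and the Y cistron at the slower coupled rate
    (`0.8 · k_p` by default) before releasing Y. Cumulative X and Y
    production is exactly 1:1, but every Y lags its X by a traversal time
    that scales with translation speed — which is why this circuit keeps
    producing XX-dominated assemblies even when translation is slowed,
    while the other circuits relax to the mixed equilibrium.

## Rate constants and pools

**Cellulosome preset** (SI units; one scaffoldin with 10 cohesin sites):
`k_pro = 5.6·10⁷ M⁻¹s⁻¹ → 0.09 s⁻¹`, `k_pro_off = 0.20`, `k_gene = 0.36`,
`k_m = 0.03`, `k_mrna_loss = 0.002`, `k_p = 0.03`, `k_out = 0.5`,
`k_bind = 1·10⁶ M⁻¹s⁻¹ → 0.002 s⁻¹`, `k_out_loss = 0.0002` (all s⁻¹);
1 promoter per gene, 100 RNA polymerases, 5 ribosomes. Molar association
rates are converted at 1 M ≡ 6·10⁸ molecules per bacterial cell (1 fL).
The one constant without a literature value is the activator–promoter
unbinding rate in the cascade; it is set to `k_act_off = 0.01 s⁻¹` (a
stable activated promoter — transcription-factor residence on the scale of
minutes), and the results are insensitive to making it stickier.

**Generic preset** (arbitrary units; 10 scaffolds × 2 sites): the four
nominal rates are transcription `k_m = 1 t⁻¹`, translation
`k_p = 0.1 [C]⁻¹t⁻¹`, export `k_out = 1 t⁻¹` and binding
`k_bind = 1 [C]⁻¹t⁻¹`. The auxiliary constants are this package's
calibration, chosen once so that the generic model exhibits the documented
phenomenology at baseline *and* in the slow-rate limit:

| constant | value | role |
|---|---|---|
| `k_pro`, `k_pro_off` | 10, 10 | fast, non-limiting promoter binding |
| `k_gene` | 0.04 t⁻¹ | rare transcription initiation → burst spacing |
| `k_mrna_loss` | 4.5 t⁻¹ | short-lived transcripts → burst duration |
| `k_ext` | 4 t⁻¹ | inter-cistron traversal (series circuits) |
| `k_elong` | 4 t⁻¹ | protein release after initiation |
| `k_act_off` | = `k_pro_off` | activator residence (cascade) |
| pools | 1 promoter/TU, 10 RNAP, 900 ribosomes | |

The structure behind these numbers matters more than the numbers: with
rare initiation and fast mRNA turnover, expression proceeds in
well-separated bursts of ~20 proteins of one type at a time (whichever
gene currently holds a transcript monopolizes the ribosome pool), so at
baseline the 20 docking sites are usually filled within one or two bursts
— homogeneous assemblies, and a bimodal parallel circuit. Because burst
size is `k_p·Rib/k_mrna_loss`, only the translation-to-degradation *ratio*
matters (the S3-type invariance, tested); because initiation, not promoter
binding, limits transcription, the stochastic distribution is insensitive
to `k_pro` over two orders of magnitude (the S4-type invariance, tested)
even though the deterministic solution may shift. When any downstream rate
is slowed far enough, many bursts of both genes accumulate before the
sites fill and every circuit converges to the combinatoric 25/50/25.

## The slow-export equilibrium limit

The equilibrium-limit experiments slow export by 10⁻⁵ of baseline. The
approach to the combinatoric limit is slow because the assembly window
grows only as `k_out^(-1/2)` (external arrivals accumulate from an
internal pool that grows roughly linearly in time): at 10⁻² of baseline
the ensembles are still visibly biased (XY ≈ 31–40%), at 10⁻⁴ most
circuits are within ~2 pp, and at 10⁻⁵ all four are within ±2.3 pp of
25/50/25 at n = 1000. "Sufficiently slow" therefore means several orders
of magnitude here, and the shipped checks use 10⁻⁵.

## Problem sizes and runtime

All headline experiments use 1,000-run ensembles, the size at which the
ensemble mean is reproducible to the percentage-point scale (for the
bimodal parallel circuit the per-run composition SD is ~0.44, so the mean
XX/YY fractions carry ~1.4 pp standard error; the XY fraction ~0.7 pp —
a realized difference between two independent ensembles is therefore a
few pp for XX/YY). Baseline generic ensembles take well under a second;
the slow-export and slow-binding conditions run tens of thousands of
events per trajectory and take seconds per 1,000-run ensemble on one CPU.
Unit tests use 20–500-run ensembles with correspondingly widened
Monte-Carlo tolerances; the acceptance-style tests run the full 1,000.

## What the model does and does not capture

The generator of conditions here *is* the model: there is no external
data. What passing tests show is internal consistency (exact agreement
with an enumerated master equation on small networks, SSA/ODE structural
identity, conservation laws, seeded reproducibility) and agreement with
the published ensemble statistics at the published conditions. They do not
validate the biological realism of, e.g., a single effective export step
(no spatial transport), the absence of ribosome queuing along a transcript,
the lumped activator mechanism of the cascade, or irreversible binding —
real cohesin–dockerin complexes do exchange on long time scales, so the
computed compositions describe assembly completion, not thermodynamic
equilibrium. The generic auxiliary constants are calibrated, not measured;
conclusions that depend on them beyond the documented invariances should
be re-checked under the user's own parameter choices (every constant is
overridable per run).

## Numerical choices and degenerate inputs

Propensity evaluation is full recomputation per event (networks have
≤ ~150 reactions; the kernel is memory-local and branch-free). Reaction
selection is a single-pass cumulative scan; waiting times use
`-log(U)/a₀`. Seeds are reduced mod 2³¹−1 for the kernel RNG. Networks
with all-zero propensities terminate immediately as incomplete
(extinction); `t_max` guards runs where loss outcompetes binding.
Metrics raise on empty or single-run inputs where a statistic is
undefined (SD of one run, distribution with zero completed runs) rather
than returning silent NaNs; the deterministic solver surfaces integrator
failure as an exception. JSON round-trips of networks are exact, and the
network fingerprint (SHA-256 of the canonical serialization) guards
against comparing an ensemble with a deterministic solution from a
different model.
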