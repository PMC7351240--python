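"""Building a custom reaction network and running both engines on it.

Constructs a minimal binding-only model (no gene expression): pre-loaded
pools of external X and Y compete irreversibly for two-site scaffolds.
With large balanced pools the combinatorics predict 25% XX, 50% XY, 25% YY;
the stochastic ensemble and the deterministic solution both recover this,
and the exact per-run outcomes still scatter around it.
"""

import numpy as np

from complexoform import (
    RateSet,
    ReactionNetwork,
    ScaffoldSpec,
    Species,
    build_binding_reactions,
    complexoform_distribution,
    enumerate_scaffold_states,
    run_ensemble,
    solve_deterministic,
)
from complexoform.metrics import deterministic_distribution
from complexoform.network import scaffold_species_name

spec = ScaffoldSpec(n_scaffolds=10, sites_per_scaffold=2)
rates = RateSet(k_pro=0, k_pro_off=0, k_gene=0, k_m=None, k_mrna_loss=0,
                k_p=0, k_out=0, k_bind=1.0)

species = [Species("X_ext", "protein_external"),
           Species("Y_ext", "protein_external"),
           *enumerate_scaffold_states(spec)]
initial = {sp.id: 0 for sp in species}
initial.update({"X_ext": 300, "Y_ext": 300,
                scaffold_species_name(0, 0): spec.n_scaffolds})
net = ReactionNetwork(species, build_binding_reactions(spec, rates),
                      initial, spec, label="binding_only_demo")

ens = run_ensemble(net, n_runs=400, base_seed=0)
dist = complexoform_distribution(ens)
det = deterministic_distribution(solve_deterministic(net, t_end=100.0))

print(f"network: {len(net.species)} species, {len(net.reactions)} reactions")
print(f"stochastic mean  XX/XY/YY = "
      f"{dist.frac_xx:.3f}/{dist.frac_xy:.3f}/{dist.frac_yy:.3f}")
print(f"deterministic    XX/XY/YY = {det[0]:.3f}/{det[1]:.3f}/{det[2]:.3f}")
print(
    "\nBoth routes approach the combinatoric 0.25/0.50/0.25 because the\n"
    "pools are large and balanced: every docking event is a fair coin flip.\n"
    "Smaller or imbalanced pools, or coupling to live gene expression,\n"
    "move the stochastic result away from this equilibrium prediction."
)
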