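"""Shared fixtures: tiny hand-built networks used across the test modules."""

from __future__ import annotations

import pytest

from complexoform.network import (
    RateSet,
    Reaction,
    ReactionNetwork,
    ScaffoldSpec,
    Species,
    build_binding_reactions,
    enumerate_scaffold_states,
    scaffold_species_name,
)


def make_binding_only_network(
    n_scaffolds: int,
    sites: int,
    n_x: int,
    n_y: int,
    k_bind: float = 1.0,
) -> ReactionNetwork:
    """A pre-loaded pool of external X/Y competing for empty scaffolds, with
    no expression reactions — the minimal assembly model."""
    spec = ScaffoldSpec(n_scaffolds, sites)
    rates = RateSet(
        k_pro=0, k_pro_off=0, k_gene=0, k_m=None, k_mrna_loss=0,
        k_p=0, k_out=0, k_bind=k_bind,
    )
    species = [
        Species("X_ext", "protein_external"),
        Species("Y_ext", "protein_external"),
        *enumerate_scaffold_states(spec),
    ]
    initial = {sp.id: 0 for sp in species}
    initial["X_ext"] = n_x
    initial["Y_ext"] = n_y
    initial[scaffold_species_name(0, 0)] = n_scaffolds
    return ReactionNetwork(
        species, build_binding_reactions(spec, rates), initial, spec,
        label=f"binding_only_{n_scaffolds}x{sites}",
    )


@pytest.fixture
def two_site_toy() -> ReactionNetwork:
    """2 X + 2 Y competing for one two-site scaffold (6 reachable states)."""
    return make_binding_only_network(1, 2, 2, 2)


@pytest.fixture
def ten_scaffold_pool() -> ReactionNetwork:
    """Excess X only, 10 two-site scaffolds: must end 100% XX."""
    return make_binding_only_network(10, 2, 40, 0)


@pytest.fixture
def simple_decay() -> ReactionNetwork:
    """Single reaction A -> B (k=2) plus an inert scaffold to give the
    network a completion criterion it can never meet."""
    spec = ScaffoldSpec(1, 1)
    species = [
        Species("A", "protein_internal"),
        Species("B", "protein_external"),
        *enumerate_scaffold_states(spec),
    ]
    initial = {sp.id: 0 for sp in species}
    initial["A"] = 3
    initial[scaffold_species_name(0, 0)] = 1
    return ReactionNetwork(
        species, [Reaction({"A": 1}, {"B": 1}, 2.0, "decay")], initial, spec,
        label="simple_decay",
    )
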