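"""Structure of the constructed reaction networks."""

from __future__ import annotations

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from complexoform import (
    CircuitKind,
    RateSet,
    ScaffoldSpec,
    assemble_network,
    build_binding_reactions,
    build_expression_reactions,
    enumerate_scaffold_states,
    network_from_json,
    network_to_json,
)
from complexoform.experiments import CELLULOSOME, GENERIC, build_preset_network
from complexoform.network import Reaction, default_pools


def relabel(name: str) -> str:
    """Swap the X and Y labels in a species or reaction id."""
    return (
        name.replace("X", "@").replace("Y", "X").replace("@", "Y")
    )


@pytest.mark.parametrize(
    "sites,expected",
    [(1, 3), (2, 6), (10, 66)],
)
def test_scaffold_state_count(sites, expected):
    """One species per unordered (nX, nY) composition with nX+nY <= sites;
    brute-force pair enumeration gives the same count."""
    states = enumerate_scaffold_states(ScaffoldSpec(1, sites))
    brute = {(nx, ny) for nx in range(sites + 1) for ny in range(sites + 1)
             if nx + ny <= sites}
    assert len(states) == expected == len(brute)
    assert {(s.n_x, s.n_y) for s in states} == brute
    assert len({s.id for s in states}) == len(states)


@settings(max_examples=20, deadline=None)
@given(st.integers(min_value=1, max_value=20))
def test_scaffold_state_count_formula(sites):
    states = enumerate_scaffold_states(ScaffoldSpec(1, sites))
    assert len(states) == (sites + 1) * (sites + 2) // 2


def test_two_site_binding_reactions():
    """A 2-site scaffold has 3 non-full states x 2 proteins = 6 irreversible
    binding reactions, with the vacant-site multiplicity folded into k."""
    rxns = build_binding_reactions(ScaffoldSpec(10, 2), GENERIC.rates)
    assert len(rxns) == 6
    empty_x = next(r for r in rxns if r.label == "bind_X:S[0X0Y]")
    assert empty_x.rate_constant == pytest.approx(2 * GENERIC.rates.k_bind)
    single = next(r for r in rxns if r.label == "bind_X:S[1X0Y]")
    assert single.rate_constant == pytest.approx(1 * GENERIC.rates.k_bind)
    # no reaction consumes a full state
    full_ids = {"S[2X0Y]", "S[1X1Y]", "S[0X2Y]"}
    assert all(not (set(r.reactants) & full_ids) for r in rxns)


def test_reversible_binding_adds_unbinding_weighted_by_occupancy():
    rates = GENERIC.rates.with_overrides(k_bind_off=0.5)
    rxns = build_binding_reactions(ScaffoldSpec(10, 2), rates)
    unb = [r for r in rxns if r.label.startswith("unbind")]
    assert len(unb) == 6  # X from {X, XX, XY}, Y from {Y, YY, XY}
    xx = next(r for r in unb if r.label == "unbind_X:S[2X0Y]")
    assert xx.rate_constant == pytest.approx(2 * 0.5)


def test_parallel_circuit_is_xy_symmetric():
    """Relabeling X <-> Y maps the parallel expression network onto itself."""
    rxns = build_expression_reactions(CircuitKind.PARALLEL, GENERIC.rates)

    def key(r: Reaction):
        return (frozenset(r.reactants.items()), frozenset(r.products.items()),
                r.rate_constant)

    original = {key(r) for r in rxns}
    swapped = {
        (frozenset((relabel(s), n) for s, n in r.reactants.items()),
         frozenset((relabel(s), n) for s, n in r.products.items()),
         r.rate_constant)
        for r in rxns
    }
    assert original == swapped


def reachable_species(net, blocked=frozenset()):
    """Species obtainable from the initial state by firing enabled reactions
    (ignoring counts beyond presence), never passing through `blocked`."""
    have = {s for s, c in net.initial_counts.items() if c > 0} - set(blocked)
    grown = True
    while grown:
        grown = False
        for r in net.reactions:
            if set(r.reactants) & set(blocked):
                continue
            if set(r.reactants) <= have:
                new = set(r.products) - have - set(blocked)
                if new:
                    have |= new
                    grown = True
    return have


@pytest.mark.parametrize("kind", [CircuitKind.CASCADE, CircuitKind.SERIES_UNCOUPLED,
                                  CircuitKind.SERIES_COUPLED])
def test_y_unreachable_without_x(kind):
    """Blocking the X-side species makes Y_int unreachable: the non-parallel
    circuits impose a strict X-before-Y dependency (in the parallel circuit
    Y stays reachable)."""
    x_species = frozenset({"mRNA_X", "X_int"})
    net = build_preset_network("generic", kind)
    assert "Y_int" in reachable_species(net)
    assert "Y_int" not in reachable_species(net, blocked=x_species)
    par = build_preset_network("generic", "parallel")
    assert "Y_int" in reachable_species(par, blocked=x_species)


def test_cascade_y_transcription_inert_at_start():
    """At t=0 the cascade Y promoter has no bound activator, so every
    reaction chain toward mRNA_Y starts from a zero-count species."""
    net = build_preset_network("generic", "cascade")
    producers = [r for r in net.reactions if "mRNA_Y" in r.products]
    for r in producers:
        assert any(net.initial_counts[s] == 0 for s in r.reactants)


def test_assemble_network_initial_state():
    net = build_preset_network("generic", "parallel")
    vac = net.vacancy_weights()
    total_vacant = sum(vac[s] * c for s, c in net.initial_counts.items())
    assert total_vacant == 20
    assert net.initial_counts["RNAP"] == 10
    assert net.initial_counts["Rib"] == 900
    assert net.initial_counts["P_X"] == net.initial_counts["P_Y"] == 1
    # no mRNA or protein at t=0
    for sp in net.species:
        if sp.role in ("mrna", "protein_internal", "protein_external"):
            assert net.initial_counts[sp.id] == 0


def test_cellulosome_initial_state():
    net = build_preset_network("cellulosome", "cascade")
    vac = net.vacancy_weights()
    assert sum(vac[s] * c for s, c in net.initial_counts.items()) == 10
    assert net.initial_counts["RNAP"] == 100
    assert net.initial_counts["Rib"] == 5


def test_scaffold_conservation_by_stoichiometry():
    """Every reaction of every preset network conserves total scaffolds
    (checked via net stoichiometric change of scaffold-state species)."""
    for preset in ("generic", "cellulosome"):
        for kind in CircuitKind:
            net = build_preset_network(preset, kind)
            scaffold_ids = {sp.id for sp in net.scaffold_species()}
            for r in net.reactions:
                net_change = sum(d for s, d in r.net_change().items()
                                 if s in scaffold_ids)
                assert net_change == 0, (preset, kind, r.label)


def test_all_reactions_uni_or_bimolecular():
    for preset in ("generic", "cellulosome"):
        for kind in CircuitKind:
            net = build_preset_network(preset, kind)
            assert all(r.order in (1, 2) for r in net.reactions)


def test_operon_cistron_windows_are_balanced():
    """Sequential transcription + directional decay give X and Y cistrons
    equal mean availability: X exists through (partial, full) stages and Y
    through (full, remnant), with the flanking stages sharing one rate."""
    rxns = build_expression_reactions(CircuitKind.SERIES_UNCOUPLED, GENERIC.rates)
    by_label = {r.label: r for r in rxns}
    assert by_label["tx_extend_XY"].rate_constant == \
        by_label["mrna_decay_3prime"].rate_constant


def test_rateset_validation():
    with pytest.raises(ValueError, match="k_bind"):
        GENERIC.rates.with_overrides(k_bind=-1)
    with pytest.raises(ValueError, match="unknown rate fields"):
        GENERIC.rates.with_overrides(k_nope=1.0)


def test_negative_pool_rejected():
    with pytest.raises(ValueError, match="negative initial count"):
        assemble_network(CircuitKind.PARALLEL, GENERIC.rates,
                         ScaffoldSpec(10, 2), {"P_X": 1, "P_Y": 1, "RNAP": -1,
                                               "Rib": 10})


def test_unknown_pool_rejected():
    with pytest.raises(ValueError, match="not part of"):
        assemble_network(CircuitKind.SERIES_COUPLED, GENERIC.rates,
                         ScaffoldSpec(10, 2), {"P_X": 1})  # series has P_XY


def test_default_pools_per_circuit():
    assert set(default_pools(CircuitKind.PARALLEL, 10, 10)) == {"P_X", "P_Y", "RNAP", "Rib"}
    assert set(default_pools(CircuitKind.SERIES_COUPLED, 10, 10)) == {"P_XY", "RNAP", "Rib"}


def test_json_round_trip():
    for kind in CircuitKind:
        net = build_preset_network("generic", kind)
        restored = network_from_json(network_to_json(net))
        assert restored.fingerprint() == net.fingerprint()
        assert network_to_json(restored) == network_to_json(net)


def test_fingerprint_changes_with_rates():
    a = build_preset_network("generic", "parallel")
    b = build_preset_network("generic", "parallel", rate_overrides={"k_bind": 0.5})
    assert a.fingerprint() != b.fingerprint()


def test_cellulosome_two_step_transcription():
    """Table-style rate sets with both k_gene and k_m produce a two-step
    transcription (initiation frees the promoter, completion frees RNAP)."""
    net = build_preset_network("cellulosome", "parallel")
    labels = {r.label for r in net.reactions}
    assert "tx_init_X" in labels and "tx_done_X" in labels
    gen = build_preset_network("generic", "parallel")
    glabels = {r.label for r in gen.reactions}
    assert "tx_init_X" in glabels  # generic is two-step as well
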