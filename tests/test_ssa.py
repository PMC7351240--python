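"""Stochastic engine: propensity conventions, direct-method statistics,
determinism, and agreement with an exhaustively enumerated master equation."""

from __future__ import annotations

import math
from fractions import Fraction
from functools import lru_cache

import numpy as np
import pytest

from complexoform import (
    SystemState,
    compile_network,
    propensities,
    run_ensemble,
    run_to_completion,
    step,
)
from complexoform.metrics import complexoform_distribution
from complexoform.ssa import derive_seeds

from conftest import make_binding_only_network


# ---------------------------------------------------------------------------
# propensities


def test_unimolecular_propensity(simple_decay):
    state = SystemState(dict(simple_decay.initial_counts))
    a = propensities(state, simple_decay)
    assert a.tolist() == [2.0 * 3]


def test_zero_count_reactant_gives_zero(simple_decay):
    state = SystemState({**simple_decay.initial_counts, "A": 0})
    assert propensities(state, simple_decay).sum() == 0.0


def test_site_multiplicity_in_binding_propensity():
    """X binding to 10 empty 2-site scaffolds with 4 external X at k=1:
    total propensity 2 * 1 * 10 * 4 = 80."""
    net = make_binding_only_network(10, 2, 4, 0)
    state = SystemState(dict(net.initial_counts))
    a = propensities(state, net)
    j = next(i for i, r in enumerate(net.reactions)
             if r.label == "bind_X:S[0X0Y]")
    assert a[j] == pytest.approx(80.0)


def test_kernel_propensities_match_reference():
    """The compiled kernel's k/r1/r2 encoding reproduces the pure-Python
    propensity vector on a random reachable state."""
    net = make_binding_only_network(3, 2, 5, 7)
    cn = compile_network(net)
    state = SystemState(dict(net.initial_counts))
    ref = propensities(state, net)
    x = cn.x0.astype(float)
    kern = cn.k * x[cn.r1] * np.where(cn.r2 >= 0, x[np.maximum(cn.r2, 0)], 1.0)
    np.testing.assert_allclose(kern, ref)


# ---------------------------------------------------------------------------
# single steps


def test_step_waiting_time_and_selection(simple_decay):
    rng = np.random.default_rng(0)
    dts = []
    for _ in range(4000):
        out = step(SystemState(dict(simple_decay.initial_counts)), simple_decay, rng)
        assert out is not None
        dts.append(out[1])
    # total propensity 6 -> mean waiting time 1/6
    mean = np.mean(dts)
    se = np.std(dts) / math.sqrt(len(dts))
    assert abs(mean - 1 / 6) < 4 * se


def test_step_selects_proportional_to_propensity():
    """Two binding channels with 3:1 propensity ratio are chosen 75/25."""
    net = make_binding_only_network(1, 1, 3, 1)  # X:Y propensities 3:1
    rng = np.random.default_rng(1)
    picks = []
    for _ in range(4000):
        _, _, j = step(SystemState(dict(net.initial_counts)), net, rng)
        picks.append(net.reactions[j].label)
    frac_x = np.mean([p.startswith("bind_X") for p in picks])
    assert abs(frac_x - 0.75) < 4 * math.sqrt(0.75 * 0.25 / 4000)


def test_step_extinction_signal(simple_decay):
    state = SystemState({**simple_decay.initial_counts, "A": 0})
    assert step(state, simple_decay, np.random.default_rng(0)) is None


# ---------------------------------------------------------------------------
# full runs


def test_inert_network_flagged_incomplete(simple_decay):
    res = run_to_completion(simple_decay, seed=1, t_max=100.0)
    assert not res.completed and res.t_asb is None
    assert res.final_counts["B"] == 3  # all A decayed, then extinction


def test_pure_x_pool_fills_all_xx(ten_scaffold_pool):
    res = run_to_completion(ten_scaffold_pool, seed=3)
    assert res.completed
    assert res.final_counts["S[2X0Y]"] == 10
    assert res.final_counts["X_ext"] == 20  # 40 - 20 bound


def test_single_site_coin_flip():
    """1 X vs 1 Y for a single-site scaffold: X wins ~50% of seeds."""
    net = make_binding_only_network(1, 1, 1, 1)
    ens = run_ensemble(net, n_runs=4000, base_seed=11)
    wins = ens.final_counts[:, ens.compiled.index("S[1X0Y]")].mean()
    assert abs(wins - 0.5) < 4 * math.sqrt(0.25 / 4000)


def test_identical_seed_bitwise_identical(two_site_toy):
    a = run_to_completion(two_site_toy, seed=99)
    b = run_to_completion(two_site_toy, seed=99)
    assert a.final_counts == b.final_counts
    assert a.t_asb == b.t_asb and a.n_events == b.n_events


def test_ensemble_deterministic_under_base_seed(two_site_toy):
    e1 = run_ensemble(two_site_toy, n_runs=50, base_seed=7)
    e2 = run_ensemble(two_site_toy, n_runs=50, base_seed=7)
    np.testing.assert_array_equal(e1.final_counts, e2.final_counts)
    np.testing.assert_array_equal(e1.t_asb, e2.t_asb)


def test_single_run_ensemble(two_site_toy):
    ens = run_ensemble(two_site_toy, n_runs=1, base_seed=5)
    assert ens.n_runs == 1
    dist = complexoform_distribution(ens)
    assert sum(dist.as_tuple()) == pytest.approx(1.0)


def test_derived_seeds_distinct():
    seeds = derive_seeds(123, 1000)
    assert len(set(seeds.tolist())) == 1000
    assert seeds.max() < 2**31


def test_monotone_occupancy_with_irreversible_binding(two_site_toy):
    """With k_bind_off = 0 the number of occupied docking sites never
    decreases along a trajectory."""
    scaffold_ids = tuple(sp.id for sp in two_site_toy.scaffold_species())
    res = run_to_completion(two_site_toy, seed=17, log_species=scaffold_ids)
    times, counts = res.log
    weights = np.array([sp.n_x + sp.n_y for sp in two_site_toy.scaffold_species()])
    occupied = counts @ weights
    assert (np.diff(occupied) >= 0).all()
    assert occupied[-1] == 2


def test_scaffold_conservation_along_trajectory(two_site_toy):
    scaffold_ids = tuple(sp.id for sp in two_site_toy.scaffold_species())
    res = run_to_completion(two_site_toy, seed=23, log_species=scaffold_ids)
    _, counts = res.log
    assert (counts.sum(axis=1) == 1).all()


# ---------------------------------------------------------------------------
# exact master-equation oracle


def terminal_distribution_oracle(n_x: int, n_y: int, sites: int):
    """Exact absorption probabilities of the binding-only master equation
    for ONE scaffold, by recursive enumeration over (free X, free Y,
    bound X, bound Y) with propensities k*(vacant)*(free count).

    Independent of the simulator: pure rational arithmetic on the embedded
    jump chain."""

    @lru_cache(maxsize=None)
    def absorb(fx: int, fy: int, bx: int, by: int):
        vacant = sites - bx - by
        if vacant == 0 or (fx == 0 and fy == 0):
            out = {}
            out[(bx, by)] = Fraction(1)
            return out
        ax = Fraction(vacant * fx)
        ay = Fraction(vacant * fy)
        total = ax + ay
        out: dict[tuple[int, int], Fraction] = {}
        if ax:
            for state, p in absorb(fx - 1, fy, bx + 1, by).items():
                out[state] = out.get(state, Fraction(0)) + (ax / total) * p
        if ay:
            for state, p in absorb(fx, fy - 1, bx, by + 1).items():
                out[state] = out.get(state, Fraction(0)) + (ay / total) * p
        return out

    return absorb(n_x, n_y, 0, 0)


def test_oracle_closed_form_small_case():
    """2 X + 2 Y on one 2-site scaffold: sequential picks give
    XX = (2/4)(1/3) = 1/6, YY = 1/6, XY = 2/3."""
    dist = terminal_distribution_oracle(2, 2, 2)
    assert dist[(2, 0)] == Fraction(1, 6)
    assert dist[(0, 2)] == Fraction(1, 6)
    assert dist[(1, 1)] == Fraction(2, 3)


def test_ssa_matches_exact_master_equation():
    """Ensemble outcome frequencies on the toy network agree with the
    brute-force CME terminal distribution within 4 Monte-Carlo SE at n=1e4."""
    n = 10_000
    net = make_binding_only_network(1, 2, 3, 2)
    exact = {k: float(v) for k, v in terminal_distribution_oracle(3, 2, 2).items()}
    ens = run_ensemble(net, n_runs=n, base_seed=2024)
    cols = {(sp.n_x, sp.n_y): i for i, sp in enumerate(ens.network.species)
            if sp.role == "scaffold_state"}
    for state, p in exact.items():
        freq = ens.final_counts[:, cols[state]].mean()
        se = math.sqrt(p * (1 - p) / n)
        assert abs(freq - p) < 4 * se, (state, freq, p)


def test_python_step_agrees_with_kernel():
    """Driving the pure-Python `step` to completion reproduces the compiled
    kernel's terminal statistics on the toy network (same kinetics, two
    implementations)."""
    net = make_binding_only_network(1, 2, 3, 2)
    n = 2000
    rng = np.random.default_rng(5)
    freq_py = {}
    for _ in range(n):
        state = SystemState(dict(net.initial_counts))
        while True:
            out = step(state, net, rng)
            if out is None:
                break
            state = out[0]
            vac = sum(net.vacancy_weights()[s] * c for s, c in state.counts.items())
            if vac == 0:
                break
        key = next((sp.n_x, sp.n_y) for sp in net.scaffold_species()
                   if state.counts[sp.id] == 1)
        freq_py[key] = freq_py.get(key, 0) + 1 / n
    exact = {k: float(v) for k, v in terminal_distribution_oracle(3, 2, 2).items()}
    for state, p in exact.items():
        se = math.sqrt(p * (1 - p) / n)
        assert abs(freq_py.get(state, 0.0) - p) < 4 * se
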