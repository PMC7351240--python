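"""Exact stochastic simulation (Gillespie direct method) of a reaction network.

Runs proceed until every docking site is occupied — after which the assembly
cannot evolve further — or until extinction (no reaction can fire) or a time
guard.  The inner loop is compiled with numba over a flat array form of the
network; :func:`propensities` and :func:`step` expose the same kinetics as
plain Python for inspection and cross-checking.

Ensembles derive one independent seed per run from a base seed through
``numpy.random.SeedSequence``, so an :class:`EnsembleResult` is bit-for-bit
reproducible from (network, n_runs, base_seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .network import ReactionNetwork

__all__ = [
    "CompiledNetwork",
    "SystemState",
    "RunResult",
    "EnsembleResult",
    "compile_network",
    "propensities",
    "step",
    "run_to_completion",
    "run_ensemble",
]

DEFAULT_T_MAX = 1e6
DEFAULT_N_RUNS = 1000


@dataclass(frozen=True)
class CompiledNetwork:
    """Flat array form of a :class:`ReactionNetwork` for the compiled kernel.

    ``k`` folds in site multiplicity, so propensity_j = k[j] * x[r1[j]]
    (* x[r2[j]] for bimolecular reactions, r2[j] == -1 otherwise).  State
    changes are stored sparsely (CSR-like) in change_ptr/idx/delta, and
    ``vac_delta`` is each reaction's effect on the total vacant-site count.
    """

    network: ReactionNetwork = field(repr=False)
    species_ids: tuple[str, ...]
    k: np.ndarray
    r1: np.ndarray
    r2: np.ndarray
    change_ptr: np.ndarray
    change_idx: np.ndarray
    change_delta: np.ndarray
    vac_delta: np.ndarray
    vac_weight: np.ndarray
    x0: np.ndarray

    @property
    def n_species(self) -> int:
        return len(self.species_ids)

    @property
    def n_reactions(self) -> int:
        return len(self.k)

    def index(self, sid: str) -> int:
        return self.species_ids.index(sid)


def compile_network(network: ReactionNetwork) -> CompiledNetwork:
    ids = tuple(sp.id for sp in network.species)
    index = {sid: i for i, sid in enumerate(ids)}
    n_r = len(network.reactions)

    k = np.empty(n_r)
    r1 = np.full(n_r, -1, dtype=np.int64)
    r2 = np.full(n_r, -1, dtype=np.int64)
    ptr = [0]
    cidx: list[int] = []
    cdel: list[int] = []
    vac_w = np.array([network.vacancy_weights()[sid] for sid in ids], dtype=np.int64)
    vac_delta = np.zeros(n_r, dtype=np.int64)

    for j, rxn in enumerate(network.reactions):
        k[j] = rxn.rate_constant
        rs: list[int] = []
        for sid, n in rxn.reactants.items():
            rs.extend([index[sid]] * n)
        if len(rs) == 1:
            r1[j] = rs[0]
        else:
            r1[j], r2[j] = rs
        for sid, d in sorted(rxn.net_change().items()):
            cidx.append(index[sid])
            cdel.append(d)
            vac_delta[j] += vac_w[index[sid]] * d
        ptr.append(len(cidx))

    x0 = np.array([network.initial_counts.get(sid, 0) for sid in ids],
                  dtype=np.int64)
    return CompiledNetwork(
        network=network,
        species_ids=ids,
        k=k,
        r1=r1,
        r2=r2,
        change_ptr=np.array(ptr, dtype=np.int64),
        change_idx=np.array(cidx, dtype=np.int64),
        change_delta=np.array(cdel, dtype=np.int64),
        vac_delta=vac_delta,
        vac_weight=vac_w,
        x0=x0,
    )


# ---------------------------------------------------------------------------
# reference (pure-Python) kinetics


@dataclass
class SystemState:
    counts: dict[str, int]
    time: float = 0.0


def propensities(state: SystemState, network: ReactionNetwork) -> np.ndarray:
    """One propensity per reaction: k times the product of reactant counts
    (site multiplicity is already folded into k for binding reactions)."""
    a = np.empty(len(network.reactions))
    for j, rxn in enumerate(network.reactions):
        v = rxn.rate_constant
        for sid, n in rxn.reactants.items():
            c = state.counts.get(sid, 0)
            for m in range(n):  # n is 1 or 2; no A+A reactions exist here
                v *= max(c - m, 0)
        a[j] = v
    return a


def step(
    state: SystemState, network: ReactionNetwork, rng: np.random.Generator
) -> tuple[SystemState, float, int] | None:
    """One direct-method event: returns (new state, dt, reaction index), or
    None when every propensity is zero (extinction)."""
    a = propensities(state, network)
    total = a.sum()
    if total <= 0.0:
        return None
    dt = rng.exponential(1.0 / total)
    j = int(rng.choice(len(a), p=a / total))
    counts = dict(state.counts)
    for sid, d in network.reactions[j].net_change().items():
        counts[sid] = counts.get(sid, 0) + d
        if counts[sid] < 0:
            raise RuntimeError(f"negative count for {sid} after {network.reactions[j].label}")
    return SystemState(counts, state.time + dt), dt, j


# ---------------------------------------------------------------------------
# compiled kernel


@njit(cache=True)
def _ssa_kernel(k, r1, r2, cptr, cidx, cdel, vdel, x0, vac0, t_max, seed,
                log_species, log_times, log_counts):
    """One run to full occupancy.  Returns (final counts, t, completed,
    n_events, n_logged).  log_times/log_counts are filled with a piecewise-
    constant trajectory of log_species when their length is non-zero."""
    np.random.seed(seed)
    x = x0.copy()
    n_r = k.shape[0]
    a = np.empty(n_r)
    t = 0.0
    vac = vac0
    n_events = 0
    n_logged = 0
    cap = log_times.shape[0]
    if cap > 0:
        log_times[0] = 0.0
        for q in range(log_species.shape[0]):
            log_counts[0, q] = x[log_species[q]]
        n_logged = 1
    while vac > 0:
        total = 0.0
        for j in range(n_r):
            v = k[j] * x[r1[j]]
            if r2[j] >= 0:
                v *= x[r2[j]]
            a[j] = v
            total += v
        if total <= 0.0:
            return x, t, False, n_events, n_logged  # extinction
        t += -np.log(np.random.random()) / total
        if t > t_max:
            return x, t_max, False, n_events, n_logged
        u = np.random.random() * total
        acc = 0.0
        j = n_r - 1
        for jj in range(n_r):
            acc += a[jj]
            if u < acc:
                j = jj
                break
        for p in range(cptr[j], cptr[j + 1]):
            x[cidx[p]] += cdel[p]
        vac += vdel[j]
        n_events += 1
        if cap > 0 and n_logged < cap:
            log_times[n_logged] = t
            for q in range(log_species.shape[0]):
                log_counts[n_logged, q] = x[log_species[q]]
            n_logged += 1
    return x, t, True, n_events, n_logged


_EMPTY_I8 = np.empty(0, dtype=np.int64)
_EMPTY_F8 = np.empty(0)
_EMPTY_C = np.empty((0, 0), dtype=np.int64)


@dataclass
class RunResult:
    """Outcome of a single stochastic run.

    ``t_asb`` (time to assembly) is the event time at which the last vacant
    docking site was filled; it is None for incomplete runs.
    """

    final_counts: dict[str, int]
    t_asb: float | None
    completed: bool
    seed: int
    n_events: int
    log: tuple[np.ndarray, np.ndarray] | None = None  # (times, counts)

    @property
    def final_state(self) -> SystemState:
        return SystemState(dict(self.final_counts),
                           self.t_asb if self.completed else 0.0)


@dataclass
class EnsembleResult:
    """A seeded ensemble of runs of one network.

    ``scaffold_counts`` is the (n_runs, n_scaffold_states) matrix of final
    scaffold-state copy numbers, in the order of ``scaffold_index``; most
    metrics are computed from it directly.
    """

    compiled: CompiledNetwork = field(repr=False)
    base_seed: int
    seeds: np.ndarray
    final_counts: np.ndarray  # (n_runs, n_species)
    t_asb: np.ndarray  # (n_runs,), nan when incomplete
    completed: np.ndarray  # (n_runs,) bool
    n_events: np.ndarray
    logs: list[tuple[np.ndarray, np.ndarray]] | None = None
    log_species: tuple[str, ...] = ()

    @property
    def n_runs(self) -> int:
        return len(self.seeds)

    @property
    def network(self) -> ReactionNetwork:
        return self.compiled.network

    @property
    def fingerprint(self) -> str:
        return self.compiled.network.fingerprint()

    def scaffold_index(self) -> list[tuple[int, int, int]]:
        """(column in final_counts, n_x, n_y) for each scaffold state."""
        out = []
        for i, sp in enumerate(self.network.species):
            if sp.role == "scaffold_state":
                out.append((i, sp.n_x, sp.n_y))
        return out

    def run(self, i: int) -> RunResult:
        counts = {sid: int(c) for sid, c in
                  zip(self.compiled.species_ids, self.final_counts[i])}
        completed = bool(self.completed[i])
        return RunResult(counts, float(self.t_asb[i]) if completed else None,
                         completed, int(self.seeds[i]), int(self.n_events[i]),
                         log=self.logs[i] if self.logs is not None else None)


def derive_seeds(base_seed: int, n: int) -> np.ndarray:
    """Independent per-run seeds (< 2^31) from one base seed."""
    ss = np.random.SeedSequence(base_seed)
    return (ss.generate_state(n, dtype=np.uint64) % (2**31 - 1)).astype(np.int64)


def run_to_completion(
    network: ReactionNetwork | CompiledNetwork,
    seed: int,
    t_max: float = DEFAULT_T_MAX,
    log_species: tuple[str, ...] = (),
    log_capacity: int = 200_000,
) -> RunResult:
    """Simulate one trajectory until all docking sites are occupied.

    Incomplete runs (extinction, or time guard exceeded) are valid results
    with ``completed=False``.  With ``log_species`` set, the run records a
    piecewise-constant trajectory of those species' counts.
    """
    if t_max <= 0:
        raise ValueError("t_max must be > 0")
    cn = network if isinstance(network, CompiledNetwork) else compile_network(network)
    vac0 = int(cn.vac_weight @ cn.x0)
    if log_species:
        ls = np.array([cn.index(s) for s in log_species], dtype=np.int64)
        lt = np.empty(log_capacity)
        lc = np.empty((log_capacity, len(ls)), dtype=np.int64)
    else:
        ls, lt, lc = _EMPTY_I8, _EMPTY_F8, _EMPTY_C
    x, t, completed, n_events, n_logged = _ssa_kernel(
        cn.k, cn.r1, cn.r2, cn.change_ptr, cn.change_idx, cn.change_delta,
        cn.vac_delta, cn.x0, vac0, t_max, int(seed) % (2**31 - 1), ls, lt, lc,
    )
    counts = {sid: int(c) for sid, c in zip(cn.species_ids, x)}
    log = (lt[:n_logged].copy(), lc[:n_logged].copy()) if log_species else None
    return RunResult(counts, t if completed else None, completed, int(seed),
                     int(n_events), log=log)


def run_ensemble(
    network: ReactionNetwork | CompiledNetwork,
    n_runs: int = DEFAULT_N_RUNS,
    base_seed: int = 0,
    t_max: float = DEFAULT_T_MAX,
    log_species: tuple[str, ...] = (),
    log_capacity: int = 200_000,
) -> EnsembleResult:
    """Run ``n_runs`` independent trajectories with per-run seeds derived
    from ``base_seed``; deterministic given (network, n_runs, base_seed)."""
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    cn = network if isinstance(network, CompiledNetwork) else compile_network(network)
    seeds = derive_seeds(base_seed, n_runs)
    vac0 = int(cn.vac_weight @ cn.x0)

    finals = np.empty((n_runs, cn.n_species), dtype=np.int64)
    t_asb = np.full(n_runs, np.nan)
    completed = np.zeros(n_runs, dtype=bool)
    n_events = np.zeros(n_runs, dtype=np.int64)
    logs: list[tuple[np.ndarray, np.ndarray]] | None = [] if log_species else None
    if log_species:
        ls = np.array([cn.index(s) for s in log_species], dtype=np.int64)
    else:
        ls = _EMPTY_I8

    for i in range(n_runs):
        if log_species:
            lt = np.empty(log_capacity)
            lc = np.empty((log_capacity, len(ls)), dtype=np.int64)
        else:
            lt, lc = _EMPTY_F8, _EMPTY_C
        x, t, done, ne, nl = _ssa_kernel(
            cn.k, cn.r1, cn.r2, cn.change_ptr, cn.change_idx, cn.change_delta,
            cn.vac_delta, cn.x0, vac0, t_max, int(seeds[i]), ls, lt, lc,
        )
        finals[i] = x
        completed[i] = done
        n_events[i] = ne
        if done:
            t_asb[i] = t
        if log_species:
            logs.append((lt[:nl].copy(), lc[:nl].copy()))

    return EnsembleResult(cn, base_seed, seeds, finals, t_asb, completed,
                          n_events, logs=logs, log_species=tuple(log_species))
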