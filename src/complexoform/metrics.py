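"""Summary statistics of assembly ensembles and deterministic solutions.

Two reporting modes mirror the two model systems:

* generic mode — scaffolds with two docking sites are classified as XX, XY
  (unordered, includes YX) or YY; the distribution is the ensemble mean of
  per-run scaffold fractions, the stochastic variation is the sum of the
  three per-class standard deviations, and the stochastic-deterministic
  discrepancy is the sum of the three absolute differences (all in scaffold
  fractions).
* cellulosome mode — a single many-site scaffold is summarized by the
  number of sites occupied by protein X; variation is the SD of that count
  across runs and discrepancy the mean absolute deviation from the
  deterministic X-site count (both in sites).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ode import DeterministicSolution
from .ssa import EnsembleResult

__all__ = [
    "ComplexoformDistribution",
    "VariationReport",
    "DiscrepancyReport",
    "AssemblyTime",
    "complexoform_distribution",
    "stochastic_variation",
    "discrepancy",
    "time_to_assembly",
    "occupancy_histogram",
    "deterministic_distribution",
    "x_site_matrix",
]


@dataclass(frozen=True)
class ComplexoformDistribution:
    """Mean fractions of scaffolds ending XX, XY/YX, or YY."""

    frac_xx: float
    frac_xy: float
    frac_yy: float
    n_complete: int
    n_incomplete: int = 0

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.frac_xx, self.frac_xy, self.frac_yy)


@dataclass(frozen=True)
class VariationReport:
    value: float
    mode: str  # "generic" | "cellulosome"


@dataclass(frozen=True)
class DiscrepancyReport:
    value: float
    mode: str


@dataclass(frozen=True)
class AssemblyTime:
    mean: float
    sd: float  # 0 (flagged by n_complete==1) for a single run
    n_complete: int
    n_incomplete: int


# ---------------------------------------------------------------------------
# helpers


def _completed(ensemble: EnsembleResult, require: bool = True) -> np.ndarray:
    mask = ensemble.completed
    if require and not mask.any():
        raise ValueError("ensemble has no completed runs")
    return mask


def composition_matrix(ensemble: EnsembleResult) -> np.ndarray:
    """(n_completed_runs, 3) per-run scaffold fractions [XX, XY, YY].

    A scaffold counts as XX when all its occupied sites hold X, YY when all
    hold Y, and XY when both proteins are present; defined for completed
    runs, where every site is occupied.
    """
    mask = _completed(ensemble)
    n_scaffolds = ensemble.network.scaffold.n_scaffolds
    cols = np.zeros((3, 0), dtype=np.int64)
    idx_xx, idx_xy, idx_yy = [], [], []
    for col, n_x, n_y in ensemble.scaffold_index():
        if n_x + n_y == 0:
            continue
        if n_y == 0:
            idx_xx.append(col)
        elif n_x == 0:
            idx_yy.append(col)
        else:
            idx_xy.append(col)
    finals = ensemble.final_counts[mask]
    out = np.empty((finals.shape[0], 3))
    for k, idx in enumerate((idx_xx, idx_xy, idx_yy)):
        out[:, k] = finals[:, idx].sum(axis=1) if idx else 0.0
    return out / n_scaffolds


def x_site_matrix(ensemble: EnsembleResult) -> np.ndarray:
    """Per-completed-run total number of X-occupied docking sites."""
    mask = _completed(ensemble)
    finals = ensemble.final_counts[mask]
    x_sites = np.zeros(finals.shape[0])
    for col, n_x, _n_y in ensemble.scaffold_index():
        if n_x:
            x_sites += n_x * finals[:, col]
    return x_sites


# ---------------------------------------------------------------------------
# the metrics


def complexoform_distribution(ensemble: EnsembleResult) -> ComplexoformDistribution:
    """Ensemble-mean fractions of XX / XY / YY scaffolds over completed runs."""
    comp = composition_matrix(ensemble)
    mean = comp.mean(axis=0)
    n_inc = int((~ensemble.completed).sum())
    return ComplexoformDistribution(*map(float, mean), comp.shape[0], n_inc)


def deterministic_distribution(
    solution: DeterministicSolution,
) -> tuple[float, float, float]:
    """XX/XY/YY scaffold fractions of a deterministic terminal composition
    (occupied scaffolds only; at convergence that is all of them)."""
    frac = np.zeros(3)
    for (n_x, n_y), amount in solution.terminal_composition().items():
        if n_x + n_y == 0:
            continue
        k = 0 if n_y == 0 else (2 if n_x == 0 else 1)
        frac[k] += amount
    total = solution.network.scaffold.n_scaffolds
    return tuple(frac / total)  # type: ignore[return-value]


def stochastic_variation(ensemble: EnsembleResult, mode: str = "generic") -> VariationReport:
    """Run-to-run spread of the final assembly (sample SD, n-1)."""
    if int(ensemble.completed.sum()) < 2:
        raise ValueError("stochastic variation needs >= 2 completed runs")
    if mode == "generic":
        comp = composition_matrix(ensemble)
        value = float(comp.std(axis=0, ddof=1).sum())
    elif mode == "cellulosome":
        value = float(x_site_matrix(ensemble).std(ddof=1))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return VariationReport(value, mode)


def discrepancy(
    ensemble: EnsembleResult,
    deterministic: DeterministicSolution,
    mode: str = "generic",
) -> DiscrepancyReport:
    """Distance between the stochastic ensemble and the deterministic
    (large-ensemble) prediction; zero in the equilibrium regime."""
    if ensemble.fingerprint != deterministic.network.fingerprint():
        raise ValueError("ensemble and deterministic solution are from different networks")
    if mode == "generic":
        stoch = np.array(complexoform_distribution(ensemble).as_tuple())
        det = np.array(deterministic_distribution(deterministic))
        value = float(np.abs(stoch - det).sum())
    elif mode == "cellulosome":
        value = float(np.abs(x_site_matrix(ensemble) - deterministic.x_sites()).mean())
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return DiscrepancyReport(value, mode)


def time_to_assembly(ensemble: EnsembleResult) -> AssemblyTime:
    """Mean and SD of the time to assembly over completed runs."""
    mask = _completed(ensemble)
    t = ensemble.t_asb[mask]
    sd = float(t.std(ddof=1)) if t.size > 1 else 0.0
    return AssemblyTime(float(t.mean()), sd, int(t.size), int((~mask).sum()))


def occupancy_histogram(ensemble: EnsembleResult) -> np.ndarray:
    """Counts of completed runs by final X-occupied sites, bins 0..sites.

    Defined for single-scaffold (cellulosome-style) networks, where the
    per-run outcome is one scaffold's composition.
    """
    if ensemble.network.scaffold.n_scaffolds != 1:
        raise ValueError("occupancy histogram requires a single-scaffold network")
    sites = ensemble.network.scaffold.sites_per_scaffold
    x = x_site_matrix(ensemble).astype(int)
    return np.bincount(x, minlength=sites + 1)
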