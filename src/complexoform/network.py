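"""Mass-action reaction networks for complexoform assembly.

A network couples gene expression through one of four circuit architectures
(parallel, cascade, series uncoupled, series coupled) to export of the two
protein products X and Y and their irreversible competitive binding to
multi-site scaffold proteins.  The same :class:`ReactionNetwork` object is
consumed by both the stochastic (Gillespie) and deterministic (ODE) engines,
so the two solution routes are guaranteed to describe identical kinetics.

Scaffold occupancy is tracked as unordered compositions ``(nX, nY)`` with
``nX + nY <= sites``; the combinatoric weight of mixed assemblies (an XY
scaffold can arise two ways) comes from the vacant-site multiplicity in the
binding propensities, not from distinct ordered species.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Mapping

__all__ = [
    "CircuitKind",
    "RateSet",
    "ScaffoldSpec",
    "Species",
    "Reaction",
    "ReactionNetwork",
    "scaffold_species_name",
    "enumerate_scaffold_states",
    "build_expression_reactions",
    "build_binding_reactions",
    "assemble_network",
    "network_to_json",
    "network_from_json",
]


#: downstream-cistron completion relative to the translation rate in the
#: series coupled circuit (dimensionless; see RateSet.coupled_y_rate)
COUPLED_Y_FACTOR = 0.8


class CircuitKind(str, Enum):
    """The four genetic circuit architectures.

    parallel          — two independent promoters, concurrent expression.
    cascade           — protein X is the transcription activator of gene Y.
    series_uncoupled  — one operon, sequential transcription, independent
                        ribosome binding sites for X and Y.
    series_coupled    — one operon, sequential transcription, a single
                        ribosome binding site so translation alternates
                        X-then-Y on each transcript.
    """

    PARALLEL = "parallel"
    CASCADE = "cascade"
    SERIES_UNCOUPLED = "series_uncoupled"
    SERIES_COUPLED = "series_coupled"


@dataclass(frozen=True)
class RateSet:
    """Kinetic constants of the expression/export/binding model.

    Bimolecular constants (``k_pro``, ``k_p``, ``k_bind``) are per-molecule
    rates (count^-1 time^-1, unit volume so concentration == count); all
    others are first order (time^-1).

    ``k_m`` selects between a one-step and a two-step transcription model:
    when ``k_m`` is None the promoter--polymerase complex releases a finished
    transcript in a single first-order step at ``k_gene`` (generic model);
    when ``k_m`` is set, ``k_gene`` is the initiation step that frees the
    promoter and ``k_m`` the elongation/completion step that frees the
    polymerase and yields the mRNA (cellulosome model, which lists both).
    """

    k_pro: float  # RNAP (or activator) binding to a promoter
    k_pro_off: float  # the reverse unbinding
    k_gene: float  # transcription (one-step) or initiation (two-step)
    k_m: float | None  # transcription completion; None = one-step model
    k_mrna_loss: float  # mRNA degradation
    k_p: float  # translation, mRNA + ribosome
    k_out: float  # protein export
    k_bind: float  # external protein binding a vacant docking site
    k_bind_off: float = 0.0  # unbinding; 0 = irreversible (all experiments)
    k_out_loss: float = 0.0  # loss of external (unbound) protein
    # operon fine structure (series circuits); None picks the natural default
    k_ext: float | None = None  # partial -> full transcript extension
    #   default: transcription completion rate (k_m if set, else k_gene)
    k_elong: float | None = None  # second-cistron translation completion
    #   (series coupled; first order); default: numeric value of k_p
    k_act_off: float | None = None  # activator-promoter unbinding (cascade);
    #   default: k_pro_off
    k_y: float | None = None  # downstream (Y) cistron completion in the
    #   series coupled circuit; default COUPLED_Y_FACTOR * k_p, so the Y lag
    #   scales with translation speed

    def __post_init__(self) -> None:
        for name in (
            "k_pro", "k_pro_off", "k_gene", "k_mrna_loss",
            "k_p", "k_out", "k_bind", "k_bind_off", "k_out_loss",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"rate {name} must be >= 0")
        if self.k_m is not None and self.k_m < 0:
            raise ValueError("rate k_m must be >= 0")
        for name in ("k_ext", "k_elong", "k_act_off", "k_y"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"rate {name} must be >= 0")

    @property
    def extension_rate(self) -> float:
        """Partial -> full operon transcript extension rate."""
        if self.k_ext is not None:
            return self.k_ext
        return self.k_m if self.k_m is not None else self.k_gene

    @property
    def elongation_rate(self) -> float:
        """Completion rate of the committed second-cistron translation
        (series coupled circuit, first order)."""
        return self.k_elong if self.k_elong is not None else self.k_p

    @property
    def activation_off_rate(self) -> float:
        """Unbinding rate of the X activator from the Y promoter (cascade)."""
        return self.k_act_off if self.k_act_off is not None else self.k_pro_off

    @property
    def coupled_y_rate(self) -> float:
        """Completion rate of the downstream Y cistron in the series coupled
        circuit.  Translational coupling through the single ribosome binding
        site makes the second cistron slower than the first; by default the
        rate tracks the translation rate (COUPLED_Y_FACTOR * k_p) so the
        X-to-Y lag scales with translation speed."""
        return self.k_y if self.k_y is not None else COUPLED_Y_FACTOR * self.k_p

    def with_overrides(self, **overrides: float) -> "RateSet":
        unknown = set(overrides) - set(self.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown rate fields: {sorted(unknown)}")
        return replace(self, **overrides)


@dataclass(frozen=True)
class ScaffoldSpec:
    """Number of scaffold proteins and docking sites on each."""

    n_scaffolds: int
    sites_per_scaffold: int

    def __post_init__(self) -> None:
        if self.n_scaffolds < 1:
            raise ValueError("n_scaffolds must be >= 1")
        if self.sites_per_scaffold < 1:
            raise ValueError("sites_per_scaffold must be >= 1")

    @property
    def total_sites(self) -> int:
        return self.n_scaffolds * self.sites_per_scaffold


#: roles a species can play; scaffold_state species carry their composition
SPECIES_ROLES = (
    "promoter",
    "promoter_complex",
    "rnap",
    "ribosome",
    "mrna",
    "protein_internal",
    "protein_external",
    "scaffold_state",
)


@dataclass(frozen=True)
class Species:
    id: str
    role: str
    # for scaffold_state species: bound copies of X and Y
    n_x: int = 0
    n_y: int = 0

    def __post_init__(self) -> None:
        if self.role not in SPECIES_ROLES:
            raise ValueError(f"unknown species role {self.role!r}")


@dataclass(frozen=True)
class Reaction:
    """A uni- or bimolecular mass-action reaction.

    ``rate_constant`` already folds in any site-multiplicity factor (a state
    with v vacant sites binds protein at v * k_bind per scaffold per
    molecule), so the propensity is always k * product of reactant counts.
    """

    reactants: Mapping[str, int]
    products: Mapping[str, int]
    rate_constant: float
    label: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "reactants", dict(self.reactants))
        object.__setattr__(self, "products", dict(self.products))
        order = sum(self.reactants.values())
        if order not in (1, 2):
            raise ValueError(
                f"reaction {self.label!r} has order {order}; "
                "all processes are uni- or bimolecular"
            )
        if self.rate_constant < 0:
            raise ValueError(f"reaction {self.label!r} has negative rate")

    @property
    def order(self) -> int:
        return sum(self.reactants.values())

    def net_change(self) -> dict[str, int]:
        delta: dict[str, int] = {}
        for sid, n in self.reactants.items():
            delta[sid] = delta.get(sid, 0) - n
        for sid, n in self.products.items():
            delta[sid] = delta.get(sid, 0) + n
        return {sid: d for sid, d in delta.items() if d != 0}


@dataclass
class ReactionNetwork:
    species: list[Species]
    reactions: list[Reaction]
    initial_counts: dict[str, int]
    scaffold: ScaffoldSpec
    kind: CircuitKind | None = None
    rates: RateSet | None = None
    label: str = ""
    _index: dict[str, int] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self._index = {sp.id: i for i, sp in enumerate(self.species)}
        if len(self._index) != len(self.species):
            raise ValueError("duplicate species ids")
        referenced = set()
        for rxn in self.reactions:
            referenced |= set(rxn.reactants) | set(rxn.products)
        missing = referenced - set(self._index)
        if missing:
            raise ValueError(f"reactions reference unknown species: {sorted(missing)}")
        for sid, n in self.initial_counts.items():
            if sid not in self._index:
                raise ValueError(f"initial count for unknown species {sid!r}")
            if n < 0:
                raise ValueError(f"negative initial count for {sid!r}")
        self._check_scaffold_conservation()

    # -- structural checks -------------------------------------------------

    def _check_scaffold_conservation(self) -> None:
        """Every reaction must conserve the total number of scaffolds."""
        scaffold_ids = {sp.id for sp in self.species if sp.role == "scaffold_state"}
        for rxn in self.reactions:
            net = sum(d for sid, d in rxn.net_change().items() if sid in scaffold_ids)
            if net != 0:
                raise ValueError(
                    f"reaction {rxn.label!r} changes total scaffold count by {net}"
                )

    # -- convenience accessors --------------------------------------------

    def species_index(self, sid: str) -> int:
        return self._index[sid]

    def scaffold_species(self) -> list[Species]:
        return [sp for sp in self.species if sp.role == "scaffold_state"]

    def vacancy_weights(self) -> dict[str, int]:
        """Vacant docking sites carried by one copy of each species (0 for
        non-scaffold species)."""
        s = self.scaffold.sites_per_scaffold
        return {
            sp.id: (s - sp.n_x - sp.n_y) if sp.role == "scaffold_state" else 0
            for sp in self.species
        }

    def fingerprint(self) -> str:
        """Stable hash of structure, rates and initial condition."""
        import hashlib

        doc = network_to_json(self)
        return hashlib.sha256(doc.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# scaffold state enumeration and binding reactions


def scaffold_species_name(n_x: int, n_y: int) -> str:
    return f"S[{n_x}X{n_y}Y]"


def enumerate_scaffold_states(spec: ScaffoldSpec) -> list[Species]:
    """One species per unordered occupancy composition (nX, nY) with
    nX + nY <= sites_per_scaffold.  XY and YX are the same composition."""
    states = []
    for total in range(spec.sites_per_scaffold + 1):
        for n_x in range(total, -1, -1):
            n_y = total - n_x
            states.append(
                Species(scaffold_species_name(n_x, n_y), "scaffold_state", n_x, n_y)
            )
    return states


def build_binding_reactions(spec: ScaffoldSpec, rates: RateSet) -> list[Reaction]:
    """Binding of external X/Y to every non-full scaffold state.

    The vacant-site multiplicity v is folded into the rate constant: a state
    with v vacant sites gains protein P at propensity v * k_bind * [state] *
    [P_ext].  With k_bind_off > 0 the reverse reactions (weighted by bound
    copies) are emitted as well; the default model is irreversible.
    """
    reactions = []
    s = spec.sites_per_scaffold
    for sp in enumerate_scaffold_states(spec):
        vacant = s - sp.n_x - sp.n_y
        if vacant > 0:
            for prot, dx, dy in (("X", 1, 0), ("Y", 0, 1)):
                target = scaffold_species_name(sp.n_x + dx, sp.n_y + dy)
                reactions.append(
                    Reaction(
                        {sp.id: 1, f"{prot}_ext": 1},
                        {target: 1},
                        vacant * rates.k_bind,
                        f"bind_{prot}:{sp.id}",
                    )
                )
        if rates.k_bind_off > 0:
            for prot, n_bound, dx, dy in (
                ("X", sp.n_x, -1, 0),
                ("Y", sp.n_y, 0, -1),
            ):
                if n_bound > 0:
                    target = scaffold_species_name(sp.n_x + dx, sp.n_y + dy)
                    reactions.append(
                        Reaction(
                            {sp.id: 1},
                            {target: 1, f"{prot}_ext": 1},
                            n_bound * rates.k_bind_off,
                            f"unbind_{prot}:{sp.id}",
                        )
                    )
    return reactions


# ---------------------------------------------------------------------------
# expression circuits


def _transcription(promoter_complex: str, promoter_free: Iterable[str],
                   mrna: str, gene: str, rates: RateSet) -> list[Reaction]:
    """Transcript synthesis from an engaged promoter--RNAP complex.

    One-step model (k_m None): the complex releases promoter, RNAP and a
    finished transcript together at k_gene.  Two-step model: initiation at
    k_gene frees the promoter (RNAP stays engaged as an elongating complex),
    completion at k_m frees the RNAP and yields the transcript.
    """
    free = dict.fromkeys(promoter_free, 1)
    if rates.k_m is None:
        return [
            Reaction({promoter_complex: 1}, {**free, "RNAP": 1, mrna: 1},
                     rates.k_gene, f"tx_{gene}")
        ]
    elong = f"E_{gene}"
    return [
        Reaction({promoter_complex: 1}, {**free, elong: 1},
                 rates.k_gene, f"tx_init_{gene}"),
        Reaction({elong: 1}, {"RNAP": 1, mrna: 1}, rates.k_m, f"tx_done_{gene}"),
    ]


def _protein_fate(gene: str, rates: RateSet) -> list[Reaction]:
    return [
        Reaction({f"{gene}_int": 1}, {f"{gene}_ext": 1}, rates.k_out, f"export_{gene}"),
        Reaction({f"{gene}_ext": 1}, {}, rates.k_out_loss, f"loss_{gene}"),
    ]


def _translation(mrna: str, gene: str, rates: RateSet,
                 tag: str = "") -> list[Reaction]:
    """Two-step translation: a free ribosome initiates on the transcript
    (bimolecular, k_p) and is sequestered while elongating, releasing the
    finished protein and itself at the elongation/release rate.  With few
    ribosomes the total translation flux saturates, so whichever gene holds
    transcripts monopolizes the machinery — the origin of same-protein
    synthesis bursts."""
    rt = f"RT_{gene}{tag}"
    return [
        Reaction({mrna: 1, "Rib": 1}, {mrna: 1, rt: 1}, rates.k_p,
                 f"transl_init_{gene}{tag}"),
        Reaction({rt: 1}, {"Rib": 1, f"{gene}_int": 1},
                 rates.elongation_rate, f"transl_done_{gene}{tag}"),
    ]


def _simple_gene(gene: str, promoter: str, rates: RateSet) -> list[Reaction]:
    """Backbone for one independently transcribed gene."""
    pc = f"{promoter}.RNAP"
    mrna = f"mRNA_{gene}"
    return [
        Reaction({promoter: 1, "RNAP": 1}, {pc: 1}, rates.k_pro, f"pro_bind_{gene}"),
        Reaction({pc: 1}, {promoter: 1, "RNAP": 1}, rates.k_pro_off,
                 f"pro_unbind_{gene}"),
        *_transcription(pc, [promoter], mrna, gene, rates),
        Reaction({mrna: 1}, {}, rates.k_mrna_loss, f"mrna_loss_{gene}"),
        *_translation(mrna, gene, rates),
        *_protein_fate(gene, rates),
    ]


def _operon_transcription(rates: RateSet) -> list[Reaction]:
    """Sequential transcription and directional (5'-to-3') decay of the
    X-then-Y operon transcript.

    A nascent transcript first carries only cistron X (mRNA_X); one
    polymerase-traversal time later (extension_rate) it becomes the full
    bicistronic mRNA_XY.  Decay runs in the same direction: the 5' X
    cistron is removed first (mRNA_XY -> mRNA_Y at the mRNA loss rate) and
    the 3' Y cistron disappears one traversal time after that.  The Y
    cistron therefore exists for exactly as long as X on average -- only
    shifted later in time -- so the operon biases WHEN each protein can be
    made, not HOW MUCH."""
    pc = "P_XY.RNAP"
    return [
        Reaction({"P_XY": 1, "RNAP": 1}, {pc: 1}, rates.k_pro, "pro_bind_XY"),
        Reaction({pc: 1}, {"P_XY": 1, "RNAP": 1}, rates.k_pro_off, "pro_unbind_XY"),
        *_transcription(pc, ["P_XY"], "mRNA_X", "XY", rates),
        Reaction({"mRNA_X": 1}, {"mRNA_XY": 1}, rates.extension_rate,
                 "tx_extend_XY"),
        Reaction({"mRNA_XY": 1}, {"mRNA_Y": 1}, rates.k_mrna_loss,
                 "mrna_decay_5prime"),
        Reaction({"mRNA_Y": 1}, {}, rates.extension_rate, "mrna_decay_3prime"),
    ]


def build_expression_reactions(kind: CircuitKind, rates: RateSet) -> list[Reaction]:
    """Expression reactions (transcription, translation, export, loss) for
    proteins X and Y under the given circuit architecture."""
    kind = CircuitKind(kind)
    if kind is CircuitKind.PARALLEL:
        return _simple_gene("X", "P_X", rates) + _simple_gene("Y", "P_Y", rates)

    if kind is CircuitKind.CASCADE:
        # Y's promoter must first be activated by an internal X molecule
        # (the product of gene X is Y's transcription activator); only the
        # activated promoter can recruit RNAP.
        act = "P_Y.X"
        pc = "P_Y.X.RNAP"
        y_gene = [
            Reaction({"P_Y": 1, "X_int": 1}, {act: 1}, rates.k_pro, "act_bind_Y"),
            Reaction({act: 1}, {"P_Y": 1, "X_int": 1}, rates.activation_off_rate,
                     "act_unbind_Y"),
            Reaction({act: 1, "RNAP": 1}, {pc: 1}, rates.k_pro, "pro_bind_Y"),
            Reaction({pc: 1}, {act: 1, "RNAP": 1}, rates.k_pro_off, "pro_unbind_Y"),
            *_transcription(pc, [act], "mRNA_Y", "Y", rates),
            Reaction({"mRNA_Y": 1}, {}, rates.k_mrna_loss, "mrna_loss_Y"),
            *_translation("mRNA_Y", "Y", rates),
            *_protein_fate("Y", rates),
        ]
        return _simple_gene("X", "P_X", rates) + y_gene

    if kind is CircuitKind.SERIES_UNCOUPLED:
        # independent ribosome binding sites: X translates while its
        # cistron exists (partial + full transcript), Y while its cistron
        # exists (full + 3' remnant), concurrently and independently
        translation = [
            *_translation("mRNA_X", "X", rates),
            *_translation("mRNA_XY", "X", rates, tag="op"),
            *_translation("mRNA_XY", "Y", rates, tag="op"),
            *_translation("mRNA_Y", "Y", rates),
        ]
    elif kind is CircuitKind.SERIES_COUPLED:
        # a single ribosome binding site: each initiating ribosome finishes
        # the X cistron first, then re-initiates through the intercistronic
        # junction and traverses the downstream Y cistron at the slower
        # coupled rate before releasing Y and itself.  Every Y-translation
        # is preceded by an X-translation on the same transcript, and Y
        # lags X by the coupled traversal time (which scales with the
        # translation rate); cumulative X and Y production stay 1:1.
        # the single RBS sits at the 5' X cistron, so initiation happens on
        # the partial and the full transcript (the ribosome trails the
        # polymerase into the Y cistron) but not on the 3' remnant; every
        # initiation yields one X and, after the coupled traversal, one Y
        translation = [
            Reaction({"mRNA_X": 1, "Rib": 1}, {"mRNA_X": 1, "RT_XY1": 1},
                     rates.k_p, "transl_init_partial"),
            Reaction({"mRNA_XY": 1, "Rib": 1}, {"mRNA_XY": 1, "RT_XY1": 1},
                     rates.k_p, "transl_init_full"),
            Reaction({"RT_XY1": 1}, {"X_int": 1, "RT_XY2": 1},
                     rates.elongation_rate, "transl_XY_X"),
            Reaction({"RT_XY2": 1}, {"Y_int": 1, "Rib": 1},
                     rates.coupled_y_rate, "transl_XY_Y"),
        ]
    else:  # pragma: no cover - CircuitKind() above already raises
        raise ValueError(f"unknown circuit kind {kind!r}")

    return (_operon_transcription(rates) + translation
            + _protein_fate("X", rates) + _protein_fate("Y", rates))


# ---------------------------------------------------------------------------
# full network assembly


def _species_from_reactions(reactions: Iterable[Reaction],
                            scaffold_states: list[Species]) -> list[Species]:
    scaffold_ids = {sp.id for sp in scaffold_states}
    seen: dict[str, Species] = {}

    def role_of(sid: str) -> str:
        if sid == "RNAP":
            return "rnap"
        if sid == "Rib" or sid.startswith("RT_") or sid.startswith("TC_"):
            return "ribosome"  # free or translating (sequestered) ribosome
        if sid.startswith("mRNA") or sid.startswith("E_"):
            return "mrna"
        if sid.endswith("_int"):
            return "protein_internal"
        if sid.endswith("_ext"):
            return "protein_external"
        if ".RNAP" in sid or ".X" in sid:
            return "promoter_complex"
        if sid.startswith("P_"):
            return "promoter"
        raise ValueError(f"cannot infer role of species {sid!r}")

    for rxn in reactions:
        for sid in list(rxn.reactants) + list(rxn.products):
            if sid not in scaffold_ids and sid not in seen:
                seen[sid] = Species(sid, role_of(sid))
    # stable, readable order: expression species first, then scaffold states
    return list(seen.values()) + scaffold_states


def assemble_network(
    kind: CircuitKind,
    rates: RateSet,
    spec: ScaffoldSpec,
    pools: Mapping[str, int],
    label: str = "",
) -> ReactionNetwork:
    """Build the complete network: expression + binding, all scaffolds empty,
    no mRNA or protein, molecule pools (promoters, RNAP, ribosomes) as given.

    ``pools`` maps species ids (e.g. ``RNAP``, ``Rib``, ``P_X``) to initial
    counts; promoter entries irrelevant to the circuit are rejected.
    """
    kind = CircuitKind(kind)
    reactions = build_expression_reactions(kind, rates) + \
        build_binding_reactions(spec, rates)
    scaffold_states = enumerate_scaffold_states(spec)
    species = _species_from_reactions(reactions, scaffold_states)
    ids = {sp.id for sp in species}

    initial = {sp.id: 0 for sp in species}
    for sid, n in pools.items():
        if sid not in ids:
            raise ValueError(f"pool species {sid!r} not part of a {kind.value} network")
        if n < 0:
            raise ValueError(f"negative initial count for {sid!r}")
        initial[sid] = int(n)
    initial[scaffold_species_name(0, 0)] = spec.n_scaffolds

    return ReactionNetwork(species, reactions, initial, spec, kind, rates,
                           label=label or kind.value)


def default_pools(kind: CircuitKind, n_rnap: int, n_rib: int) -> dict[str, int]:
    """One promoter per transcription unit plus the RNAP/ribosome pools."""
    kind = CircuitKind(kind)
    if kind in (CircuitKind.PARALLEL, CircuitKind.CASCADE):
        promoters = {"P_X": 1, "P_Y": 1}
    else:
        promoters = {"P_XY": 1}
    return {**promoters, "RNAP": n_rnap, "Rib": n_rib}


# ---------------------------------------------------------------------------
# serialization


def network_to_json(network: ReactionNetwork) -> str:
    doc = {
        "label": network.label,
        "kind": network.kind.value if network.kind else None,
        "scaffold": {
            "n_scaffolds": network.scaffold.n_scaffolds,
            "sites_per_scaffold": network.scaffold.sites_per_scaffold,
        },
        "species": [
            {"id": sp.id, "role": sp.role, "n_x": sp.n_x, "n_y": sp.n_y}
            for sp in network.species
        ],
        "reactions": [
            {
                "reactants": dict(rxn.reactants),
                "products": dict(rxn.products),
                "k": rxn.rate_constant,
                "label": rxn.label,
            }
            for rxn in network.reactions
        ],
        "initial": dict(network.initial_counts),
    }
    return json.dumps(doc, indent=2, sort_keys=True)


def network_from_json(doc: str) -> ReactionNetwork:
    data = json.loads(doc)
    species = [
        Species(sp["id"], sp["role"], sp.get("n_x", 0), sp.get("n_y", 0))
        for sp in data["species"]
    ]
    reactions = [
        Reaction(r["reactants"], r["products"], r["k"], r["label"])
        for r in data["reactions"]
    ]
    scaffold = ScaffoldSpec(**data["scaffold"])
    kind = CircuitKind(data["kind"]) if data.get("kind") else None
    return ReactionNetwork(species, reactions, data["initial"], scaffold, kind,
                           label=data.get("label", ""))
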