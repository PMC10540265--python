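"""Species/reaction data model for DNA-gated bioreactor circuits.

A circuit is a closed chemical reaction network over named species. Each
non-enzyme species carries a multiset of the oligonucleotide strand labels
it contains, which fixes the conservation structure: every strand total
(and every enzyme) is invariant along any trajectory. Rate laws are
mass-action, bilinear enzymatic (rate = k*[E]*[S]) or Michaelis-Menten
(rate = k*[E]*[S]/(Km+[S])).

Units are fixed package-wide: concentrations in uM, time in hours;
bimolecular constants in uM^-1 h^-1, unimolecular in h^-1, Km in uM.
"""

from __future__ import annotations

from collections.abc import Callable, Iterable, Mapping
from dataclasses import dataclass, field

import numpy as np
import yaml

from .errors import ConfigurationError, ValidationError

ROLES = frozenset(
    {
        "nmof_tether",
        "gquadruplex",
        "fuel",
        "blocker_duplex",
        "displaced_duplex",
        "free_strand",
        "intermediate",
        "complex",
        "enzyme",
        "waste",
    }
)

RATE_LAWS = frozenset({"mass_action", "enzymatic_linear", "enzymatic_mm"})


@dataclass(frozen=True)
class Species:
    """A named chemical species.

    ``strands`` maps a strand label (e.g. ``"3"``) to its copy number in the
    species. Enzymes carry no strands; waste retains the composition of
    whatever it was cut from.
    """

    species_id: str
    role: str
    strands: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self):
        if self.role not in ROLES:
            raise ValidationError(f"unknown role {self.role!r} for species {self.species_id!r}")
        if any(c <= 0 for c in self.strands.values()):
            raise ValidationError(f"strand counts must be positive in {self.species_id!r}")
        if self.role not in ("enzyme", "waste") and not self.strands:
            raise ValidationError(
                f"non-enzyme, non-waste species {self.species_id!r} needs a strand composition"
            )
        object.__setattr__(self, "strands", dict(self.strands))


@dataclass
class SpeciesCatalog:
    """Ordered collection of the species of one circuit."""

    entries: list[Species]

    def __post_init__(self):
        ids = [s.species_id for s in self.entries]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate species_id in catalog")
        self._index = {sid: i for i, sid in enumerate(ids)}

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, species_id: str) -> bool:
        return species_id in self._index

    def __getitem__(self, species_id: str) -> Species:
        return self.entries[self._index[species_id]]

    @property
    def species_ids(self) -> list[str]:
        return [s.species_id for s in self.entries]

    def index(self, species_id: str) -> int:
        return self._index[species_id]

    def strand_labels(self) -> list[str]:
        labels: set[str] = set()
        for s in self.entries:
            labels.update(s.strands)
        return sorted(labels)


@dataclass
class Reaction:
    """One reaction: multiset reactants -> multiset products with a rate law.

    For enzymatic laws the catalyst must appear with identical count on both
    sides; its concentration enters the flux but its net stoichiometry is zero.
    """

    reactants: Mapping[str, int]
    products: Mapping[str, int]
    rate_law: str
    rate_constant_id: str
    catalyst: str | None = None
    km_id: str | None = None
    label: str = ""

    def __post_init__(self):
        if self.rate_law not in RATE_LAWS:
            raise ConfigurationError(f"unknown rate law {self.rate_law!r}")
        if self.rate_law.startswith("enzymatic") and self.catalyst is None:
            raise ConfigurationError(f"rate law {self.rate_law} requires a catalyst")
        if self.rate_law == "enzymatic_mm" and self.km_id is None:
            raise ConfigurationError("enzymatic_mm requires a km_id")
        self.reactants = dict(self.reactants)
        self.products = dict(self.products)
        if self.catalyst is not None:
            if self.reactants.get(self.catalyst, 0) != self.products.get(self.catalyst, 0) or (
                self.catalyst not in self.reactants
            ):
                raise ValidationError(
                    f"catalyst {self.catalyst!r} must appear unchanged on both sides"
                )

    def substrates(self) -> dict[str, int]:
        """Reactants excluding the catalyst copy (the species the flux acts on)."""
        subs = dict(self.reactants)
        if self.catalyst is not None:
            subs.pop(self.catalyst)
        return subs

    def stoichiometry(self, catalog: SpeciesCatalog) -> np.ndarray:
        """Net change vector over the catalog (integer valued)."""
        change = np.zeros(len(catalog))
        for sid, n in self.reactants.items():
            change[catalog.index(sid)] -= n
        for sid, n in self.products.items():
            change[catalog.index(sid)] += n
        return change

    def check_strand_balance(self, catalog: SpeciesCatalog) -> None:
        """Per-strand-label atom balance, exact in integer arithmetic."""
        for label in catalog.strand_labels():
            lhs = sum(n * catalog[sid].strands.get(label, 0) for sid, n in self.reactants.items())
            rhs = sum(n * catalog[sid].strands.get(label, 0) for sid, n in self.products.items())
            if lhs != rhs:
                raise ValidationError(
                    f"reaction {self.label or self.rate_constant_id}: strand {label} "
                    f"unbalanced ({lhs} -> {rhs})"
                )


@dataclass
class RateConstantSet:
    """Positive rate constants keyed by id; Km values live in the same map.

    ``source`` records where the values came from: ``"builtin"`` for the
    package's documented defaults, ``"config"`` for user-supplied fitted
    values, ``"fit"`` for estimates produced by the inference module.
    """

    values: dict[str, float]
    source: str = "user"

    def __post_init__(self):
        for k, v in self.values.items():
            v = float(v)
            if not np.isfinite(v) or v <= 0:
                raise ValidationError(f"rate constant {k!r} must be positive and finite, got {v}")
            self.values[k] = v

    def __getitem__(self, key: str) -> float:
        return self.values[key]

    def replace(self, **updates: float) -> "RateConstantSet":
        vals = dict(self.values)
        vals.update(updates)
        return RateConstantSet(vals, source=self.source)

    def relative_errors(self, other: "RateConstantSet") -> dict[str, float]:
        """|self - other| / other per shared id."""
        return {
            k: abs(self.values[k] - other.values[k]) / other.values[k]
            for k in self.values
            if k in other.values
        }


@dataclass
class ReactionNetwork:
    """A closed reaction network with its derived conservation relations.

    ``conserved_quantities`` is a list of (label, coefficient vector) pairs;
    one per strand label (coefficients = strand copy number per species) and
    one per enzyme. Orthogonality to every reaction's stoichiometry vector is
    verified at construction.
    """

    name: str
    catalog: SpeciesCatalog
    reactions: list[Reaction]
    conserved_quantities: list[tuple[str, np.ndarray]] = field(default_factory=list)

    def __post_init__(self):
        for rxn in self.reactions:
            for sid in list(rxn.reactants) + list(rxn.products):
                if sid not in self.catalog:
                    raise ValidationError(f"reaction references unknown species {sid!r}")
            rxn.check_strand_balance(self.catalog)
        if not self.conserved_quantities:
            self.conserved_quantities = derive_conserved_quantities(self.catalog)
        for label, vec in self.conserved_quantities:
            for rxn in self.reactions:
                resid = float(np.dot(vec, rxn.stoichiometry(self.catalog)))
                if resid != 0.0:
                    raise ValidationError(
                        f"conserved quantity {label!r} broken by reaction "
                        f"{rxn.label or rxn.rate_constant_id} (residual {resid})"
                    )

    @property
    def species_ids(self) -> list[str]:
        return self.catalog.species_ids

    def rate_constant_ids(self) -> list[str]:
        ids: list[str] = []
        for rxn in self.reactions:
            ids.append(rxn.rate_constant_id)
            if rxn.km_id is not None:
                ids.append(rxn.km_id)
        return sorted(set(ids))

    def species_with_role(self, role: str) -> list[str]:
        return [s.species_id for s in self.catalog.entries if s.role == role]

    def stoichiometric_matrix(self) -> np.ndarray:
        """n_species x n_reactions matrix of net stoichiometric changes."""
        return np.column_stack([r.stoichiometry(self.catalog) for r in self.reactions])

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "species": [
                {"id": s.species_id, "role": s.role, "strands": dict(s.strands)}
                for s in self.catalog.entries
            ],
            "reactions": [
                {
                    "label": r.label,
                    "reactants": dict(r.reactants),
                    "products": dict(r.products),
                    "rate_law": r.rate_law,
                    "rate_constant_id": r.rate_constant_id,
                    "catalyst": r.catalyst,
                    "km_id": r.km_id,
                }
                for r in self.reactions
            ],
        }

    @classmethod
    def from_dict(cls, data: dict) -> "ReactionNetwork":
        catalog = SpeciesCatalog(
            [Species(s["id"], s["role"], s.get("strands") or {}) for s in data["species"]]
        )
        reactions = [
            Reaction(
                reactants=r["reactants"],
                products=r["products"],
                rate_law=r["rate_law"],
                rate_constant_id=r["rate_constant_id"],
                catalyst=r.get("catalyst"),
                km_id=r.get("km_id"),
                label=r.get("label", ""),
            )
            for r in data["reactions"]
        ]
        return cls(name=data.get("name", "circuit"), catalog=catalog, reactions=reactions)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "ReactionNetwork":
        return cls.from_dict(yaml.safe_load(text))


def derive_conserved_quantities(catalog: SpeciesCatalog) -> list[tuple[str, np.ndarray]]:
    """Strand totals plus one total per enzyme species."""
    out: list[tuple[str, np.ndarray]] = []
    for label in catalog.strand_labels():
        vec = np.array([float(s.strands.get(label, 0)) for s in catalog.entries])
        out.append((f"strand_{label}", vec))
    for s in catalog.entries:
        if s.role == "enzyme":
            vec = np.zeros(len(catalog))
            vec[catalog.index(s.species_id)] = 1.0
            out.append((f"enzyme_{s.species_id}", vec))
    return out


def conserved_totals(network: ReactionNetwork, state: Iterable[float]) -> dict[str, float]:
    """Value of every conserved quantity at ``state`` (uM)."""
    y = np.asarray(list(state) if not isinstance(state, np.ndarray) else state, dtype=float)
    if y.shape != (len(network.catalog),):
        raise ValidationError(
            f"state dimension {y.shape} does not match catalog size {len(network.catalog)}"
        )
    return {label: float(np.dot(vec, y)) for label, vec in network.conserved_quantities}


def compile_rhs(
    network: ReactionNetwork,
    constants: RateConstantSet,
    *,
    negative_tolerance: float = 1e-6,
) -> Callable[[float, np.ndarray], np.ndarray]:
    """Compile the network into a derivative function ``f(t, y) -> dy/dt``.

    State is the concentration vector (uM) in catalog order; the return is in
    uM/h. Fluxes: mass_action ``k * prod [reactant]^multiplicity``;
    enzymatic_linear ``k*[E]*[S]``; enzymatic_mm ``k*[E]*[S]/(Km+[S])``.
    Concentrations more negative than ``negative_tolerance`` raise; smaller
    excursions (solver round-off) are clamped to zero inside flux evaluation.
    """
    missing = [k for k in network.rate_constant_ids() if k not in constants.values]
    if missing:
        raise ConfigurationError(f"missing rate constants: {missing}")

    n = len(network.catalog)
    stoich = network.stoichiometric_matrix()  # n x m
    plans = []
    for rxn in network.reactions:
        subs = rxn.substrates()
        sub_idx = np.array([network.catalog.index(s) for s in subs for _ in range(subs[s])])
        k = constants[rxn.rate_constant_id]
        cat_idx = network.catalog.index(rxn.catalyst) if rxn.catalyst is not None else -1
        km = constants[rxn.km_id] if rxn.km_id is not None else 0.0
        if rxn.rate_law == "enzymatic_mm" and len(sub_idx) != 1:
            raise ConfigurationError("enzymatic_mm requires exactly one substrate")
        plans.append((rxn.rate_law, k, sub_idx, cat_idx, km))

    def rhs(t: float, y: np.ndarray) -> np.ndarray:
        y = np.asarray(y, dtype=float)
        if y.shape != (n,):
            raise ValidationError(f"state dimension {y.shape}, expected ({n},)")
        if y.min() < -negative_tolerance:
            raise ValidationError(f"negative concentration in state (min {y.min():.3e} uM)")
        yc = np.maximum(y, 0.0)
        flux = np.empty(len(plans))
        for j, (law, k, sub_idx, cat_idx, km) in enumerate(plans):
            if law == "mass_action":
                flux[j] = k * np.prod(yc[sub_idx])
            elif law == "enzymatic_linear":
                flux[j] = k * yc[cat_idx] * np.prod(yc[sub_idx])
            else:  # enzymatic_mm
                s = yc[sub_idx[0]]
                flux[j] = k * yc[cat_idx] * s / (km + s)
        return stoich @ flux

    return rhs
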