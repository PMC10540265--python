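"""Builders for the two fuel-driven dissipative bioreactor circuits.

Both circuits share a motif: a fuel strand transiently drives formation of a
catalytically active supramolecular complex (NMOF tether + hemin-G-quadruplex
bridged by a linker strand), while an enzyme consumes the fuel and thereby
returns the system to its resting state.

Nickase circuit
    The fuel (strand 5) displaces the blocker duplex T/L (strands 3/4),
    releasing the linker T (3), which assembles the active complex with the
    NMOF tether G (1) and the G-quadruplex B (2). The nicking endonuclease
    cleaves the fuel inside the L/fuel duplex (4/5); the liberated L (4)
    then strips T out of the complex, regenerating the resting module.

Exonuclease III circuit
    The fuel T2 (strand 8) directly bridges the NMOF tether G (6) and the
    G-quadruplex B (7) into the active complex. Exo III digests the fuel
    only inside the assembled complex (its recessed 3' end), releasing both
    constituents and producing waste fragments.

Species ids are single letters shared across both circuits (G, B, C, F, ...)
so downstream code can address "the complex" or "the fuel" uniformly.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import ConfigurationError
from .network import Reaction, ReactionNetwork, Species, SpeciesCatalog

COMPLEX_ID = "C"
FUEL_ID = "F"


@dataclass(frozen=True)
class CircuitOptions:
    """Model-variant flags shared by both circuit builders.

    assembly
        "sequential": the linker first binds the NMOF tether, then the
        G-quadruplex docks (two bimolecular steps). "lumped": a single
        effective step consuming all three constituents at once.
    enzyme_law
        "linear" for the bilinear flux k*[E]*[S] (substrate far below Km),
        or "mm" for the Michaelis-Menten form (requires km).
    digest_intermediate
        Exo III only: also digest fuel inside the partially assembled
        tether-fuel intermediate. Off by default; the assembled complex is
        engineered to be the only substrate.
    """

    assembly: str = "sequential"
    enzyme_law: str = "linear"
    km: float | None = None
    digest_intermediate: bool = False

    def __post_init__(self):
        if self.assembly not in ("sequential", "lumped"):
            raise ConfigurationError(f"unknown assembly option {self.assembly!r}")
        if self.enzyme_law not in ("linear", "mm"):
            raise ConfigurationError(f"unknown enzyme_law option {self.enzyme_law!r}")
        if self.enzyme_law == "mm" and self.km is None:
            raise ConfigurationError("enzyme_law 'mm' requires a km value")

    @property
    def enzymatic_rate_law(self) -> str:
        return "enzymatic_linear" if self.enzyme_law == "linear" else "enzymatic_mm"


def _enzyme_kwargs(options: CircuitOptions, km_id: str) -> dict:
    if options.enzyme_law == "mm":
        return {"rate_law": "enzymatic_mm", "km_id": km_id}
    return {"rate_law": "enzymatic_linear"}


def make_nickase_circuit(options: CircuitOptions | None = None) -> ReactionNetwork:
    """Nickase-gated circuit over strands 1-5.

    Reactions (sequential assembly default):
        R1   TL + F -> LF + T          fuel displaces the blocker duplex
        R2a  G + T -> GT               linker binds the NMOF tether
        R2b  GT + B -> C               G-quadruplex docks, active complex
        R3   LF --N--> L + W           nickase cleaves fuel, frees L
        R4   C + L -> G + B + TL       L strips the linker, resting state

    Rate constant ids: k_displace, k_bind_tether, k_bind_quadruplex (or
    k_assemble when lumped), k_nick (+ km_nick for the MM variant),
    k_disassemble.
    """
    options = options or CircuitOptions()
    species = [
        Species("G", "nmof_tether", {"1": 1}),
        Species("B", "gquadruplex", {"2": 1}),
        Species("TL", "blocker_duplex", {"3": 1, "4": 1}),
        Species("F", "fuel", {"5": 1}),
        Species("T", "free_strand", {"3": 1}),
        Species("LF", "displaced_duplex", {"4": 1, "5": 1}),
        Species("L", "free_strand", {"4": 1}),
        Species("C", "complex", {"1": 1, "2": 1, "3": 1}),
        Species("N", "enzyme"),
        Species("W", "waste", {"5": 1}),
    ]
    if options.assembly == "sequential":
        species.insert(7, Species("GT", "intermediate", {"1": 1, "3": 1}))

    reactions = [
        Reaction({"TL": 1, "F": 1}, {"LF": 1, "T": 1}, "mass_action", "k_displace", label="R1"),
    ]
    if options.assembly == "sequential":
        reactions += [
            Reaction({"G": 1, "T": 1}, {"GT": 1}, "mass_action", "k_bind_tether", label="R2a"),
            Reaction({"GT": 1, "B": 1}, {"C": 1}, "mass_action", "k_bind_quadruplex", label="R2b"),
        ]
    else:
        reactions.append(
            Reaction({"G": 1, "B": 1, "T": 1}, {"C": 1}, "mass_action", "k_assemble", label="R2")
        )
    reactions += [
        Reaction(
            {"LF": 1, "N": 1},
            {"L": 1, "W": 1, "N": 1},
            rate_constant_id="k_nick",
            catalyst="N",
            label="R3",
            **_enzyme_kwargs(options, "km_nick"),
        ),
        Reaction(
            {"C": 1, "L": 1},
            {"G": 1, "B": 1, "TL": 1},
            "mass_action",
            "k_disassemble",
            label="R4",
        ),
    ]
    return ReactionNetwork("nickase", SpeciesCatalog(species), reactions)


def make_exoiii_circuit(options: CircuitOptions | None = None) -> ReactionNetwork:
    """Exonuclease-III-gated circuit over strands 6-8.

    Reactions (sequential assembly default):
        R1a  G + F -> GT               fuel binds the NMOF tether
        R1b  GT + B -> C               G-quadruplex docks, active complex
        R2   C --E--> G + B + W        Exo III digests the fuel in the complex

    With ``digest_intermediate`` an additional pathway GT --E--> G + W is
    enabled. The G-quadruplex itself is never an Exo III substrate.
    Rate constant ids: k_bind_tether, k_bind_quadruplex (or k_assemble),
    k_digest (+ km_digest), k_digest_intermediate when enabled.
    """
    options = options or CircuitOptions()
    species = [
        Species("G", "nmof_tether", {"6": 1}),
        Species("B", "gquadruplex", {"7": 1}),
        Species("F", "fuel", {"8": 1}),
        Species("C", "complex", {"6": 1, "7": 1, "8": 1}),
        Species("E", "enzyme"),
        Species("W", "waste", {"8": 1}),
    ]
    if options.digest_intermediate and options.assembly != "sequential":
        raise ConfigurationError("digest_intermediate requires sequential assembly")
    if options.assembly == "sequential":
        species.insert(3, Species("GT", "intermediate", {"6": 1, "8": 1}))

    reactions: list[Reaction] = []
    if options.assembly == "sequential":
        reactions += [
            Reaction({"G": 1, "F": 1}, {"GT": 1}, "mass_action", "k_bind_tether", label="R1a"),
            Reaction({"GT": 1, "B": 1}, {"C": 1}, "mass_action", "k_bind_quadruplex", label="R1b"),
        ]
    else:
        reactions.append(
            Reaction({"G": 1, "B": 1, "F": 1}, {"C": 1}, "mass_action", "k_assemble", label="R1")
        )
    reactions.append(
        Reaction(
            {"C": 1, "E": 1},
            {"G": 1, "B": 1, "W": 1, "E": 1},
            rate_constant_id="k_digest",
            catalyst="E",
            label="R2",
            **_enzyme_kwargs(options, "km_digest"),
        )
    )
    if options.digest_intermediate:
        reactions.append(
            Reaction(
                {"GT": 1, "E": 1},
                {"G": 1, "W": 1, "E": 1},
                rate_constant_id="k_digest_intermediate",
                catalyst="E",
                label="R3",
                **_enzyme_kwargs(options, "km_digest"),
            )
        )
    return ReactionNetwork("exoiii", SpeciesCatalog(species), reactions)


def make_circuit(circuit: str, options: CircuitOptions | None = None) -> ReactionNetwork:
    """Dispatch on circuit tag: "nickase" or "exoiii"."""
    builders = {"nickase": make_nickase_circuit, "exoiii": make_exoiii_circuit}
    try:
        return builders[circuit](options)
    except KeyError:
        raise ConfigurationError(f"unknown circuit {circuit!r}; expected one of {sorted(builders)}")
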