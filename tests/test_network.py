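"""Reaction-network construction, conservation structure and the compiled RHS."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fuelcircuits import (
    CircuitOptions,
    ConfigurationError,
    RateConstantSet,
    Reaction,
    ReactionNetwork,
    Species,
    SpeciesCatalog,
    ValidationError,
    compile_rhs,
    conserved_totals,
    make_circuit,
    make_exoiii_circuit,
    make_nickase_circuit,
)

ALL_BUILDS = [
    ("nickase", CircuitOptions()),
    ("nickase", CircuitOptions(assembly="lumped")),
    ("nickase", CircuitOptions(enzyme_law="mm", km=1.0)),
    ("exoiii", CircuitOptions()),
    ("exoiii", CircuitOptions(assembly="lumped")),
    ("exoiii", CircuitOptions(digest_intermediate=True)),
]


@pytest.mark.parametrize("circuit,options", ALL_BUILDS)
def test_every_reaction_conserves_strands_and_quantities(circuit, options):
    """Per-strand atom balance and conservation-vector orthogonality are exact."""
    net = make_circuit(circuit, options)
    for rxn in net.reactions:
        rxn.check_strand_balance(net.catalog)  # raises on violation
    stoich = net.stoichiometric_matrix()
    for label, vec in net.conserved_quantities:
        residual = vec @ stoich
        assert np.all(residual == 0.0), f"{label} not conserved"


def test_nickase_default_structure(nickase):
    assert [r.label for r in nickase.reactions] == ["R1", "R2a", "R2b", "R3", "R4"]
    labels = {label for label, _ in nickase.conserved_quantities}
    assert labels == {"strand_1", "strand_2", "strand_3", "strand_4", "strand_5", "enzyme_N"}
    assert nickase.catalog["C"].strands == {"1": 1, "2": 1, "3": 1}


def test_nickase_lumped_replaces_assembly_steps(nickase, nickase_lumped):
    assert [r.label for r in nickase_lumped.reactions] == ["R1", "R2", "R3", "R4"]
    # conserved totals unchanged relative to the sequential variant
    assert {l for l, _ in nickase_lumped.conserved_quantities} == {
        l for l, _ in nickase.conserved_quantities
    }


def test_exoiii_complex_is_only_enzyme_substrate(exoiii):
    """Digestion acts only on species containing the fuel strand; never the G-quadruplex."""
    for rxn in exoiii.reactions:
        if rxn.rate_law.startswith("enzymatic"):
            for sid in rxn.substrates():
                assert "8" in exoiii.catalog[sid].strands
                assert exoiii.catalog[sid].role != "gquadruplex"
    assert exoiii.catalog["C"].strands == {"6": 1, "7": 1, "8": 1}


def test_exoiii_strand8_total_spans_fuel_intermediates_complex_waste(exoiii):
    vec = dict(zip(exoiii.species_ids, dict(exoiii.conserved_quantities)["strand_8"]))
    assert {s for s, c in vec.items() if c} == {"F", "GT", "C", "W"}


def test_invalid_option_combinations_raise():
    with pytest.raises(ConfigurationError):
        CircuitOptions(enzyme_law="mm")  # mm without km
    with pytest.raises(ConfigurationError):
        CircuitOptions(assembly="both")
    with pytest.raises(ConfigurationError):
        make_exoiii_circuit(CircuitOptions(assembly="lumped", digest_intermediate=True))
    with pytest.raises(ConfigurationError):
        make_circuit("ligase")


def test_catalyst_must_appear_unchanged():
    with pytest.raises(ValidationError):
        Reaction({"S": 1}, {"P": 1}, "enzymatic_linear", "k", catalyst="E")


def test_network_rejects_unknown_species_and_duplicate_ids():
    catalog = SpeciesCatalog([Species("A", "free_strand", {"1": 1})])
    rxn = Reaction({"A": 1, "X": 1}, {"A": 1, "X": 1}, "mass_action", "k")
    with pytest.raises(ValidationError):
        ReactionNetwork("bad", catalog, [rxn])
    with pytest.raises(ValidationError):
        SpeciesCatalog([Species("A", "free_strand", {"1": 1}), Species("A", "enzyme")])


def test_serialization_round_trip_is_lossless(nickase, exoiii):
    for net in (nickase, exoiii):
        clone = ReactionNetwork.from_yaml(net.to_yaml())
        assert clone.to_dict() == net.to_dict()
        assert np.array_equal(clone.stoichiometric_matrix(), net.stoichiometric_matrix())


# -- compiled RHS ------------------------------------------------------------

def _toy_network():
    species = [
        Species("A", "free_strand", {"1": 1}),
        Species("B", "free_strand", {"2": 1}),
        Species("AB", "displaced_duplex", {"1": 1, "2": 1}),
        Species("E", "enzyme"),
    ]
    rxn = Reaction({"A": 1, "B": 1}, {"AB": 1}, "mass_action", "k")
    return ReactionNetwork("toy", SpeciesCatalog(species), [rxn])


def test_rhs_bimolecular_example():
    """A + B -> C at k=1: state (1,2,0) uM gives derivatives (-2,-2,+2) uM/h."""
    net = _toy_network()
    rhs = compile_rhs(net, RateConstantSet({"k": 1.0}))
    dy = rhs(0.0, np.array([1.0, 2.0, 0.0, 0.0]))
    np.testing.assert_allclose(dy, [-2.0, -2.0, 2.0, 0.0])


def test_rhs_enzymatic_catalyst_is_unchanged(nickase, nickase_constants):
    rhs = compile_rhs(nickase, nickase_constants)
    rng = np.random.default_rng(0)
    for _ in range(5):
        y = rng.uniform(0, 2, size=len(nickase.catalog))
        dy = rhs(0.0, y)
        assert dy[nickase.catalog.index("N")] == 0.0


def test_rhs_michaelis_menten_limits():
    """[S] >> Km saturates at k*[E]; [S] << Km reduces to (k/Km)*[E]*[S]."""
    species = [Species("S", "free_strand", {"1": 1}), Species("P", "waste", {"1": 1}),
               Species("E", "enzyme")]
    rxn = Reaction({"S": 1, "E": 1}, {"P": 1, "E": 1}, "enzymatic_mm", "k",
                   catalyst="E", km_id="km")
    net = ReactionNetwork("mm", SpeciesCatalog(species), [rxn])
    k, km, e = 2.0, 0.5, 0.3
    rhs = compile_rhs(net, RateConstantSet({"k": k, "km": km}))
    flux_sat = -rhs(0.0, np.array([5000.0, 0.0, e]))[0]
    assert flux_sat == pytest.approx(k * e, rel=1e-3)
    s_small = 1e-6
    flux_lin = -rhs(0.0, np.array([s_small, 0.0, e]))[0]
    assert flux_lin == pytest.approx(k / km * e * s_small, rel=1e-3)


def test_rhs_errors():
    net = _toy_network()
    with pytest.raises(ConfigurationError):
        compile_rhs(net, RateConstantSet({"other": 1.0}))
    rhs = compile_rhs(net, RateConstantSet({"k": 1.0}))
    with pytest.raises(ValidationError):
        rhs(0.0, np.array([-1.0, 1.0, 0.0, 0.0]))
    with pytest.raises(ValidationError):
        rhs(0.0, np.array([1.0, 1.0]))


@settings(deadline=None, derandomize=True, max_examples=25)
@given(
    st.integers(min_value=0, max_value=2**32 - 1),
    st.sampled_from(["nickase", "exoiii"]),
)
def test_rhs_matches_bruteforce_flux_oracle(state_seed, circuit):
    """The compiled RHS equals an independent per-reaction flux summation."""
    net = make_circuit(circuit)
    ids = net.rate_constant_ids()
    rng = np.random.default_rng(state_seed)
    constants = RateConstantSet(dict(zip(ids, rng.uniform(0.1, 10.0, len(ids)))))
    y = rng.uniform(0.0, 3.0, size=len(net.catalog))

    expected = np.zeros_like(y)
    for rxn in net.reactions:
        subs = rxn.substrates()
        if rxn.rate_law == "mass_action":
            flux = constants[rxn.rate_constant_id]
            for sid, n in subs.items():
                flux *= y[net.catalog.index(sid)] ** n
        elif rxn.rate_law == "enzymatic_linear":
            flux = constants[rxn.rate_constant_id] * y[net.catalog.index(rxn.catalyst)]
            for sid, n in subs.items():
                flux *= y[net.catalog.index(sid)] ** n
        else:
            (sid,) = subs
            s = y[net.catalog.index(sid)]
            flux = (
                constants[rxn.rate_constant_id]
                * y[net.catalog.index(rxn.catalyst)]
                * s / (constants[rxn.km_id] + s)
            )
        for sid, n in rxn.reactants.items():
            expected[net.catalog.index(sid)] -= n * flux
        for sid, n in rxn.products.items():
            expected[net.catalog.index(sid)] += n * flux

    actual = compile_rhs(net, constants)(0.0, y)
    np.testing.assert_allclose(actual, expected, rtol=1e-12, atol=1e-14)


# -- conserved totals --------------------------------------------------------

def test_conserved_totals_at_base_condition(nickase, nickase_conditions):
    """Strand-3 total equals the 2 uM loaded as the T/L blocker duplex."""
    state = nickase_conditions["base"].state_vector(nickase)
    totals = conserved_totals(nickase, state)
    assert totals["strand_3"] == pytest.approx(2.0)
    assert totals["strand_5"] == pytest.approx(3.0)
    assert totals["enzyme_N"] == pytest.approx(0.046)
    assert conserved_totals(nickase, np.zeros(len(nickase.catalog))) == {
        label: 0.0 for label, _ in nickase.conserved_quantities
    }


@settings(deadline=None, derandomize=True, max_examples=20)
@given(st.integers(min_value=0, max_value=2**32 - 1))
def test_totals_invariant_under_reaction_application(seed):
    """Applying any reaction's stoichiometric change leaves every total unchanged."""
    net = make_nickase_circuit()
    rng = np.random.default_rng(seed)
    y = rng.uniform(0.0, 2.0, size=len(net.catalog))
    before = conserved_totals(net, y)
    for rxn in net.reactions:
        after = conserved_totals(net, y + 0.1 * rxn.stoichiometry(net.catalog))
        for label in before:
            assert after[label] == pytest.approx(before[label], abs=1e-12)


def test_conserved_totals_dimension_mismatch(nickase):
    with pytest.raises(ValidationError):
        conserved_totals(nickase, np.zeros(3))
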