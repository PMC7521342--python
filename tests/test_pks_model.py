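"""The assembly-line chemistry: elementary domain steps, the DH geometry
rule, forward simulation of the affinin architecture, naming, SMILES and
retrobiosynthetic search."""

import itertools

import pytest
from hypothesis import given, settings, strategies as st

from alkapks.pks_model import (
    AcylChain,
    AssemblySpec,
    ChainParseError,
    DoubleBond,
    IncompleteTailoringError,
    InfeasibleTargetError,
    InvalidExtenderError,
    InvalidStateError,
    ModuleSpec,
    UnsupportedModuleError,
    canonical_smiles,
    chain_smiles,
    condense,
    dehydrate,
    enoyl_reduce,
    infer_architecture,
    name_chain,
    offload,
    parse_chain,
    reduce_keto,
    run_module,
    simulate_assembly,
)


def chain(descriptor, beta="saturated"):
    c = parse_chain(descriptor)
    return AcylChain(c.n_carbons, c.bonds, beta)


# --- chain type invariants ------------------------------------------------

@pytest.mark.parametrize(
    "kwargs",
    [
        dict(n_carbons=1),
        dict(n_carbons=4, bonds=(DoubleBond(2, "E"), DoubleBond(3, "Z"))),
        dict(n_carbons=4, bonds=(DoubleBond(2, "E"), DoubleBond(2, "Z"))),
        dict(n_carbons=4, bonds=(DoubleBond(4, "E"),)),
        dict(n_carbons=4, beta_state="enol"),
    ],
)
def test_invalid_chains_rejected(kwargs):
    with pytest.raises(ValueError):
        AcylChain(**kwargs)


def test_double_bond_validation():
    with pytest.raises(ValueError):
        DoubleBond(1, "E")
    with pytest.raises(ValueError):
        DoubleBond(2, "cis")


# --- elementary steps -----------------------------------------------------

def test_condense_starter_gives_c4_keto():
    out = condense(AcylChain(2))
    assert (out.n_carbons, out.bonds, out.beta_state) == (4, (), "keto")


def test_condense_shifts_every_locant():
    out = condense(chain("C8-4Z,6E"))
    assert name_chain(out) == "C10-6Z,8E" and out.beta_state == "keto"


def test_condense_rejects_bad_extender_and_untailored_chain():
    with pytest.raises(InvalidExtenderError):
        condense(AcylChain(2), 3)
    with pytest.raises(InvalidExtenderError):
        condense(AcylChain(2), 0)
    with pytest.raises(InvalidStateError):
        condense(AcylChain(4, beta_state="keto"))


def test_keto_reduction_state_machine():
    hydroxyl = reduce_keto(AcylChain(4, beta_state="keto"))
    assert hydroxyl.beta_state == "hydroxyl"
    with pytest.raises(InvalidStateError):
        reduce_keto(hydroxyl)
    kept = reduce_keto(chain("C8-6Z", beta="keto"))
    assert kept.bonds == chain("C8-6Z").bonds


@pytest.mark.parametrize(
    "prev,expected", [(None, "E"), ("E", "Z"), ("Z", "E")]
)
def test_dehydration_geometry_rule(prev, expected):
    out = dehydrate(AcylChain(4, beta_state="hydroxyl"), prev)
    assert out.bond_at(2).geometry == expected
    assert out.beta_state == "saturated"


def test_dehydration_requires_hydroxyl():
    with pytest.raises(InvalidStateError):
        dehydrate(AcylChain(4, beta_state="keto"))


def test_enoyl_reduction_removes_only_delta2():
    out = enoyl_reduce(chain("C8-2E,4Z,6E"))
    assert name_chain(out) == "C8-4Z,6E"
    with pytest.raises(InvalidStateError):
        enoyl_reduce(chain("C8-4Z,6E"))


def test_full_reductive_cycle_is_saturating():
    # condense -> KR -> DH -> ER composes to a saturated, bond-free chain
    out = enoyl_reduce(dehydrate(reduce_keto(condense(AcylChain(2)))))
    assert (out.n_carbons, out.bonds, out.beta_state) == (4, (), "saturated")


# --- modules --------------------------------------------------------------

def test_module_class_is_pure_function_of_domains():
    assert ModuleSpec.gamma("m").module_class == "gamma"
    assert ModuleSpec.delta("m").module_class == "delta"
    kr_only = ModuleSpec(name="m", domains=frozenset({"KS", "AT", "ACP", "KR"}))
    assert kr_only.module_class is None


def test_module_requires_core_domains():
    with pytest.raises(ValueError):
        ModuleSpec(name="m", domains=frozenset({"KR", "DH"}))


def test_run_module_rejects_inconsistent_reductive_sets():
    dh_no_kr = ModuleSpec(name="m", domains=frozenset({"KS", "AT", "ACP", "DH"}))
    with pytest.raises(UnsupportedModuleError):
        run_module(AcylChain(2), dh_no_kr)
    er_no_dh = ModuleSpec(
        name="m", domains=frozenset({"KS", "AT", "ACP", "KR", "ER"})
    )
    with pytest.raises(UnsupportedModuleError):
        run_module(AcylChain(2), er_no_dh)


def test_run_module_extended_classes_are_opt_in():
    kr_only = ModuleSpec(name="m", domains=frozenset({"KS", "AT", "ACP", "KR"}))
    with pytest.raises(UnsupportedModuleError):
        run_module(AcylChain(2), kr_only)
    out, retained = run_module(AcylChain(2), kr_only, allow_extended=True)
    assert out.beta_state == "hydroxyl" and retained is None


@pytest.mark.parametrize(
    "start,cls,prev,expected,retained",
    [
        ("C2", "gamma", None, "C4-2E", "E"),
        ("C4-2E", "gamma", "E", "C6-2Z,4E", "Z"),
        ("C6-2Z,4E", "delta", "Z", "C8-4Z,6E", None),
        ("C8-4Z,6E", "gamma", None, "C10-2E,6Z,8E", "E"),
    ],
)
def test_module_cycles_of_the_affinin_line(start, cls, prev, expected, retained):
    module = ModuleSpec.from_class(cls, "m")
    out, ret = run_module(chain(start), module, prev)
    assert name_chain(out) == expected
    assert ret == retained


# --- assembly -------------------------------------------------------------

AFFININ_CLASSES = ("gamma", "gamma", "delta", "gamma")


def test_affinin_assembly_trace():
    spec = AssemblySpec.from_classes(AFFININ_CLASSES, amine="isobutylamine")
    product, trace = simulate_assembly(spec)
    assert [name_chain(c) for c in trace.intermediates()] == [
        "C4-2E", "C6-2Z,4E", "C8-4Z,6E", "C10-2E,6Z,8E"
    ]
    assert product.name == "C10-2E,6Z,8E"
    assert product.common_name == "affinin"
    assert product.linkage == "amide"


def test_all_delta_assembly_is_the_fas_limit():
    product, trace = simulate_assembly(AssemblySpec.from_classes(["delta"] * 4))
    assert product.chain.bonds == ()
    assert product.chain.n_carbons == 10
    assert all(r.after_tailoring.bond_at(2) is None for r in trace.records)


def test_carbon_conservation_and_parity_across_random_architectures():
    rng_specs = itertools.product(("gamma", "delta"), repeat=5)
    for classes in rng_specs:
        product, trace = simulate_assembly(
            AssemblySpec.from_classes(classes, te_present=False)
        )
        assert product.chain.n_carbons == 2 + 2 * len(classes)
        ncs = [r.after_tailoring.n_carbons for r in trace.records]
        assert ncs == [4 + 2 * i for i in range(len(classes))]
        for record in trace.records:
            assert all(b.position % 2 == 0 for b in record.after_tailoring.bonds)


# --- offloading and SMILES ------------------------------------------------

def test_offload_affinin_smiles_matches_reference_structure():
    # reference: hand-built isomeric SMILES of the N-isobutyl
    # 2E,6Z,8E-decatrienamide, canonicalized independently
    product = offload(parse_chain("C10-2E,6Z,8E"), "isobutylamine")
    assert product.smiles == canonical_smiles(
        "C/C=C/C=C\\CC/C=C/C(=O)NCC(C)C"
    )


def test_offload_minor_amide_analogue():
    product = offload(parse_chain("C10-2E,6Z,8E"), "2-methylbutylamine")
    assert product.linkage == "amide"
    assert product.smiles == canonical_smiles(
        "C/C=C/C=C\\CC/C=C/C(=O)NCC(C)CC"
    )


def test_offload_free_acid_degenerate_name():
    product = offload(parse_chain("C4"))
    assert (product.linkage, product.name) == ("free-acid", "C4")
    assert product.smiles == canonical_smiles("CCCC(=O)O")


def test_offload_requires_tailored_chain():
    with pytest.raises(IncompleteTailoringError):
        offload(AcylChain(4, beta_state="keto"))


def test_smiles_geometry_distinguishes_e_and_z():
    e_form = canonical_smiles(chain_smiles(parse_chain("C6-2E"), "free-acid"))
    z_form = canonical_smiles(chain_smiles(parse_chain("C6-2Z"), "free-acid"))
    assert e_form != z_form


# --- naming ---------------------------------------------------------------

@pytest.mark.parametrize(
    "descriptor", ["C4", "C10-2E,6Z,8E", "C6-2Z,4E", "C18-2E,14Z"]
)
def test_name_parse_round_trip_examples(descriptor):
    assert name_chain(parse_chain(descriptor)) == descriptor


@pytest.mark.parametrize(
    "bad", ["X4", "C", "C4-", "C4-2", "C4-2X", "C10-2E,", "C10-2E;4Z", "C4-3E,2E"]
)
def test_parse_errors_carry_position(bad):
    with pytest.raises(ChainParseError) as err:
        parse_chain(bad)
    assert err.value.position >= 0


@st.composite
def valid_chains(draw):
    n = draw(st.sampled_from([4, 6, 8, 10, 12, 14, 16, 18]))
    positions = [p for p in range(2, n - 1, 2)]
    chosen = sorted(draw(st.sets(st.sampled_from(positions), max_size=len(positions))))
    bonds = tuple(
        DoubleBond(p, draw(st.sampled_from(["E", "Z"]))) for p in chosen
    )
    return AcylChain(n_carbons=n, bonds=bonds)


@given(valid_chains())
@settings(max_examples=200, derandomize=True)
def test_naming_bijection_on_random_chains(c):
    assert parse_chain(name_chain(c)) == c


# --- retrobiosynthesis ----------------------------------------------------

def test_affinin_architecture_is_unique_over_gamma_delta():
    hits = infer_architecture(parse_chain("C10-2E,6Z,8E"))
    assert hits == [AFFININ_CLASSES]


def test_saturated_target_needs_all_delta():
    assert infer_architecture(parse_chain("C10")) == [("delta",) * 4]


def test_parity_mismatch_is_infeasible():
    with pytest.raises(InfeasibleTargetError):
        infer_architecture(AcylChain(3))
    with pytest.raises(InfeasibleTargetError):
        infer_architecture(AcylChain(2))


def test_forward_inverse_round_trip_exhaustive_to_six_modules():
    for m in range(1, 7):
        for classes in itertools.product(("gamma", "delta"), repeat=m):
            product, _ = simulate_assembly(
                AssemblySpec.from_classes(classes, te_present=False)
            )
            recovered = infer_architecture(product.chain)
            assert classes in recovered
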