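"""Displacement-chain semantics: anchors, chain growth, release, truth tables."""

import itertools

import pytest
from hypothesis import given, settings, strategies as st

from dsdlogic import (
    ANCHOR_STRONG,
    ANCHOR_WEAK,
    STATE_ORDER,
    ValidationError,
    anchor_sites,
    evaluate_gate,
    exposed_toeholds,
    extend_chains,
    generate_fixture,
    release_decision,
    truth_table,
)
from dsdlogic.chains import ChainSet

from conftest import input_subset


def _input(gate, name):
    return next(s for s in gate.inputs if s.name == name)


# -- anchors ----------------------------------------------------------------

def test_exposed_toeholds_flank_the_reporter(or_gate, and_gate, majority_gate):
    assert exposed_toeholds(or_gate) == {1, 4}
    assert exposed_toeholds(majority_gate) == {1, 4}
    assert exposed_toeholds(and_gate) == frozenset()


def test_anchor_sites_examples(or_gate, and_gate, majority_gate):
    # the reporter-twin input has nowhere to initiate on the intact duplex
    assert anchor_sites(_input(majority_gate, "fh"), majority_gate) == []
    # on the blunt AND duplex, ab can only fray in at the template end
    assert anchor_sites(_input(and_gate, "ab"), and_gate) == [(1, ANCHOR_WEAK)]
    # efh initiates at the exposed E toehold
    assert anchor_sites(_input(or_gate, "efh"), or_gate) == [(1, ANCHOR_STRONG)]
    # efhg sees both exposed toeholds
    assert anchor_sites(_input(or_gate, "efhg"), or_gate) == [
        (1, ANCHOR_STRONG), (4, ANCHOR_STRONG)
    ]


# -- chain growth -----------------------------------------------------------

def test_and_cooperative_chain_covers_everything(and_gate):
    chains = extend_chains(and_gate, list(and_gate.inputs))
    full = [c for c in chains.chains if c.coverage == (1, 4)]
    assert full, "all three inputs must build a chain covering the duplex"
    assert all(set(c.members) == {"ab", "cd", "bc"} for c in full)


def test_and_without_bridge_never_merges(and_gate):
    present = [_input(and_gate, "ab"), _input(and_gate, "cd")]
    chains = extend_chains(and_gate, present)
    assert sorted(c.coverage for c in chains.chains) == [(1, 2), (3, 4)]
    assert all(c.anchor_kind == ANCHOR_WEAK for c in chains.chains)
    assert all(len(c.members) == 1 for c in chains.chains)


def test_majority_hand_over_hand_join(majority_gate):
    present = [_input(majority_gate, "ef"), _input(majority_gate, "fh")]
    chains = extend_chains(majority_gate, present)
    assert len(chains.chains) == 1
    (chain,) = chains.chains
    assert chain.anchor_kind == ANCHOR_STRONG
    assert chain.coverage == (1, 3)
    assert set(chain.members) == {"ef", "fh"}


def test_extend_chains_rejects_foreign_strand(or_gate, and_gate):
    with pytest.raises(ValidationError):
        extend_chains(or_gate, [and_gate.inputs[0]])


def test_fixpoint_is_order_independent(any_gate):
    for state in STATE_ORDER:
        present = input_subset(any_gate, state)
        fingerprints = {
            extend_chains(any_gate, list(perm)).canonical()
            for perm in itertools.permutations(present)
        }
        assert len(fingerprints) == 1


# -- release decision --------------------------------------------------------

def test_two_strong_chains_release_by_union(majority_gate):
    present = [_input(majority_gate, "ef"), _input(majority_gate, "hg")]
    chains = extend_chains(majority_gate, present)
    assert len(chains.chains) == 2
    assert release_decision(majority_gate, chains) == 1


def test_union_of_weak_chains_does_not_release(and_gate):
    present = [_input(and_gate, "ab"), _input(and_gate, "cd")]
    chains = extend_chains(and_gate, present)
    covered = set().union(*(c.positions for c in chains.chains))
    assert covered == and_gate.footprint_positions  # covered, yet not released
    assert release_decision(and_gate, chains) == 0


def test_empty_chainset_never_releases(any_gate):
    assert release_decision(any_gate, ChainSet(chains=())) == 0


# -- truth tables ------------------------------------------------------------

BOOLEAN = {
    "OR": lambda x, y, z: x | y | z,
    "AND": lambda x, y, z: x & y & z,
    "MAJORITY": lambda x, y, z: 1 if x + y + z >= 2 else 0,
}


def test_truth_tables_equal_boolean_functions(any_gate):
    fn = BOOLEAN[any_gate.name]
    table = truth_table(any_gate)
    for row in table.rows:
        assert row.output == fn(*row.inputs), row.inputs


def test_truth_table_row_order_is_fixed(any_gate):
    assert tuple(r.inputs for r in truth_table(any_gate).rows) == STATE_ORDER


def test_evaluate_rejects_malformed_state(or_gate):
    with pytest.raises(ValidationError):
        evaluate_gate(or_gate, (1, 0))
    with pytest.raises(ValidationError):
        evaluate_gate(or_gate, (1, 0, 2))


def test_determinism(any_gate):
    for state in STATE_ORDER:
        present = input_subset(any_gate, state)
        first = extend_chains(any_gate, present)
        second = extend_chains(any_gate, present)
        assert first == second


# -- monotonicity property ---------------------------------------------------

@settings(max_examples=40, derandomize=True)
@given(
    kind=st.sampled_from(["OR-like", "AND-like", "MAJORITY-like", "random-valid"]),
    n=st.integers(min_value=4, max_value=7),
    seed=st.integers(min_value=0, max_value=10_000),
)
def test_adding_inputs_never_turns_release_off(kind, n, seed):
    gate = generate_fixture(kind, n, seed)
    for state in STATE_ORDER:
        bit = evaluate_gate(gate, state)
        for i in range(3):
            if state[i] == 0:
                grown = tuple(b | (1 if j == i else 0) for j, b in enumerate(state))
                assert evaluate_gate(gate, grown) >= bit
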