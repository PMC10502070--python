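"""Core model: complement algebra, built-in gates, validation, file round-trip."""

import pytest
from hypothesis import given, settings, strategies as st

from dsdlogic import (
    Domain,
    GateSystem,
    Strand,
    ValidationError,
    build_gate_system,
    complement,
    paper_gate,
    read_gate_file,
    write_gate_file,
    gate_to_spec,
    PAPER_GATE_NAMES,
)
from dsdlogic.core import LABEL_FLUOROPHORE, LABEL_QUENCHER


# -- complement algebra ------------------------------------------------------

def test_domain_complement_is_case_swap():
    F = Domain("F")
    assert complement(F).name == "f"
    assert complement(complement(F)) == F


domain_names = st.text(
    alphabet=st.sampled_from("ABCDEFGHabcdefgh"), min_size=1, max_size=3
).filter(lambda s: s != s.swapcase())


@settings(max_examples=60, derandomize=True)
@given(st.lists(domain_names, min_size=1, max_size=6, unique=True))
def test_strand_complement_is_involution(names):
    strand = Strand("x" + "".join(names), tuple(Domain(n) for n in names))
    assert complement(complement(strand)) == strand


def test_strand_complement_reverses_antiparallel():
    A, B, C, D = (Domain(n) for n in "ABCD")
    s = Strand("ABCD", (A, B, C, D))
    assert complement(s).domain_names == ("d", "c", "b", "a")


def test_complement_rejects_unknown_types():
    with pytest.raises(ValidationError):
        complement("F")


def test_domain_without_cased_character_rejected():
    with pytest.raises(ValidationError):
        Domain("123")


# -- built-in gates ----------------------------------------------------------

def test_exactly_three_builtin_gates():
    assert len(PAPER_GATE_NAMES) == 3
    with pytest.raises(ValidationError):
        paper_gate("XOR")


def test_or_gate_design(or_gate):
    assert or_gate.template.domain_names == ("E", "F", "H", "G")
    assert or_gate.incumbent_footprint == (2, 3)
    assert tuple(s.name for s in or_gate.inputs) == ("efh", "fhg", "efhg")
    assert or_gate.template.label == LABEL_QUENCHER
    assert or_gate.incumbent.label == LABEL_FLUOROPHORE


def test_and_gate_is_blunt_full_footprint(and_gate):
    assert and_gate.incumbent_footprint == (1, 4)
    assert tuple(s.name for s in and_gate.inputs) == ("ab", "cd", "bc")


def test_majority_gate_inputs(majority_gate):
    assert tuple(s.name for s in majority_gate.inputs) == ("ef", "hg", "fh")
    # the third input is the unlabelled twin of the reporter
    assert majority_gate.inputs[2].domain_names == majority_gate.incumbent.domain_names
    assert majority_gate.inputs[2].label is None


def test_every_input_maps_to_contiguous_template_run(any_gate):
    for inp in any_gate.inputs:
        lo, hi = any_gate.map_interval(inp)
        assert 1 <= lo <= hi <= any_gate.n_positions
        assert hi - lo + 1 == len(inp.domains)


# -- validation --------------------------------------------------------------

def _or_spec():
    return {
        "domains": [
            {"name": "E", "role": "toehold", "length_nt": 6},
            {"name": "F"}, {"name": "H"},
            {"name": "G", "role": "toehold", "length_nt": 6},
        ],
        "strands": [
            {"name": "EFHG", "domains": ["E", "F", "H", "G"],
             "label": "quencher_BHQ1"},
            {"name": "fh", "domains": ["f", "h"], "label": "fluorophore_FAM"},
            {"name": "efh", "domains": ["e", "f", "h"]},
            {"name": "fhg", "domains": ["f", "h", "g"]},
            {"name": "efhg", "domains": ["e", "f", "h", "g"]},
        ],
        "gate": {
            "name": "OR",
            "template": "EFHG",
            "incumbent": "fh",
            "incumbent_footprint": [2, 3],
            "inputs": ["efh", "fhg", "efhg"],
        },
    }


def test_build_gate_system_reproduces_builtin(or_gate):
    built = build_gate_system(_or_spec())
    assert built.template.domain_names == or_gate.template.domain_names
    assert built.incumbent_footprint == or_gate.incumbent_footprint
    assert tuple(s.name for s in built.inputs) == tuple(
        s.name for s in or_gate.inputs
    )


@pytest.mark.parametrize(
    "mutate, match",
    [
        (lambda s: s["gate"].update(incumbent_footprint=[1, 3]), "not complementary"),
        (lambda s: s["gate"].update(inputs=["efh", "fhg"]), "exactly 3 inputs"),
        (lambda s: s["strands"].append(
            {"name": "efh", "domains": ["e", "f", "h"]}), "duplicate"),
        (lambda s: s["gate"].update(template="nope"), "not a declared strand"),
        (lambda s: s["strands"][1].update(domains=["f", "g"]), "not complementary"),
    ],
)
def test_invalid_specifications_are_named(mutate, match):
    spec = _or_spec()
    mutate(spec)
    with pytest.raises(ValidationError, match=match):
        build_gate_system(spec)


def test_template_with_repeated_domain_rejected():
    F = Domain("F")
    f = F.complement()
    with pytest.raises(ValidationError, match="repeated"):
        GateSystem(
            name="bad",
            template=Strand("FF", (F, F), label=LABEL_QUENCHER),
            incumbent=Strand("ff", (f, f), label=LABEL_FLUOROPHORE),
            incumbent_footprint=(1, 2),
            inputs=(Strand("f1", (f,)), Strand("f2", (f,)), Strand("f3", (f,))),
        )


# -- file round-trip ---------------------------------------------------------

@pytest.mark.parametrize("suffix", [".yaml", ".json"])
def test_gate_file_round_trip(tmp_path, any_gate, suffix):
    path = tmp_path / f"gate{suffix}"
    write_gate_file(any_gate, path)
    loaded = read_gate_file(path)
    assert gate_to_spec(loaded) == gate_to_spec(any_gate)


def test_unparseable_gate_file(tmp_path):
    path = tmp_path / "bad.yaml"
    path.write_text("gate: [unclosed")
    with pytest.raises(ValidationError):
        read_gate_file(path)
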