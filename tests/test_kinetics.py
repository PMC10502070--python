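"""Kinetic layer: network compilation, SSA, readout, truth-table consistency."""

import numpy as np
import pytest

from dsdlogic import (
    STATE_ORDER,
    RateParameters,
    ValidationError,
    compile_reactions,
    kinetic_truth_table,
    readout,
    simulate,
    truth_table,
)
from dsdlogic.kinetics import SignalReadout, free_reporter_fraction


FAST = RateParameters(t_end=2000.0, copies=50)


def _strand_totals(network, counts):
    totals = {}
    for i, strands in enumerate(network.species_strands):
        for key, mult in strands:
            totals[key] = totals.get(key, 0) + mult * int(counts[i])
    return totals


# -- compilation -------------------------------------------------------------

def test_zero_input_network_has_no_enabled_reactions(and_gate):
    network = compile_reactions(and_gate, (0, 0, 0))
    x = np.array(network.initial_counts)
    for rxn in network.reactions:
        assert any(x[i] == 0 for i in rxn.reactants)


def test_or_single_input_has_anchor_and_release_channels(or_gate):
    network = compile_reactions(or_gate, (1, 0, 0))
    kinds = {r.name.split(":")[0] for r in network.reactions}
    assert "strong" in kinds
    assert "release" in kinds
    assert "fray" not in kinds  # efh initiates at an exposed toehold


def test_every_reaction_conserves_strand_counts(any_gate):
    for state in STATE_ORDER:
        network = compile_reactions(any_gate, state)
        x0 = np.array(network.initial_counts)
        before = _strand_totals(network, x0)
        S = network.stoichiometry()
        for r in range(len(network.reactions)):
            after = _strand_totals(network, x0 + S[r])
            assert after == before, network.reactions[r].name


def test_and_gate_has_no_strong_channel(and_gate):
    for state in STATE_ORDER:
        network = compile_reactions(and_gate, state)
        assert not any(r.name.startswith("strong:") for r in network.reactions)


# -- simulation --------------------------------------------------------------

def test_zero_reaction_network_gives_constant_trajectory(or_gate):
    network = compile_reactions(or_gate, (0, 0, 0))
    traj = simulate(network, t_end=100.0, seed=1)
    assert np.array_equal(traj.final_counts(), network.initial_counts)


def test_same_seed_gives_identical_trajectory(or_gate):
    network = compile_reactions(or_gate, (1, 1, 1), rates=FAST)
    a = simulate(network, t_end=FAST.t_end, seed=11)
    b = simulate(network, t_end=FAST.t_end, seed=11)
    assert np.array_equal(a.times, b.times)
    assert np.array_equal(a.reaction_indices, b.reaction_indices)


def test_different_seeds_diverge(or_gate):
    network = compile_reactions(or_gate, (1, 1, 1), rates=FAST)
    a = simulate(network, t_end=FAST.t_end, seed=1)
    b = simulate(network, t_end=FAST.t_end, seed=2)
    assert not np.array_equal(a.times, b.times)


def test_or_all_inputs_release_nearly_everything(or_gate):
    network = compile_reactions(or_gate, (1, 1, 1), rates=FAST)
    for seed in (1, 2, 3):
        traj = simulate(network, t_end=FAST.t_end, seed=seed)
        assert free_reporter_fraction(traj) >= 0.9


def test_strand_conservation_along_trajectory(majority_gate):
    network = compile_reactions(majority_gate, (1, 1, 0), rates=FAST)
    traj = simulate(network, t_end=FAST.t_end, seed=5)
    assert _strand_totals(network, traj.final_counts()) == _strand_totals(
        network, np.array(network.initial_counts)
    )


# -- readout -----------------------------------------------------------------

@pytest.mark.parametrize(
    "free_fraction, f_max, boundary, signal, bit",
    [(0.0, 150.0, 50.0, 0.0, 0),
     (1.0, 150.0, 50.0, 150.0, 1),
     (0.5, 150.0, 50.0, 75.0, 1)],
)
def test_readout_arithmetic(free_fraction, f_max, boundary, signal, bit, monkeypatch):
    import dsdlogic.kinetics as kin

    monkeypatch.setattr(kin, "free_reporter_fraction", lambda traj: free_fraction)
    result = kin.readout(object(), f_max=f_max, boundary=boundary)
    assert result == SignalReadout(
        free_fraction=free_fraction, signal_au=signal, bit=bit
    )


def test_signal_exactly_at_boundary_reads_zero_with_warning(monkeypatch):
    import dsdlogic.kinetics as kin

    monkeypatch.setattr(kin, "free_reporter_fraction", lambda traj: 0.5)
    with pytest.warns(UserWarning, match="boundary"):
        result = kin.readout(object(), f_max=100.0, boundary=50.0)
    assert result.bit == 0 and result.at_boundary


def test_invalid_scales_rejected():
    with pytest.raises(ValidationError):
        RateParameters(f_max=40.0, boundary=50.0)
    with pytest.raises(ValidationError):
        RateParameters(k_fray=2.0)  # fray must stay below strong


# -- kinetic truth tables ----------------------------------------------------

def test_kinetic_bits_match_logical_bits(any_gate):
    kinetic = kinetic_truth_table(any_gate, rates=FAST, seeds=(1, 2, 3))
    logical = truth_table(any_gate)
    assert kinetic.outputs == logical.outputs


def test_zero_input_baseline_is_exactly_zero(any_gate):
    kinetic = kinetic_truth_table(any_gate, rates=FAST, seeds=(1,))
    assert kinetic.rows[0].inputs == (0, 0, 0)
    assert kinetic.rows[0].signal == 0.0


def test_bits_invariant_under_doubling_copies(majority_gate):
    lo = kinetic_truth_table(majority_gate, rates=FAST, copies=50, seeds=(1, 2))
    hi = kinetic_truth_table(majority_gate, rates=FAST, copies=100, seeds=(1, 2))
    assert lo.outputs == hi.outputs
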