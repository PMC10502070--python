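"""Logical truth tables of the three built-in gates.

Builds the OR, AND and MAJORITY gate systems and runs the displacement-chain
engine over all eight input combinations.  Each printed row is an input
state (INPUT1 INPUT2 INPUT3) and the output bit: 1 means the input strands
can displace the fluorophore-labelled reporter from its quencher-labelled
template, so fluorescence would rise.
"""

from dsdlogic import PAPER_GATE_NAMES, paper_gate, truth_table

for name in PAPER_GATE_NAMES:
    table = truth_table(paper_gate(name))
    print(f"\n{name} gate — high states: {sum(table.outputs)} of 8")
    for row in table.rows:
        print(f"  ({row.inputs[0]} {row.inputs[1]} {row.inputs[2]}) -> {row.output}")
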