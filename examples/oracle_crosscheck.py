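"""Cross-check the chain rules against the exhaustive state-space oracle.

The chain engine decides release by interval reachability; the oracle
explores every explicit binding state under single-position moves.  The AND
gate is the interesting case: ab and cd alone fray in from the two blunt
ends but form disconnected fronts that cannot strip the reporter — only the
bridging input bc connects them.
"""

from dsdlogic import STATE_ORDER, evaluate_gate, oracle_enumerate, paper_gate

gate = paper_gate("AND")
print("AND gate: chain engine vs brute-force state enumeration")
for state in STATE_ORDER:
    present = [inp for inp, bit in zip(gate.inputs, state) if bit]
    chain_bit = evaluate_gate(gate, state)
    oracle_bit = oracle_enumerate(gate, present)
    marker = "ok" if chain_bit == oracle_bit else "MISMATCH"
    print(f"  ({state[0]} {state[1]} {state[2]})  chain={chain_bit} "
          f"oracle={oracle_bit}  {marker}")
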