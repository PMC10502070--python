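"""Define a custom gate system, save it, reload it and evaluate it.

Generates a five-domain AND-like system (blunt duplex, three overlapping
inputs), writes the gate-specification YAML, reloads it and verifies that
the reloaded system still computes three-input AND.
"""

import tempfile
from pathlib import Path

from dsdlogic import generate_fixture, read_gate_file, truth_table, write_gate_file

gate = generate_fixture("AND-like", n_domains=5, seed=7)
print("template:", gate.template.name, "| inputs:",
      ", ".join(s.name for s in gate.inputs))

path = Path(tempfile.mkdtemp()) / "custom_gate.yaml"
write_gate_file(gate, path)
reloaded = read_gate_file(path)

table = truth_table(reloaded)
print("truth table bits:", table.outputs)
print("computes AND:", table.outputs == (0, 0, 0, 0, 0, 0, 0, 1))
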