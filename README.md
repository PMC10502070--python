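# dsdlogic

Domain-level simulation of DNA strand-displacement logic gates.

`dsdlogic` decides, for any combination of DNA input strands added to an
annealed reporter duplex, whether the fluorophore-labelled reporter strand is
released — and therefore whether the fluorescence output of the molecular
logic gate reads 1. It ships the three classic three-input gate designs
(OR, AND, MAJORITY) built from toehold-mediated strand displacement, and is
aimed at people designing or teaching DNA logic circuits who want to check a
gate design *before* ordering oligos.

## The model

A gate system is a quencher-labelled (BHQ1) template strand holding a
fluorophore-labelled (FAM) incumbent (the reporter) over a contiguous
*footprint* of template domains, plus three input strands. Domains are
indivisible hybridization units; `F`/`f` denote a complementary pair.

**Logical engine (displacement chains).** An input can initiate on the
complex at a *strong* anchor — an exposed toehold flanking the reporter — or
at a *weak* anchor — a template terminal position reachable only through end
fraying of the duplex. An anchored chain claims the contiguous template run
its members complement, and any present input overlapping that run by at
least one domain *joins* the chain (hand-over-hand displacement through the
internal toehold exposed at the junction). The reporter is released iff

* a single chain's coverage contains the whole footprint, or
* the union of strong-anchored chains' coverages does.

Disconnected weak chains never release: two isolated fray events cannot
sustain a continuous branch-migration front. This is exactly what makes the
blunt-duplex AND gate conjunctive — `ab` and `cd` fray in from the two ends,
but only the bridging strand `bc` connects the fronts.

**Oracle.** An independent breadth-first enumeration over explicit binding
states (who holds each template position) with single-position binding,
fraying, zipping and branch-migration moves, subject to the same anchoring
constraints. It agrees with the chain engine on all built-in gates and on
randomly generated systems.

**Kinetic engine.** The logical moves are compiled into a stochastic
chemical reaction network (anchor, join, release, unbind channels over
complex configurations) and sampled with Gillespie's exact algorithm. The
endpoint readout is `signal = free_reporter_fraction × F_max` (default
F_max = 150 a.u.), binarized at a boundary of 50 a.u.: above the boundary
reads 1, below reads 0.

**Sequence design.** Random domain sequences under standard constraints
(exact reverse-complement pairs, GC window, homopolymer cap, k-mer
orthogonality screen), with FASTA import/export.

## Worked example

```python
from dsdlogic import paper_gate, truth_table, evaluate_gate

gate = paper_gate("MAJORITY")
print(truth_table(gate).outputs)   # (0, 0, 0, 0, 1, 1, 1, 1)
print(evaluate_gate(gate, (1, 0, 1)))  # 1 — two inputs suffice
```

Running `python examples/truth_tables.py` prints all three gates:

```
OR gate — high states: 7 of 8        # every state except (0 0 0)
AND gate — high states: 1 of 8       # only (1 1 1)
MAJORITY gate — high states: 4 of 8  # (1 1 0) (1 0 1) (0 1 1) (1 1 1)
```

and `python examples/kinetic_readout.py` shows the stochastic readout for
MAJORITY, e.g. state `(1 0 1)` reaching `150.0 a.u. -> 1` while single-input
states stay at `0.0 a.u. -> 0`. The same is available from the shell:

```bash
dsdlogic truthtable --gate OR                    # 8-row CSV
dsdlogic evaluate --gate AND --state 110         # AND (1 1 0) -> 0
dsdlogic simulate --gate OR --state 100 --out traj.tsv
dsdlogic fixtures --kind AND-like --n 5 --seed 7 --out-prefix mygate
dsdlogic validate --spec mygate.yaml
```

`examples/` holds one short script per capability; `docs/methods.md`
describes the model, its assumptions and its limits.

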