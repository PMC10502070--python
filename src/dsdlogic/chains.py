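"""Logical execution layer: displacement-chain reachability.

Whether a set of input strands can release the reporter is decided without
kinetics, by building *displacement chains* to a fixpoint:

* a chain is **anchored** either at a *strong* site — an exposed template
  toehold (a position the incumbent's footprint leaves unpaired) the input
  complements — or at a *weak* site — a template terminal position (1 or n)
  the input complements even though it is paired, reachable through end
  fraying of the duplex;
* an anchored chain *covers* the contiguous template run its members
  complement;
* any present input overlapping a chain's coverage in at least one position
  *joins* the chain (hand-over-hand displacement: the junction left by the
  previous invader exposes an internal toehold) and extends the coverage.

The reporter is released iff a single chain's coverage contains the whole
incumbent footprint, or the union of strong-anchored chains' coverages does.
Two disconnected weak (fray-anchored) chains never release: isolated end
fraying cannot sustain a continuous migration front across the duplex.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Optional, Sequence

from .core import (
    STATE_ORDER,
    GateSystem,
    Strand,
    TruthTable,
    TruthTableRow,
    ValidationError,
)

__all__ = [
    "ANCHOR_STRONG",
    "ANCHOR_WEAK",
    "Chain",
    "ChainSet",
    "exposed_toeholds",
    "anchor_sites",
    "extend_chains",
    "release_decision",
    "evaluate_gate",
    "truth_table",
]

ANCHOR_STRONG = "strong_toehold"
ANCHOR_WEAK = "weak_fray"

TraceFn = Optional[Callable[[str], None]]


@dataclass(frozen=True)
class Chain:
    """A maximal anchored displacement chain.

    ``coverage`` is the contiguous 1-based inclusive template interval the
    chain has claimed (the union of its members' complementary runs).
    """

    anchor_kind: str
    anchor_position: int
    members: tuple[str, ...]  # invader strand names, in join order
    coverage: tuple[int, int]

    @property
    def positions(self) -> frozenset[int]:
        lo, hi = self.coverage
        return frozenset(range(lo, hi + 1))


@dataclass(frozen=True)
class ChainSet:
    chains: tuple[Chain, ...]

    @property
    def strong_coverage(self) -> frozenset[int]:
        """Union of the coverages of all strong-anchored chains."""
        out: set[int] = set()
        for ch in self.chains:
            if ch.anchor_kind == ANCHOR_STRONG:
                out |= ch.positions
        return frozenset(out)

    def canonical(self) -> tuple:
        """Order-free fingerprint (for equality across processing orders)."""
        return tuple(sorted(
            (c.anchor_kind, c.anchor_position, frozenset(c.members), c.coverage)
            for c in self.chains
        ))


def exposed_toeholds(gate: GateSystem) -> frozenset[int]:
    """Template positions left single-stranded by the incumbent footprint."""
    return frozenset(range(1, gate.n_positions + 1)) - gate.footprint_positions


def anchor_sites(invader: Strand, gate: GateSystem) -> list[tuple[int, str]]:
    """Where (and how) an invader can initiate on the annealed gate complex.

    Strong anchors sit at exposed toeholds the invader complements; weak
    anchors sit at template terminal positions (1 or n) the invader
    complements even if they are paired (end fraying).  An exposed terminal
    is reported once, as strong.
    """
    lo, hi = gate.map_interval(invader)
    exposed = exposed_toeholds(gate)
    sites: list[tuple[int, str]] = []
    for p in range(lo, hi + 1):
        if p in exposed:
            sites.append((p, ANCHOR_STRONG))
        elif p in (1, gate.n_positions):
            sites.append((p, ANCHOR_WEAK))
    return sites


def _merge(a: tuple[int, int], b: tuple[int, int]) -> tuple[int, int]:
    return (min(a[0], b[0]), max(a[1], b[1]))


def _overlaps(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return a[0] <= b[1] and b[0] <= a[1]


def extend_chains(
    gate: GateSystem,
    present_inputs: Iterable[Strand],
    trace: TraceFn = None,
) -> ChainSet:
    """Grow all displacement chains to their fixpoint.

    Inputs are processed in the order given; the fixpoint is order-free (a
    chain's final membership is the set of present inputs transitively
    connected to its anchor by coverage overlap), so permuting
    ``present_inputs`` yields the same :class:`ChainSet`.
    """
    present = list(present_inputs)
    for inp in present:
        if inp.name not in {s.name for s in gate.inputs}:
            raise ValidationError(
                f"strand {inp.name!r} is not an input of gate {gate.name!r}"
            )
    intervals = {inp.name: gate.map_interval(inp) for inp in present}

    chains: list[dict] = []
    for inp in present:
        for pos, kind in anchor_sites(inp, gate):
            chains.append({
                "anchor_kind": kind,
                "anchor_position": pos,
                "members": [inp.name],
                "coverage": intervals[inp.name],
            })
            if trace:
                trace(f"anchor {kind} {inp.name} at position {pos} "
                      f"covering {intervals[inp.name]}")

    changed = True
    while changed:
        changed = False
        for ch in chains:
            for inp in present:
                if inp.name in ch["members"]:
                    continue
                if _overlaps(intervals[inp.name], ch["coverage"]):
                    ch["members"].append(inp.name)
                    new_cov = _merge(ch["coverage"], intervals[inp.name])
                    if trace:
                        trace(f"join {inp.name} -> chain@{ch['anchor_position']} "
                              f"extend {ch['coverage']} -> {new_cov}")
                    ch["coverage"] = new_cov
                    changed = True
    return ChainSet(chains=tuple(
        Chain(
            anchor_kind=ch["anchor_kind"],
            anchor_position=ch["anchor_position"],
            members=tuple(ch["members"]),
            coverage=ch["coverage"],
        )
        for ch in chains
    ))


def release_decision(gate: GateSystem, chains: ChainSet) -> int:
    """1 iff the chains displace the incumbent over its whole footprint.

    Either a single chain (any anchor kind — a connected migration front)
    covers the footprint, or the union of strong-anchored chains does.
    """
    footprint = gate.footprint_positions
    for ch in chains.chains:
        if footprint <= ch.positions:
            return 1
    if footprint <= chains.strong_coverage:
        return 1
    return 0


def _select_inputs(gate: GateSystem, state: Sequence[int]) -> list[Strand]:
    state = tuple(state)
    if len(state) != 3 or any(b not in (0, 1) for b in state):
        raise ValidationError(f"input state must be a triple of bits, got {state!r}")
    return [inp for inp, bit in zip(gate.inputs, state) if bit]


def evaluate_gate(gate: GateSystem, state: Sequence[int], trace: TraceFn = None) -> int:
    """Logical output bit for one input combination (INPUT1, INPUT2, INPUT3)."""
    present = _select_inputs(gate, state)
    return release_decision(gate, extend_chains(gate, present, trace=trace))


def truth_table(gate: GateSystem) -> TruthTable:
    """Full 8-row truth table in the fixed state order."""
    rows = tuple(
        TruthTableRow(inputs=state, output=evaluate_gate(gate, state))
        for state in STATE_ORDER
    )
    return TruthTable(gate_name=gate.name, rows=rows)
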