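"""Coarse-grained stochastic kinetics of gate operation.

The logical moves of :mod:`dsdlogic.chains` — strong-toehold anchoring,
terminal-fray anchoring, overlap joining, reporter release and dissociation
of a lone anchored invader — are compiled into a chemical reaction network
over *complex configurations* (which chains a gate complex currently
carries) plus free-strand pools.  The network is sampled with the exact
stochastic simulation algorithm (Gillespie's direct method), giving a
fluorescence-style readout: the fraction of reporter strands no longer
co-complexed with the quencher-labelled template, scaled to arbitrary
units and binarized at a boundary (signal above the boundary reads 1,
below reads 0).

Branch migration inside a chain is collapsed into the anchor/join/release
channels: the experiment resolves endpoint fluorescence, not migration
intermediates.  Bimolecular propensities are ``k * nA * nB`` in arbitrary
per-copy units.  There are no leak reactions unless a leak rate is set, so
the zero-input baseline is exactly zero.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .core import (
    STATE_ORDER,
    GateSystem,
    Strand,
    TruthTable,
    TruthTableRow,
    ValidationError,
)
from .chains import ANCHOR_STRONG, ANCHOR_WEAK, anchor_sites

__all__ = [
    "RateParameters",
    "ReactionNetwork",
    "Reaction",
    "SignalReadout",
    "Trajectory",
    "compile_reactions",
    "simulate",
    "readout",
    "kinetic_truth_table",
    "DEFAULT_SEEDS",
]

#: Default seed set for a fluorescence-style truth-table run.
DEFAULT_SEEDS: tuple[int, ...] = tuple(range(1, 11))


@dataclass(frozen=True)
class RateParameters:
    """Rate constants and run defaults, in arbitrary (per-copy) time units.

    Strong toehold anchoring is orders of magnitude faster than terminal
    fraying; release once the footprint is displaced is fast and
    irreversible; a lone anchored invader may dissociate.
    """

    k_strong: float = 1.0
    k_fray: float = 1e-3
    k_join: float = 1.0
    k_release: float = 10.0
    k_unbind1: float = 0.1
    k_leak: float = 0.0  # off by default: no spurious release channel
    t_end: float = 1e4
    copies: int = 100
    f_max: float = 150.0
    boundary: float = 50.0

    def __post_init__(self) -> None:
        for nm in ("k_strong", "k_fray", "k_join", "k_release", "k_unbind1", "k_leak"):
            if getattr(self, nm) < 0:
                raise ValidationError(f"rate {nm} must be >= 0")
        if not self.k_fray < self.k_strong:
            raise ValidationError("k_fray must be smaller than k_strong")
        if self.copies < 1:
            raise ValidationError("copies must be >= 1")
        if not (self.f_max > self.boundary > 0):
            raise ValidationError("need f_max > boundary > 0")


# A chain inside a complex configuration: (anchor_kind, members, coverage).
_KChain = tuple[str, frozenset, tuple[int, int]]
# A configuration: (released?, frozenset of chains)
_Config = tuple[bool, frozenset]


@dataclass(frozen=True)
class Reaction:
    """One mass-action channel: reactants -> products at rate ``rate``."""

    name: str
    reactants: tuple[int, ...]  # species indices (1 or 2 entries)
    products: tuple[int, ...]
    rate: float


@dataclass(frozen=True)
class ReactionNetwork:
    """Species, channels and initial counts for one gate + input state."""

    gate_name: str
    state: tuple[int, int, int]
    species_names: tuple[str, ...]
    species_strands: tuple[frozenset, ...]  # multiset-as-frozenset of (strand, count)
    reactions: tuple[Reaction, ...]
    initial_counts: tuple[int, ...]

    @property
    def n_species(self) -> int:
        return len(self.species_names)

    def stoichiometry(self) -> np.ndarray:
        S = np.zeros((len(self.reactions), self.n_species), dtype=np.int64)
        for r, rxn in enumerate(self.reactions):
            for i in rxn.reactants:
                S[r, i] -= 1
            for i in rxn.products:
                S[r, i] += 1
        return S


@dataclass(frozen=True)
class Trajectory:
    """A sample path: event times and fired reaction indices.

    Counts at any time are reconstructed from the initial counts and the
    stoichiometry, keeping storage proportional to the number of events.
    """

    network: ReactionNetwork
    seed: int
    t_end: float
    times: np.ndarray
    reaction_indices: np.ndarray

    def final_counts(self) -> np.ndarray:
        x = np.array(self.network.initial_counts, dtype=np.int64)
        if len(self.reaction_indices):
            S = self.network.stoichiometry()
            fired = np.bincount(self.reaction_indices, minlength=len(S))
            x = x + fired @ S
        return x

    def counts_dataframe(self, max_points: Optional[int] = None):
        """Tidy (time, species, count) table; optionally thinned."""
        import pandas as pd

        S = self.network.stoichiometry()
        idx = np.arange(len(self.times))
        if max_points is not None and len(idx) > max_points:
            idx = np.unique(np.linspace(0, len(idx) - 1, max_points).astype(int))
        x = np.array(self.network.initial_counts, dtype=np.int64)
        records = [(0.0, nm, int(c)) for nm, c in zip(self.network.species_names, x)]
        cum = np.zeros_like(x)
        last = -1
        for i in idx:
            for j in range(last + 1, i + 1):
                cum += S[self.reaction_indices[j]]
            last = i
            for nm, c in zip(self.network.species_names, x + cum):
                records.append((float(self.times[i]), nm, int(c)))
        return pd.DataFrame(records, columns=["time", "species", "count"])

    def to_tsv(self, path, max_points: Optional[int] = 2000) -> None:
        self.counts_dataframe(max_points=max_points).to_csv(
            path, sep="\t", index=False
        )


@dataclass(frozen=True)
class SignalReadout:
    free_fraction: float
    signal_au: float
    bit: int
    at_boundary: bool = False


# ---------------------------------------------------------------------------
# network compilation
# ---------------------------------------------------------------------------

def _chain_positions(cov: tuple[int, int]) -> frozenset[int]:
    return frozenset(range(cov[0], cov[1] + 1))


def _config_releases(chains: frozenset, footprint: frozenset) -> bool:
    strong: set[int] = set()
    for kind, _members, cov in chains:
        pos = _chain_positions(cov)
        if footprint <= pos:
            return True
        if kind == ANCHOR_STRONG:
            strong |= pos
    return footprint <= strong


def _config_moves(
    gate: GateSystem,
    chains: frozenset,
    present: list[Strand],
    intervals: dict[str, tuple[int, int]],
):
    """Yield (kind, input_name_or_None, new_chains) logical moves.

    kind is one of 'strong', 'fray', 'join', 'unbind'; release is handled
    separately.  Chain coverages within one complex stay pairwise disjoint;
    a join merges every chain the newcomer overlaps.
    """
    chain_list = sorted(chains)
    emitted: set = set()
    for inp in present:
        iv = intervals[inp.name]
        ipos = _chain_positions(iv)
        # new anchored chain (claims its full run; must not clash)
        taken = set()
        for _k, _m, cov in chain_list:
            taken |= _chain_positions(cov)
        overlapping = [c for c in chain_list if _chain_positions(c[2]) & ipos]
        if not overlapping:
            for pos, kind in anchor_sites(inp, gate):
                if ipos & taken:
                    continue
                newc = (
                    ANCHOR_STRONG if kind == ANCHOR_STRONG else ANCHOR_WEAK,
                    frozenset({inp.name}),
                    iv,
                )
                move = (
                    "strong" if kind == ANCHOR_STRONG else "fray",
                    inp.name,
                    chains | {newc},
                )
                if move not in emitted:  # one channel per distinct outcome
                    emitted.add(move)
                    yield move
        else:
            # join: merge all chains the newcomer overlaps
            if any(inp.name in c[1] for c in overlapping):
                continue
            kinds = {c[0] for c in overlapping}
            members = frozenset().union(*(c[1] for c in overlapping)) | {inp.name}
            lo = min(min(c[2][0] for c in overlapping), iv[0])
            hi = max(max(c[2][1] for c in overlapping), iv[1])
            merged = (
                ANCHOR_STRONG if ANCHOR_STRONG in kinds else ANCHOR_WEAK,
                members,
                (lo, hi),
            )
            rest = chains - set(overlapping)
            if any(
                _chain_positions(c[2]) & _chain_positions(merged[2]) for c in rest
            ):
                continue
            yield ("join", inp.name, rest | {merged})
    # unbind of single-member chains
    for c in chain_list:
        if len(c[1]) == 1:
            (member,) = c[1]
            yield ("unbind", member, chains - {c})


def compile_reactions(
    gate: GateSystem,
    state: Sequence[int],
    rates: Optional[RateParameters] = None,
    copies: Optional[int] = None,
    max_species: int = 4096,
) -> ReactionNetwork:
    """Enumerate reachable complex configurations and their channels.

    Initial counts: ``copies`` annealed template:incumbent duplexes and
    ``copies`` of each *present* input (1:1 stoichiometry).  Every channel
    conserves each strand species' total copy number; a released complex is
    absorbing (the freed reporter does not re-invade).
    """
    rates = rates or RateParameters()
    n_copies = rates.copies if copies is None else copies
    if n_copies < 1:
        raise ValidationError("copies must be >= 1")
    state = tuple(int(b) for b in state)
    if len(state) != 3 or any(b not in (0, 1) for b in state):
        raise ValidationError(f"input state must be a triple of bits, got {state!r}")
    present = [inp for inp, bit in zip(gate.inputs, state) if bit]
    intervals = {inp.name: gate.map_interval(inp) for inp in present}
    footprint = gate.footprint_positions

    rate_of = {
        "strong": rates.k_strong,
        "fray": rates.k_fray,
        "join": rates.k_join,
        "unbind": rates.k_unbind1,
    }

    # species bookkeeping ----------------------------------------------------
    species_names: list[str] = []
    species_strands: list[frozenset] = []
    index: dict[str, int] = {}

    def add_species(name: str, strands: dict) -> int:
        if name in index:
            return index[name]
        index[name] = len(species_names)
        species_names.append(name)
        species_strands.append(frozenset(strands.items()))
        return index[name]

    def config_name(cfg: _Config) -> str:
        released, chains = cfg
        if not chains and not released:
            return "complex:annealed"
        parts = []
        for kind, members, cov in sorted(chains):
            tag = "S" if kind == ANCHOR_STRONG else "W"
            parts.append(f"{tag}[{'+'.join(sorted(members))}@{cov[0]}-{cov[1]}]")
        body = ",".join(parts) if parts else "bare"
        return f"complex:{'released:' if released else ''}{body}"

    def config_strands(cfg: _Config) -> dict:
        released, chains = cfg
        out = {gate.template.name: 1}
        if not released:
            out["incumbent:" + gate.incumbent.name] = 1
        for _k, members, _cov in chains:
            for m in members:
                out["input:" + m] = out.get("input:" + m, 0) + 1
        return out

    free_input_idx: dict[str, int] = {}
    for inp in present:
        free_input_idx[inp.name] = add_species(
            "free:" + inp.name, {"input:" + inp.name: 1}
        )
    free_incumbent = add_species(
        "free:" + gate.incumbent.name + ":reporter",
        {"incumbent:" + gate.incumbent.name: 1},
    )

    start: _Config = (False, frozenset())
    start_idx = add_species(config_name(start), config_strands(start))

    reactions: list[Reaction] = []
    seen: dict[_Config, int] = {start: start_idx}
    frontier = [start]
    while frontier:
        cfg = frontier.pop()
        released, chains = cfg
        i_cfg = seen[cfg]
        if released:
            continue  # absorbing
        for kind, inp_name, new_chains in _config_moves(
            gate, chains, present, intervals
        ):
            new_cfg: _Config = (False, new_chains)
            if new_cfg not in seen:
                seen[new_cfg] = add_species(
                    config_name(new_cfg), config_strands(new_cfg)
                )
                if len(seen) > max_species:
                    raise ValidationError(
                        f"reaction network exceeds {max_species} configurations; "
                        "reduce the system size or use the logical engine"
                    )
                frontier.append(new_cfg)
            j = seen[new_cfg]
            i_free = free_input_idx[inp_name]
            if kind == "unbind":
                reactions.append(Reaction(
                    name=f"unbind:{inp_name}:{species_names[i_cfg]}",
                    reactants=(i_cfg,), products=(j, i_free),
                    rate=rate_of[kind],
                ))
            else:
                reactions.append(Reaction(
                    name=f"{kind}:{inp_name}:{species_names[i_cfg]}",
                    reactants=(i_cfg, i_free), products=(j,),
                    rate=rate_of[kind],
                ))
        if _config_releases(chains, footprint):
            rel_cfg: _Config = (True, chains)
            if rel_cfg not in seen:
                seen[rel_cfg] = add_species(
                    config_name(rel_cfg), config_strands(rel_cfg)
                )
                frontier.append(rel_cfg)
            reactions.append(Reaction(
                name=f"release:{species_names[i_cfg]}",
                reactants=(i_cfg,), products=(seen[rel_cfg], free_incumbent),
                rate=rates.k_release,
            ))
        if rates.k_leak > 0 and not chains:
            rel_cfg = (True, chains)
            if rel_cfg not in seen:
                seen[rel_cfg] = add_species(
                    config_name(rel_cfg), config_strands(rel_cfg)
                )
                frontier.append(rel_cfg)
            reactions.append(Reaction(
                name="leak:" + species_names[i_cfg],
                reactants=(i_cfg,), products=(seen[rel_cfg], free_incumbent),
                rate=rates.k_leak,
            ))

    counts = [0] * len(species_names)
    counts[start_idx] = n_copies
    for inp in present:
        counts[free_input_idx[inp.name]] = n_copies
    return ReactionNetwork(
        gate_name=gate.name,
        state=state,  # type: ignore[arg-type]
        species_names=tuple(species_names),
        species_strands=tuple(species_strands),
        reactions=tuple(reactions),
        initial_counts=tuple(counts),
    )


# ---------------------------------------------------------------------------
# exact stochastic simulation (Gillespie direct method)
# ---------------------------------------------------------------------------

def simulate(
    network: ReactionNetwork,
    t_end: float = 1e4,
    seed: int = 0,
    max_events: Optional[int] = None,
) -> Trajectory:
    """Sample one exact trajectory of the jump process.

    Identical (network, t_end, seed) give bitwise-identical trajectories.
    """
    if t_end <= 0:
        raise ValidationError("t_end must be positive")
    rng = np.random.default_rng(seed)
    n_rxn = len(network.reactions)
    x = list(network.initial_counts)
    times: list[float] = []
    fired: list[int] = []
    if n_rxn == 0:
        return Trajectory(network, seed, t_end,
                          np.array(times), np.array(fired, dtype=np.int64))

    rates = [r.rate for r in network.reactions]
    reactants = [r.reactants for r in network.reactions]
    # per-reaction sparse stoichiometry
    deltas: list[list[tuple[int, int]]] = []
    for r in network.reactions:
        d: dict[int, int] = {}
        for i in r.reactants:
            d[i] = d.get(i, 0) - 1
        for i in r.products:
            d[i] = d.get(i, 0) + 1
        deltas.append([(i, v) for i, v in d.items() if v])

    def propensity(r: int) -> float:
        p = rates[r]
        for i in reactants[r]:
            p *= x[i]
        return p

    props = [propensity(r) for r in range(n_rxn)]
    total = sum(props)
    t = 0.0
    while total > 0:
        t += rng.exponential(1.0 / total)
        if t > t_end:
            break
        u = rng.random() * total
        acc = 0.0
        r = n_rxn - 1
        for k in range(n_rxn):
            acc += props[k]
            if u < acc:
                r = k
                break
        for i, v in deltas[r]:
            x[i] += v
        times.append(t)
        fired.append(r)
        if max_events is not None and len(fired) >= max_events:
            break
        props = [propensity(k) for k in range(n_rxn)]
        total = sum(props)
    return Trajectory(network, seed, t_end,
                      np.array(times), np.array(fired, dtype=np.int64))


def free_reporter_fraction(trajectory: Trajectory) -> float:
    """Fraction of reporter strands not co-complexed with the quencher."""
    net = trajectory.network
    x = trajectory.final_counts()
    free = 0
    total = 0
    for i, (nm, strands) in enumerate(zip(net.species_names, net.species_strands)):
        inc = sum(cnt for key, cnt in strands if key.startswith("incumbent:"))
        if inc:
            total += inc * int(x[i])
            if nm.startswith("free:"):
                free += inc * int(x[i])
    if total == 0:
        return 0.0
    return free / total


def readout(
    trajectory: Trajectory,
    f_max: float = 150.0,
    boundary: float = 50.0,
) -> SignalReadout:
    """Binarize the endpoint fluorescence of one trajectory.

    ``signal = free_fraction * f_max``; signal strictly above the boundary
    reads 1, below reads 0.  A signal exactly at the boundary is reported as
    0 with ``at_boundary=True`` (only "above" and "below" are defined).
    """
    if not (f_max > boundary > 0):
        raise ValidationError("need f_max > boundary > 0")
    ff = free_reporter_fraction(trajectory)
    signal = ff * f_max
    at_boundary = signal == boundary
    bit = 1 if signal > boundary else 0
    if at_boundary:
        import warnings

        warnings.warn(
            "signal exactly at the binarization boundary; reporting 0",
            stacklevel=2,
        )
    return SignalReadout(
        free_fraction=ff, signal_au=signal, bit=bit, at_boundary=at_boundary
    )


def kinetic_truth_table(
    gate: GateSystem,
    rates: Optional[RateParameters] = None,
    copies: Optional[int] = None,
    t_end: Optional[float] = None,
    seeds: Sequence[int] = DEFAULT_SEEDS,
) -> TruthTable:
    """Fluorescence-style truth table: per state, the median endpoint signal
    across seeds and its binarization."""
    rates = rates or RateParameters()
    if not seeds:
        raise ValidationError("at least one seed is required")
    t_stop = rates.t_end if t_end is None else t_end
    rows = []
    for state in STATE_ORDER:
        network = compile_reactions(gate, state, rates=rates, copies=copies)
        signals = []
        for seed in seeds:
            traj = simulate(network, t_end=t_stop, seed=seed)
            signals.append(
                readout(traj, f_max=rates.f_max, boundary=rates.boundary).signal_au
            )
        med = float(statistics.median(signals))
        rows.append(TruthTableRow(
            inputs=state,
            output=1 if med > rates.boundary else 0,
            signal=med,
        ))
    return TruthTable(gate_name=gate.name, rows=tuple(rows))
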