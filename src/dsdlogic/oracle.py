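"""Brute-force verification oracle over explicit binding states.

Independent of the chain layer, this module decides reporter release by
breadth-first search over *binding states*: who holds each template domain
position.  Elementary moves are

* binding of a free invader at a currently unpaired position it complements
  (tagged *strong* if the position is an initially exposed toehold,
  *joined* if it is an internal opening created by earlier displacement);
* fray binding at a template terminal position even while paired (*weak*);
* junction binding at a breathing duplex junction (*joined*);
* zipping of a bound strand into an adjacent unpaired position of its run;
* single-position branch-migration steps in either direction (a bound strand
  extends by one position, the displaced occupant shrinks by one);
* removal of any strand pushed down to zero held positions.

Anchoring constraints mirror the chain rules: the move that strips the
incumbent's last held position is only allowed when the invaders covering
the footprint form legitimate displacement fronts — either one front whose
members' complementary runs are transitively connected by overlap, or
strong-anchored fronts whose held positions jointly cover the footprint.
Without that constraint a blunt duplex could always be stripped from both
ends by two disconnected fray events.

The search is exact within its size bounds (template <= 8 domains, <= 6
invader species, one copy per species) and raises
:class:`OracleInconclusiveError` if the state budget is exceeded — never a
silent 0.
"""

from __future__ import annotations

from collections import deque
from typing import Iterable, Sequence

from .core import GateSystem, Strand, ValidationError
from .chains import exposed_toeholds

__all__ = ["OracleInconclusiveError", "oracle_enumerate"]

TAG_STRONG = "strong"
TAG_WEAK = "weak"
TAG_JOINED = "joined"
TAG_INCUMBENT = "incumbent"

# a bound strand: (strand_key, held_start, held_end, tag)
Bound = tuple[str, int, int, str]
State = frozenset  # of Bound


class OracleInconclusiveError(RuntimeError):
    """The state budget was exhausted before the search completed."""


def _components(entries: list[tuple[Bound, tuple[int, int]]]) -> list[list[Bound]]:
    """Group bound invaders by transitive overlap of their mappable runs."""
    n = len(entries)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            (lo1, hi1), (lo2, hi2) = entries[i][1], entries[j][1]
            if lo1 <= hi2 and lo2 <= hi1:
                parent[find(i)] = find(j)
    comps: dict[int, list[Bound]] = {}
    for i in range(n):
        comps.setdefault(find(i), []).append(entries[i][0])
    return list(comps.values())


def _valid_release(
    state_without_incumbent: Iterable[Bound],
    footprint: frozenset[int],
    maps: dict[str, tuple[int, int]],
) -> bool:
    """Anchoring-legitimacy of a state in which the incumbent holds nothing."""
    relevant = []
    for entry in state_without_incumbent:
        key, s, e, tag = entry
        held = set(range(s, e + 1))
        if held & footprint:
            relevant.append((entry, maps[key]))
    covered: set[int] = set()
    for (key, s, e, tag), _ in relevant:
        covered |= set(range(s, e + 1))
    if not footprint <= covered:
        return False
    comps = _components(relevant)
    strong_held: set[int] = set()
    for comp in comps:
        held = set()
        strong = False
        for key, s, e, tag in comp:
            held |= set(range(s, e + 1))
            strong = strong or tag == TAG_STRONG
        if footprint <= held:
            return True  # one connected migration front covers everything
        if strong:
            strong_held |= held
    return footprint <= strong_held


def oracle_enumerate(
    gate: GateSystem,
    present_inputs: Iterable[Strand],
    max_states: int = 200_000,
) -> int:
    """1 iff a state with the incumbent fully unbound is reachable.

    ``present_inputs`` are treated as distinct species, one copy each (a
    displaced copy returns to the free pool and may rebind).
    """
    present = list(present_inputs)
    n = gate.n_positions
    if n > 8:
        raise ValidationError(
            f"oracle bound exceeded: template has {n} > 8 domains"
        )
    if len(present) > 6:
        raise ValidationError(
            f"oracle bound exceeded: {len(present)} > 6 invader species"
        )
    footprint = gate.footprint_positions
    exposed = exposed_toeholds(gate)
    inc_key = "incumbent:" + gate.incumbent.name
    maps: dict[str, tuple[int, int]] = {inc_key: gate.incumbent_footprint}
    for inp in present:
        key = "input:" + inp.name
        if key in maps:
            raise ValidationError(f"duplicate input species {inp.name!r}")
        maps[key] = gate.map_interval(inp)

    lo, hi = gate.incumbent_footprint
    start: State = frozenset({(inc_key, lo, hi, TAG_INCUMBENT)})

    def successors(state: State):
        occ: dict[int, Bound] = {}
        bound_keys = set()
        for entry in state:
            key, s, e, _tag = entry
            bound_keys.add(key)
            for p in range(s, e + 1):
                occ[p] = entry

        def shrink(entry: Bound, p: int):
            """Remove position p (an interval end) from a bound entry.

            Returns the replacement entry or None if the strand drops to
            zero held positions (and unbinds).
            """
            key, s, e, tag = entry
            if s == e:
                return None
            if p == s:
                return (key, s + 1, e, tag)
            return (key, s, e - 1, tag)

        # -- moves for free invader species --------------------------------
        for key, (mlo, mhi) in maps.items():
            if key == inc_key or key in bound_keys:
                continue
            for p in range(mlo, mhi + 1):
                if p not in occ:
                    tag = TAG_STRONG if p in exposed else TAG_JOINED
                    yield state | {(key, p, p, tag)}
                    continue
                victim = occ[p]
                vkey, vs, ve, vtag = victim
                if p not in (vs, ve):
                    continue  # only interval ends can be invaded
                if p in (1, n):
                    tag = TAG_WEAK
                elif _is_junction(occ, victim, p, n):
                    tag = TAG_JOINED
                else:
                    continue
                shrunk = shrink(victim, p)
                new = set(state)
                new.discard(victim)
                if shrunk is not None:
                    new.add(shrunk)
                new.add((key, p, p, tag))
                if shrunk is None and vkey == inc_key:
                    if not _valid_release([x for x in new], footprint, maps):
                        continue
                yield frozenset(new)

        # -- zip / migrate for bound strands --------------------------------
        for entry in state:
            key, s, e, tag = entry
            mlo, mhi = maps[key]
            for p, grown in ((s - 1, (key, s - 1, e, tag)),
                             (e + 1, (key, s, e + 1, tag))):
                if not (mlo <= p <= mhi):
                    continue
                new = set(state)
                new.discard(entry)
                if p not in occ:
                    new.add(grown)
                    yield frozenset(new)
                    continue
                victim = occ[p]
                if victim == entry:
                    continue
                vkey = victim[0]
                shrunk = shrink(victim, p)
                new.discard(victim)
                if shrunk is not None:
                    new.add(shrunk)
                new.add(grown)
                if shrunk is None and vkey == inc_key:
                    if not _valid_release([x for x in new], footprint, maps):
                        continue
                yield frozenset(new)

    seen = {start}
    frontier = deque([start])
    while frontier:
        state = frontier.popleft()
        for nxt in successors(state):
            if nxt in seen:
                continue
            if not any(entry[0] == inc_key for entry in nxt):
                return 1
            seen.add(nxt)
            if len(seen) > max_states:
                raise OracleInconclusiveError(
                    f"state budget of {max_states} states exceeded; "
                    "the search is inconclusive"
                )
            frontier.append(nxt)
    return 0


def _is_junction(occ: dict[int, Bound], victim: Bound, p: int, n: int) -> bool:
    """True if position p sits at a duplex junction that can breathe open.

    p is an end of the victim's held interval; the adjacent position on the
    far side of the victim must exist and be held by a *different* strand.
    """
    _key, vs, ve, _tag = victim
    beyond = p - 1 if p == vs else p + 1
    if not (1 <= beyond <= n):
        return False
    other = occ.get(beyond)
    return other is not None and other != victim
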