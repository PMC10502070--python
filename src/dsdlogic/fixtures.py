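"""Synthetic gate-system generator.

Produces structurally valid gate systems analogous to the three built-in
designs — a toehold-flanked reporter whose every input covers the footprint
(OR-like), a blunt full-footprint duplex with three overlapping inputs
(AND-like), a two-toehold reporter with two flank inputs and one
toehold-free middle input (MAJORITY-like) — plus fully random valid systems
for property testing.  Generation is deterministic in (kind, n_domains,
seed).
"""

from __future__ import annotations

import string

import numpy as np

from .core import (
    LABEL_FLUOROPHORE,
    LABEL_QUENCHER,
    Domain,
    GateSystem,
    Strand,
    ValidationError,
)

__all__ = ["FIXTURE_KINDS", "generate_fixture"]

FIXTURE_KINDS = ("OR-like", "AND-like", "MAJORITY-like", "random-valid")

_LETTERS = string.ascii_uppercase


def _template(n: int, footprint: tuple[int, int]) -> Strand:
    domains = []
    fp = set(range(footprint[0], footprint[1] + 1))
    for i in range(1, n + 1):
        role = "recognition" if i in fp else "toehold"
        length = 15 if role == "recognition" else 6
        domains.append(Domain(name=_LETTERS[i - 1], role=role, length_nt=length))
    return Strand("".join(d.name for d in domains), tuple(domains),
                  label=LABEL_QUENCHER)


def _substrand(template: Strand, lo: int, hi: int, label=None) -> Strand:
    domains = tuple(d.complement() for d in template.domains[lo - 1:hi])
    return Strand("".join(d.name for d in domains), domains, label=label)


def _gate(name, template, footprint, input_runs) -> GateSystem:
    incumbent = _substrand(template, *footprint, label=LABEL_FLUOROPHORE)
    inputs = tuple(_substrand(template, lo, hi) for lo, hi in input_runs)
    return GateSystem(
        name=name, template=template, incumbent=incumbent,
        incumbent_footprint=footprint, inputs=inputs,
    )


def generate_fixture(kind: str, n_domains: int, seed: int) -> GateSystem:
    """Generate a valid gate system of the requested structural family.

    ``n_domains`` is the template length (4..8 for the structured kinds,
    3..8 for random-valid; the enumeration oracle handles up to 8).
    """
    if kind not in FIXTURE_KINDS:
        raise ValidationError(
            f"unknown fixture kind {kind!r}; valid kinds: {', '.join(FIXTURE_KINDS)}"
        )
    rng = np.random.default_rng(seed)
    n = int(n_domains)
    if n > 8:
        raise ValidationError("n_domains must be <= 8 (oracle bound)")

    if kind == "OR-like":
        if n < 4:
            raise ValidationError("OR-like fixtures need n_domains >= 4")
        footprint = (2, n - 1)
        template = _template(n, footprint)
        runs = [(1, n - 1), (2, n), (1, n)]
        return _gate(f"OR-like-{n}-{seed}", template, footprint, runs)

    if kind == "AND-like":
        if n < 4:
            raise ValidationError("AND-like fixtures need n_domains >= 4")
        footprint = (1, n)
        template = _template(n, footprint)
        # three overlapping runs [1,p], [p,q], [q,n] with 1 < p < q < n
        p = int(rng.integers(2, n - 1))
        q = int(rng.integers(p + 1, n))
        runs = [(1, p), (q, n), (p, q)]  # inputs 1, 2 are the flanks; 3 bridges
        return _gate(f"AND-like-{n}-{seed}", template, footprint, runs)

    if kind == "MAJORITY-like":
        if n < 4:
            raise ValidationError("MAJORITY-like fixtures need n_domains >= 4")
        footprint = (2, n - 1)
        template = _template(n, footprint)
        # flanks [1,m] and [m+1,n] split the footprint; the middle input is
        # the reporter's run and has no anchor of its own
        m = int(rng.integers(2, n - 1))
        runs = [(1, m), (m + 1, n), footprint]
        return _gate(f"MAJORITY-like-{n}-{seed}", template, footprint, runs)

    # random-valid: arbitrary contiguous footprint and input runs
    if n < 3:
        raise ValidationError("random-valid fixtures need n_domains >= 3")
    lo = int(rng.integers(1, n))
    hi = int(rng.integers(lo, n + 1))
    footprint = (lo, hi)
    template = _template(n, footprint)
    runs = []
    used = set()
    while len(runs) < 3:
        a = int(rng.integers(1, n + 1))
        b = int(rng.integers(a, n + 1))
        if (a, b) == footprint and footprint in used:
            continue  # at most one reporter twin among the inputs
        if (a, b) in used:
            continue
        used.add((a, b))
        runs.append((a, b))
    return _gate(f"random-valid-{n}-{seed}", template, footprint, runs)
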