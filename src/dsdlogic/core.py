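"""Core data model for domain-level strand-displacement gate systems.

A *domain* is a contiguous stretch of DNA bases treated as an indivisible
hybridization unit, named by a (case-sensitive) identifier; the Watson-Crick
complement of a domain is written by swapping the case of its name, so ``F``
and ``f`` are complementary partners.  A *strand* is an ordered 5'->3' list of
domains, optionally end-labelled with a fluorophore (FAM) or a quencher
(BHQ1).  A *gate system* is an annealed template:incumbent duplex — the
quencher-labelled template holds the fluorophore-labelled incumbent (the
reporter) over a contiguous *footprint* of template positions — together with
exactly three named input strands.  Releasing the incumbent separates
fluorophore from quencher and produces signal.

The three built-in gates implement three-input OR, AND and MAJORITY logic:

=========  ==========  =========  =========  =====================
gate       template    incumbent  footprint  inputs (1, 2, 3)
=========  ==========  =========  =========  =====================
OR         E·F·H·G     fh         [2, 3]     efh, fhg, efhg
AND        A·B·C·D     abcd       [1, 4]     ab, cd, bc
MAJORITY   E·F·H·G     fh         [2, 3]     ef, hg, fh
=========  ==========  =========  =========  =====================
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Optional

__all__ = [
    "LABEL_FLUOROPHORE",
    "LABEL_QUENCHER",
    "STATE_ORDER",
    "Domain",
    "Strand",
    "GateSystem",
    "TruthTable",
    "TruthTableRow",
    "ValidationError",
    "complement",
    "build_gate_system",
    "paper_gate",
    "PAPER_GATE_NAMES",
]

LABEL_FLUOROPHORE = "fluorophore_FAM"
LABEL_QUENCHER = "quencher_BHQ1"
_LABELS = {LABEL_FLUOROPHORE, LABEL_QUENCHER, None}

#: The fixed presentation order of the eight input states of a three-input
#: gate: (0 0 0) (1 0 0) (0 1 0) (0 0 1) (1 1 0) (1 0 1) (0 1 1) (1 1 1).
STATE_ORDER: tuple[tuple[int, int, int], ...] = (
    (0, 0, 0), (1, 0, 0), (0, 1, 0), (0, 0, 1),
    (1, 1, 0), (1, 0, 1), (0, 1, 1), (1, 1, 1),
)

PAPER_GATE_NAMES = ("OR", "AND", "MAJORITY")


class ValidationError(ValueError):
    """A gate system, strand or specification violates a structural invariant."""


@dataclass(frozen=True)
class Domain:
    """A named hybridization unit.

    Parameters
    ----------
    name:
        Case-sensitive identifier; the complement is the case-swapped name.
    role:
        ``"toehold"`` (short, initiation site) or ``"recognition"`` (long).
        The role is metadata here; displacement semantics live in
        :mod:`dsdlogic.chains`.
    length_nt:
        Domain length in nucleotides, used by sequence design.
    """

    name: str
    role: str = "recognition"
    length_nt: int = 15

    def __post_init__(self) -> None:
        if not self.name:
            raise ValidationError("domain name must be nonempty")
        if self.name == self.name.swapcase():
            raise ValidationError(
                f"domain name {self.name!r} has no cased character; "
                "complement naming (case swap) would be ambiguous"
            )
        if self.role not in ("toehold", "recognition"):
            raise ValidationError(f"domain {self.name!r}: unknown role {self.role!r}")
        if self.length_nt <= 0:
            raise ValidationError(f"domain {self.name!r}: length_nt must be positive")

    @property
    def complement_name(self) -> str:
        return self.name.swapcase()

    @property
    def canonical_name(self) -> str:
        """Uppercase member of the (X, x) complement pair."""
        return self.name.upper()

    @property
    def is_canonical(self) -> bool:
        return self.name == self.name.upper()

    def complement(self) -> "Domain":
        return replace(self, name=self.name.swapcase())


@dataclass(frozen=True)
class Strand:
    """An ordered 5'->3' list of domains with an optional end label."""

    name: str
    domains: tuple[Domain, ...]
    label: Optional[str] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "domains", tuple(self.domains))
        if not self.name:
            raise ValidationError("strand name must be nonempty")
        if not self.domains:
            raise ValidationError(f"strand {self.name!r}: domain list is empty")
        if self.label not in _LABELS:
            raise ValidationError(
                f"strand {self.name!r}: label must be one of "
                f"{sorted(l for l in _LABELS if l)} or None, got {self.label!r}"
            )

    @property
    def domain_names(self) -> tuple[str, ...]:
        return tuple(d.name for d in self.domains)

    def complement(self) -> "Strand":
        """Antiparallel complement: reversed list of domain complements.

        The complement's name is the case-swapped, reversed name, so the
        operation is an involution on every field.
        """
        return Strand(
            name=self.name.swapcase()[::-1],
            domains=tuple(d.complement() for d in reversed(self.domains)),
            label=self.label,
        )


def complement(x):
    """Watson-Crick complement of a :class:`Domain` or :class:`Strand`.

    For a domain the partner is the case-swapped name; for a strand the
    result is the reversed list of domain complements (antiparallel
    convention).  ``complement`` is an involution.
    """
    if isinstance(x, (Domain, Strand)):
        return x.complement()
    raise ValidationError(f"cannot complement object of type {type(x).__name__}")


@dataclass(frozen=True)
class GateSystem:
    """An annealed reporter duplex plus exactly three named input strands.

    ``incumbent_footprint`` is the contiguous, 1-based inclusive interval of
    template domain positions initially paired with the incumbent.
    """

    name: str
    template: Strand
    incumbent: Strand
    incumbent_footprint: tuple[int, int]
    inputs: tuple[Strand, Strand, Strand]

    def __post_init__(self) -> None:
        object.__setattr__(self, "inputs", tuple(self.inputs))
        object.__setattr__(
            self, "incumbent_footprint", tuple(self.incumbent_footprint)
        )
        _validate_gate(self)

    # -- geometry helpers ------------------------------------------------

    @property
    def n_positions(self) -> int:
        return len(self.template.domains)

    @property
    def footprint_positions(self) -> frozenset[int]:
        lo, hi = self.incumbent_footprint
        return frozenset(range(lo, hi + 1))

    def template_domain(self, position: int) -> Domain:
        return self.template.domains[position - 1]

    def map_interval(self, strand: Strand) -> tuple[int, int]:
        """Template interval a strand invades, as 1-based inclusive bounds.

        The strand's domains must be the complements of a contiguous run of
        template domains (orientation-insensitively: figure naming lists a
        strand's domains in template order).
        """
        interval = _map_interval_or_none(self.template, strand)
        if interval is None:
            raise ValidationError(
                f"strand {strand.name!r} is not complementary to a contiguous "
                f"run of template {self.template.name!r} domains"
            )
        return interval

    def all_strands(self) -> tuple[Strand, ...]:
        return (self.template, self.incumbent) + self.inputs

    def domains(self) -> tuple[Domain, ...]:
        """All distinct domains of the system (template domains + complements)."""
        seen: dict[str, Domain] = {}
        for strand in self.all_strands():
            for d in strand.domains:
                seen.setdefault(d.name, d)
        return tuple(seen.values())


def _map_interval_or_none(template: Strand, strand: Strand):
    tmpl_names = [d.name for d in template.domains]
    want = sorted(d.complement_name for d in strand.domains)
    k = len(want)
    for start in range(len(tmpl_names) - k + 1):
        run = sorted(tmpl_names[start:start + k])
        if run == want:
            return (start + 1, start + k)
    return None


def _validate_gate(gate: GateSystem) -> None:
    tmpl = gate.template
    names = [d.name for d in tmpl.domains]
    if len(set(names)) != len(names):
        raise ValidationError(
            f"template {tmpl.name!r} has repeated domains; positions would be ambiguous"
        )
    canon = {n.upper() for n in names}
    if len(canon) != len(names):
        raise ValidationError(
            f"template {tmpl.name!r} carries a domain and its complement"
        )
    lo, hi = gate.incumbent_footprint
    n = gate.n_positions
    if not (1 <= lo <= hi <= n):
        raise ValidationError(
            f"incumbent footprint [{lo}, {hi}] is not a contiguous interval "
            f"within template positions 1..{n}"
        )
    # incumbent must be the complement of exactly the footprint run
    want = sorted(d.complement_name for d in gate.incumbent.domains)
    have = sorted(names[lo - 1:hi])
    if want != have:
        raise ValidationError(
            f"incumbent {gate.incumbent.name!r} is not complementary to "
            f"template positions {lo}..{hi}"
        )
    if len(gate.inputs) != 3:
        raise ValidationError(
            f"a gate takes exactly 3 inputs, got {len(gate.inputs)}"
        )
    if gate.template.label != LABEL_QUENCHER:
        raise ValidationError(f"template {tmpl.name!r} must carry the quencher label")
    if gate.incumbent.label != LABEL_FLUOROPHORE:
        raise ValidationError(
            f"incumbent {gate.incumbent.name!r} must carry the fluorophore label"
        )
    for inp in gate.inputs:
        if _map_interval_or_none(tmpl, inp) is None:
            raise ValidationError(
                f"input {inp.name!r} is not complementary to a contiguous run "
                f"of template {tmpl.name!r} domains"
            )
    # Name uniqueness.  One sanctioned exception: an input may share the
    # incumbent's name iff it is the incumbent's unlabelled twin (identical
    # domain list) — the MAJORITY gate's third input is the reporter sequence.
    strand_names = [s.name for s in gate.all_strands()]
    seen: dict[str, Strand] = {}
    for s in gate.all_strands():
        if s.name in seen:
            twin_ok = (
                seen[s.name] is gate.incumbent
                and s in gate.inputs
                and s.domain_names == gate.incumbent.domain_names
            )
            if not twin_ok:
                raise ValidationError(f"duplicate strand name {s.name!r}")
        seen[s.name] = seen.get(s.name, s)
    input_names = [s.name for s in gate.inputs]
    if len(set(input_names)) != 3:
        raise ValidationError(f"duplicate input strand names: {input_names}")
    del strand_names


@dataclass(frozen=True)
class TruthTableRow:
    inputs: tuple[int, int, int]
    output: int
    signal: Optional[float] = None


@dataclass(frozen=True)
class TruthTable:
    """Eight rows mapping input triples to outputs, in the fixed state order."""

    gate_name: str
    rows: tuple[TruthTableRow, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "rows", tuple(self.rows))
        if tuple(r.inputs for r in self.rows) != STATE_ORDER:
            raise ValidationError(
                "truth table must have exactly 8 rows in the order "
                "(000)(100)(010)(001)(110)(101)(011)(111)"
            )

    @property
    def outputs(self) -> tuple[int, ...]:
        return tuple(r.output for r in self.rows)

    @property
    def signals(self) -> tuple[Optional[float], ...]:
        return tuple(r.signal for r in self.rows)

    def high_states(self) -> tuple[tuple[int, int, int], ...]:
        return tuple(r.inputs for r in self.rows if r.output == 1)

    def to_csv(self, path_or_buf=None):
        """Write as CSV (columns input1,input2,input3,output[,signal])."""
        import pandas as pd

        data = {
            "input1": [r.inputs[0] for r in self.rows],
            "input2": [r.inputs[1] for r in self.rows],
            "input3": [r.inputs[2] for r in self.rows],
            "output": [r.output for r in self.rows],
        }
        if any(r.signal is not None for r in self.rows):
            data["signal"] = [r.signal for r in self.rows]
        return pd.DataFrame(data).to_csv(path_or_buf, index=False)

    @classmethod
    def from_csv(cls, path_or_buf, gate_name: str = "") -> "TruthTable":
        import pandas as pd

        df = pd.read_csv(path_or_buf)
        rows = []
        for _, rec in df.iterrows():
            rows.append(
                TruthTableRow(
                    inputs=(int(rec["input1"]), int(rec["input2"]), int(rec["input3"])),
                    output=int(rec["output"]),
                    signal=float(rec["signal"]) if "signal" in df.columns else None,
                )
            )
        return cls(gate_name=gate_name, rows=tuple(rows))


# ---------------------------------------------------------------------------
# construction
# ---------------------------------------------------------------------------

def build_gate_system(spec: Mapping) -> GateSystem:
    """Build a validated :class:`GateSystem` from a specification record.

    ``spec`` is a mapping with sections ``domains`` (list of records with
    ``name`` and optional ``role``/``length_nt``; lowercase complements are
    implied), ``strands`` (records with ``name``, ``domains`` list, optional
    ``label``) and ``gate`` (``template``, ``incumbent``,
    ``incumbent_footprint`` two-element list, ``inputs`` three names).
    See :mod:`dsdlogic.gatefile` for the on-disk YAML/JSON rendering.
    """
    for section in ("domains", "strands", "gate"):
        if section not in spec:
            raise ValidationError(f"specification is missing section {section!r}")
    domains: dict[str, Domain] = {}
    for rec in spec["domains"]:
        d = Domain(
            name=rec["name"],
            role=rec.get("role", "recognition"),
            length_nt=int(rec.get("length_nt", 15)),
        )
        if d.name in domains:
            raise ValidationError(f"duplicate domain name {d.name!r}")
        domains[d.name] = d
    # implied complements
    for d in list(domains.values()):
        comp = d.complement()
        existing = domains.get(comp.name)
        if existing is None:
            domains[comp.name] = comp
        elif existing.length_nt != d.length_nt:
            raise ValidationError(
                f"domains {d.name!r} and {comp.name!r} are complements but "
                f"declare different lengths"
            )

    strands: dict[str, Strand] = {}
    strand_list: list[Strand] = []
    for rec in spec["strands"]:
        missing = [dn for dn in rec["domains"] if dn not in domains]
        if missing:
            raise ValidationError(
                f"strand {rec['name']!r} references unknown domain(s) {missing}"
            )
        s = Strand(
            name=rec["name"],
            domains=tuple(domains[dn] for dn in rec["domains"]),
            label=rec.get("label"),
        )
        if s.name in strands:
            raise ValidationError(f"duplicate strand name {s.name!r}")
        strand_list.append(s)
        strands[s.name] = s

    g = spec["gate"]
    for key in ("template", "incumbent", "incumbent_footprint", "inputs"):
        if key not in g:
            raise ValidationError(f"gate section is missing field {key!r}")

    def _lookup(name: str, role: str) -> Strand:
        if name not in strands:
            raise ValidationError(f"gate {role} {name!r} is not a declared strand")
        return strands[name]

    template = _lookup(g["template"], "template")
    incumbent = _lookup(g["incumbent"], "incumbent")
    if len(g["inputs"]) != 3:
        raise ValidationError(
            f"a gate takes exactly 3 inputs, got {len(g['inputs'])}"
        )
    inputs = []
    for nm in g["inputs"]:
        if nm == incumbent.name:
            # the unlabelled twin of the reporter (MAJORITY's third input)
            twin = next(
                (s for s in strand_list
                 if s.name == nm and s.label is None
                 and s.domain_names == incumbent.domain_names),
                None,
            )
            inputs.append(twin if twin is not None
                          else replace(incumbent, label=None))
        else:
            inputs.append(_lookup(nm, "input"))
    footprint = tuple(int(v) for v in g["incumbent_footprint"])
    if len(footprint) != 2:
        raise ValidationError(
            "incumbent_footprint must be a [start, end] pair of 1-based positions"
        )
    return GateSystem(
        name=str(g.get("name", spec.get("name", "gate"))),
        template=template,
        incumbent=incumbent,
        incumbent_footprint=footprint,  # type: ignore[arg-type]
        inputs=tuple(inputs),  # type: ignore[arg-type]
    )


def _mk(name: str, role: str = "recognition", length: int = 15) -> Domain:
    return Domain(name=name, role=role, length_nt=length)


def paper_gate(name: str) -> GateSystem:
    """Return one of the three built-in gates: ``OR``, ``AND`` or ``MAJORITY``.

    OR: template E·F·H·G (BHQ1) holds reporter fh on {F,H}; any of efh, fhg,
    efhg can initiate at an exposed flanking toehold (E or G) and displace fh.

    AND: blunt duplex ABCD:abcd (no exposed toehold); only the cooperative
    hand-over-hand action of ab, bc and cd together strips abcd.

    MAJORITY: same reporter duplex as OR, but the inputs ef, hg and fh each
    cover too little alone — any two of them suffice.
    """
    key = name.upper()
    if key not in PAPER_GATE_NAMES:
        raise ValidationError(
            f"unknown built-in gate {name!r}; valid names: {', '.join(PAPER_GATE_NAMES)}"
        )
    if key in ("OR", "MAJORITY"):
        E, F, H, G = (
            _mk("E", "toehold", 6), _mk("F"), _mk("H"), _mk("G", "toehold", 6)
        )
        e, f, h, g = (d.complement() for d in (E, F, H, G))
        template = Strand("EFHG", (E, F, H, G), label=LABEL_QUENCHER)
        incumbent = Strand("fh", (f, h), label=LABEL_FLUOROPHORE)
        if key == "OR":
            inputs = (
                Strand("efh", (e, f, h)),
                Strand("fhg", (f, h, g)),
                Strand("efhg", (e, f, h, g)),
            )
        else:
            inputs = (
                Strand("ef", (e, f)),
                Strand("hg", (h, g)),
                Strand("fh", (f, h)),  # unlabelled twin of the reporter
            )
        return GateSystem(
            name=key, template=template, incumbent=incumbent,
            incumbent_footprint=(2, 3), inputs=inputs,
        )
    A, B, C, D = _mk("A"), _mk("B"), _mk("C"), _mk("D")
    a, b, c, d = (x.complement() for x in (A, B, C, D))
    template = Strand("ABCD", (A, B, C, D), label=LABEL_QUENCHER)
    incumbent = Strand("abcd", (a, b, c, d), label=LABEL_FLUOROPHORE)
    inputs = (Strand("ab", (a, b)), Strand("cd", (c, d)), Strand("bc", (b, c)))
    return GateSystem(
        name="AND", template=template, incumbent=incumbent,
        incumbent_footprint=(1, 4), inputs=inputs,
    )
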