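"""Nucleotide-level sequence design for gate systems.

Domains receive random DNA sequences subject to the usual strand-
displacement design hygiene: complementary domain pairs (X, x) are exact
reverse complements, GC content stays inside a window, homopolymer runs are
capped at four bases, and (by default) non-complementary domains avoid
sharing k-mers with each other's reverse complements so that spurious
cross-hybridization toeholds are not planted.  Strand sequences are the
5'->3' concatenation of their domain sequences in listed order.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import Domain, GateSystem, Strand, ValidationError

__all__ = [
    "SequenceAssignment",
    "assign_sequences",
    "validate_orthogonality",
    "write_fasta",
    "read_fasta",
]

_ALPHABET = "ACGT"


def _revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


@dataclass(frozen=True)
class SequenceAssignment:
    """Mapping from domain name to an ACGT string.

    Complement pairs map to exact reverse complements; strand sequences are
    derived by concatenation.
    """

    sequences: dict  # domain name -> str

    def __post_init__(self) -> None:
        for name, seq in self.sequences.items():
            if set(seq) - set(_ALPHABET):
                raise ValidationError(
                    f"domain {name!r}: sequence contains non-ACGT characters"
                )
        for name, seq in self.sequences.items():
            partner = name.swapcase()
            if partner in self.sequences:
                if self.sequences[partner] != _revcomp(seq):
                    raise ValidationError(
                        f"domains {name!r} and {partner!r} are not reverse "
                        "complements"
                    )

    def domain(self, name: str) -> str:
        if name not in self.sequences:
            raise ValidationError(f"no sequence assigned to domain {name!r}")
        return self.sequences[name]

    def strand(self, strand: Strand) -> str:
        """5'->3' concatenation of the strand's domain sequences."""
        return "".join(self.domain(d.name) for d in strand.domains)


def _gc_window(length: int, gc_range: tuple[float, float]) -> tuple[int, int]:
    lo_f, hi_f = gc_range
    if not (0.0 <= lo_f <= hi_f <= 1.0):
        raise ValidationError(f"gc_range {gc_range!r} is not a valid interval")
    lo = int(np.ceil(lo_f * length))
    hi = int(np.floor(hi_f * length))
    return lo, hi


def _max_run(seq: str) -> int:
    best = run = 1
    for a, b in zip(seq, seq[1:]):
        run = run + 1 if a == b else 1
        best = max(best, run)
    return best


def _kmers(seq: str, k: int) -> set:
    if len(seq) < k:
        return set()
    return {seq[i:i + k] for i in range(len(seq) - k + 1)}


def assign_sequences(
    gate: GateSystem,
    seed: int,
    gc_range: tuple[float, float] = (0.3, 0.7),
    max_homopolymer: int = 4,
    avoid_shared_kmers: Optional[int] = 6,
    max_tries: int = 20_000,
) -> SequenceAssignment:
    """Draw a deterministic random sequence assignment for a gate system.

    One sequence is drawn per complement pair (for the uppercase member; the
    lowercase partner is its reverse complement).  Each candidate must fall
    inside ``gc_range``, contain no homopolymer run longer than
    ``max_homopolymer``, and — unless ``avoid_shared_kmers`` is None — share
    no k-mer with previously placed non-complementary domains or their
    reverse complements.

    Raises :class:`ValidationError`, naming the domain, when the constraints
    are unsatisfiable for its length.
    """
    rng = np.random.default_rng(seed)
    domains = gate.domains()
    canon: dict[str, Domain] = {}
    for d in domains:
        canon.setdefault(d.canonical_name, d if d.is_canonical else d.complement())

    sequences: dict[str, str] = {}
    placed_words: set = set()  # k-mers of all placed strands, both orientations
    for name in sorted(canon):
        d = canon[name]
        lo, hi = _gc_window(d.length_nt, gc_range)
        if lo > hi:
            raise ValidationError(
                f"domain {name!r}: no sequence of length {d.length_nt} has GC "
                f"fraction within {gc_range!r}"
            )
        for _ in range(max_tries):
            seq = "".join(rng.choice(list(_ALPHABET), size=d.length_nt))
            gc = seq.count("G") + seq.count("C")
            if not (lo <= gc <= hi):
                continue
            if _max_run(seq) > max_homopolymer:
                continue
            if avoid_shared_kmers is not None:
                k = avoid_shared_kmers
                words = _kmers(seq, k) | _kmers(_revcomp(seq), k)
                if words & placed_words:
                    continue
            else:
                words = set()
            break
        else:
            raise ValidationError(
                f"domain {name!r}: could not draw a sequence satisfying the "
                f"constraints in {max_tries} tries"
            )
        sequences[d.name] = seq
        sequences[d.complement_name] = _revcomp(seq)
        placed_words |= words
    return SequenceAssignment(sequences=dict(sequences))


def validate_orthogonality(
    assignment: SequenceAssignment, k: int = 6
) -> list[tuple[str, str, str]]:
    """Cross-hybridization screen.

    Reports every pair of non-complementary domains that shares a length-k
    word with the reverse complement of the other (such a shared word is a
    spurious toehold).  Returns a list of (domain_a, domain_b, shared_word);
    an empty list is a pass.
    """
    if k < 4:
        raise ValidationError("word length k must be >= 4")
    names = sorted(assignment.sequences)
    report: list[tuple[str, str, str]] = []
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            if b == a.swapcase():
                continue
            shared = sorted(
                _kmers(assignment.sequences[a], k)
                & _kmers(_revcomp(assignment.sequences[b]), k)
            )
            for word in shared:
                report.append((a, b, word))
    return report


def orthogonality_report_tsv(report, path) -> None:
    import pandas as pd

    pd.DataFrame(report, columns=["domain_a", "domain_b", "shared_word"]).to_csv(
        path, sep="\t", index=False
    )


def write_fasta(gate: GateSystem, assignment: SequenceAssignment, path) -> None:
    """One record per strand of the gate system (name = strand name).

    When an input is the incumbent's unlabelled twin (same name, same
    domains), a single record is written.
    """
    records = []
    seen = set()
    for strand in gate.all_strands():
        if strand.name in seen:
            continue
        seen.add(strand.name)
        records.append(SeqRecord(
            Seq(assignment.strand(strand)), id=strand.name, description="",
        ))
    SeqIO.write(records, path, "fasta")


def read_fasta(gate: GateSystem, path) -> SequenceAssignment:
    """Reconstruct and validate a sequence assignment from FASTA.

    Every strand of the gate must have a record; record lengths must match
    the strand's domain lengths; only ACGT is accepted.  The reconstructed
    per-domain sequences must be mutually consistent (each domain seen in
    several strands must read identically) and complement pairs must be
    reverse complements, otherwise a :class:`ValidationError` names the
    offending record.
    """
    by_name = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        by_name[rec.id] = str(rec.seq).upper()
    sequences: dict[str, str] = {}
    for strand in gate.all_strands():
        if strand.name not in by_name:
            raise ValidationError(f"FASTA record {strand.name!r} is missing")
        seq = by_name[strand.name]
        if set(seq) - set(_ALPHABET):
            raise ValidationError(
                f"FASTA record {strand.name!r} contains non-ACGT characters"
            )
        expected = sum(d.length_nt for d in strand.domains)
        if len(seq) != expected:
            raise ValidationError(
                f"FASTA record {strand.name!r} has length {len(seq)}, "
                f"expected {expected}"
            )
        offset = 0
        for d in strand.domains:
            piece = seq[offset:offset + d.length_nt]
            offset += d.length_nt
            if d.name in sequences and sequences[d.name] != piece:
                raise ValidationError(
                    f"FASTA record {strand.name!r}: domain {d.name!r} reads "
                    f"{piece} but was previously {sequences[d.name]}"
                )
            sequences[d.name] = piece
    try:
        return SequenceAssignment(sequences=sequences)
    except ValidationError as exc:
        raise ValidationError(f"FASTA at {path}: {exc}") from exc
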