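"""Nucleotide primitives for in-frame expression-library analysis.

This module owns the low-level sequence machinery shared by the rest of the
package: a strict DNA alphabet, the degenerate primer symbols used in
library design (D, H, K, W plus the concrete bases), the standard genetic
code, frame-aware translation and stop-codon scanning, and streaming FASTA
I/O.

Conventions
-----------
* Sequences are handled on the sense (mRNA) strand only; there is no
  reverse-complement scanning anywhere in the package, because the method
  concerns translation of the cloned sense strand.
* Coordinates are 0-based half-open internally. User-facing output (CLI)
  converts to 1-based where appropriate.
* Triplet scans use complete codons only: a trailing partial codon (1-2 nt)
  is ignored.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator, Optional, Union

from Bio import SeqIO
from Bio.Data.CodonTable import standard_dna_table
from Bio.SeqIO.FastaIO import FastaWriter
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

# ---------------------------------------------------------------------------
# Errors
# ---------------------------------------------------------------------------


class InframeError(Exception):
    """Base class for package errors."""


class AlphabetError(InframeError, ValueError):
    """A sequence contains characters outside the accepted alphabet."""


class InputFormatError(InframeError, ValueError):
    """A file is not in the expected format (e.g. malformed FASTA)."""


class ConstraintError(InframeError, ValueError):
    """A domain invariant is violated (primer, construct or model)."""


# ---------------------------------------------------------------------------
# Alphabets and degenerate symbols
# ---------------------------------------------------------------------------

DNA_BASES = "ACGT"

#: Degenerate-symbol semantics used in the primer design: each code denotes
#: an equal mixture of the listed bases.  Concrete bases expand to
#: themselves.  Codes outside this table (N, R, Y, ...) are deliberately
#: rejected: the primer templates use only these eight symbols.
DEGENERATE_EXPANSIONS: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "K": frozenset("GT"),
    "W": frozenset("AT"),
}

DEGENERATE_CODES = frozenset(DEGENERATE_EXPANSIONS)


def expansion_of(code: str) -> frozenset[str]:
    """Return the base set denoted by a degenerate (or concrete) symbol."""
    try:
        return DEGENERATE_EXPANSIONS[code]
    except KeyError:
        raise AlphabetError(
            f"unsupported degenerate symbol {code!r}; "
            f"allowed: {''.join(sorted(DEGENERATE_CODES))}"
        ) from None


def validate_template(template: str) -> str:
    """Canonicalize and validate a degenerate template string."""
    t = template.upper().replace("U", "T")
    bad = set(t) - DEGENERATE_CODES
    if bad:
        raise AlphabetError(
            f"template contains unsupported symbols {sorted(bad)}; "
            f"allowed: {''.join(sorted(DEGENERATE_CODES))}"
        )
    return t


# ---------------------------------------------------------------------------
# NucSeq
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class NucSeq:
    """A validated DNA sequence over {A,C,G,T}.

    Input is canonicalized at construction: lowercase is uppercased and 'U'
    (RNA notation) is mapped to 'T'.  Any other character raises
    :class:`AlphabetError`.  Empty sequences are rejected unless
    ``allow_empty=True`` is passed (used for optional construct parts such
    as an absent linker).
    """

    bases: str
    id: Optional[str] = None

    def __init__(self, bases: str, id: Optional[str] = None, *, allow_empty: bool = False):
        canonical = bases.upper().replace("U", "T")
        bad = set(canonical) - set(DNA_BASES)
        if bad:
            raise AlphabetError(
                f"sequence{' ' + id if id else ''} contains non-ACGT characters: {sorted(bad)}"
            )
        if not canonical and not allow_empty:
            raise AlphabetError("empty sequence not allowed here")
        object.__setattr__(self, "bases", canonical)
        object.__setattr__(self, "id", id)

    def __len__(self) -> int:
        return len(self.bases)

    def __str__(self) -> str:
        return self.bases

    def __getitem__(self, item) -> str:
        return self.bases[item]


SeqLike = Union[str, NucSeq]


def as_bases(seq: SeqLike) -> str:
    """Coerce a str or NucSeq to a validated, canonical base string."""
    if isinstance(seq, NucSeq):
        return seq.bases
    return NucSeq(seq, allow_empty=True).bases


# ---------------------------------------------------------------------------
# Genetic code
# ---------------------------------------------------------------------------


def _build_standard_table() -> tuple[frozenset[str], dict[str, str]]:
    fwd = dict(standard_dna_table.forward_table)
    stops = frozenset(standard_dna_table.stop_codons)
    aa_map = {**fwd, **{c: "*" for c in stops}}
    return stops, aa_map


@dataclass(frozen=True)
class CodonTable:
    """The standard genetic code with stop codons rendered as '*'."""

    stop_codons: frozenset[str]
    aa_map: dict[str, str] = field(repr=False)

    def __post_init__(self):
        if len(self.aa_map) != 64:
            raise ConstraintError(f"codon table must map 64 codons, got {len(self.aa_map)}")
        if len(self.stop_codons) != 3:
            raise ConstraintError("codon table must declare exactly 3 stop codons")


_stops, _aa_map = _build_standard_table()
STANDARD_TABLE = CodonTable(stop_codons=_stops, aa_map=_aa_map)
STOP_CODONS = STANDARD_TABLE.stop_codons  # {TAA, TAG, TGA}

TRUNCATE_AT_STOP = "truncate_at_stop"
READ_THROUGH = "read_through"


def iter_codons(seq: SeqLike, frame: int = 0) -> Iterator[str]:
    """Yield the complete codons of ``seq`` starting at ``frame`` (0|1|2)."""
    bases = as_bases(seq)
    if frame not in (0, 1, 2):
        raise ValueError(f"frame must be 0, 1 or 2, got {frame}")
    for i in range(frame, len(bases) - 2, 3):
        yield bases[i : i + 3]


def translate(seq: SeqLike, frame: int = 0, stop_policy: str = TRUNCATE_AT_STOP) -> str:
    """Translate complete codons of ``seq`` in the given frame.

    With ``truncate_at_stop`` the peptide ends at (and excludes everything
    after) the first stop codon, which is not itself included.  With
    ``read_through`` stops are rendered as '*' and translation continues to
    the last complete codon.  A trailing partial codon is ignored.
    """
    bases = as_bases(seq)
    if frame >= len(bases):
        raise ValueError(f"frame {frame} is not inside a sequence of length {len(bases)}")
    if stop_policy not in (TRUNCATE_AT_STOP, READ_THROUGH):
        raise ValueError(f"unknown stop_policy {stop_policy!r}")
    aa = STANDARD_TABLE.aa_map
    out = []
    for codon in iter_codons(bases, frame):
        residue = aa[codon]
        if residue == "*" and stop_policy == TRUNCATE_AT_STOP:
            break
        out.append(residue)
    return "".join(out)


def first_stop_codon_index(seq: SeqLike, frame: int = 0) -> Optional[int]:
    """0-based index of the first complete codon that is a stop, or None.

    Scans only the ⌊(L - frame)/3⌋ complete codons; trailing bases that do
    not form a full triplet are never counted as stops.
    """
    for i, codon in enumerate(iter_codons(seq, frame)):
        if codon in STOP_CODONS:
            return i
    return None


def matches_template(seq: SeqLike, template: str) -> bool:
    """True iff every base of ``seq`` lies in the corresponding template
    symbol's expansion.  Lengths must agree."""
    bases = as_bases(seq)
    t = validate_template(template)
    if len(bases) != len(t):
        raise ValueError(
            f"sequence length {len(bases)} does not match template length {len(t)}"
        )
    return all(b in DEGENERATE_EXPANSIONS[s] for b, s in zip(bases, t))


# ---------------------------------------------------------------------------
# FASTA I/O
# ---------------------------------------------------------------------------

PathOrHandle = Union[str, Path, IO[str]]


def iter_raw_fasta(source: PathOrHandle) -> Iterator[tuple[str, str]]:
    """Stream (id, sequence) pairs from a FASTA file.

    Case is canonicalized to upper and 'U' mapped to 'T'; no further
    alphabet validation is performed here so that callers can implement
    their own policy for ambiguous bases (see utr_stats).  Raises
    :class:`InputFormatError` if the file does not start with a FASTA
    header.
    """
    own = isinstance(source, (str, Path))
    handle = open(source) if own else source
    try:
        pos = handle.tell() if handle.seekable() else None
        lineno = 0
        for line in handle:
            lineno += 1
            if line.strip():
                if not line.startswith(">"):
                    raise InputFormatError(
                        f"not a FASTA file: line {lineno} should start with '>'"
                    )
                break
        if pos is not None:
            handle.seek(pos)
        for rec in SeqIO.parse(handle, "fasta"):
            yield rec.id, str(rec.seq).upper().replace("U", "T")
    finally:
        if own:
            handle.close()


def read_fasta(source: PathOrHandle) -> Iterator[NucSeq]:
    """Stream strictly validated :class:`NucSeq` records from a FASTA file.

    Non-ACGT characters raise :class:`AlphabetError` naming the record.
    """
    for rec_id, bases in iter_raw_fasta(source):
        yield NucSeq(bases, id=rec_id)


def write_fasta(records: Iterable[SeqLike], dest: PathOrHandle, width: int = 60) -> int:
    """Write records to FASTA (wrapped at ``width`` columns); returns count.

    Records without an id are numbered ``seq_1, seq_2, ...`` in order.
    """
    seq_records = []
    for i, rec in enumerate(records, start=1):
        rec_id = rec.id if isinstance(rec, NucSeq) and rec.id else f"seq_{i}"
        seq_records.append(SeqRecord(Seq(as_bases(rec)), id=rec_id, description=""))
    own = isinstance(dest, (str, Path))
    handle = open(dest, "w") if own else dest
    try:
        writer = FastaWriter(handle, wrap=width)
        n = writer.write_file(seq_records)
    finally:
        if own:
            handle.close()
    return n
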