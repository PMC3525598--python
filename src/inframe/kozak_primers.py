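"""Degenerate Kozak forward-primer set: representation, expansion, matching.

An in-frame cDNA expression library is built with forward primers that
anneal directly at the translational start site, so that cloned inserts
begin at ATG and 5'-UTR sequence is excluded.  To cover the sequence
diversity of vertebrate Kozak contexts, the primer set combines two
concrete primers carrying the most frequent consensus contexts with two
degenerate primer mixes whose variable positions are equal-mixture symbols
(D = A/G/T, H = A/C/T, K = G/T, W = A/T).

Each primer is a constant 16-nt ligation sequence (used for
homologous-recombination cloning, not annealing) followed by a 16-symbol
Kozak-region template spanning positions -12..+4 around the start codon,
with ATG fixed at +1..+3.

Coordinate systems
------------------
Three equivalent namings for the Kozak region are used:

====================  ==========================
internal window index  0 .. 15  (0-based)
primer/table position  17 .. 32
Kozak coordinate       -12 .. -1, +1 .. +3, +4
====================  ==========================
"""

from __future__ import annotations

import csv
import itertools
from dataclasses import dataclass
from math import prod
from pathlib import Path
from typing import IO, Iterator, Optional, Sequence, Union

import numpy as np

from .seqcore import (
    DEGENERATE_EXPANSIONS,
    ConstraintError,
    InputFormatError,
    SeqLike,
    as_bases,
    matches_template,
    validate_template,
)

#: Constant 5' ligation/homology segment shared by all built-in forward
#: primers (primer positions 1-16); serves In-Fusion cloning, not annealing.
LIGATION_SEQ = "CGGAGGAAGCGGATCC"

#: The polyT reverse primer used for first-strand synthesis, recorded for
#: reference; its 5' segment TAGATCCGGTGGATC is the 3'-side ligation
#: sequence.  Not used computationally.
POLYT_REVERSE_PRIMER = "TAGATCCGGTGGATCCTTTTTTTTTTTTTTTTTTTTTTTTTTTTTTGC"

KOZAK_WINDOW_LEN = 16
_ATG_SLICE = slice(12, 15)  # window indices of the fixed start codon


def window_index_to_table_pos(i: int) -> int:
    """Internal window index (0-15) -> primer/table position (17-32)."""
    if not 0 <= i < KOZAK_WINDOW_LEN:
        raise ValueError(f"window index out of range: {i}")
    return i + 17


def window_index_to_kozak_coord(i: int) -> int:
    """Internal window index -> Kozak coordinate (-12..-1, +1..+4).

    There is no position 0 in Kozak numbering; -1 abuts +1 (the A of ATG).
    """
    if not 0 <= i < KOZAK_WINDOW_LEN:
        raise ValueError(f"window index out of range: {i}")
    return i - 12 if i < 12 else i - 11


def kozak_coord_to_window_index(c: int) -> int:
    """Kozak coordinate (-12..-1, +1..+4) -> internal window index."""
    if -12 <= c <= -1:
        return c + 12
    if 1 <= c <= 4:
        return c + 11
    raise ValueError(f"Kozak coordinate out of range: {c}")


@dataclass(frozen=True)
class KozakContext:
    """A concrete 16-nt window spanning -12..+4 of an annotated start codon.

    The start codon ATG is fixed at +1..+3 (window indices 12-14).
    """

    window: str

    def __post_init__(self):
        w = as_bases(self.window)
        if len(w) != KOZAK_WINDOW_LEN:
            raise ConstraintError(
                f"Kozak context must be {KOZAK_WINDOW_LEN} nt, got {len(w)}"
            )
        if w[_ATG_SLICE] != "ATG":
            raise ConstraintError(
                f"Kozak context positions +1..+3 must be ATG, got {w[_ATG_SLICE]}"
            )
        object.__setattr__(self, "window", w)

    def __str__(self) -> str:
        return self.window


@dataclass(frozen=True)
class DegeneratePrimer:
    """A forward-primer template: ligation sequence + degenerate Kozak region.

    ``kozak_template`` is a 16-symbol string over {A,C,G,T,D,H,K,W} whose
    positions 13-15 (1-based; window indices 12-14) are exactly A,T,G.  The
    full concrete primer is ``ligation_seq`` followed by one expansion of
    the template.  ``mix_weight`` is the primer's relative proportion in
    the PCR mix.
    """

    name: str
    ligation_seq: str
    kozak_template: str
    mix_weight: float

    def __post_init__(self):
        object.__setattr__(self, "ligation_seq", as_bases(self.ligation_seq))
        t = validate_template(self.kozak_template)
        if len(t) != KOZAK_WINDOW_LEN:
            raise ConstraintError(
                f"primer {self.name!r}: Kozak template must be "
                f"{KOZAK_WINDOW_LEN} symbols, got {len(t)}"
            )
        if t[_ATG_SLICE] != "ATG":
            raise ConstraintError(
                f"primer {self.name!r}: template positions +1..+3 must be "
                f"ATG, got {t[_ATG_SLICE]}"
            )
        if self.mix_weight < 0:
            raise ConstraintError(f"primer {self.name!r}: negative mix weight")
        object.__setattr__(self, "kozak_template", t)

    @property
    def degenerate_positions(self) -> tuple[int, ...]:
        """Window indices whose symbol expands to more than one base."""
        return tuple(
            i
            for i, s in enumerate(self.kozak_template)
            if len(DEGENERATE_EXPANSIONS[s]) > 1
        )


@dataclass(frozen=True)
class PrimerSet:
    """An ordered, weighted collection of degenerate primers."""

    primers: tuple[DegeneratePrimer, ...]

    def __post_init__(self):
        object.__setattr__(self, "primers", tuple(self.primers))
        names = [p.name for p in self.primers]
        if len(set(names)) != len(names):
            raise ConstraintError("primer names must be unique")

    def __iter__(self):
        return iter(self.primers)

    def __len__(self):
        return len(self.primers)

    def __getitem__(self, name: str) -> DegeneratePrimer:
        for p in self.primers:
            if p.name == name:
                return p
        raise KeyError(name)

    @property
    def normalized_weights(self) -> tuple[float, ...]:
        total = sum(p.mix_weight for p in self.primers)
        if total <= 0:
            raise ConstraintError("primer mix weights must not all be zero")
        return tuple(p.mix_weight / total for p in self.primers)


def builtin_primer_set() -> PrimerSet:
    """The built-in four-primer set (primers 1-2, mixes 3-4).

    Kozak regions: primer 1 carries the strong consensus CCCGCCGCCACCATGG,
    primer 2 the variant CCCGCCGCCGCCATGG; mixes 3 and 4 are degenerate
    templates covering the remaining reported context combinations.  Mix
    weights 24:16:30:30 reflect the primers' approximate relative
    proportions among vertebrate Kozak sequences.
    """
    return PrimerSet(
        primers=(
            DegeneratePrimer("primer_1", LIGATION_SEQ, "CCCGCCGCCACCATGG", 24),
            DegeneratePrimer("primer_2", LIGATION_SEQ, "CCCGCCGCCGCCATGG", 16),
            DegeneratePrimer("primer_mix_3", LIGATION_SEQ, "DDDHDDHDAAAGATGH", 30),
            DegeneratePrimer("primer_mix_4", LIGATION_SEQ, "DDDHDDHDKGKWATGH", 30),
        )
    )


# ---------------------------------------------------------------------------
# Combinatorics
# ---------------------------------------------------------------------------


def degeneracy_count(primer: DegeneratePrimer) -> int:
    """Number of distinct concrete Kozak sequences the template denotes.

    This is the product over template positions of the expansion-set sizes.
    """
    return prod(len(DEGENERATE_EXPANSIONS[s]) for s in primer.kozak_template)


def total_combinations(primer_set: PrimerSet) -> int:
    """Sum of degeneracy counts over the set's primers.

    Note this counts with multiplicity across primers; the built-in
    templates are pairwise disjoint, so for them it equals the size of the
    union (177,149).
    """
    if len(primer_set) == 0:
        raise ConstraintError("cannot total an empty primer set")
    return sum(degeneracy_count(p) for p in primer_set)


class ExpansionLimitError(ConstraintError):
    """Refusal to enumerate a template whose degeneracy exceeds the limit."""


def expand_template(template: str, limit: Optional[int] = None) -> Iterator[str]:
    """Enumerate all concrete sequences of a degenerate template.

    Yields in lexicographic order, duplicate-free; the count equals the
    product of per-position degeneracies.  If ``limit`` is given and the
    count exceeds it, raises :class:`ExpansionLimitError` naming the count
    before any sequence is produced.
    """
    t = validate_template(template)
    count = prod(len(DEGENERATE_EXPANSIONS[s]) for s in t)
    if limit is not None and count > limit:
        raise ExpansionLimitError(
            f"template expands to {count} sequences, exceeding limit {limit}"
        )
    choices = [sorted(DEGENERATE_EXPANSIONS[s]) for s in t]
    return ("".join(bases) for bases in itertools.product(*choices))


def expand_primer(primer: DegeneratePrimer, limit: Optional[int] = None) -> Iterator[str]:
    """Enumerate the concrete 16-nt Kozak sequences of a primer's template."""
    return expand_template(primer.kozak_template, limit=limit)


def restrict_template(
    template: str, variable_indices: Sequence[int], fill: SeqLike
) -> str:
    """Fix all but the given window indices of a template to concrete bases.

    ``fill`` supplies the concrete base for every fixed position (a full
    16-nt sequence; bases at ``variable_indices`` are ignored).  Each fill
    base must be admissible under the template symbol at its position.
    Used to reproduce position-restricted expansions such as the printed
    nine combinations of a mix at two positions.
    """
    t = validate_template(template)
    f = as_bases(fill)
    if len(f) != len(t):
        raise ConstraintError(f"fill length {len(f)} != template length {len(t)}")
    keep = set(variable_indices)
    out = []
    for i, (sym, base) in enumerate(zip(t, f)):
        if i in keep:
            out.append(sym)
        else:
            if base not in DEGENERATE_EXPANSIONS[sym]:
                raise ConstraintError(
                    f"fill base {base} at window index {i} is not admissible "
                    f"under template symbol {sym}"
                )
            out.append(base)
    return "".join(out)


# ---------------------------------------------------------------------------
# Context classification and sampling
# ---------------------------------------------------------------------------


def classify_context(
    primer_set: PrimerSet, context: Union[KozakContext, SeqLike]
) -> list[str]:
    """Names of all primers whose template matches the context window.

    An empty list means the transcript's context is not captured by the
    set.  Templates need not be disjoint, so more than one name may be
    returned; callers should report such multiplicity rather than assume a
    unique source.
    """
    window = context.window if isinstance(context, KozakContext) else as_bases(context)
    window = KozakContext(window).window  # validates length and ATG
    return [
        p.name for p in primer_set if matches_template(window, p.kozak_template)
    ]


def sample_primers(
    primer_set: PrimerSet,
    n: int,
    seed: Union[int, np.random.Generator],
) -> list[tuple[str, str]]:
    """Draw ``n`` concrete full primers from the weighted mix.

    The source primer is chosen proportionally to its mix weight; each
    degenerate position is then resolved uniformly over its expansion
    ("equal mixture").  Returns ``(source_name, full_sequence)`` pairs
    where the full sequence is ligation sequence + concrete Kozak region.
    Deterministic for a fixed integer seed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    weights = primer_set.normalized_weights
    idx = rng.choice(len(primer_set), size=n, p=weights)
    draws: list[tuple[str, str]] = []
    for i in idx:
        p = primer_set.primers[i]
        kozak = "".join(
            s if len(DEGENERATE_EXPANSIONS[s]) == 1
            else sorted(DEGENERATE_EXPANSIONS[s])[rng.integers(len(DEGENERATE_EXPANSIONS[s]))]
            for s in p.kozak_template
        )
        draws.append((p.name, p.ligation_seq + kozak))
    return draws


def sample_primer(
    primer_set: PrimerSet, seed: Union[int, np.random.Generator]
) -> tuple[str, str]:
    """Single draw from the weighted primer mix (see :func:`sample_primers`)."""
    return sample_primers(primer_set, 1, seed)[0]


# ---------------------------------------------------------------------------
# TSV primer definitions
# ---------------------------------------------------------------------------

_TSV_COLUMNS = ["name", "ligation_seq", "kozak_template", "weight"]


def read_primer_tsv(source: Union[str, Path, IO[str]]) -> PrimerSet:
    """Load a user-supplied primer set from TSV.

    Columns: name, ligation_seq, kozak_template, weight.  Each row is
    validated against the same invariants as the built-in primers.
    """
    own = isinstance(source, (str, Path))
    handle = open(source) if own else source
    try:
        reader = csv.DictReader(handle, delimiter="\t")
        if reader.fieldnames is None or [c.strip() for c in reader.fieldnames] != _TSV_COLUMNS:
            raise InputFormatError(
                f"primer TSV must have columns {_TSV_COLUMNS}, got {reader.fieldnames}"
            )
        primers = []
        for row in reader:
            try:
                weight = float(row["weight"])
            except (TypeError, ValueError):
                raise InputFormatError(
                    f"primer {row.get('name')!r}: weight {row.get('weight')!r} is not a number"
                ) from None
            primers.append(
                DegeneratePrimer(
                    name=row["name"].strip(),
                    ligation_seq=row["ligation_seq"].strip(),
                    kozak_template=row["kozak_template"].strip(),
                    mix_weight=weight,
                )
            )
    finally:
        if own:
            handle.close()
    if not primers:
        raise InputFormatError("primer TSV contains no rows")
    return PrimerSet(primers=tuple(primers))


def write_primer_tsv(primer_set: PrimerSet, dest: Union[str, Path, IO[str]]) -> None:
    own = isinstance(dest, (str, Path))
    handle = open(dest, "w", newline="") if own else dest
    try:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(_TSV_COLUMNS)
        for p in primer_set:
            writer.writerow([p.name, p.ligation_seq, p.kozak_template, p.mix_weight])
    finally:
        if own:
            handle.close()
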