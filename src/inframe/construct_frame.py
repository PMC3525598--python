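"""Prey fusion-construct modeling and translation-outcome prediction.

A prey construct in a split-fluorophore complementation screen is an
N-terminal tag CDS (e.g. the YFP1 fragment, amino acids 1-158), a flexible
linker (default (Gly-Gly-Gly-Gly-Ser)x2), and a library insert.  When the
insert retains its 5'-UTR, the tag's reading frame runs through the UTR
before reaching the insert's CDS, so the UTR can (a) introduce a stop
codon that truncates the fusion inside the UTR, or (b) shift the frame so
the CDS is mistranslated until a downstream stop — in either case the cell
expresses a short "artificial peptide" instead of the intended fusion.

This module assembles such constructs, predicts the translated product,
classifies the outcome, and compares the same insert with and without its
5'-UTR — the in-silico counterpart of running the paired expression
constructs side by side.

Cloning junctions (restriction sites, recombination sequences, epitope
tags) are modeled as frame-neutral and stop-free by default, i.e. they
contribute 0 nt; all frame effects are attributed to the 5'-UTR.  Two
config hooks relax this: an explicit ``junction`` sequence for users who
know their vector, and a 12-nt Kozak ``spacer`` (context positions
-12..-1) for constructs built from the library's own primers, which lets
one detect the rare spacer-encoded stops.  Both segments are grouped with
the UTR into the "upstream insert region" for stop localisation and
frame arithmetic.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Optional

from .seqcore import (
    READ_THROUGH,
    ConstraintError,
    NucSeq,
    SeqLike,
    as_bases,
    first_stop_codon_index,
    translate,
)

#: Default linker CDS: encodes the flexible decapeptide GGGGSGGGGS.
DEFAULT_LINKER_CDS = "GGTGGAGGTGGATCT" * 2

#: Length of the YFP1 tag (amino acids 1-158) used in the reference
#: construct design.  The tag's nucleotide sequence is vector-specific and
#: not bundled; any ATG-initiated, stop-free, frame-aligned tag CDS is
#: accepted.
REFERENCE_TAG_LENGTH_AA = 158
REFERENCE_LINKER_LENGTH_AA = 10

KOZAK_SPACER_LEN = 12


class Outcome(str, enum.Enum):
    """Predicted translation outcome of a prey construct."""

    FULL_LENGTH_FUSION = "FULL_LENGTH_FUSION"
    STOP_IN_UTR = "STOP_IN_UTR"
    FRAMESHIFT_TRUNCATED = "FRAMESHIFT_TRUNCATED"
    IN_FRAME_TRUNCATED = "IN_FRAME_TRUNCATED"
    NO_STOP_READTHROUGH = "NO_STOP_READTHROUGH"


def _require(condition: bool, clause: str) -> None:
    if not condition:
        raise ConstraintError(f"construct invariant violated: {clause}")


@dataclass(frozen=True)
class ConstructDesign:
    """A prey fusion construct: tag + linker [+ junction + 5'-UTR + spacer] + CDS.

    Invariants (checked at construction, errors name the violated clause):

    * ``tag_cds`` begins with ATG, is a multiple of 3 and stop-free in its
      frame 0;
    * ``linker_cds`` is a multiple of 3 and stop-free (may be empty);
    * ``insert_cds`` ends with a stop codon (its final 3 nt); a full-length
      clone is a multiple of 3, but out-of-frame library fragments are
      accepted so frameshift scenarios can be modeled;
    * ``kozak_spacer``, when present, is exactly 12 nt.

    ``junction`` (default empty) and ``kozak_spacer`` (default absent) are
    the optional explicit-vector hooks described in the module docstring.
    """

    tag_cds: SeqLike
    insert_cds: SeqLike
    linker_cds: SeqLike = DEFAULT_LINKER_CDS
    insert_utr: Optional[SeqLike] = None
    junction: SeqLike = ""
    kozak_spacer: Optional[SeqLike] = None

    def __post_init__(self):
        tag = as_bases(self.tag_cds)
        linker = as_bases(self.linker_cds)
        cds = as_bases(self.insert_cds)
        utr = as_bases(self.insert_utr) if self.insert_utr is not None else None
        junction = as_bases(self.junction)
        spacer = as_bases(self.kozak_spacer) if self.kozak_spacer is not None else None

        _require(tag.startswith("ATG"), "tag_cds must begin with ATG")
        _require(len(tag) % 3 == 0, "tag_cds length must be a multiple of 3")
        _require(
            first_stop_codon_index(tag, 0) is None, "tag_cds must be stop-free"
        )
        _require(len(linker) % 3 == 0, "linker_cds length must be a multiple of 3")
        _require(
            linker == "" or first_stop_codon_index(linker, 0) is None,
            "linker_cds must be stop-free",
        )
        _require(len(cds) >= 3, "insert_cds must contain at least one codon")
        _require(
            first_stop_codon_index(cds[-3:], 0) == 0,
            "insert_cds must end with a stop codon",
        )
        _require(utr is None or len(utr) > 0, "insert_utr, when given, must be non-empty")
        _require(
            spacer is None or len(spacer) == KOZAK_SPACER_LEN,
            f"kozak_spacer must be exactly {KOZAK_SPACER_LEN} nt",
        )

        object.__setattr__(self, "tag_cds", tag)
        object.__setattr__(self, "linker_cds", linker)
        object.__setattr__(self, "insert_cds", cds)
        object.__setattr__(self, "insert_utr", utr)
        object.__setattr__(self, "junction", junction)
        object.__setattr__(self, "kozak_spacer", spacer)

    @property
    def upstream_region(self) -> str:
        """Everything between the linker and the insert CDS."""
        parts = [self.junction]
        if self.insert_utr is not None:
            parts.append(self.insert_utr)
        if self.kozak_spacer is not None:
            parts.append(self.kozak_spacer)
        return "".join(parts)

    def without_utr(self) -> "ConstructDesign":
        """The same design with the 5'-UTR removed."""
        return ConstructDesign(
            tag_cds=self.tag_cds,
            insert_cds=self.insert_cds,
            linker_cds=self.linker_cds,
            insert_utr=None,
            junction=self.junction,
            kozak_spacer=self.kozak_spacer,
        )


@dataclass(frozen=True)
class ExpressionPrediction:
    """Predicted translation product of an assembled prey construct.

    ``peptide`` is the product translated from the tag's ATG, truncated at
    the first stop codon (the stop itself is not included).
    ``artificial_peptide_length_aa`` counts the residues encoded by codons
    lying wholly or partly downstream of the linker, before the first stop
    — the length of the unintended peptide stretch a frameshift or early
    stop produces (for a correct fusion it equals the insert-derived
    residue count).  ``stop_codon_index`` is the 0-based codon index of
    the first stop, or None under read-through.
    """

    outcome: Outcome
    peptide: str
    total_length_aa: int
    artificial_peptide_length_aa: int
    stop_codon_index: Optional[int]

    def as_dict(self) -> dict:
        return {
            "outcome": self.outcome.value,
            "total_length_aa": self.total_length_aa,
            "artificial_peptide_length_aa": self.artificial_peptide_length_aa,
            "stop_codon_index": self.stop_codon_index,
            "peptide": self.peptide,
        }


def assemble_prey(design: ConstructDesign) -> NucSeq:
    """Concatenate tag + linker + junction + UTR + spacer + insert CDS.

    Junctions contribute exactly the bases the design declares (0 nt by
    default); total length is the sum of the part lengths.
    """
    return NucSeq(
        design.tag_cds + design.linker_cds + design.upstream_region + design.insert_cds,
        id="prey_construct",
    )


def predict_expression(design: ConstructDesign) -> ExpressionPrediction:
    """Translate the assembled construct from the tag ATG and classify.

    Classification (first match wins):

    1. no stop codon anywhere -> NO_STOP_READTHROUGH;
    2. first stop wholly inside the upstream insert region (UTR, plus any
       junction/spacer) -> STOP_IN_UTR;
    3. upstream region length not a multiple of 3 -> FRAMESHIFT_TRUNCATED;
    4. first stop is the insert CDS's own terminal stop ->
       FULL_LENGTH_FUSION;
    5. otherwise -> IN_FRAME_TRUNCATED (an in-frame stop upstream of the
       CDS terminus).
    """
    assembled = assemble_prey(design).bases
    peptide_rt = translate(assembled, 0, READ_THROUGH)
    stop_idx = peptide_rt.find("*")
    total_codons = len(assembled) // 3
    pre_insert_nt = len(design.tag_cds) + len(design.linker_cds)
    upstream = design.upstream_region
    up_start = pre_insert_nt
    up_end = pre_insert_nt + len(upstream)

    if stop_idx == -1:
        outcome = Outcome.NO_STOP_READTHROUGH
        total_aa = total_codons
        peptide = peptide_rt
        stop_codon_index = None
    else:
        total_aa = stop_idx
        peptide = peptide_rt[:stop_idx]
        stop_codon_index = stop_idx
        stop_nt_start = 3 * stop_idx
        stop_nt_end = stop_nt_start + 3
        if up_start <= stop_nt_start and stop_nt_end <= up_end:
            outcome = Outcome.STOP_IN_UTR
        elif len(upstream) % 3 != 0:
            outcome = Outcome.FRAMESHIFT_TRUNCATED
        elif stop_nt_end == len(assembled):
            # translation reached the insert CDS's own terminal stop
            outcome = Outcome.FULL_LENGTH_FUSION
        else:
            outcome = Outcome.IN_FRAME_TRUNCATED

    last_codon = stop_idx if stop_idx != -1 else total_codons
    artificial = max(0, last_codon - pre_insert_nt // 3)

    return ExpressionPrediction(
        outcome=outcome,
        peptide=peptide,
        total_length_aa=total_aa,
        artificial_peptide_length_aa=artificial,
        stop_codon_index=stop_codon_index,
    )


@dataclass(frozen=True)
class UTRComparison:
    """Side-by-side predictions for a construct with and without its UTR."""

    with_utr: ExpressionPrediction
    without_utr: ExpressionPrediction

    @property
    def outcome_changed(self) -> bool:
        return self.with_utr.outcome != self.without_utr.outcome

    def as_dict(self) -> dict:
        return {
            "with_utr": self.with_utr.as_dict(),
            "without_utr": self.without_utr.as_dict(),
            "outcome_changed": self.outcome_changed,
            "artificial_peptide_length_with_utr": self.with_utr.artificial_peptide_length_aa,
            "artificial_peptide_length_without_utr": self.without_utr.artificial_peptide_length_aa,
        }


def compare_with_without_utr(design: ConstructDesign) -> UTRComparison:
    """Predict the paired constructs with and without the insert's 5'-UTR.

    Raises :class:`ConstraintError` if the design carries no UTR — the
    comparison is only meaningful for a UTR-bearing insert.
    """
    if design.insert_utr is None:
        raise ConstraintError(
            "compare_with_without_utr requires a design with an insert_utr"
        )
    return UTRComparison(
        with_utr=predict_expression(design),
        without_utr=predict_expression(design.without_utr()),
    )
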