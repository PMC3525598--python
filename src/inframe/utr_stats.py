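"""5'-UTR database analysis: frameshift and premature-stop statistics.

When a cDNA library is built from full-length mRNAs, each expression
construct fuses an N-terminal tag (and linker) to the insert's 5'-UTR
followed by its coding sequence.  The tag's reading frame then runs
straight into the UTR, so two sequence properties of the UTR decide the
fate of the fusion:

* length: a UTR whose length is not a multiple of 3 shifts the downstream
  CDS out of the tag's frame;
* stop content: a stop codon (TAA/TAG/TGA) among the UTR's frame-0
  triplets truncates translation before the CDS is reached.

A UTR is *correct* — i.e. the construct is predicted to express the intended
full-length fusion — only when it is frame-neutral AND stop-free.  This
module classifies individual UTR records on those two axes and aggregates
database-level fractions, including the full 2x2 (frameshift x stop) joint
table so that both the per-record intersection and the marginal readings
are recoverable.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Union

from Bio.SeqRecord import SeqRecord

from .seqcore import (
    AlphabetError,
    NucSeq,
    SeqLike,
    first_stop_codon_index,
    iter_raw_fasta,
)


@dataclass(frozen=True)
class UTRAnalysis:
    """Per-record classification of one 5'-UTR sequence.

    ``remainder`` is the UTR length mod 3; a non-zero remainder shifts the
    downstream CDS frame.  ``has_stop`` scans frame-0 complete triplets
    only (the frame continuous with an in-frame upstream tag across a
    frame-neutral junction).  ``correct`` is the per-record intersection:
    frame-neutral and stop-free.
    """

    record_id: Optional[str]
    length_nt: int
    remainder: int
    causes_frameshift: bool
    has_stop: bool
    correct: bool


@dataclass(frozen=True)
class DatabaseSummary:
    """Database-level fractions plus the 2x2 frameshift-by-stop joint table.

    ``n_records`` counts analyzable (strict-ACGT) records; records with
    ambiguous bases are excluded from the fractions and reported in
    ``n_excluded``.  The four joint counts always sum to ``n_records``.
    """

    n_records: int
    n_frameshift: int
    n_stop: int
    n_correct: int
    n_frameshift_and_stop: int
    n_frameshift_only: int
    n_stop_only: int
    n_neither: int
    n_excluded: int = 0

    @property
    def frac_frameshift(self) -> float:
        return self.n_frameshift / self.n_records

    @property
    def frac_stop(self) -> float:
        return self.n_stop / self.n_records

    @property
    def frac_correct(self) -> float:
        return self.n_correct / self.n_records

    def as_dict(self) -> dict:
        return {
            "n_records": self.n_records,
            "n_excluded": self.n_excluded,
            "frac_frameshift": self.frac_frameshift,
            "frac_stop": self.frac_stop,
            "frac_correct": self.frac_correct,
            "joint_counts": {
                "frameshift_and_stop": self.n_frameshift_and_stop,
                "frameshift_only": self.n_frameshift_only,
                "stop_only": self.n_stop_only,
                "neither": self.n_neither,
            },
        }


def analyze_utr(seq: SeqLike) -> UTRAnalysis:
    """Classify one 5'-UTR record.

    Raises :class:`AlphabetError` for empty or non-ACGT input.
    """
    rec = seq if isinstance(seq, NucSeq) else NucSeq(seq)
    if len(rec) == 0:
        raise AlphabetError("cannot analyze an empty UTR sequence")
    remainder = len(rec) % 3
    has_stop = first_stop_codon_index(rec, frame=0) is not None
    causes_frameshift = remainder != 0
    return UTRAnalysis(
        record_id=rec.id,
        length_nt=len(rec),
        remainder=remainder,
        causes_frameshift=causes_frameshift,
        has_stop=has_stop,
        correct=not causes_frameshift and not has_stop,
    )


RecordLike = Union[SeqLike, tuple, SeqRecord]


def _coerce(record: RecordLike) -> NucSeq:
    if isinstance(record, NucSeq):
        return record
    if isinstance(record, str):
        return NucSeq(record)
    if isinstance(record, tuple):
        rec_id, bases = record
        return NucSeq(bases, id=rec_id)
    if isinstance(record, SeqRecord):
        return NucSeq(str(record.seq), id=record.id)
    raise TypeError(f"cannot interpret {type(record).__name__} as a UTR record")


def summarize(
    records: Iterable[RecordLike],
    analyses_out: Optional[list[UTRAnalysis]] = None,
) -> DatabaseSummary:
    """Single-pass aggregation of per-record UTR classifications.

    Streaming: memory is constant in the number of records (unless
    ``analyses_out`` is supplied to collect the per-record results).
    Records containing ambiguous bases (N etc.) or that are empty are
    counted as excluded and do not enter the fractions.  Raises
    ``ValueError`` when no analyzable record is seen.
    """
    n = n_fs = n_stop = n_both = 0
    n_excluded = 0
    for record in records:
        try:
            analysis = analyze_utr(_coerce(record))
        except AlphabetError:
            n_excluded += 1
            continue
        n += 1
        n_fs += analysis.causes_frameshift
        n_stop += analysis.has_stop
        n_both += analysis.causes_frameshift and analysis.has_stop
        if analyses_out is not None:
            analyses_out.append(analysis)
    if n == 0:
        raise ValueError(
            f"no analyzable UTR records ({n_excluded} excluded as ambiguous/empty)"
        )
    n_neither = n - n_fs - n_stop + n_both
    return DatabaseSummary(
        n_records=n,
        n_frameshift=n_fs,
        n_stop=n_stop,
        n_correct=n_neither,
        n_frameshift_and_stop=n_both,
        n_frameshift_only=n_fs - n_both,
        n_stop_only=n_stop - n_both,
        n_neither=n_neither,
        n_excluded=n_excluded,
    )


def summarize_fasta(
    path: Union[str, Path],
    analyses_out: Optional[list[UTRAnalysis]] = None,
) -> DatabaseSummary:
    """Summarize a UTR FASTA file (UTRdb-style, one record per variant)."""
    return summarize(iter_raw_fasta(path), analyses_out=analyses_out)
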