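"""Synthetic UTR databases, Kozak contexts, and transcripts, with closed-form
expectations.

The generators here stand in for downloads of real UTR databases during
testing and calibration.  They draw sequences with controlled, simple
statistical structure — i.i.d. base composition for UTR bodies and an
independent per-position frequency model for Kozak contexts — for which the
frameshift/stop statistics of :mod:`inframe.utr_stats` and the capture
probability of a primer set have exact closed forms.  Simulation versus
closed form is the package's parameter-recovery oracle.

Randomness: every generator takes a single integer seed; internally a
``numpy.random.SeedSequence`` is spawned into independent child streams
(one per sequence component) so outputs are reproducible and the streams
are statistically independent.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .seqcore import (
    DEGENERATE_EXPANSIONS,
    DNA_BASES,
    STANDARD_TABLE,
    STOP_CODONS,
    ConstraintError,
    NucSeq,
    first_stop_codon_index,
)
from .kozak_primers import (
    KOZAK_WINDOW_LEN,
    KozakContext,
    PrimerSet,
    kozak_coord_to_window_index,
)

_SENSE_CODONS = sorted(set(STANDARD_TABLE.aa_map) - set(STOP_CODONS))

#: Kozak coordinates of the 13 variable context positions (ATG at +1..+3 is
#: fixed): -12..-1 plus +4.
VARIABLE_KOZAK_COORDS: tuple[int, ...] = tuple(range(-12, 0)) + (4,)


def _validate_dist(dist: dict[str, float], what: str) -> dict[str, float]:
    full = {b: float(dist.get(b, 0.0)) for b in DNA_BASES}
    extra = set(dist) - set(DNA_BASES)
    if extra:
        raise ConstraintError(f"{what}: unknown bases {sorted(extra)}")
    if any(v < 0 for v in full.values()):
        raise ConstraintError(f"{what}: negative probability")
    total = sum(full.values())
    if abs(total - 1.0) > 1e-9:
        raise ConstraintError(f"{what}: probabilities sum to {total}, not 1")
    return full


@dataclass(frozen=True)
class FrequencyModel:
    """Base-composition model for synthetic sequences.

    ``base_freqs`` is the global i.i.d. composition used for UTR bodies and
    CDS codon sampling.  ``kozak_position_freqs`` optionally gives one
    distribution per variable Kozak coordinate (-12..-1 and +4, keyed by
    the integer coordinate) for context generation; coordinates omitted
    from the dict fall back to ``base_freqs``.
    """

    base_freqs: dict[str, float] = field(
        default_factory=lambda: {b: 0.25 for b in DNA_BASES}
    )
    kozak_position_freqs: Optional[dict[int, dict[str, float]]] = None

    def __post_init__(self):
        object.__setattr__(
            self, "base_freqs", _validate_dist(self.base_freqs, "base_freqs")
        )
        if self.kozak_position_freqs is not None:
            validated = {}
            for coord, dist in self.kozak_position_freqs.items():
                if coord not in VARIABLE_KOZAK_COORDS:
                    raise ConstraintError(
                        f"kozak_position_freqs: coordinate {coord} is not a "
                        f"variable context position"
                    )
                validated[int(coord)] = _validate_dist(
                    dist, f"kozak_position_freqs[{coord}]"
                )
            object.__setattr__(self, "kozak_position_freqs", validated)

    def position_dist(self, coord: int) -> dict[str, float]:
        """Distribution at a variable Kozak coordinate (fallback: base_freqs)."""
        if self.kozak_position_freqs and coord in self.kozak_position_freqs:
            return self.kozak_position_freqs[coord]
        return self.base_freqs

    def p_stop_codon(self) -> float:
        """Probability that an i.i.d. triplet is a stop codon.

        p = f(T)f(A)f(A) + f(T)f(A)f(G) + f(T)f(G)f(A).
        """
        f = self.base_freqs
        return sum(f[c[0]] * f[c[1]] * f[c[2]] for c in STOP_CODONS)


def default_kozak_model() -> FrequencyModel:
    """Frequency model with the two literature-quoted context positions.

    At Kozak -12 (primer position 17) the reported vertebrate frequencies
    are A 23%, G 23%, C 35%, T 19%; at -4 (position 25) A 25%, G 15%, T 7%,
    with the residual mass (53%) assigned to C.  All other variable
    positions default to a uniform distribution: the full per-position
    census is not reproduced here.
    """
    return FrequencyModel(
        kozak_position_freqs={
            -12: {"A": 0.23, "C": 0.35, "G": 0.23, "T": 0.19},
            -4: {"A": 0.25, "C": 0.53, "G": 0.15, "T": 0.07},
        }
    )


# ---------------------------------------------------------------------------
# Length distributions
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LengthDistribution:
    """Distribution over positive integer sequence lengths.

    Constructed via :meth:`uniform`, :meth:`fixed` or :meth:`empirical`.
    ``pmf_items`` yields (length, probability) pairs and is the basis of
    the closed-form expectations.
    """

    kind: str
    params: tuple

    @classmethod
    def uniform(cls, a: int, b: int) -> "LengthDistribution":
        """Discrete uniform over the integers a..b inclusive."""
        if not (1 <= a <= b):
            raise ConstraintError(f"uniform length bounds must satisfy 1 <= a <= b, got ({a}, {b})")
        return cls("uniform", (int(a), int(b)))

    @classmethod
    def fixed(cls, length: int) -> "LengthDistribution":
        if length < 1:
            raise ConstraintError(f"fixed length must be positive, got {length}")
        return cls("fixed", (int(length),))

    @classmethod
    def empirical(cls, lengths: Sequence[int]) -> "LengthDistribution":
        """Uniform over a list of observed lengths (duplicates weight)."""
        vals = tuple(int(x) for x in lengths)
        if not vals:
            raise ConstraintError("empirical length list must be non-empty")
        if any(v < 1 for v in vals):
            raise ConstraintError("lengths must be positive integers")
        return cls("empirical", vals)

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.kind == "uniform":
            a, b = self.params
            return rng.integers(a, b + 1, size=n)
        if self.kind == "fixed":
            return np.full(n, self.params[0], dtype=int)
        vals = np.asarray(self.params)
        return vals[rng.integers(len(vals), size=n)]

    def pmf_items(self) -> Iterable[tuple[int, float]]:
        if self.kind == "uniform":
            a, b = self.params
            p = 1.0 / (b - a + 1)
            return ((length, p) for length in range(a, b + 1))
        if self.kind == "fixed":
            return [(self.params[0], 1.0)]
        n = len(self.params)
        counts: dict[int, int] = {}
        for v in self.params:
            counts[v] = counts.get(v, 0) + 1
        return ((length, c / n) for length, c in sorted(counts.items()))

    @property
    def min_length(self) -> int:
        return min(length for length, _ in self.pmf_items())


def parse_length_spec(spec: str) -> LengthDistribution:
    """Parse a CLI length spec: 'uniform:a:b', 'fixed:L' or 'empirical:l1,l2,...'."""
    parts = spec.split(":")
    try:
        if parts[0] == "uniform" and len(parts) == 3:
            return LengthDistribution.uniform(int(parts[1]), int(parts[2]))
        if parts[0] == "fixed" and len(parts) == 2:
            return LengthDistribution.fixed(int(parts[1]))
        if parts[0] == "empirical" and len(parts) == 2:
            return LengthDistribution.empirical(
                [int(x) for x in parts[1].split(",") if x]
            )
    except (ValueError, ConstraintError) as exc:
        raise ConstraintError(f"bad length spec {spec!r}: {exc}") from exc
    raise ConstraintError(
        f"bad length spec {spec!r}; expected uniform:a:b, fixed:L or empirical:l1,l2,..."
    )


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------


def _child_rngs(seed: int, n: int) -> list[np.random.Generator]:
    """Spawn n independent child streams from one integer seed."""
    children = np.random.SeedSequence(seed).spawn(n)
    return [np.random.default_rng(c) for c in children]


def _base_arrays(model: FrequencyModel):
    bases = np.array(list(DNA_BASES))
    probs = np.array([model.base_freqs[b] for b in DNA_BASES])
    return bases, probs


def gen_utr_db(
    n: int,
    lengths: LengthDistribution,
    model: Optional[FrequencyModel] = None,
    seed: int = 0,
) -> list[NucSeq]:
    """Draw ``n`` i.i.d.-composition UTR records.

    Record lengths come from ``lengths`` and bases i.i.d. from the model's
    ``base_freqs``; byte-identical output for a fixed seed.  Records are
    named ``utr_1 .. utr_n``.
    """
    if n < 0:
        raise ConstraintError(f"n must be non-negative, got {n}")
    model = model or FrequencyModel()
    (rng_len, rng_base) = _child_rngs(seed, 2)
    lens = lengths.sample(rng_len, n)
    bases, probs = _base_arrays(model)
    flat = rng_base.choice(bases, size=int(lens.sum()), p=probs)
    records = []
    offset = 0
    for i, length in enumerate(lens, start=1):
        records.append(NucSeq("".join(flat[offset : offset + length]), id=f"utr_{i}"))
        offset += length
    return records


@dataclass(frozen=True)
class SummaryExpectation:
    """Closed-form expectations for the UTR database summary fractions.

    For UTR length L with i.i.d. bases and per-triplet stop probability p:

    * E[frac_frameshift] = P(L mod 3 != 0)
    * E[frac_stop]       = E_L[1 - (1-p)^floor(L/3)]
    * E[frac_correct]    = E_L[ 1{L mod 3 = 0} (1-p)^(L/3) ]
    """

    p_stop_codon: float
    frac_frameshift: float
    frac_stop: float
    frac_correct: float


def expected_summary(
    lengths: LengthDistribution, model: Optional[FrequencyModel] = None
) -> SummaryExpectation:
    """Exact expectations of the summarize() fractions under the model."""
    model = model or FrequencyModel()
    p = model.p_stop_codon()
    q = 1.0 - p
    e_fs = e_stop = e_correct = 0.0
    for length, w in lengths.pmf_items():
        n_codons = length // 3
        stop_free = q ** n_codons
        if length % 3 != 0:
            e_fs += w
        else:
            e_correct += w * stop_free
        e_stop += w * (1.0 - stop_free)
    return SummaryExpectation(
        p_stop_codon=p,
        frac_frameshift=e_fs,
        frac_stop=e_stop,
        frac_correct=e_correct,
    )


def gen_kozak_contexts(
    n: int,
    model: Optional[FrequencyModel] = None,
    seed: int = 0,
) -> list[KozakContext]:
    """Draw ``n`` Kozak contexts from the per-position frequency model.

    ATG is fixed at +1..+3; each of the 13 variable positions is drawn
    independently from its position distribution.  Raises
    :class:`ConstraintError` when the model carries no position table.
    """
    model = model or default_kozak_model()
    if model.kozak_position_freqs is None:
        raise ConstraintError(
            "gen_kozak_contexts requires a model with kozak_position_freqs"
        )
    (rng,) = _child_rngs(seed, 1)
    bases = np.array(list(DNA_BASES))
    cols: dict[int, np.ndarray] = {}
    for coord in VARIABLE_KOZAK_COORDS:
        dist = model.position_dist(coord)
        probs = np.array([dist[b] for b in DNA_BASES])
        cols[kozak_coord_to_window_index(coord)] = rng.choice(bases, size=n, p=probs)
    contexts = []
    for i in range(n):
        window = [""] * KOZAK_WINDOW_LEN
        for idx, col in cols.items():
            window[idx] = col[i]
        window[12:15] = "ATG"
        contexts.append(KozakContext("".join(window)))
    return contexts


def capture_probability(
    primer_set: PrimerSet, model: Optional[FrequencyModel] = None
) -> float:
    """Exact probability that a model-drawn context matches >= 1 primer.

    Because context positions are independent, the probability that a
    context matches a given sub-collection of templates factorizes over
    positions (per-position mass of the intersection of the templates'
    admissible base sets); inclusion-exclusion over non-empty
    sub-collections then gives the union probability.
    """
    model = model or default_kozak_model()
    primers = list(primer_set)
    total = 0.0
    for r in range(1, len(primers) + 1):
        sign = (-1) ** (r + 1)
        for subset in itertools.combinations(primers, r):
            prob = 1.0
            for idx in range(KOZAK_WINDOW_LEN):
                allowed = frozenset(DNA_BASES)
                for p in subset:
                    allowed &= DEGENERATE_EXPANSIONS[p.kozak_template[idx]]
                if idx in (12, 13, 14):
                    # context has ATG here with probability 1
                    if not {"ATG"[idx - 12]} <= allowed:
                        prob = 0.0
                        break
                    continue
                coord = idx - 12 if idx < 12 else 4
                dist = model.position_dist(coord)
                prob *= sum(dist[b] for b in allowed)
                if prob == 0.0:
                    break
            total += sign * prob
    return total


# ---------------------------------------------------------------------------
# Transcripts
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SyntheticTranscript:
    """A synthetic mRNA: 5'-UTR ending in the context's -12..-1 segment,
    then the CDS (ATG ... terminal stop) whose first post-ATG base is the
    context's +4 base."""

    utr: NucSeq
    cds: NucSeq
    context: KozakContext

    @property
    def full(self) -> NucSeq:
        return NucSeq(self.utr.bases + self.cds.bases, id=self.utr.id)


def _codon_probs(model: FrequencyModel, codons: Sequence[str]) -> np.ndarray:
    f = model.base_freqs
    probs = np.array([f[c[0]] * f[c[1]] * f[c[2]] for c in codons])
    total = probs.sum()
    if total <= 0:
        raise ConstraintError(
            "base_freqs assign zero mass to every candidate codon; "
            "cannot generate a CDS under this composition"
        )
    return probs / total


def gen_transcripts(
    n: int,
    utr_lengths: LengthDistribution,
    cds_lengths: LengthDistribution,
    model: Optional[FrequencyModel] = None,
    seed: int = 0,
    utr_stop_free: bool = False,
    max_retries: int = 1000,
) -> list[SyntheticTranscript]:
    """Generate ``n`` transcripts with a Kozak-embedded CDS start.

    Each transcript is UTR + CDS where the UTR's last 12 nt are the
    sampled context's -12..-1 segment, the CDS begins ATG and ends with a
    terminal stop codon, the first base after ATG is the context's +4
    base, and the CDS body is stop-free in frame 0 (guaranteed by sampling
    each body codon from the 61 sense codons with probabilities induced by
    ``base_freqs``, renormalized — exact, no rejection).

    ``utr_lengths`` must have support >= 12 (the context prefix);
    ``cds_lengths`` must be multiples of 3 and >= 9 (ATG + >= 1 body codon
    + stop).  With ``utr_stop_free`` the UTR is rejection-sampled until
    frame-0 stop-free (bounded by ``max_retries`` per record).
    """
    model = model or default_kozak_model()
    for length, _ in cds_lengths.pmf_items():
        if length % 3 != 0 or length < 9:
            raise ConstraintError(
                f"cds length {length} invalid: must be a multiple of 3 and >= 9"
            )
    if utr_lengths.min_length < 12:
        raise ConstraintError(
            "utr lengths must be >= 12 nt (the Kozak -12..-1 segment)"
        )
    rng_len, rng_utr, rng_ctx, rng_cds = _child_rngs(seed, 4)

    f = model.base_freqs
    if sum(f[c[0]] * f[c[1]] * f[c[2]] for c in STOP_CODONS) >= 1.0 - 1e-12:
        raise ConstraintError("base_freqs make every triplet a stop codon")
    sense_probs = _codon_probs(model, _SENSE_CODONS)
    stop_list = sorted(STOP_CODONS)
    stop_probs_raw = np.array([f[c[0]] * f[c[1]] * f[c[2]] for c in stop_list])
    stop_probs = (
        stop_probs_raw / stop_probs_raw.sum()
        if stop_probs_raw.sum() > 0
        else np.full(3, 1 / 3)
    )
    # sense codons grouped by first base, for the +4-constrained first codon
    by_first: dict[str, tuple[list[str], np.ndarray]] = {}
    for b in DNA_BASES:
        group = [c for c in _SENSE_CODONS if c[0] == b]
        by_first[b] = (group, _codon_probs(model, group))

    bases_arr, base_probs = _base_arrays(model)
    position_dists = {
        kozak_coord_to_window_index(coord): np.array(
            [model.position_dist(coord)[b] for b in DNA_BASES]
        )
        for coord in VARIABLE_KOZAK_COORDS
    }

    def draw_context() -> KozakContext:
        window = [""] * KOZAK_WINDOW_LEN
        for idx, probs in position_dists.items():
            window[idx] = bases_arr[rng_ctx.choice(4, p=probs)]
        window[12:15] = "ATG"
        return KozakContext("".join(window))

    utr_lens = utr_lengths.sample(rng_len, n)
    cds_lens = cds_lengths.sample(rng_len, n)

    out = []
    for i in range(n):
        L_utr, L_cds = int(utr_lens[i]), int(cds_lens[i])
        # in stop-free mode the context is redrawn with the prefix: a
        # context whose -12..-1 segment carries an aligned stop would
        # otherwise make the rejection loop unsatisfiable
        for attempt in range(max_retries):
            ctx = draw_context()
            prefix = "".join(rng_utr.choice(bases_arr, size=L_utr - 12, p=base_probs))
            utr = prefix + ctx.window[:12]
            if not utr_stop_free:
                break
            if first_stop_codon_index(utr, 0) is None:
                break
        else:
            raise ConstraintError(
                f"could not draw a stop-free UTR of length {L_utr} in "
                f"{max_retries} attempts under this composition"
            )
        n_body = (L_cds - 6) // 3
        group, group_probs = by_first[ctx.window[15]]
        first = group[rng_cds.choice(len(group), p=group_probs)]
        rest = [
            _SENSE_CODONS[j]
            for j in rng_cds.choice(len(_SENSE_CODONS), size=n_body - 1, p=sense_probs)
        ]
        stop = stop_list[rng_cds.choice(3, p=stop_probs)]
        cds = "ATG" + first + "".join(rest) + stop
        out.append(
            SyntheticTranscript(
                utr=NucSeq(utr, id=f"tx_{i + 1}"),
                cds=NucSeq(cds, id=f"tx_{i + 1}_cds"),
                context=ctx,
            )
        )
    return out
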