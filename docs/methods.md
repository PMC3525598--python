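# Methods

## The model

An expression construct in a bait–prey screen is modelled as the
concatenation, on the sense strand, of

```
tag CDS  +  linker CDS  [+ junction]  [+ 5'-UTR]  [+ Kozak spacer]  +  insert CDS
```

translated from the tag's ATG in a single frame with the standard genetic
code, truncating at the first stop codon. The tag (reference design: the
YFP1 fragment, amino acids 1–158) and linker (default
(Gly-Gly-Gly-Gly-Ser)×2, encoded `GGTGGAGGTGGATCT` ×2) are required to be
ATG-initiated (tag), frame-aligned and stop-free, so every frame or stop
effect downstream is attributable to the segments between linker and
insert CDS. Cloning junctions are frame-neutral and stop-free by default
(contributing 0 nt): vector junction sequences are vector-specific and
typically unpublished, and the design argument attributes expression
failures to the 5′-UTR alone. Users who know their vector can supply an
explicit `junction` sequence, and constructs built from the library's own
primers can carry the concrete 12-nt Kozak spacer (−12..−1); both segments
are grouped with the UTR into the *upstream insert region* for stop
localisation and frame arithmetic, so a spacer-encoded stop is detected
and reported as `STOP_IN_UTR`.

Outcome classification of the first stop codon (first rule that applies):

1. no stop anywhere → `NO_STOP_READTHROUGH`;
2. stop wholly inside the upstream insert region → `STOP_IN_UTR`;
3. upstream region length mod 3 ≠ 0 → `FRAMESHIFT_TRUNCATED` (this covers
   stops that span the UTR/CDS junction);
4. translation ends at the insert CDS's own terminal stop →
   `FULL_LENGTH_FUSION`;
5. otherwise → `IN_FRAME_TRUNCATED`.

The *artificial peptide length* is the number of residues encoded by
codons lying wholly or partly downstream of the linker, before the first
stop. Junction-spanning codons count: whether published artificial-peptide
lengths include junction-encoded residues is not stated anywhere we know
of, so the package fixes the convention that makes the quantity
well-defined and monotone in the truncation point. Because tag+linker is
always a codon multiple, this equals (first-stop codon index) −
(tag+linker length)/3. For a correct fusion the same formula counts the
insert-derived residues; the value is only "artificial" when the outcome
is not `FULL_LENGTH_FUSION`.

The insert CDS must end in a stop codon (its final 3 nt) but need not be a
codon multiple: library inserts include out-of-frame fragments, and the
frameshift scenarios require modelling them. `FULL_LENGTH_FUSION` is only
reachable when the global frame puts that terminal stop in-frame.

## UTR statistics

A 5′-UTR of length *L* is classified by two independent predicates:

- **frameshift**: *L* mod 3 ≠ 0;
- **premature stop**: at least one of the ⌊*L*/3⌋ complete frame-0
  triplets (grouping from the first base; trailing 1–2 nt ignored) is
  TAA/TAG/TGA. Frame 0 is the frame continuous with an upstream in-frame
  tag across a frame-neutral junction; other frames are not scanned.

The "correct" fraction is the per-record **intersection** (frame-neutral
AND stop-free), not the product of marginals — per construct that is what
"expresses the intended protein" means. The 2×2 joint table is reported so
the marginal reading is also recoverable. Records containing ambiguous
bases (N, etc., present in real UTR database dumps) are excluded from the
fractions and counted in `n_excluded`; silent dropping would bias the
fractions invisibly. Aggregation is single-pass and constant-memory so
full database-scale FASTA files stream.

## Primer combinatorics

Primer templates are stored 5′→3′ exactly as designed; matching uses only
the 16-nt Kozak region — the ligation segment serves recombination
cloning, not annealing. A context is *captured* iff it matches a template
exactly: mismatch-tolerant annealing is deliberately not modelled, since
the design argument is combinatorial coverage, not hybridisation
thermodynamics. Degeneracy is the product of per-position expansion-set
sizes; enumeration is lexicographic and duplicate-free, and an expansion
request above the caller's limit is refused with the offending count
named. Templates are not assumed disjoint (the built-in four happen to
be): classification returns every matching primer.

Limitations inherent to the design, surfaced by `capture_probability`: no
built-in template admits C or T at Kozak −3, so contexts with a pyrimidine
there are never captured; coverage of "all" contexts is approximate.

## Synthetic data

`gen_utr_db` draws record lengths from a configurable distribution
(uniform/fixed/empirical) and bases i.i.d. from a global composition —
emulating the record structure of a UTR database while deliberately
omitting real-UTR features (GC gradients, uORFs, length–composition
correlation). Passing oracle tests therefore demonstrates correctness of
the *counting machinery*, not that real databases have any particular
fraction. Under this model the summary fractions have closed forms
(per-triplet stop probability *p* from the composition; expectations over
the length distribution), used as 3-binomial-SE oracles at n = 30,000 —
large enough that a systematic error of a fraction of a percentage point
is detected, small enough to keep the default suite fast.

`gen_kozak_contexts` draws the 13 variable context positions (−12..−1, +4)
independently per position. Defaults: the two positions with literature
frequencies use them (−12: A 23 %, G 23 %, C 35 %, T 19 %; −4: A 25 %,
G 15 %, T 7 %, residual 53 % assigned to C, made explicit rather than
renormalised); all other positions are uniform, since a full per-position
census is not reproduced here. Capture probability under any such model is
computed exactly by inclusion–exclusion over template subsets (per-position
independence factorises each intersection term).

`gen_transcripts` emits UTR + CDS with the sampled context embedded: the
UTR's last 12 nt are the context's −12..−1 segment and the first base
after ATG is the context's +4 base. CDS bodies are stop-free *by
construction* — each codon is drawn from the 61 sense codons with the
probabilities induced by the base composition, renormalised (exact, no
rejection). The optional stop-free-UTR mode rejection-samples the whole
UTR (redrawing the context with it, since a context segment can carry an
aligned stop) with a bounded retry budget.

All generators derive their streams from one integer seed via
`numpy.random.SeedSequence.spawn`, so each component (lengths, UTR bodies,
contexts, CDS codons) has an independent, reproducible stream.

## Numerical and interface choices

- Coordinates are 0-based half-open internally; CLI output reports both
  primer/table positions (17–32) and Kozak coordinates (−12..+4).
- Base→integer recoding is not used anywhere; classification operates
  directly on characters, with outcome-identical results.
- Sequences are strictly {A,C,G,T} after canonicalisation (lowercase
  uppercased, U→T); ambiguity codes beyond the four primer symbols
  D/H/K/W are rejected with a clear error rather than silently matched.
- Exit codes: 0 success, 2 usage, 3 input format, 4 constraint violation.
- Tie-breaks: expansion order is lexicographic; sampling resolves
  degenerate positions uniformly (the "equal mixture" semantics of the
  synthesis chemistry).

## Known limitations

- Ribosome behaviour (leaky scanning, reinitiation, IRES) is out of scope:
  translation is modelled as strict frame-0 scanning from the tag ATG.
- 3′-UTR effects are not modelled.
- Historical database-scale fractions (e.g. from specific UTRdb releases)
  and construct-specific artificial-peptide lengths depend on inputs that
  are release- or vector-specific; they can be reproduced by running
  `utrstats`/`predict` on user-supplied reference sequences but are not
  built-in results.
- Melting temperature and secondary structure of primers are not
  computed; the reverse polyT primer is recorded as a constant only.
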