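# inframe

Toolkit for designing and analysing **in-frame cDNA expression libraries** —
libraries built with Kozak-anchored PCR primers so that every cloned insert
begins at its start codon, with the 5′-untranslated region (5′-UTR) removed.

## Why

Bait–prey screens (yeast two-hybrid, split-fluorophore protein
complementation) express library inserts as C-terminal fusions to an
N-terminal tag. A conventional cDNA library retains each transcript's
5′-UTR between the tag/linker and the coding sequence. Translated in the
tag's frame, a 5′-UTR of length *L* shifts the insert's frame whenever
*L* mod 3 ≠ 0, and truncates the fusion whenever one of its frame-0
triplets is a stop codon (TAA/TAG/TGA). Either way the cell expresses a
short *artificial peptide* instead of the intended fusion — a major source
of false positives and false negatives in interaction screens.

The remedy modelled here is a forward-primer mixture that anneals directly
at the translational start site: two concrete primers carrying the most
frequent vertebrate Kozak contexts plus two degenerate mixes (symbols
D = A/G/T, H = A/C/T, K = G/T, W = A/T, each an equal mixture) covering the
remaining context combinations, combined in the ratio 24∶16∶30∶30.

`inframe` provides the computational pieces of that design:

- **kozak_primers** — the built-in primer set (16-nt ligation sequence +
  16-symbol Kozak-region template spanning −12..+4, ATG fixed at +1..+3);
  degeneracy counting, lexicographic expansion, context classification and
  weighted mix sampling; user primer sets via TSV.
- **utr_stats** — per-record 5′-UTR classification (frameshift: *L* mod
  3 ≠ 0; premature stop: any stop among the ⌊*L*/3⌋ frame-0 triplets;
  correct: neither) and streaming database summaries with the full 2×2
  joint table.
- **construct_frame** — assembly of prey constructs (tag + linker
  [+ 5′-UTR] + insert CDS), prediction of the translated product, outcome
  classification (`FULL_LENGTH_FUSION`, `STOP_IN_UTR`,
  `FRAMESHIFT_TRUNCATED`, `IN_FRAME_TRUNCATED`, `NO_STOP_READTHROUGH`) and
  artificial-peptide length, with paired with/without-UTR comparisons.
- **synthetic_data** — seeded generators for i.i.d.-composition UTR
  databases, position-frequency Kozak contexts and full transcripts, plus
  the closed-form expectations used as simulation oracles: with
  per-triplet stop probability
  *p* = *f*(T)*f*(A)*f*(A) + *f*(T)*f*(A)*f*(G) + *f*(T)*f*(G)*f*(A),
  E[frameshift] = P(*L* mod 3 ≠ 0), E[stop] = E_L[1 − (1 − *p*)^⌊L/3⌋],
  E[correct] = E_L[1{L mod 3 = 0}(1 − *p*)^(L/3)].
- **cli** — `inframe primers | utrstats | predict | simulate`, each writing
  a JSON run manifest (parameters, seed, input digests, version).

## Worked example

Degeneracy of the built-in primer set:

```
$ inframe primers --count
name            kozak_template    degeneracy  mix_weight
primer_1        CCCGCCGCCACCATGG  1           24
primer_2        CCCGCCGCCGCCATGG  1           16
primer_mix_3    DDDHDDHDAAAGATGH  19683       30
primer_mix_4    DDDHDDHDKGKWATGH  157464      30
total           -                 177149      -
```

Mix 3 has nine three-way positions (3⁹ = 19,683 sequences); mix 4 swaps
three of its concrete positions for two-way symbols (3⁹·2³ = 157,464);
together with the two concrete primers the mixture covers 177,149 distinct
Kozak-region sequences.

A toy 3-record UTR database (one frame-neutral stop-free record, one
stop-carrying record, one length-4 record):

```
$ inframe utrstats utrs.fasta
{
  "n_records": 3,
  "n_excluded": 0,
  "frac_frameshift": 0.3333333333333333,
  "frac_stop": 0.3333333333333333,
  "frac_correct": 0.3333333333333333,
  "joint_counts": {"frameshift_and_stop": 0, "frameshift_only": 1,
                   "stop_only": 1, "neither": 1}
}
```

Effect of a stop-carrying UTR on a minimal prey construct:

```
$ inframe predict --tag ATGGGA --linker '' --utr TAAGGG --cds AAATAA
# with UTR:    STOP_IN_UTR, 2 aa total, 0 aa artificial
# without UTR: FULL_LENGTH_FUSION, 3 aa total
```

With the UTR, translation stops at the UTR's TAA after the 2-residue tag
peptide MG; with the UTR removed, the intended 3-residue fusion MGK is
expressed, ending at the insert's own terminal stop.

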