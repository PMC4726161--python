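# mitescan

Genome-wide detection of **miniature inverted-repeat transposable elements
(MITEs)** — short (50–800 nt), non-autonomous Class II transposons that occur
in high copy number and carry a characteristic structure: a terminal inverted
repeat (TIR) pair at the element ends, flanked on both sides by a short exact
target site duplication (TSD, 2–10 nt) created on insertion.

`mitescan` is for genome annotators and transposon biologists who want
structurally complete, full-length MITE families with exact genomic
coordinates, without consensus-building artifacts.

## Method

1. **Numeric TIR screen.** Each base maps to a complex score
   (A → 1, T → −1, C → *j*, G → −*j*), so a Watson–Crick pair always sums to
   zero. For two 10-nt windows with cumulative (window) scores summing to
   *C*, a TIR pair requires |Re(*C*)| + |Im(*C*)| ≤ 2 — zero for a perfect
   inverted repeat, exactly 2 per single non-complementary pair. Prefix sums
   make the screen exhaustive over every window placement with a body span
   of 50–800 nt. Because the statistic is order-insensitive (compensating
   mismatches cancel), every screened pair is then verified position-wise
   (≤ 1 mismatch), and an exact flanking TSD of 2–10 nt is required
   (longest qualifying length wins).
2. **False-positive filters.** A candidate is removed when a TIR arm has a
   homopolymer/dinucleotide stretch ≥ 8 nt, a TIR arm has G/C or A/T content
   < 20%, the body's normalized Lempel–Ziv complexity
   c(n)·log₄(n)/n is < 0.675, or a 2-nt TSD is not `TA`.
3. **Family clustering.** Greedy longest-first clustering: a candidate joins
   a family when its alignment to the family seed reaches identity ≥ 80%
   (matches / shorter length) and coverage ≥ 99% (aligned span / longer
   length). Families with < 3 members are dropped. An optional `cd-hit-est`
   backend is available as a cross-check.
4. **Flank validation.** True transposition leaves divergent flanking
   sequence: for each member, 50 nt outside each TSD copy is compared
   left-vs-left and right-vs-right within the family; when two flanks share
   ≥ 25 aligned matches, only the first member in genomic order is kept.
   Families retaining ≥ 3 valid members survive.
5. **Representative selection.** Each family reports the member maximizing
   Σ_{j≠i} score(i, j) over optimal local alignment scores — a real genomic
   sequence, so the family anchors to exact coordinates.

## Worked example

Generate a synthetic genome with planted families, then detect them:

```bash
mitescan simulate --seed 5 --families 2 --copies 3 --genome-length 40000 --out sim5
mitescan run --genome sim5.fa --out result
```

The run prints the stage-by-stage summary:

```
candidates      89
pass_filters    35
families_clustered      31
families_min_copy       2
families_final  2
members_final   6
flank_drops     0
```

Of 89 structurally valid TIR+TSD candidates in the 41 kb genome, 35 pass
the complexity/composition filters; they cluster into 31 families, of which
only the 2 planted families have ≥ 3 copies; all 6 planted copies carry
divergent flanks, so both families survive flank validation intact. Outputs:

- `result.families.fa` — one representative sequence per family, header
  carrying family id, genomic location (1-based inclusive), TIR length, TSD
  and member count;
- `result.members.gff3` / `result.members.tsv` — every member with
  coordinates, TIR mismatch count and TSD;
- `result.log` — the resolved configuration and per-stage counts.

The same pipeline is available as a library:

```python
import mitescan as ms
genomes, truth = ms.generate_planted_genome(seed=5, n_families=2,
                                            copies_per_family=3,
                                            genome_len=40_000)
summary = ms.detect(genomes, ms.PipelineConfig())
print(summary.counts())
```

Every threshold above is a field of `PipelineConfig` (equivalently a CLI
flag or a `key: value` config file; flag beats file beats default).

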