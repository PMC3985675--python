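# adaseed

Transition-constrained adaptive seeds for distant DNA homology search.

`adaseed` is a toolkit for the *seeding* stage of DNA similarity search
between diverged sequences (think mammal–mammal or insect–insect genome
comparison), where plain exact-match seeding misses many true
homologies. It implements, end to end:

- **Subset seed patterns** over the alphabet `{0, T, 1}`: `1` requires a
  base match, `T` tolerates transitions (A↔G, C↔T — the substitutions
  that dominate real genome divergence), `0` is a don't-care. A
  pattern's *weight* is #`1` + ½·#`T`; e.g. `11101011` has span 8 and
  weight 6, and `11T0TT010T` has span 10 and weight 5.
- **Exact seed sensitivity**: for a set of patterns and an i.i.d.
  alignment model over (transversion, transition, match) with
  probabilities (p_v, p_s, p_m), the probability that some pattern hits
  a random gapless alignment of length *l* is computed exactly by
  forward dynamic programming over a deterministic hit automaton — with
  a brute-force 3^l enumeration oracle for verification.
- **Seed design**: random-restart hill climbing over weight-preserving
  pattern moves, co-designing *n* complementary patterns that maximize
  joint sensitivity.
- **Adaptive seeds** over **subset suffix arrays**: patterns are
  extended cyclically (`110T → 110T110T…`) and, from each query
  position, the minimum-length match occurring at most *m* times in the
  reference is found by interval narrowing over a per-pattern suffix
  array sorted under position-dependent letter classes.
- **Seed-and-extend alignment**: gapless X-drop extension (drop limit
  *y*), a gapless score gate *d* with the default rule
  `d = round(t·ln(m·r/10n))` (*r* = unmasked reference bases, *t* = score
  scale), then affine-gap X-drop extension (drop limit *ydrop*), with
  MAF output. Two stock scoring schemes: match/mismatch +1/−1 with
  gaps 7/1 (minimum score 35), and HoxD70 with gaps 400/30 (minimum
  score 4000).
- **A synthetic benchmark**: a related-genome-pair simulator with
  configurable identity, transition:transversion ratio, indels and
  lowercase-masked self-similar repeats, plus the chunk benchmark:
  sample random 1 kb chunks from one genome, align them to the other
  under a grid of configurations, and count per configuration the
  chunks where it missed the best score any configuration found.

Lowercase (repeat-masked) letters are replaced by N before indexing and
alignment, so repeats neither seed nor score. All coordinates are
0-based half-open; '−'-strand query coordinates count from the start of
the reverse-complement strand, as in MAF.

## Worked example

Simulate a 100 kb genome pair at 70% identity with a 3:2
transition:transversion ratio, index the ancestor under a designed
transition seed, and align a 1 kb chunk of the derived genome:

```sh
$ cat sim.yaml
genome_length: 100000
identity: 0.70
ts_tv_ratio: 1.5
indel_rate: 0.02
repeat_fraction: 0.05

$ adaseed simulate --config sim.yaml --out sim/ --rng-seed 7
identity 70.02% transitions 17.99% transversions 11.99%

$ printf '1T0T0T10TT1\n' > seeds.txt     # see examples/
$ adaseed index --ref sim/ancestor.fa --seeds seeds.txt --out idx/
indexed 1 pattern(s) over 100000 bases

$ adaseed align --ref sim/ancestor.fa --index-dir idx/ --query chunk.fa \
    --scheme last --m 100 --d 25 --out out.maf
1 alignment(s) written to out.maf

$ head -3 out.maf
##maf version=1 program=adaseed
a score=354
s ancestor 20062 930 + 100000 CACCGCCAGATTTACC...
```

The simulator reports the realized substitution spectrum counted from
its recorded truth alignment (here 70.02/17.99/11.99 against the
requested 70/18/12). The chunk was cut at derived position 20 000; the
aligner recovers it at ancestor positions 20 062–20 992 with score 354
under the +1/−1 scheme (930 aligned reference bases, indels included).

The exact sensitivity of that seed for gapless alignments of length 64
under the matching model:

```sh
$ adaseed sens --seeds seeds.txt --model 0.12,0.18,0.7 --length 64
0.997011231962905
```

`examples/` contains single and 4-pattern seed sets produced by
`adaseed design` for the 3:2 and 1:1 transition:transversion models;
the 3:2 sets come out visibly richer in `T` positions.

## Library use

```python
import adaseed as a

s = a.seed_set(["11T0TT010T"])
model = a.BernoulliModel(0.12, 0.18, 0.70)     # (p_v, p_s, p_m)
a.sensitivity_dp(s, model, l=64)                # exact hit probability

ref = a.mask_lowercase(open("ref.txt").read(), "ref")
idx = a.build_index(ref, a.parse_pattern("1T1"))
records = a.align(a.mask_lowercase("ACGT...", "q"), [idx],
                  a.last_scheme(), m=10, k=1)
```

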