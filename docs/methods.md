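# Methods

## The model

`hairpinscan` predicts pre-miRNA hairpins by asking, at every genomic
position, whether a stem-loop of fixed geometry would be thermodynamically
stable.  A window starting at position *i* consists of a 5' stem-arm of
length *l* (default 25 nt), a terminal loop of *n* nt (every *n* in
[n_min, n_max], default [5, 20]) and a 3' stem-arm of *l* nt immediately
after the loop.  All coordinates are 0-based half-open; GFF3 output is
converted to 1-based inclusive at the boundary.

The two arms are globally aligned (Needleman–Wunsch) rather than folded,
which is what makes the method quadratic per window instead of cubic in the
precursor length: the stem of a hairpin is, to a good approximation, a
duplex of the two arms, and pseudoknots/exterior loops do not occur in a
stem-loop.  The 3' arm is stored 3'→5' so an alignment match corresponds to
an antiparallel base pair (AU, UA, GC, CG, or the GU/UG wobble).  The
terminal loop separates the arms but is never scored.

### Nearest-neighbour energy

The free energy of a candidate is the sum of nearest-neighbour (NN) motif
increments over the aligned stem, in kcal/mol at 37 °C:

* **Helix**: Σ ΔG_stack over consecutive pairs, + ΔG_sym (0.43) if the
  duplex is self-complementary, + 0.45 per AU/GU helix end ("RU end",
  R = purine).
* **Internal loop** of n = n1 + n2 unpaired bases:
  ΔG_i(n) + 0.6·|n1 − n2| + first/last terminal-mismatch terms
  + 0.7 per RU closing pair.  1×1 and 1×2 loops use this same general
  form (no special tables).
* **Bulge**: n = 1 keeps the flanking stack (ΔG_stack of the two closing
  pairs), adds ΔG_i(1), −0.9 if a bulged C sits next to a paired C,
  −RT·ln t for the t sequence-identical bulge placements (t is the run
  length of the bulged base across the site, counting equal closing-pair
  flanks), and 0.45 per RU closing pair; n > 1 is ΔG_i(n) alone.
* **Loops over 30 nt**: ΔG_i(30) + 1.75·RT·ln(n/30)
  (Jacobson–Stockmayer form; RT = 8.3144621 J/(mol·K) × 310.15 K / 4184
  ≈ 0.6163 kcal/mol).
* **Dangling end**: a single unpaired base at a stem terminus is a table
  lookup on (closing pair, base, side); longer terminal unpaired runs are
  left unscored (a warning is emitted).

The RU penalty is *applied* when the RU closure/end is present (λ = 1);
the scalar penalties (0.6, 0.7, 0.45, −0.9) and the constants R, T are
fixed.  Tables ship as TSVs under `hairpinscan/data/`: Watson–Crick
stacking uses the standard Turner/Mathews ΔG°37 values; wobble stacking,
loop initiations, terminal mismatches and dangles are rounded
representative values constructed to satisfy the model's invariants
(duplex-reversal symmetry of stacking, non-decreasing loop initiation for
n ≥ 3, stabilizing mismatches/dangles).  Unit tests pin the tables by
checksum; energies produced with them are internally consistent but are
not a drop-in for any specific published parameter release.

### Banded DP and exact re-scoring

The DP maximises a *surrogate* score whose increments are locally additive
negated energies: a match following a match credits the true stacking
increment of that pair step (the first pair of a helix is free), a
mismatch step charges ΔG_i(2)/2, and each gap step charges the 1-nt bulge
initiation.  Two DP states per cell (last symbol was a match / was not)
make the stacking rule exact over paths.  Ties prefer diagonal moves over
deletions over insertions and a match predecessor over a non-match one, so
the traceback is deterministic and stems stay compact.

The energy *reported* for every candidate is never the DP score: the
traceback is decomposed into motifs and re-scored exactly with the model
above.  The surrogate only steers the search; its residual gap against the
enumerated optimum is measured in the tests, not assumed zero.

A band `|row − col| ≤ dw` prunes the matrix corners; `dw` bounds the bulge
imbalance of any alignment prefix.  Default `dw = 5` (range 1..l);
`full_matrix` sets `dw = l`.  Cell counts are instrumented: the full
matrix grows as (l+1)², the band as Θ(l·dw).

### Scan, prescreen and overlap resolution

All windows for one (strand, n) are scored in a single vectorized batch.
Windows whose *surrogate* energy exceeds `threshold + prescreen_margin`
are discarded without exact re-scoring; the margin (default 15 kcal/mol)
is generous because the surrogate over-penalises bulges (up to ~4 kcal/mol
per bulged base relative to the exact model) and ignores stabilizing
mismatch/dangle terms.  `prescreen_margin=None` re-scores every window;
the tests verify that the default margin reproduces the exhaustive result
exactly on dense small-scale scans.  Both strands are scanned by default
(reverse-complement coordinates are mapped back to the forward frame), and
overlapping (i, n) variants of one locus are reduced greedily to the
best-energy candidate per strand.

The default energy threshold is −20.6 kcal/mol; the plant-style geometry
(l = 48, loop 5..70, threshold ≈ −42.8) is reachable through the same
options.

## sRNA-seq modules

**Pre-processing (`procin`).**  Covered runs of the reference (coverage ≥ `min_reads`,
default 1) become expressed regions; regions shorter than `min_len`
(default 70 nt, the approximate pre-miRNA length) are extended by
`min_len` on both sides.  Within a region of length p, reads covering the
middle coordinate (p//2, region-local) are disregarded; the highest
remaining read stack — reads whose starts agree within ±1 nt, ties going
to the 5' side then the smaller coordinate — sets the arm length:
l = i + 1 for a 5' stack ending at 0-based inclusive position i, and
l = p − j + 1 for a 3' stack starting at 1-based position j.  Mirroring
the arm gives the maximum terminal-loop length t = p − 2l (so
2l + t = p exactly, and the middle-read exclusion guarantees t ≥ 0).
Per-region scan configs use arm length l and loop range [n_min, t].

**Dicer-signature check (`dicer`).**  Reads over a predicted hairpin are assigned to their
majority region among 5' arm (mature), loop and 3' arm (star); ties favour
the arms.  A read is "overlapping" when the percentage of its bases
outside its primary region exceeds the first tunable; the hairpin fails
when the percentage of overlapping reads exceeds the second.  (0, 0) is
the strict mode: it passes iff no read crosses any boundary.  The check is
advisory and filters nothing in the scan pipeline.

## Calibration and evaluation

The threshold calibration scans the input genome and an i.i.d. multinomial
genome of the same composition, then returns the largest energy at which
the random genome yields zero "true" hits, where a random candidate is
true only if its locus coordinates equal a control locus exactly
(continuous energies, no binning; the returned value is the next float
below the most stable matching hit, capped by a configurable ceiling which
is also returned when there are no hits).

Evaluation follows the arm-containment rule: a prediction is a true
positive when one of its arm intervals fully contains a control interval
on the same strand; a prediction covering several controls is credited
once (lowest energy wins the pairing), uncovered controls are false
negatives, unmatched predictions false positives.  Sensitivity, precision
and specificity are percentages; specificity requires an explicit
true-negative count and zero-denominator ratios are reported as undefined,
never as zero.

## Synthetic study conditions

The fixture generator emulates the intended use case: a 50-kb uniform
(A=C=G=U=0.25) background with ten non-overlapping planted hairpins —
GC-rich (80% GC) 25-nt arms, 8-nt random loop, the 3' arm the reverse
complement of the 5' arm, optionally degraded by round(rate·l)
substitutions (mismatches) and single-base deletions (bulges) per arm —
plus a designated 22-nt "mature" control starting 1 nt into the 5' arm,
and optional arm-anchored 22-nt read stacks with loop-spanning reads.
Problem sizes (50 kb for recovery, 20 kb for calibration, 100–200 arm
pairs for the DP oracle) were chosen to exercise genome-scale behaviour at
desk scale.

What this does *not* emulate: real genomes are not i.i.d. (repeats,
isochores, tRNA/rRNA stem-loops — masking exists for a reason), real
pre-miRNA stems contain wobble pairs and asymmetric loops, and real read
stacks have 3' heterogeneity.  Passing tests demonstrate the algorithmic
properties (exact DP within its band, exact additive re-scoring, the
stated formulas and rules), not field accuracy on real data.

Two honest consequences of the design are visible in the numbers.  First,
a uniform random background yields many genuine low-energy hairpins at the
−20.6 default, so precision on synthetic genomes is a few percent; it is
deterministic per seed and reported as computed.  Second, when the random
terminal loop of a planted hairpin happens to be partially
self-complementary, a 1-nt-shifted window has genuinely lower energy
(longer stem) and wins overlap resolution, and the strict containment rule
may then miss the control by one base — perfect-stem sensitivity is
therefore 100% for most seeds but can read 90% for some.

## Numerical choices and limitations

* All arithmetic is float64 kcal/mol; RT is converted from J once.
* DP tie-breaks and candidate ordering are fully deterministic; identical
  inputs and seeds give identical outputs, byte-for-byte in the writers.
* Sequences are normalized to uppercase RNA; IUPAC ambiguity codes
  (including N from masking) never pair, and non-IUPAC symbols are masked
  to N with a warning.
* A candidate alignment beginning or ending with a ≥2-base unpaired run is
  scored without those bases (warning); single bases are dangling ends.
* The symmetry correction can only trigger when an arm equals the reverse
  of its partner's pairing sequence — rare inside one hairpin, but kept
  for model completeness.
* Multibranch content inside the terminal loop, coaxial stacking, special
  hairpin-loop bonuses and temperature dependence beyond T = 310.15 K are
  out of scope; the loop is unscored by construction.
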