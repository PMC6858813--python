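# Methods

## Duplex model

A candidate site is scored as a gapless antiparallel duplex: transcript
window positions `start..start+L−1` (5′→3′) face miRNA positions `L..1`.
Hydrogen bonds per pair are G·C = 3, A·U = 2, and the two non-canonical
wobble pairs G·U = A·C = 1; every other combination is 0. Positions with
0 bonds stay in register — unpaired nucleotides do not shift the frame,
and bulges or internal loops are not modeled (the scanning and scoring
layer is deliberately a pure per-position sum; a bulge-aware aligner
could be substituted behind `align_at` without touching the site,
cluster or table layers). `N` in either sequence scores 0 bonds at that
position rather than invalidating the record.

The free energy is linear in the bond total: `ΔG = −k_hb·B` and
`ΔGm = −k_hb·Bmax`, where `Bmax` is the bond total against the exact
canonical complement (3 per G/C, 2 per A/U). The site criterion is the
energy fraction `100·B/Bmax ≥ threshold`, with the threshold defaulting
to 87 %. The comparison uses the unrounded ratio; printed tables round
ratios and energies to integers and compactions to one decimal, always
with ties away from zero (so 6.75 → 6.8 and −121.8 → −122).

The fraction is computed directly from the integer bond counts, so a
perfect complement is exactly 100 % and the criterion is independent of
floating-point energy arithmetic and of `k_hb` entirely.

### The energy constant

Published per-site energies are printed in kJ/mole but the bond→energy
conversion itself is not. `k_hb = 2.11` kJ/mole per hydrogen bond
reproduces those magnitudes: for registry miRNAs of known sequence,
`|ΔGm| = |printed ΔG| / (printed ratio/100)` divided by the sequence's
`Bmax` lands at ≈2.105–2.118. `fit_bond_energy` performs this
least-squares calibration (through the origin, weighted by `Bmax`) for
any set of observations; `k_hb` is a parameter of `EnergyModel` for
users who prefer a different scale. All table-derived statistics use the
printed energies, never engine-computed kJ/mole, so nothing downstream
depends on this constant.

### What the criterion is not

There is no seed-region requirement, no nearest-neighbor (Turner)
thermodynamics, no secondary-structure or accessibility correction, and
no conservation filter. The whole-duplex energy fraction is the single
criterion. Scores from this model are therefore comparable with each
other but not with RNAhybrid/ViennaRNA free energies.

## Scanning

`scan` evaluates every start `1..len(t)−L+1` (vectorized over the
transcript with a 5×5 bond matrix) and reports each qualifying start as
a separate site; runs of tandem-repeat hits are never merged. The test
suite holds the scanner to exact agreement with an independently written
brute-force enumeration on random instances up to 1 kb.

## Sites, groups and tables

Sites are localized to 5′UTR/CDS/3′UTR by their **start** nucleotide
(1-based from the first transcript nucleotide; a boundary-straddling
site keeps its start's label, so every site has exactly one region).

Printed tables compress a run of equally spaced starts of one miRNA to
one row: "name (n)" with "lo ÷ hi" ranges. Expansion places n starts in
arithmetic progression; grouping (the inverse) is a greedy left-to-right
scan taking the longest equal-step run from each unconsumed start,
breaking step ties toward the smallest step. One published row (a
4-site group spanning 2060 ÷ 2095) has a range not divisible into
integer steps; the table parser therefore expands leniently — n starts
at rounded evenly spaced positions between the printed endpoints — which
leaves every aggregate statistic (count, total length, span, energies)
unchanged. Direct calls to `expand_group` default to strict mode and
raise on such rows. Ranged energies contribute their endpoint mean to
every expanded site; this is an averaging device, not a per-site
estimate, and it reproduces the published mean energies.

The three packaged tables are transcribed fixtures. Three identifiers
are kept verbatim with printed typos ("D00436.3p-miR", "D00915.3p-miR",
"ID0296.3p-miR"); `PROSE_ALIASES` maps them to their running-text
spellings.

## Clusters and compaction

Clusters are connected components of the interval-overlap graph over
occupied intervals `[start, start+L−1]`, requiring ≥1 shared nucleotide
(abutting sites do not cluster). Since intervals are contiguous, a
sorted sweep computes the components; order invariance and
partition/maximality are property-tested against an explicit union-find
oracle.

Span uses the convention `max(start+L) − min(start) + 1` — one
nucleotide beyond the inclusive union. It is the convention that
reproduces the published cluster sizes and is applied uniformly;
a handful of published spans differ from *any* single convention by
±1–2 nt and are treated as source arithmetic, not modeled. Compaction is
total summed site length over span. Singleton clusters report their
length only (span and compaction are undefined and returned as `None`);
in per-region footprints a singleton contributes its site length. The
per-region "compaction" is total site length over footprint, e.g. ≈7.0
for a trailer region where 619 nt of sites occupy an 89-nt footprint.

Mean ΔG over a block with a tied half (−110.5) rounds away from zero to
−111 under the uniform rule; one published block prints the same mean as
−110.

## Synthetic data generator

`synth.generate` emulates the site structures the scanner is meant to
find, on an i.i.d. background (uniform base frequencies by default,
GC content configurable): a 1 kb transcript (150 nt leader / 600 nt
CDS / 250 nt trailer — ordinary mRNA proportions) and five miRNAs of
17–25 nt, matching the length range of real site catalogues. The default
plants are: one exact complement; one site weakened by two wobble pairs;
one with a wobble plus a 0-bond mismatch; and two tandem runs (6 sites
at step 2, 4 sites at step 3) built from periodic miRNAs over repeat
regions — the mechanism behind published stepped-start site runs.
Each plant's bond total and energy fraction are computed a priori from
the chosen corruptions (a wobble costs 2 bonds at a G/C position, 1 at
A/U; a mismatch costs the full canonical bonds), giving exact ground
truth for recovery tests. A single seeded RNG stream makes output
byte-reproducible per (config, seed); plants may not overlap each other
or the transcript bounds, and tandem runs are planted uncorrupted.

What the generator does **not** emulate: real transcript base
composition and repeat structure, expression levels, or any biological
correlation between miRNA and target. Passing recovery tests therefore
demonstrates correctness of the scanner and statistics on known ground
truth, not predictive accuracy on real transcriptomes.

## Problem sizes

Oracle-equivalence checks use 100 random instances with miRNAs of
17–25 nt and transcripts up to 1 kb, the size regime where exhaustive
rescoring is itself trustworthy; the synthetic bundle is a single 1 kb
transcript. The table-driven statistics are exact recomputations over
the full packaged catalogues (216 expanded sites).

## Known limitations

- Gapless scoring cannot represent the rare published schemes with a
  bulged nucleotide; such sites would score slightly low.
- The linear energy model ignores stacking and position effects; the
  87 % criterion inherits that simplification.
- Grouping cannot distinguish "two isolated sites of one miRNA" from a
  printed 2-site group when spacing allows either; round-trips preserve
  the expanded site set, not necessarily the original row layout.
- Region labels come from a sidecar TSV; no GenBank/GFF feature parsing.
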