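# Methods

This note documents the models and procedures implemented in `selexgram`,
the parameter choices that matter, what the synthetic-data generators do and
do not emulate, and the numerical conventions.

## Preprocessing model

Raw selection-round reads are assumed to be laid out as
`[sample barcode][5′ adapter][UMI][insert][3′ adapter]`. Demultiplexing uses
exact matching of the sample barcode at the 5′ terminus with zero
mismatches: published barcode sets are short and error-correcting
assignment would trade reproducibility for a marginal yield gain.
Adapters are located by exact substring search, taking the first occurrence
from each end (leftmost for the 5′ adapter, rightmost for the 3′ adapter).
The UMI is a random barcode (default 5 nt, configurable) sitting
immediately 5′ of the insert; PCR duplicates are collapsed on the
**(UMI, insert)** pair rather than the UMI alone, because distinct inserts
sharing a UMI by chance are real molecules, not duplicates. Inserts are
kept when their length is 38–40 nt inclusive and they contain no ambiguous
base (k-mer counting requires unambiguous positions). All sequences are
canonicalized to the RNA alphabet (T → U) on input; tag FASTA output uses U.

## Enrichment z-scores

For one sample and round, let `count(m)` be the number of tags containing
k-mer `m` at least once (presence, not occurrence, counting — a tag with
five CACACA copies contributes one) and `f(m) = count(m)/N`. The z-score is
the standardization of `f` over the complete 4^k motif universe,

    z_raw(m) = (f(m) − mean_f) / sd_f ,

with the **population** standard deviation: the universe is the fixed,
complete enumeration of 4^k motifs, not a sample from a larger population.
Background (e.g. affinity of the resin or tag, amplification bias) is
removed by subtracting the matched negative-control round's z-score for the
same motif: `z_corr(m) = z_raw,sample(m) − z_raw,control(m)`. Subtraction is
used rather than a ratio because z-scores can be zero or negative. A table
in which every motif has the same frequency has no enrichment signal; its
z-scores are defined as 0 (with a relative tolerance of 1e−12 on sd_f to
absorb floating-point noise in constant vectors).

Headline reports default to round 4; the RRM-only derivative is reported at
round 2 (its CA specificity is lost under later, more stringent washes).
Both are configurable. Motif reports flag z > 1.5, the threshold used for
highlighting enriched motifs in cross-sample correlation scatter plots;
correlations are Pearson's r over the corrected z of the identical motif
universe, undefined (NaN) when either vector has zero variance.

## Pair-spacing analysis

A tag contains the ordered pair `(m1, m2)` at gap `g` when `m1` starts at
position `i` and `m2` at `i + 4 + g`; the gap counts the nucleotides
strictly between the two tetramers (the `N_g` of `GGCA-N20-CACA`).
Containment per (pair, gap, tag) is binary; overlapping occurrences are all
considered when locating pairs. The full universe is 65,536 ordered pairs ×
26 gaps (0–25). Cell frequencies are standardized **jointly** over that
universe rather than per gap: a single heat map displays all gaps on one
color scale, which requires z values comparable across gaps. Correction
again subtracts the control cell z. Pairs are ranked by the arithmetic mean
of their 26 corrected cell z values; ties break lexicographically.

Motif-class groups are selected from the top-500 ranked pairs of the
reference (full-length protein) sample: (a) the 10 highest-ranked pairs of
two CA-rich tetramers, (b)–(e) the four orientation/anchor combinations of
a CA-rich tetramer with GGCA or CGGC, and (f) pairs of GGC-core elements.
Membership is frozen on the reference sample and then applied to the
corrected z of each derivative sample, mirroring the study design in which
combinations identified for the full-length protein are profiled in the
truncation data sets. For the RRM-only sample, groups b+d and c+e are
merged by group letter into two summary profiles. Heat-map annotation marks
cells above z = 4.6 (full-length and RRM-like samples) or z = 2.5
(KH-domain derivatives).

A **CA-rich** tetramer contains no G, at least three C/A residues, at least
one adjacent CA or AC alternation, and neither CCC nor AAA; exhaustive
enumeration gives 30 of 256 tetramers. The array scanner (below) takes its
CA-element list as a parameter defaulting to these 30, because the
operational list used for published transcriptome scans was a curated
subset (13 tetramers) that is not reproduced in the accessible text;
absolute array counts (and hence group-size splits) depend on this list.

## Motif-array grammar

A motif array in a transcript region is an ordered anchor pair of GGC-core
hits (G1 before G2) satisfying, with all gaps end-to-start:

1. `30 ≤ gap(G1, G2) ≤ 200`;
2. two CA-element hits C1 < C2 strictly between the anchors with
   `gap(G1, C1) ≥ 10`, `gap(C1, C2) ≥ 6`, `gap(C2, G2) ≥ 10`;
3. a CA-element hit outside the anchor pair with gap 6–200 from the nearer
   anchor (downstream of G2 or upstream of G1).

These bounds are deliberately looser than the in vitro spacing optima, to
admit longer structural loops in cellular transcripts. Overlapping GGC-core
hits (CGGCA contains both CGGC and GGCA) are all candidate anchors.
Qualifying anchor pairs are reduced to a non-overlapping set by greedy
left-to-right selection on the anchor interval `[G1.start, G2.end)`: the
study reports per-UTR array counts without defining overlap handling, and
greedy non-overlap is deterministic and conservative (never counts two
arrays sharing an anchor). Within a qualifying pair the reported witnesses
(C1, C2, external CA) are the leftmost qualifying hits, and the external CA
with the smallest gap (downstream preferred on ties); existence, not the
witness choice, determines whether an array is reported. Every emitted
array re-verifies all three criteria from its stored coordinates.
Coordinates are 0-based half-open throughout, including BED output;
scanning is sense-strand only. Per-region array counts are grouped as
{0, 1, 2/3, ≥4}.

## Binding index and group comparison

`B = tag_count / expression` per region, where tags are counted by their
start coordinate (the truncation-position convention for iCLIP, where the
read start marks the crosslink-adjacent position; midpoint counting is
available). Expression is a positive per-region value (mean coverage);
regions with zero or missing expression are excluded rather than producing
infinite indices, with no additional minimum-coverage threshold. Each
non-zero array-count group is compared against the array-free group with
Welch's unequal-variance two-sample t test,

    t = (m_a − m_b) / sqrt(s_a²/n_a + s_b²/n_b),

with Welch–Satterthwaite degrees of freedom and two-sided p-values; no
multiple-testing correction is applied to the three comparisons. Groups
with fewer than two members are skipped with a flag. Two identical
degenerate (zero-variance) groups define t = 0, p = 1.

## Synthetic-data generators

**SELEX simulator.** Round 0 is a uniform random pool of `pool_size`
inserts of 40 nt. Round r+1 is drawn from round r with replacement with
probability proportional to `w(s)^schedule[r]`, where
`w(s) = 1 + Σ gain·[s contains motif] + Σ gain·[s contains the pair at its
planted gap]`. The additive weight is the simplest model in which
affinities of independent elements combine; the per-round exponent schedule
(default 1.0, 1.5, 2.0, 2.5) is the simplest monotone analog of wash
stringency increasing each round. Defaults used throughout the tests:
pool 50,000 for single-hexamer recovery and 20,000 for pair-spacing
recovery (desk-scale pools that keep a full run in seconds on one CPU),
gain 3 (a planted sequence is retained 4× more efficiently per unit of
stringency — strong but not saturating at round 1), 4 rounds. The simulator
does not model PCR bias, sequencing errors, secondary-structure-dependent
selection, or thermodynamic binding; its purpose is planted-truth recovery,
not quantitative reproduction of published z magnitudes.

A caution for interpreting *neutral* simulations (no planted gains):
because rounds resample with replacement, tag multiplicities accumulate and
inflate the tails of the corrected z distribution. Even in the idealized
limit, the expected maximum of |z_s − z_c| over 4096 hexamers for two
independent neutral runs is already ≈ √2·Φ⁻¹(1 − 1/8192) ≈ 5, and the
multiplicity effect pushes observed maxima to ≈ 5–6 at pool 50,000. The
meaningful calibration guard — enforced in the test suite and reported by
the acceptance script — is therefore that the neutral maximum stays far
below the planted-detection signal (corrected z ≈ 46–48 for a gain-3
hexamer), not below an absolute constant.

**101-mer fixtures.** The wild-type sequence realizes
`GGCA-N20-CACA-N14-CACA-N22-CGGC-N4-(CA)4` in exactly 101 nt, with 8 nt of
5′ and 9 nt of 3′ flank. The published spacer/flank nucleotides are not in
the accessible text, so spacers are fixed {U,G} patterns verified (by
exhaustive scan, including block junctions) to contain no GGC-core or
CA-element occurrence; scanner results on the fixtures depend only on the
motif layout. The mutant series replaces CA elements and/or GGC-core
elements with UG runs (`CA->UG`, `GGC->UG`, `allUG`), swaps the 5′ GGCA
anchor with the first internal CACA (`GGC<->CA`; `GGC<->CA_UG` additionally
mutates the remaining CA elements), and relocates the (CA)4 repeat to the
5′ end by exchanging it with the 5′ flank block (`(CA)4<->`, which
preserves the hit multiset). The exact substitutions of the swap variants
are this package's reading of the published variant names; the published
full sequences are not reproducible from the accessible text. Note that
under the strict grammar the relocated (CA)4 no longer provides an external
CA at gap ≥ 6, so `(CA)4<->` scans to 0 arrays — consistent with the
grammar, and irrelevant to the wild-type/UG-mutant contrasts the tests
assert.

**Regulome.** Each region draws a planted array count k from
{0: 0.44, 1: 0.16, 2: 0.08, 3: 0.08, 4: 0.24} (mirroring the observed
transcriptome-wide split of array-count groups), embeds k copies of the
wild-type 101-mer template in uniform random background, and scrubs every
GGC-core occurrence touching a background position (mutating one background
base to U, which cannot create a new GGC-core) so that planted templates
are the only anchor sources — background CA elements remain, as in real
UTRs. Templates are separated by ≥ 180 nt of background so that anchors of
neighboring arrays sit > 200 nt apart and cannot form cross-template
qualifying pairs; regions too short for k templates are extended and
logged. Expression is lognormal(μ = 1, σ = 1); tag counts are
Poisson(expression · (λ0 + λ1·k)) with defaults λ0 = 2, λ1 = 4 (= 2·λ0, a
strong planted coupling), and tag positions are uniform with a 50% bias
into array spans (cosmetic only — the B index uses counts, not positions).
The generator does not emulate 3′-UTR length/composition biases, expression-
dependent CLIP detectability, or crosslinking sequence preferences; passing
tests therefore demonstrate correctness of the pipeline's computations and
its ability to recover planted structure, not performance on real
transcriptomes.

All generators are deterministic given their seed (byte-identical output).

## Problem sizes and numerical conventions

The test suite and acceptance script use: pools of 50,000 (hexamer
recovery, neutral diagnostics) and 20,000 (pair-spacing recovery, 3 gaps ×
3 seeds); a 2,000-region regulome for the positive coupling and 20 × 500
regions for the null; 100 random sequences up to 3 kb for scanner/brute-
force equivalence. These sizes make every planted effect unambiguous while
keeping a complete run within a few minutes on a single CPU. k-mer and
pair-containment counting use integer k-mer encoding (A=0, C=1, G=2, U=3,
so indices sort lexicographically) with per-row sort/deduplicate/bincount;
ties in motif and pair rankings break lexicographically; extremely small
Welch p-values in the acceptance report are computed in log space through
the incomplete-beta series of the t survival function.

## Known limitations

- The exact z-score definition behind the published tables is not printed
  in the accessible text; containment-frequency standardization over the
  motif universe with control subtraction is one defensible reading, stated
  here exactly so results are reproducible.
- Absolute array counts depend on the CA-element list (see above); the
  default is the full 30-tetramer enumeration, so counts are an upper bound
  relative to a curated 13-element list.
- Whether overlapping arrays should ever be counted separately is
  undefined in the source; the greedy non-overlap reduction is one
  deterministic choice, exercised identically by implementation and test
  oracle.
- Pair-spacing analysis is limited to tetramers and gaps 0–25 by design;
  no significance machinery beyond the z framework is provided.
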