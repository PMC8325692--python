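# Methods

## The candidate screen

S-RNases — the style determinants of gametophytic self-incompatibility
(GSI) in Rosaceae — are distinguishable from their non-S RNase T2
relatives by a conjunction of features, each implemented as one filter
over a feature table:

| filter | rule | default | rationale |
| --- | --- | --- | --- |
| signal peptide | present | — | the determinant is secreted into the style transmitting tract |
| domain integrity | coverage > 0.60 (strict) | 0.60 | truncated ORFs and pseudo-genes lack a functional catalytic domain |
| isoelectric point | pI ∈ [8, 10] (inclusive) | 8, 10 | S-RNases are basic proteins |
| intron count | ≤ 2 (inclusive) | 2 | S-RNase gene models carry at most two introns |
| pattern 4 | motif absent | `CPSS[NS]G` | the motif diagnoses non-S lineage members |

Boundary semantics matter: domain coverage is strictly greater-than
(categorical ">60%"/"<60%" annotations are accepted and the label decides;
when both a numeric fraction and a label are present the numeric value
wins), while the pI window and intron bound are inclusive — family
members with pI 8.07/8.08 are genuine survivors. Applied as pure
predicates the five filters commute; the per-stage removal lists in a
`ScreenReport` depend on order, which is fixed as signal peptide → domain
→ pI → introns → pattern 4. Pattern 4 is placed last, where it cannot
perturb the earlier stage counts.

Allele pairing then runs in two stages over the filter survivors of one
species. Stage 1 keeps unordered pairs with percent identity inside the
inclusive [30, 90] polymorphism window: true alleles are strongly
diverged, yet identical sequences would be one gene. Stage 2 applies the
within-genus > cross-tribe rule — a pair survives only when its
within-pair identity exceeds each member's maximum identity to every
supplied cross-tribe reference S-RNase. The packaged cross-tribe
reference is synthetic (see "Fixtures" below). An externally supplied
identity matrix always takes precedence over identities computed from
sequences, so published similarity values can be reproduced exactly.

## Protein feature primitives

**Isoelectric point.** Net charge is the sum of Henderson–Hasselbalch
terms for the ionizable side chains (D, E, C, Y negative; H, K, R
positive) plus the free termini, with the Bjellqvist pK set (the table
behind the common web tools for protein pI): side-chain pKs C 9.0,
D 4.05, E 4.45, H 5.98, K 10.0, R 12.0, Y 10.0; C-terminus 3.55 (D 4.55,
E 4.75 when terminal); N-terminus 7.5 with residue-specific values for
A, M, S, P, T, V, E, G. The charge curve is strictly decreasing in pH,
so pI is found by bisection on [0, 14] to 1e-3 pH. Nonstandard residues
carry zero charge and are counted with a warning. The solver is verified
against a 1e-4-step grid scan of the charge curve and against an
independent implementation of the same model; note that *appending* an
acidic residue can legitimately raise pI slightly by swapping the
residue-specific C-terminal pK, so monotonicity holds for internal
insertions only.

**Molecular weight.** Sum of average residue masses plus one water
(kDa); B/Z/X take the mean of their constituent residues.

**Percent identity.** End-to-end Needleman–Wunsch with match +1,
mismatch 0, gap −1 (a substitution matrix may replace match/mismatch);
ties break diagonal-first, then up. Identity = identical aligned columns
÷ total alignment columns × 100, to two decimals — internal *and*
terminal gap columns count in the denominator. The published 56.48 %
allelic identity came from a desktop tool with unknown parameters, so it
is treated as a tolerance-banded reference, not an exact target; the
aligner itself is verified by exhaustive enumeration of all alignments
on short pairs (score must be optimal, identity achievable by an optimal
alignment).

**Domain coverage** is the union length of hit envelopes on the model
divided by model length (merged closed intervals, order- and
duplication-invariant); **intron count** is exons − 1 over a sorted
non-overlapping exon list; **region projection** cuts a query row of a
reference alignment at named column spans (the C1–C3/RC4/C5 conserved
and RHV hypervariable regions of Rosaceae S-RNases) and strips gaps.

## GSI genetics

A diploid S-genotype is an unordered allele pair over a configurable
universe (default {Sa, Sb}). Genotype calling from amplicon band
patterns declares an allele present when a band lies within a tolerance
of its expected size; the two default sizes are 350/359 bp, encoding the
known 9-bp inter-allele offset (absolute sizes are placeholders — only
the offset is established). A band matching two alleles is an error,
never a guess, so allele sizes must be separated by more than twice the
tolerance; the user-facing default tolerance is 2 bp.

The cross model: each pollen haplotype (the pollen parent's two alleles
in equal proportion) is rejected iff it matches either style allele.
The compatible fraction is 0, 0.5 or 1; the binary outcome is
"compatible" iff the fraction is positive, matching field scoring where
half-compatible pollinations still set fruit. The model is deliberately
asymmetric — a heterozygous style rejects a homozygous donor completely
while the reciprocal cross passes half the pollen.

Progeny simulation has two modes. `mendelian` (default for selfed
progeny, since the species' SI is leaky enough to yield selfed seed)
draws one maternal and one paternal haplotype uniformly; `gsi` restricts
the paternal draw to haplotypes the maternal style accepts and returns
no offspring when all pollen is rejected. A single numpy generator per
call, seeded, makes runs bit-reproducible.

Segregation testing is χ² goodness of fit with expected counts allocated
proportionally to the stated ratio and df = classes − 1 (via
`scipy.stats.chisquare`). For the packaged 214-progeny population
(48:106:60 vs 1:2:1) the statistic is 1.3645 with p ≈ 0.5055. Null
calls (no band) are reported separately and never merged into a fourth
genotype class. At n = 214 the test's realized type-I error at α = 0.05
is ≈ 5.2 % (slightly above nominal from count discreteness).

## S-locus mapping

All coordinates are 1-based inclusive; interval length counts both
endpoints, so the three-block overlap Chr6:2792689–5489398 has length
2,696,710 bp and spans 2.7 Mb. Megabase spans round half-up at the
configured decimal (raw bp is always available). Flanking clips the
start at 1. Intersection is max-of-starts to min-of-ends, which is
order-invariant, idempotent and associative; mixed chromosomes are an
error. Gene residency uses the single published point coordinate per
gene (full spans are not available in the source tables). BED export
converts to 0-based half-open.

## Expression

2^−ΔΔCt with technical replicates averaged by arithmetic mean before
differencing; per-replicate scatter is reported (population SD) but not
propagated, since no propagation rule is established for the assay
design. The default reference gene label is EF-1α.

## Synthetic data

`generate_feature_table` plants allele pairs whose members pass every
filter (signal peptide present, coverage ~U(0.70, 0.95), pI ~U(8, 10),
introns ≤ 2, no motif) among decoys that each carry at least one
disqualifying feature, drawn from realistic ranges (decoy pI ~U(4, 8)
for the pI failure mode; amino-acid counts 50–916, mirroring the
empirical family tables). Planted pair sequences are built by
substituting a `1 − target/100` fraction of positions of a random
230-residue protein, which lands the realized global-alignment identity
within about three points of the target at lengths ≥ 150. The identity
matrix covers *all* record pairs — planted pairs from their sequences,
everything else drawn low (U(5, 25)) — as a real all-vs-all matrix
would, so decoys that survive filters under feature noise still meet
defined entries. Optional Gaussian jitter on coverage (sd 0.05) and pI
(sd 0.2) models measurement noise; with planted pI uniform over the full
[8, 10] window that jitter analytically removes ≈ 8 % of planted records
at the inclusive filter (≈ 15 % of pairs), so recovery under noise is
scored per record at the filter stage, where recall is ≈ 0.92.

`generate_progeny_bands` emits one band per distinct allele with
Gaussian size noise and refuses noise sd at or above half the smallest
inter-allele offset (calls would be ambiguous by construction). The
tolerance stamped on generated patterns defaults to the widest
unambiguous window (0.499 × that offset — nearest-allele assignment),
under which 1-bp noise against the 9-bp offset is recovered essentially
perfectly. `generate_block_set` anchors one block's start and one
block's end exactly at the planted overlap and jitters the rest outward
(clipped at 1), so the intersection equals the planted interval by
construction; with no planted overlap it emits pairwise disjoint spans.

What the generators do *not* emulate: real sequence homology structure
(decoys carry features, not sequences), nucleotide-level gene models,
partial gel failures or band dropout, and linkage to pollen-side F-box
genes. Passing recovery tests therefore demonstrates the pipeline's
logic and calibration, not performance on raw field data.

## Fixtures and problem sizes

The packaged tables transcribe the published 14-gene *F. vesca* and
13-gene *F. viridis* RNase T2 family characteristics, the 29-line
genotype panel, the 48:106:60 progeny population and the three
chromosome-6 collinear blocks. Two identity values (56.48, 30.88) are
measured; all other pairwise identity entries are placeholders below the
30 % window floor, consistent with the qualitative published statement,
and the cross-tribe reference identities are synthetic (both files say
so in their headers). Signal-peptide calls are consumed as annotations;
the package ships no predictor.

Default test and acceptance problem sizes — 2000 type-I replicates at
n = 214, 200 sequences for the pI oracle, 50 screen-recovery seeds,
5000-progeny band recovery — were chosen to bound Monte-Carlo error
well inside the asserted bands while keeping a full run in seconds.

## Known limitations

- The screen consumes precomputed features; domain searches (profile
  HMMs) and signal-peptide prediction are upstream tools.
- Interspecific unilateral incompatibility is out of scope: the
  phenomenon is SI-independent and no quantitative model is available.
- Amplicon absolute sizes are placeholders; only the 9-bp offset is
  meaningful.
- The 56.48 %/30.88 % identities depend on unpublished alignment
  parameters; the packaged matrix reproduces them as inputs rather than
  recomputing them from deposited sequences.
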