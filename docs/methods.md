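# Methods

This note documents the models, numerical choices, and limitations of
`hml9map`'s analyses, and what its synthetic-data validation does and
does not demonstrate.

## Coordinates and the reference model

All internal coordinates are 1-based inclusive; BED input/output converts
to 0-based half-open at the boundary. The proviral reference is a single
sequence with an ordered region map (LTR5, gag, pro, pol, env, LTR3).
The canonical map is the Dfam LTR14C–HERVK14C–LTR14C layout with
pro/pol overlapping by 25 bp (ribosomal frameshift) and env ending 2 bp
before the 3'LTR. Validation requires LTR5 to start at position 1,
non-decreasing region starts, and LTR lengths within 5 % of each other.
Ungapped chromosome length is sequence length minus N bases, which
mirrors assembly gap accounting without requiring a gap table.

The packaged catalog tables are hand transcriptions of the published
HML-9 element catalog; every provirus and solo-LTR row is checked
against `length = end − start + 1` at load time. The solo-LTR "percent
of LTR" column is the aligned-base count relative to the 587 bp LTR
(not the genomic footprint relative to it), which is the only reading
consistent with insertion-carrying rows.

## Discovery

The search is a from-scratch seed-and-extend design: genome k-mers
(k = 11) are indexed at stride 5; every query offset is looked up on
both strands (the minus strand via the reverse-complemented query);
diagonals with at least 2 seed hits are extended without gaps under an
x-drop rule (match +2, mismatch −3, x-drop 18); extended blocks are
chained colinearly by weighted dynamic programming (weight
matches − mismatches, reference gap ≤ 8 kb and genomic gap ≤ 10 kb per
step). Two filters control false positives, both tuned on synthetic
genomes: a chain must carry ≥ 50 total matches and contain at least one
block of ≥ 25 matched bases. The block floor matters because colinear
chaining across generous gaps can accumulate scattered chance 11–14 bp
matches into a spurious chain, while any genuine homologous segment
extends into a block hundreds of bases long; a 25 bp near-exact chance
run has probability on the order of 4^−25 per position.

Chains on one chromosome and strand merge into a locus when their
genomic gap is ≤ 10 kb (configurable). Merging is purely positional: a
single integration legitimately produces multiple chains (internal
deletions split the alignment, and each genomic LTR matches both
reference LTRs when those are near-identical). A consequence is that two
genuinely distinct elements closer than the merge gap would fuse; the
synthetic generator therefore spaces plants ≥ 12 kb apart, and tandem
elements closer than 10 kb are a documented limitation.

A locus is called a provirus when ≥ 20 aligned bases fall inside
gag..env, otherwise a solo LTR. The small floor makes the call robust to
x-drop extension overhanging an LTR boundary by a few bases. Solo-LTR
coverage is computed against the 587 bp LTR with 3'LTR-aligned positions
folded onto 5'LTR coordinates, so the double match against two
near-identical reference LTRs is not double-counted. Locus naming takes
the cytoband containing the locus midpoint (midpoint rather than start:
stable under small boundary shifts), falling back to
`chrom:start-end`.

## Structural annotation

Each element (oriented per its discovery strand) is aligned to the full
reference with Biopython's PairwiseAligner: global mode, match +2,
mismatch −3, gap open −12, gap extend −1, and free end gaps on both
sequences, so terminal truncations and flanking sequence are not
penalized. Columns are classified as match, mismatch, element gap
(deletion) or reference gap (insertion); ambiguity codes score as
mismatches.

Region integrity is defined as the percentage of a region's reference
positions aligned to an element base — a *presence* measure, not an
identity measure, so an anciently diverged but physically complete
region still scores near 100 %. Qgap counts element-gap columns strictly
inside the aligned span; terminal truncations are excluded, which is the
only definition consistent with heavily truncated catalog rows showing
near-zero Qgap. Coverage is aligned columns over the reference length.

`extract_region_sequences` projects each element onto reference
coordinates (one character per reference position, `-` where unaligned,
insertions dropped). All downstream per-region comparisons — consensus
building, divergence, LTR–LTR dating — operate in this shared coordinate
frame, so no multiple sequence alignment step is needed.

## Dating

Divergence D defaults to the p-distance with pairwise deletion (columns
where either sequence has a gap or ambiguity are skipped); the clock
arithmetic in the replayed catalog is linear in D with no visible
correction, which is consistent with this choice. The Kimura
two-parameter distance, D = −½·ln((1−2P−Q)·√(1−2Q)), is available for
users who want a multiple-hit correction; it is always ≥ the p-distance
and raises a saturation error when the logarithm's argument is
non-positive.

Internal regions are dated against a majority-rule consensus of the
region set passing the 90 % integrity screen (gap wins a column only
above 50 % gap frequency; base ties break to the reference base, then
alphabetically). Majority consensus stands in for likelihood-based
ancestral reconstruction; at the ≤ 20 % divergences relevant here the
two agree to within the test tolerances on synthetic data, and the
substitution is deliberate for determinism. The age is
T = mean(D)·100/0.2 My with NA regions skipped and the mean taken over
unrounded values (required to reproduce the catalog's printed ages).
LTR pairs require both LTRs at ≥ 50 % integrity and date to
T = D·100/0.2/2. Ages are reported to 2 decimals with NA propagation.

Neighbor joining is implemented directly with deterministic lowest-index
tie-breaking and non-negative branch lengths, and is cross-checked
against scikit-bio's implementation in the tests. It is a clustering
aid, not a substitute for model-based phylogenetics: no substitution
model selection, rate heterogeneity, or bootstrap support is attempted.

## Chromosomal distribution and context

Expected counts are e = Cl·n/Tl. Two complementary tests are reported:
a Pearson goodness-of-fit chi-square across chromosomes
(df = C − 1; chromosomes with zero expectation and nonzero observation
are excluded with a warning), and per-chromosome two-sided exact
binomial tests of o against Binomial(n, Cl/Tl) with Benjamini–Hochberg
adjustment. The per-chromosome construction exists because a single
goodness-of-fit statistic cannot attribute an excess to one chromosome.

Context classification: Intergenic (no gene-span overlap; no gene ids,
orientation NA), Intron (inside a gene, touching no exon), Exon_intron
(inside a gene, overlapping exon sequence), Exonic_intergenic
(overlapping a gene but extending beyond its span). Orientation is
relative to the overlapping gene with the largest overlap. Summaries
group Exonic_intergenic with Exon_intron (both are exon-overlapping
classes), matching how catalog-level percentages are broken down; raw
per-locus categories are always preserved.

## Regulatory domains and enrichment

Basal domains are strand-aware TSS windows (5,000 bp upstream, 1,000 bp
downstream, clipped to the chromosome). Each side extends to the nearer
of the closest neighboring basal boundary and 1,000,000 bp. Basal
domains are inviolable — a neighbor can stop extension but never
truncate a basal region — and the region between two genes' basal
domains is covered by both genes' extensions, which is what produces
two-gene associations. The implementation is tested for exact agreement
with a per-base brute-force scan.

An element associates with every gene whose extended domain contains the
element *midpoint* (single-point membership matches how TSS-distance
plots are built; an any-overlap variant would change counts for long
elements). Signed distance is measured in the gene's reading direction;
bins are left-closed at 5/50/500 kb.

ORA uses the hypergeometric upper tail P(X ≥ k) over categories
intersected with the universe and restricted to sizes [5, 2000], BH
adjustment across tested categories, and the top 10 by FDR (ties by p,
then category id). Curated domain overrides from web services are not
reproduced; category systems are supplied as plain two-column TSVs.

## Motifs and PBS

PWMs (JASPAR text format) are normalized per column with a
background-proportional pseudocount totaling 0.8 and scored as
Σ log2(p/background). A window's relative score is
(S − S_min)/(S_max − S_min) over the attainable score range; hits
require relative score ≥ 0.95 by default, both strands are scanned, and
antisense hits are reported in plus-strand coordinates. Ambiguous bases
contribute zero log-odds (background probability). A flat matrix
(S_max = S_min) is flagged degenerate and every window reports relative
score 1.0. Overlapping hits of one matrix are all reported.

The PBS search examines 18-mers at offsets 1–30 downstream of the 5'LTR
end (a superset of the canonical ~3–20 range; the offset is reported so
the expectation is checkable) against the reverse complement of each
tRNA's 3'-terminal 18-mer, with ties broken by smaller offset then
library order. The identity floor is 12/18: random sequence reaches 9/18
in almost every 30-offset window against even a small library, so a 0.5
floor would call a PBS on noise, while genuine PBSs at these divergences
sit at ≥ 16/18. Conservation logos use IC_i = 2 − H_i bits with Shannon
entropy over per-column base frequencies.

## Synthetic data

The generator plants elements whose statistical structure matches the
dating model's assumptions: a provirus is built from the reference with
its 3'LTR replaced by a copy of the 5'LTR (identical twins at
integration), then the two LTR copies and the internal region are
mutated independently at divergence rate × age, so the expected LTR–LTR
p-distance is ≈ 2 × 0.002 × age. Substitutions are per-site Bernoulli
draws with a Kimura kernel (κ = 2: transitions half of all
substitutions); each site mutates at most once per call, so the expected
changed fraction equals the target exactly, while two independently
mutated copies can collide at a site — the resulting LTR–LTR deficit is
≈ 3 % relative at age 20 My and is why clock-recovery slopes sit
slightly below 1. Deletions are applied after mutation. The synthetic
reference is a uniform-random 8,608 bp sequence with the canonical
region map, identical twin LTRs, and an optional planted PBS; it is a
synthetic stand-in, not the real Dfam entry.

Planted elements *replace* a same-length window of background sequence
rather than inserting, so gene and truth coordinates need no shifting;
for the analyses validated here (discovery, classification, integrity,
dating, context, association) the two constructions are equivalent.
Plants are spaced ≥ 12 kb apart (above the locus-merge gap) and placed
to satisfy requested context targets: "intron" fully inside an intron,
"exon" straddling an exon–intron junction (hence truth context
Exon_intron), "intergenic" clear of genes by a 200 bp margin.

What the synthetic validation does not show: performance on real genomic
repeat background (the background is i.i.d. uniform ACGT, the easiest
case for seed specificity), indel-rich divergence (indels default off),
GC structure, nested or tandem insertions, and the behaviour of BLAT's
exact scoring. Catalog replay, by contrast, exercises the summary and
clock arithmetic on real published values.

## Problem sizes and determinism

Default validation sizes are desk-scale by design: genomes of 0.4–1 Mb,
five seeded replicate genomes for recall/precision, 50 planted
proviruses for clock recovery, 20 null replicates for distribution-test
calibration. All randomness flows from explicit integer seeds through
numpy Generators; the pipeline writes no timestamps into report tables,
and rerunning a config byte-reproduces every output. Derived seeds are
decoupled (reference vs background genome) because two streams seeded
with the same integer are identical, which would embed a perfect
reference copy in the background.

## Known limitations

- Tandem distinct elements within the 10 kb merge gap fuse into one
  locus.
- Integrity is presence-based; a region can score 100 % while coding
  capacity is destroyed by substitutions or frameshifts (ORF analysis is
  out of scope).
- Majority consensus slightly underestimates divergence from the true
  ancestor for small screened sets, biasing internal ages low by a few
  percent in small groups.
- The chi-square and binomial constructions are both reported; neither
  is claimed to be *the* published per-chromosome procedure, which is
  not fully specified.
- PWM hit counts depend on the matrix set supplied; no matrix database
  is bundled.
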