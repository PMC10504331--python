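# Methods

This note records the models behind `pelagiscope`, the parameter defaults
and why they were chosen, what the synthetic generator does and does not
emulate, and the numerical conventions that make results deterministic.

## Recruitment model

An alignment is reduced to five integers: reference start, the
reference-consuming span from the CIGAR (M/=/X/D), the read length, and the
NM edit distance. Identity is defined as

    identity = (aligned_length − NM) / aligned_length

over reference-consuming columns, so NM's indel bases (when present) count
against identity. This matches common mapper semantics; other definitions
(per-read-base identity, gap-compressed identity) differ at the margins and
no single convention is universal.

Filter defaults follow the conservative virome-recruitment standard:
minimum identity **0.95**, minimum aligned-read fraction **0.90**, minimum
covered fraction (breadth) **0.40**. The breadth filter exists because
isolated genes shared with other community members can recruit reads to a
genome that is not actually present; requiring 40% of the genome to be
touched suppresses these false positives. Genomes failing breadth are
reported with RPKM zeroed and the raw value kept in a diagnostic column, so
abundance tables stay rectangular across samples.

Competitive assignment gives each read to the genome with the highest
identity, ties broken by longer alignment, then lexicographically smallest
genome id. The ordering is total, so assignment is independent of input
order.

RPKM = reads / (genome kb) / (million denominator reads). The default
denominator is the sample's total read count (`sample_reads`), matching the
practice of subsampling viromes to a fixed depth before recruitment;
`filtered_mapped_reads` is available for within-sample compositional use.

## Coverage, HVRs and DTRs

Depth is accumulated from alignment spans with a difference array;
deletions consume reference and count as covered, as depth-from-span tools
report them.

The HVR rule is relative: maximal runs of per-base depth **< 20% of the
genome-wide median**, kept at length **≥ 500 bp**. The median is the *lower*
median (element at index ⌊(n−1)/2⌋ of the sorted vector) so the threshold
is deterministic on integer profiles. Calls are suppressed entirely when
the median is below **10×** — at junk-level coverage a sub-median run says
nothing. The published precedent for this style of rule is sometimes quoted
with a "500 kb" minimum length; on a 35 kb genome that is a unit slip
(called HVRs in this size class are 1–5 kb), and 500 bp is the intended
floor. Note also that relative (20%-of-median) and absolute ("depth < 100")
formulations of the same call disagree when median depth is very high; this
package implements the relative rule only.

DTR detection is an exact string comparison: the largest L in
[min_dtr=20, max_dtr=1000] with prefix(L) == suffix(L), capped below half
the genome length. Mismatched repeats are out of scope. The complementary
coverage signature — terminal windows at ~2× the interior, because both
physical copies of the repeat recruit to the single collapsed copy in the
assembly — is exposed as `terminal_coverage_ratio`.

## ANI and taxonomy

ANI is fragment-based and bidirectional (ANIb-style): the query is cut into
non-overlapping 1000 bp fragments (a trailing fragment shorter than
max(100, fragment/2) is dropped), each fragment is placed at its best
edit-distance infix alignment in the subject (edlib), fragment identities
≥ 0.3 are averaged, and the two directions are averaged. Fragments below
0.3 identity are treated as "no hit", mirroring BLAST-based ANI.
Deterministic, no sketching. Values below ~75% are flagged unreliable:
down there the number is dominated by alignment method artefacts, so
published inter-family values are treated as qualitative.

Taxon assignment applies thresholds by single linkage (connected components
of the ≥-threshold graph): species at **95%**, genus at **60%**, the
convention used for phage isolate dereplication. Because the species edge
set is a subset of the genus edge set, species clusters provably nest
inside genus clusters.

Gene-content relatedness between two genomes with n_a and n_b protein
clusters, k shared, in a universe of N clusters, is the upper tail
P(X ≥ k), X ~ Hypergeometric(N, n_b, n_a), computed via scipy's log-gamma
implementation and verified against exhaustive subset enumeration for all
N ≤ 12. The universe defaults to the distinct clusters across the compared
genome set; "all clusters in the table" is available when the table is a
superset. Core genes of a group are the clusters with at least one member
in every genome.

## SNV population profiling

Per-sample pileups count A/C/G/T at each reference position from reads
passing the recruitment identity/fraction filters. Departure is
1 − consensus_count/coverage (bounded by 0.75 over four bases); consensus
ties resolve to the reference base. Position filters: coverage ≥ **10×**
and departure ≥ **0.10** — the field's usual SNV-profiling cut-offs, both
exposed in the config since published analyses often cite "recommended
cut-offs" without numbers. Sample filter: the genome must be ≥ **70%**
covered (breadth) for a sample's profile to enter the matrix; the 70%
cutoff is interpreted as breadth, not mean depth, consistent with how
covered-fraction cutoffs are used elsewhere in the pipeline.

The matrix holds departures for the union of SNV positions across retained
samples: a called SNV contributes its departure, a covered-but-invariant
position contributes 0, and a position under 10× in that sample is missing
(NaN). Missing entries are mean-imputed per position for clustering and
stay flagged in the output. Rows are clustered with average-linkage
Euclidean hierarchical clustering (scipy), cut at k groups or a distance
threshold; dendrograms serialise to Newick. Isolate genomes can join the
clustering as 0/1 pseudo-profiles (1 where the isolate differs from the
reference).

The substitution-accumulation estimator is deliberate arithmetic, not a
model fit: subs = μ · L · g · t for each of the two literature bounds on μ
(10⁻⁶ and 10⁻⁴ substitutions · site⁻¹ · infection⁻¹), with one
generation-equivalent per year as the default g.

## Ecology

Latitude bands on |latitude|: Polar [66°, 90°], Temperate [33°, 66°),
Tropical [0°, 33°). The source convention writes overlapping closed
intervals; here a boundary sample belongs to the higher band (66° is
Polar, 33° is Temperate), one fixed choice.

Prevalence: a genome needs non-zero RPKM in ≥ 5 samples before any
distribution claim. Regressions are plain OLS of RPKM on one covariate,
missing values dropped pairwise, two-sided slope p-values; the genome ×
covariate grid gets Benjamini–Hochberg q-values (raw p-values are kept
alongside). Effect sizes between genomes are the plain difference of
medians — not mean-of-bootstrap-medians — with a seeded percentile
bootstrap CI (default 5000 resamples); medians are used because
recruitment abundances are extremely skewed.

## Synthetic generator

What it emulates: i.i.d. genomes at a target G+C; exact planted terminal
repeats; strain populations with per-site substitution rates that differ
inside and outside a planted HVR interval; reads drawn multinomially from
community weights, uniformly positioned, with i.i.d. substitution errors;
SAM records reported against the *species reference* with NM equal to the
true mismatch count (strain divergence + error) — the mechanism that makes
planted HVRs drop out of recruitment exactly as diverged populations do in
real viromes; and sample environments along a latitude gradient
(temperature = 30 − 0.33·|lat| + N(0, 1) °C; oxygen, chlorophyll and
nutrients rising in colder water, salinity flat) with genome weights given
by user abundance models.

What it does not emulate: indels and structural variation, quality scores,
paired ends, chimeras, GC- or position-biased sampling, cross-genome
mapping ambiguity for unrelated genomes (a helper provides multi-reference
records only for substitution-derived sibling genomes). Passing tests
therefore demonstrate correctness of the quantification logic under a
clean substitution-only error model, not robustness to real library
artefacts. Defaults: read length 100 bp, error rate 0.5% — plausible
short-read values, configurable, not inferred from any particular dataset.
Scenario tests that need the 95%-identity filter to separate a 10%-diverged
population use 250 bp reads (the read length of 2×250 libraries): at
100 bp the mismatch binomial is too wide for >99% separation, at 250 bp it
is comfortably narrow.

Reads never overhang the linear genome ends, so terminal bases have
expected depth n/(L − L_read + 1) rather than n·L_read/L, and breadth
reaches 1.0 only at deep coverage; DTR coverage doubling is emulated by
optionally double-weighting start positions inside either repeat copy
(off by default).

All randomness flows from explicit integer seeds through
`numpy.random.default_rng`; identical seeds give byte-identical SAM/TSV
output. The pipeline driver fans a single global seed out to stages by
fixed offsets.

## Problem sizes in the test and acceptance runs

Simulated checks run at desk scale, chosen to keep every Monte-Carlo
tolerance at 3–4σ: HVR recovery uses 20 replicates of a 35,392 bp genome
at ~200× coverage (72,000 reads); recruitment fidelity uses 20,000 reads
over two 5 kb genomes; the ecology gradient uses 80 samples × 3,000 reads;
DTR recovery uses 100 planted 1.2 kb genomes; hypergeometric exactness
enumerates all 3,016 configurations with universe ≤ 12. Headline
biogeography statistics of the motivating study (global RPKM medians,
R² against temperature, absolute effect sizes) depend on the actual ocean
virome dataset and are not reproduced here; the pipeline instead
demonstrates recovery of planted effects with the same statistics.

## Known limitations

- ANI below ~75% is reported but flagged; do not use it for family-level
  claims.
- The HVR caller has no significance model; it is a thresholding rule.
- Competitive assignment only sees the alignments it is given; if the
  upstream mapper reports a read against one genome only, no competition
  happens.
- `read_sam` requires NM tags; records without them are skipped and then
  reported as a single error.
- Coordinates are 0-based half-open internally and in BED; human-readable
  reports are 1-based inclusive.
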