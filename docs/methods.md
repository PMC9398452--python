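# Methods

## The measurement model

Spike-in controlled ChIP-seq allows histone-mark densities to be compared
between samples and species: a fixed proportion of barcoded nucleosomes is
added to each chromatin preparation, so the ratio of barcode fragments in
ChIP versus input (E_si) calibrates the per-locus ChIP/input ratio
(E_locus). The histone modification density HMD = E_locus / E_si is
dimensionless; ~1 corresponds to the bulk level represented by the
spike-in panel, and constitutively heterochromatic regions run well above
it. Windows are 25 bp, non-overlapping, 0-based half-open (bin *i* covers
[25·i, 25·i+25)); "fragment coverage" is the mean per-base fragment depth
in the window. Windows with fewer than five input fragments are masked as
missing rather than producing unstable ratios.

## Per-TE magnitude and extent

Spreading of H3K9me2 from a silenced TE is local (it dies off within
~10 kb), so each TE is scored against its own neighbourhood:

- **Local background**: median of non-missing 25-bp HMD values pooled from
  20–40 kb upstream and downstream. Far enough that spreading does not
  contaminate it, close enough to track regional chromatin state. Regions
  truncated at chromosome ends fall back to the available side.
- **m-HMD**: per 1-kb window (anchored at the TE boundary, stepping
  outward in exact 1-kb strides; partial terminal windows dropped), the
  median of its 40 background-normalized units, requiring ≥ 10 non-missing
  units. Medians, not means, because HMD is right-skewed and occasional
  mapping artifacts produce extreme bins.
- **Magnitude**: mean of the two first-window m-HMDs; a TE with one
  estimable side uses that side alone.
- **Extent**: length of the initial run of windows with m-HMD strictly
  above 1, averaged over sides, capped at 20 kb. A missing first window
  makes the side unestimable; missing windows further out end the run.

Estimates are computed per replicate and then averaged per TE (a TE
missing in one replicate uses the other), rather than averaging tracks —
replicate-level estimates preserve the between-replicate variability that
the reproducibility checks look at. Flanking windows that overlap another
annotated TE are retained (dropping them would bias against TE-dense
regions); this is flagged for sensitivity analysis.

The two-genome variant, available when two strains of a species are
assembled, replaces the local background with the homologous TE-free
sequence in the alternative strain: magnitude is the ratio of first-window
m-HMDs, extent the farthest window where the focal m-HMD consecutively
exceeds the alternative one (also capped at 20 kb, for symmetry with the
single-genome estimate). TEs inside H3K9me2 peaks shared by both strains,
or whose homologous site lies within 1 kb of a TE in the alternative
strain, are excluded — the enrichment there cannot be attributed to the
focal TE.

Side asymmetry: for an intergenic TE with an identified genic side, the
z-score is (intergenic − genic) divided by the standard deviation of that
difference across all included TEs. The normalization constant is a design
choice (only "normalized difference" is prescribed by the estimator's
definition); an SD across TEs puts all genomes on a comparable scale. If
every difference is exactly zero the z-scores are zero; a nonzero constant
difference leaves the z undefined and raises.

## TE annotation rules

Raw repeat calls are post-processed deterministically: iterative family
assignment (a TE joins a family only if ≥ 80 % of its covered query bases
— the union of aligned query intervals, the denominator the rule leaves
open — hit one and only one family; newly assigned TEs join the reference
set for the next of four rounds); same-family records within 500 bp merged
(span = union, resolved greedily left-to-right after sorting),
different-family records within 500 bp both discarded; DINE-1 and
telomeric families (HeT-A, TART, TAHRE) removed; ≥ 500 bp and fully inside
the supplied euchromatin intervals required; full-length iff span ≥ 70 %
of the family's canonical length. Assignment precedes merging, matching
the order in which the inputs become available. Location category uses
exon > intron > intergenic precedence.

## Gene association

Each TE links to its closest gene (ties broken toward the smaller gene
id); orientation is strand-aware (upstream of the TSS ⇒ 5′). Genic HMD is
the mean over non-missing gene-body bins, with TE-containing genes
excluded. Expression is RPKM averaged over two replicates; genes at zero
in both replicates are dropped and the rest ranked descending (average
ranks for ties). Allele z-scores between strains: gene-body HMD z uses the
SD of the pooled per-bin values of both alleles (pooling, rather than
averaging per-strain SDs, follows the definition literally; flagged for
sensitivity); the expression-rank z uses the SD of the four per-replicate
rank values — the expression analogue is not otherwise pinned down.

## Population frequency

Presence/absence per population strain is decided purely from
contig-to-assembly alignment geometry (read filtering at MAPQ ≥ 50 and
contig assembly are upstream contracts): absent if one contig spans ≥ 20 bp
beyond both TE edges; present if two distinct contigs span the start and
end boundaries (each ≥ 30 bp inside, ≥ 20 bp outside, ≥ 50 bp total) or
one such boundary contig plus a contig wholly inside the TE; otherwise
missing. Contradictory evidence (absence and presence geometries from
different contigs) is called missing — conflicts have no prescribed
resolution, and discarding them is conservative. A focal TE absent from
every strain with a usable call is a singleton (low frequency); present
anywhere, high frequency; all-missing, unknown. Criterion (b)'s internal
contig has no minimum aligned length beyond what the aligner reports.

## Statistical layer

Group sizes in the comparative analyses are tiny (4 vs 4 genomes, ≤ 23
families), so the rank tests enumerate their exact null distributions:
Mann–Whitney p = 2·P(U ≤ min(U, n₁n₂−U)) over all C(n₁+n₂, n₁) group
assignments (average ranks for ties), capped at 1; the binomial sign test
doubles the smaller tail at p₀ = ½; Spearman enumerates all n!
permutations for n ≤ 9 untied observations and otherwise uses the
t-approximation (the exact route is the default; at n = 8 the two differ
enough to matter, so both are exposed). Logistic regressions are fit by
maximum likelihood with explicit separation/non-convergence flags —
with ≤ 30 insertions per family and collinear predictors, silent
quasi-separation would otherwise corrupt the coefficient signs that the
sign test consumes. Linear models report type-I (sequential) F-tests in
the stated predictor order; interaction models are expressed by adding a
product column. PGLS assumes Brownian motion on the supplied tree
(covariance = shared root-to-MRCA branch length), is solved by Cholesky
whitening, and reduces exactly to OLS under an identity-proportional
covariance. The gene-wise screen computes, per gene, the Spearman ρ
between expression rank and per-genome mean magnitude and the expression
coefficient from (magnitude ~ expression + species complex), then compares
a candidate gene set against the rest by Mann–Whitney and asymptotic
two-sample Kolmogorov–Smirnov (sample sizes there are thousands of genes).

## k-mer repeat quantification

Heterochromatic repeats too short or too repetitive to assemble are
quantified read-level: canonical 12-mer counts in IP and input, each
normalized by the library's uniquely-mapped (MAPQ ≥ 30) read count —
supplied as an external scalar, since alignment is out of scope — with
enrichment called at a threefold normalized ratio, inclusive (the boundary
convention is a choice; ≥ keeps the printed threshold attainable).
k-mers absent from the input but present in the IP are treated as
infinitely enriched and included. Abundance in PCR-free WGS reads is the
summed count of the enriched set per total read.

## The synthetic-data generator

The generator emulates the statistical structure the estimators assume,
with known truth:

- **Layout**: TEs and genes packed without overlap by stick-breaking of
  the free space (round-robin over chromosomes); `min_gap` optionally
  enforces isolation. Euchromatin boundaries cover the chromosomes.
- **Signal**: expected HMD = background (default 1) plus A·exp(−d/λ) from
  each TE edge, A the per-TE amplitude, λ the decay length (default
  2 kb, which puts the decay-to-background point near 10 kb). The decay
  form is a modeling choice — the spreading profile it mimics was observed,
  not parameterized — and is stated in the config rather than claimed as
  mechanism. Per-TE amplitudes are lognormal around the configured mean
  (CV default 0.5) so that true effects vary between TEs and rank-recovery
  is meaningful. TE bodies sit at background + A.
- **Restraint**: on a side whose nearest highly expressed gene (true
  RPKM ≥ 10) has its promoter within 20 kb, λ is multiplied by the
  restraint factor between the TE edge and that promoter, continuing at
  the unrestrained rate beyond it (continuous profile). Distant promoters
  exert no restraint.
- **Counts**: input ~ Poisson(mean coverage, default 25/bin; recovery runs
  use 100), ChIP ~ Poisson(coverage × expected HMD × spike-in ratio);
  `noise_dispersion` > 0 switches both to gamma-Poisson. Spike-in barcodes
  are two Poisson scalars around 400 fragments (the depth the experimental
  design targets) consistent with the configured ratio; barcode-panel
  specificity is not simulated.
- **Expression**: true RPKM lognormal (median 8, σ = 1.5 — a realistic
  span from silent to highly expressed), observed with 5 % replicate noise.
- **Population evidence**: each TE is a singleton or segregates (default
  half each, per-strain presence 0.3); evidence contigs follow the
  caller's geometries exactly, and a configurable fraction of strains gets
  a single boundary contig (satisfying no rule) to exercise the missing
  path.

The generator also supplies the oracle for the extent: a Monte-Carlo
expected run length that simulates window medians and a background median
directly from the count model, without touching the estimation code. The
oracle models an isolated TE, so recovery comparisons enforce
`min_gap = 80 kb` — flanks (20 kb) and backgrounds (20–40 kb) of adjacent
TEs must not overlap, otherwise neighbour contamination shifts means and
correlates per-TE estimates.

What passing recovery tests show — and what they do not: the generator
draws independent Poisson counts around a smooth expected profile. Real
ChIP data add mappability gaps, fragment-length autocorrelation between
adjacent bins, copy-number variation, antibody efficiency differences and
cell-type heterogeneity (embryos average over tissues). Recovery of A and
the run-length expectation therefore validates the estimator's arithmetic
and its behaviour under count noise, not robustness to alignment or
biological artifacts.

## Numerical choices and degenerate inputs

Medians of even-length samples are midpoint-interpolated. Exact-test
enumeration uses a 1e-9 slack when comparing tied U values and 1e-12 for
permutation ρ. Zero spike-in counts, zero normalizers, constant responses,
rank-deficient designs, single-TE asymmetry sets and sub-minimum
observation counts raise instead of returning values. All simulation
randomness flows from a single integer seed through named substreams, so
identical configurations are bit-identical.

## Known limitations

- Alignment, assembly, peak calling, SV-based boundary refinement and
  ortholog mapping are consumed as inputs, never re-implemented; their
  error modes are invisible here.
- The family-assignment denominator, the side-z normalization, the pooled
  allele-z SD, the inclusive threefold k-mer threshold and the missing-on-
  conflict population rule are documented choices where the estimator
  definitions leave room; each is centralized so sensitivity analyses can
  swap them.
- Exact Spearman p-values at n = 8 differ from the t-approximation by
  enough to move borderline calls; both routes are exposed.
- The extent estimator's expectation depends on coverage through the noise
  in window medians (deeper data ⇒ longer runs); comparisons across
  samples assume comparable depth.
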