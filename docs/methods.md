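# Methods

This note documents the models and procedures implemented in `clipmaps`,
the defaults and why they were chosen, the design decisions taken where
several readings were possible, and what the synthetic validation does and
does not establish.

## Site model and occupancy

A cross-link site is a genomic T (on the read strand) with transition count
*k*, coverage *n* and an upstream-assigned p-value. The package consumes
sites with p-values already attached; the upstream read processing and the
site-level statistical model are out of scope by design.

- **High-confidence filter**: keep sites with p ≤ `p_max` (default 0.005)
  and coverage ≥ `min_coverage` (default 2). Both bounds are inclusive.
- **SNP filter**: a position where ≥ 75% of input-library reads carry the
  same transition is a strain SNP, not a cross-link; such sites are
  removed. Positions absent from the control are untouched.
- **Occupancy**: `occupancy = transitions / input_coverage`, the input
  coverage being the control library's RNA concentration at the site. This
  normalizes binding for transcript abundance. Sites with zero control
  coverage have an undefined ratio and are dropped (count logged) rather
  than pseudocounted: the control is measured under comparable conditions,
  so a site it does not cover is not trustworthy.
- **Capping**: occupancies above the dataset's 95th-percentile value are
  replaced by that value. The empirical quantile uses linear interpolation
  between order statistics (numpy's default), stated here so results are
  bit-reproducible. Capping is applied per merged factor dataset, after
  filtering; whether the original analyses capped before or after
  transcript-level aggregation is not determinable, and the choice is
  isolated in one function.
- **Replicate merging** sums k and n per position; the merged site carries
  the *minimum* replicate p-value. Re-deriving pooled p-values would
  require the upstream site model, which is out of scope; the minimum rule
  preserves the ordering the filters need and is isolated in
  `merge_replicates`.

## Transcript classes and enrichment

Overlapping annotations are resolved per nucleotide by the fixed priority
rRNA > tRNA > snRNA > snoRNA > intron > CDS > UTR > SUT > CUT > NUT. The
single UTR slot covers utr5 and utr3 (they cannot overlap within one
gene's chosen isoform). One isoform per gene is kept: the most abundant,
ties broken by length then lexicographic id so selection is deterministic.

Per factor, each high-confidence site contributes its read coverage to the
one class at its position. The factors × classes matrix X is
log₂-transformed (zero cells get pseudocount 1, logged when applied) and
double-centered:

    X̃[f,c] = X′[f,c] − mean_c X′[f,·] − mean_f X′[·,c] + mean X′

This is the unique linear correction after which every row and column sum
is zero; it removes factor-specific depth and class-specific size offsets
so X̃[f,c] measures binding of factor f to class c *relative to the other
factors and classes*. The per-class coefficient of variation is computed
on per-factor class fractions (row-normalized raw counts, population SD /
mean); computing it on centered scores would divide by a zero mean. The
choice is config-exposed.

## Metagene profiles

Profiles average site occupancy over mRNA major isoforms aligned at the
TSS or pA site (or stop codon / gene boundaries) over offsets ±700 nt,
5′→3′ in transcript orientation. Eligibility: length ≥ 1500 nt and no
other mRNA within 700 nt on the flank outside the anchor (upstream of the
TSS, downstream of the pA site) — on the same strand for sense profiles,
on the opposite strand for antisense profiles, so the signal comes from
the central gene only. Short-ncRNA profiles (e.g. snoRNA-anchored) drop
the length filter via `min_length=0`.

Sites in snRNAs, rRNAs and tRNAs are removed before profiling (they
dominate raw signal); explicit interval exclusion supports removing
annotated NUT/CUT regions when testing where an upstream signal
originates. Offsets beyond a transcript's chromosome end contribute 0:
averaging is over a fixed window of length-filtered transcripts.

Smoothing is a centered 41-nt moving average applied to the
transcript-averaged profile (not per transcript), with window truncation
at the edges — no padding invents data outside ±700. The 95% confidence
band is a percentile bootstrap over transcripts (default 1500 iterations,
implemented as multinomial reweighting so it is a single matrix product);
the same smoothing is applied inside each replicate so the band matches
the curve, and the band is clamped to contain the point estimate. Profiles
are min–max normalized after smoothing (the order is a config flag); a
constant profile cannot be normalized and is emitted as zeros with a
warning. The normalization makes the antisense maximum equal the
background binding level when a factor has no true antisense signal.

## Co-occupancy, co-localization, embedding

Occupancy of a factor on a transcript is the sum of its site occupancies
inside the transcript, strand-aware; a site overlapping several same-strand
transcripts counts toward each (a unique-assignment mode exists).
Co-occupancy is the Pearson correlation of these totals between factors
over all transcripts. Co-localization sums factor f's occupancy at offsets
±1..±40 around each of factor f′'s sites (the centered T excluded), then
normalizes z[f,f′] by (row total × column total); since the final score is
the Pearson correlation between rows of the normalized matrix, the
transposed normalization reading (also provided) changes only the
intermediate. The 2-D embedding applies t-SNE to distances 1 − r with a
fixed seed; perplexity is capped below the number of factors. t-SNE is a
called standard algorithm, not reimplemented.

## Translation- and decay-linked binding

- **Transcript optimality**: unweighted mean of per-codon optimality
  scores over the reading frame. The score table is an input; synthetic
  tables draw scores uniformly.
- **Codon enrichment** for a factor: occupancy-weighted mean codon
  fraction over the unweighted mean, per codon. Uniform occupancy gives
  exactly 1 for every codon; the identity Σ_c w̄_c·score_c / Σ_c w̄_c = 1
  (weights = mean codon fractions) holds by construction. 90% CIs come
  from bootstrapping transcripts with replacement (default 1000 draws).
  Fractions are computed over sense codons; stop codons are excluded
  (config-exposed).
- **Feature curves**: transcripts trimmed to the feature's 5–95% quantile
  range, sorted by feature, sliding-window mean of occupancy with window =
  10% of the retained transcripts (the window fraction is config-exposed;
  the original curve estimator is not named anywhere, and a windowed mean
  is the simplest estimator producing curves of the observed smoothness).
- **Surplus-binding model**: ordinary least squares of total occupancy on
  half-life, `occupancy = a·t½ + b`, after 5–95% trimming of half-lives.
  *b* is baseline binding to all transcripts; *a·t½* is surplus binding to
  transcripts undergoing degradation (a factor recruited only upon
  degradation has a ≫ b). Percentile-bootstrap 95% CIs for a, b and a/b;
  an intercept whose CI excludes positive values makes a/b unstable and is
  flagged. The fit is scale-equivariant: scaling occupancies by k scales a
  and b by k and leaves a/b fixed.
- **Feature significance**: Gaussian linear model of per-nucleotide
  occupancy (total/length, which removes the trivial length dependence) on
  length, optimality, expression and half-life; transcripts restricted to
  the intersection of per-feature 5–95% ranges (the per-feature-independent
  alternative changes the retained set only marginally and the intersection
  is reproducible). Each feature's p-value is the likelihood-ratio test of
  the full model against the model with that feature deleted, χ²(1); the
  full-model coefficient sign gives the correlation direction. Features
  enter untransformed by default (log flags exist for the skewed ones);
  condition number > 1e8 of the standardized design raises a collinearity
  error naming the worst pair.

Half-lives, expression and optimality come from input tables. The
half-life estimation method itself is out of scope; synthetic half-lives
are lognormal (median 15 min, log-SD 0.6 — the range of published yeast
mRNA half-life compilations) with a configurable Gaussian-copula
correlation to optimality and expression, since these features are
inter-correlated in real data and the regression exists precisely to
disentangle them.

## Positional k-mer enrichment

Up to 5000 sites per factor are used, ranked by ascending p-value with
ties broken by descending occupancy then coordinate (deterministic).
Windows span sequence positions −5..+8 around the cross-linked T so that
4-mer start offsets −5..+5 are fully covered; minus-strand windows are
reverse-complemented so the cross-linked base reads as T at offset 0.
Enrichment per (k-mer, offset) cell:

    enrichment = (n + 1) / (N · Π_j P_base[j])

with background P_A = P_T = 0.31, P_C = P_G = 0.19 (yeast genome
frequencies). The position coinciding with the cross-link contributes no
background factor ("T-bias correction": every window has T there by
construction, so P = 1); the uncorrected variant is available and labeled
in output metadata. Cells whose k-mer covers offset 0 with a non-T base
are infeasible and masked. The matrix is reported as log₂. Note that the
+1 pseudocount biases the expected null enrichment of rare (CG-rich)
cells above 1 — at N = 1000 background windows the mean feasible-cell
enrichment is ≈ 1.2, not 1.0 — which is why depletion scores saturate at
small N.

## Synthetic data generator

The generator emulates the statistical structure the analyses assume, not
raw sequencing: i.i.d. genomes at yeast base frequencies; transcripts
placed with configurable spacing (an isolated fraction with ≥ 1600-nt
flanks passes all metagene neighbor filters); mRNAs with utr5/cds/utr3
segments (CDS a clean ORF — in-frame stops rewritten — with optional
intron); ncRNA classes at study-like proportions scaled down ~30×;
features from a Gaussian copula with configurable correlation; an input
control with coverage ∝ expression, multiplicative lognormal noise, a 10%
antisense/flanking pervasive-transcription background, and planted SNP
positions (transition fraction ≥ 0.75). Factor datasets draw transcripts
∝ class weight × (a·t½ + b) (or an explicit per-transcript weight
vector), positions from uniform / Gaussian-at-anchor / 5′-exponential
profiles snapped to the nearest strand-sense T, transition counts
negative-binomial around occupancy × control concentration (so capping
sees realistic tails), and p-values Uniform(0, 0.005) for planted sites
versus Uniform(0.005, 1) or coverage-1 for decoys — filters only need the
ordering, and the upstream p-value model is out of scope. Per-site
occupancy noise has constant mean so a transcript's *total* occupancy
stays proportional to its planted weight, keeping the surplus-binding
relation linear. Motif preferences are planted by writing the k-mer into
the genome at the stated offset from selected sites; composition bias by
rewriting codons toward a target fraction. Everything is deterministic
under the configured seeds (byte-identical site tables).

What passing synthetic checks shows: the implementations recover exactly
the structure they claim to measure, at realistic sizes, through the same
code paths real data would take. What they do not show: robustness to
mapping artifacts, PCR duplicates, non-uniform fragmentation, U-content
differences between classes, or misannotation — none of which the
generator emulates.

## Validation problem sizes

The validation experiments (`clipmaps.validation`, driven by
`scripts/acceptance.py` and `tests/test_acceptance.py`) use: 100 random
30×13 matrices for centering margins; 2000 sites with 30% decoys for
filter fidelity; 5 factors × 10 seeds with 5-fold planted preferences
(≥ 20,000 reads per factor) for class enrichment; 500 isolated mRNAs with
2500 sites (Gaussian at pA−100, SD 30) plus a 6×-deeper uniform background
factor for metagene recovery; 100 replicates × 2000 transcripts × 500
bootstrap draws for the half-life model; 500 null simulations (n = 400)
plus one n = 2000 power run for the likelihood-ratio test; 500 mRNAs with
a 2× AAA fraction planted in half for codon enrichment; 1000 background
windows and 5000 sites with 50% planted AAAA for motifs; and 3 groups × 3
factors × 6000 sites over 1000 mRNAs, 5 embedding seeds, for
co-occupancy. The half-life experiment plants additive Gaussian noise of
amplitude 0.1 on the occupancy scale; under least squares, multiplicative
noise of the same nominal size would leave the small intercept
statistically unidentifiable at this sample size, which is a property of
the estimator, not of the implementation.

## Known limitations

- Merged-replicate p-values use the min rule (see above), so merged
  site lists are slightly anti-conservative at the p-boundary relative to
  a pooled re-evaluation.
- The co-localization intermediate C depends on which marginal-product
  normalization is chosen; only the final correlation matrix R is
  invariant, and only R should be interpreted.
- t-SNE coordinates are seed-dependent; only neighborhood structure is
  meaningful, and the validation checks nearest-centroid separability over
  several seeds rather than coordinates.
- The LRT assumes Gaussian errors; with heavy-tailed occupancy residuals
  its p-values are approximate (the null calibration check passes at the
  sizes used, but real occupancy distributions are heavier-tailed than the
  generator's).
- Antisense profiles of a factor with no antisense sites are identically
  zero and are reported as degenerate (all-zero after normalization, with
  a warning) rather than as a max/mean ratio.
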