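# Methods

This note documents the models and procedures implemented in `floramap`,
the assumptions behind them, the parameters that matter, and the places
where a genuine design choice had to be made.

## Read cleaning

Paired 2×150 bp reads carry an inline 8-mer barcode and the trnL g/h
primers (g: `GGGCAATCCTGAGCCAA`, h: `CCATTGAGTCTCTGCACCTATC`) on both mates.
Because the P6-loop amplicon (10–143 bp) is usually shorter than the read,
most pairs are *palindromes*: each mate contains the entire amplicon and
runs on into the opposite adapter. Merging therefore scans **all** overlap
offsets of the reverse-complemented mate against the forward mate, in both
innie (overlap at the read ends) and outie (overlap at the read starts)
geometry, and accepts the offset with the most matching bases subject to an
overlap of ≥10 nt at ≥75% identity. In outie geometry the bases overhanging
the overlap on either flank are adapter read-through and are trimmed. Ties
between candidate offsets are broken toward the longer merged insert and
then toward the smaller offset; disagreeing overlap bases take the
higher-quality base, with the forward base winning quality ties. No
fragment-length prior is used (the merge is purely identity-maximising).

Demultiplexing happens on the merged read: exactly one barcode within 1
mismatch at each end, both ends agreeing, and both primers within 1
mismatch. Reads within 1 mismatch of two different barcodes are discarded
as ambiguous rather than assigned — the conservative choice, avoiding
cross-sample bleed. Barcode, primers and their reverse complements are then
trimmed, and the quality filter (arithmetic mean Phred strictly greater
than 30, computed on raw Phred scores over the retained bases only) and the
length filter (insert ≥ 20 nt) are applied in that order. The
`CleaningReport` satisfies kept + removed = input at every stage by
construction, and the batch totals are tested against an independent
per-read re-application of the four rules.

## Pairwise identity

Clustering and the internal similarity search share one aligner: a fitting
semi-global alignment (query aligned end to end, subject end gaps free)
with match +1, mismatch −1, gap −2. Identity is matching columns over
alignment columns; internal gaps count as columns, subject end gaps do not.
Aligning the query globally is essential: with free end gaps on *both*
sequences, two unrelated sequences share a perfect one-column overlap and
identity becomes meaningless as a clustering criterion. Tie-breaks are
pinned (diagonal > up > left; endpoint = first maximum scanning the last
row left to right) so that any independent implementation of the same
convention reproduces the exact (matches, columns) pair — the test suite
contains such an oracle.

## Chimera screening and clustering

Chimeras are modelled as two-parent recombinants among dereplicated
sequences. A candidate is flagged when some breakpoint lets a left parent
and a distinct right parent — each with at least 2× the candidate's
abundance, the usual de novo abundance-skew convention — jointly explain
strictly more of its positions than any single parent, at a combined
identity ≥ 0.99 over the candidate. Both parent arms must span at least 10
positions: a one-base terminal arm carries no evidence of recombination and
would let a coincidental match adjacent to a point mutation masquerade as a
breakpoint. Per-parent match profiles use direct positional comparison when
parent and candidate are equal length (exact for the concatenation model)
and the aligner otherwise. The detector is calibrated for perfect recall on
constructed equal-length chimeras and zero false positives on point mutants
over a seeded 200-case suite; realistic PCR chimera formation (partial
extension, multi-parent) is out of scope.

Clustering is greedy and abundance-ordered: unique sequences sorted by
decreasing total count (ties lexicographic) each join the first centroid at
≥ 97% identity or found a new OTU, making the result independent of input
file order. A singleton is an OTU whose *global* count is 1; singletons are
dropped from the table and counted. Clustering is pooled across samples,
matching the single global OTU inventory the analysis uses.

## LCA consensus taxonomy

Hits for a query are truncated to the 300 best by score (hits tied with the
300th score are all kept, so the rule is stable under input order), then
filtered to query coverage strictly above 80% (denominator: query length —
the centroid — since that is the length whose representation matters).
Voting proceeds from species downward: at each rank only hits with identity
strictly above the rank threshold (97/95/90%) are eligible, and the query
is assigned when ≥51% of the eligible, rank-named hits agree on the entire
lineage down to that rank (hierarchical consistency, so a species winner's
genus and family are automatically its ancestors). The 51% is read as a
fraction of the rank-eligible retained hits, not of the original 300; both
the fraction and the thresholds are configurable. Unassigned OTUs and OTUs
resolving to non-plant kingdoms are removed before community analysis, with
removal counts reported per category.

One caveat is worth stating because it is easy to assume otherwise: the
resolved rank is **not** monotone in the identity thresholds. Lowering the
species threshold admits additional (typically congeneric) hits into the
species-eligible set; those hits can break the 51% species consensus while
the genus consensus still holds, so a more permissive threshold can yield a
*shallower* assignment. This is intrinsic to consensus voting with a
rank-eligible denominator, and the test suite demonstrates it on random hit
tables. Removing a dissenting hit, by contrast, can never demote an
assignment, and that property is asserted over the same tables.

## Size factors, dispersion trend, and the VST

Sequencing depth is normalised by DESeq-style median-of-ratios size
factors (reference: per-OTU geometric mean; fallback to positive entries
when no OTU is present everywhere), rescaled to geometric mean 1. Per-OTU
dispersions are method-of-moments, α̂ = (s² − μ̄)/μ̄², on normalised counts,
and the parametric trend α(μ) = a₀ + a₁/μ is fitted across OTUs by
iteratively reweighted least squares with Tukey-bisquare weights, which
resists the heavy upper tail of moment estimates. This is deliberately not
a full shrinkage/GLM pipeline: only the trend is needed for the transform,
and the moment + robust-regression fit recovers (a₀, a₁) well within the
tolerances the tests assert on simulated negative-binomial counts.

Under the trend the NB variance is v(μ) = (1 + a₁)μ + a₀μ², and the VST is
the closed-form antiderivative of v^{-1/2}:

    vst(x) = log( (2a₀x + b + 2√(a₀x(a₀x + b))) / b ) / √a₀,   b = 1 + a₁,

which is 0 at x = 0 (no pseudocount needed), strictly increasing, and tends
to 2√(x/b) in the Poisson limit a₀ → 0. Per-site VST richness is the *sum*
of transformed values over OTUs (a mean or diversity index would also be
defensible; the sum is the default and configurable).

## Spatial correlation

Distances are haversine great-circle kilometres on a sphere of radius
6371 km (mean Earth radius). Distance classes are equal-frequency (sorted
pairs split into near-equal chunks), 13 classes by default, following the
reference implementation of the modified t-test. Per class, Moran's I with
binary weights estimates the spatial correlation of each variable; the
class values fill symmetric correlation matrices R_x, R_y (diagonal 1), and
with the centring projector B the estimated variance of the sample
correlation is var(r) = tr(B R_x B R_y)/(tr(B R_x)·tr(B R_y)). The
effective sample size M̂ = 1 + 1/var(r) is clamped into (2, n] (M̂ = n
exactly when both correlograms vanish), and significance uses
F = (M̂ − 2)r²/(1 − r²) on (1, M̂ − 2) degrees of freedom, reported next to
the naive p-value. Degenerate correlogram estimates (non-positive variance)
fall back to no correction rather than an undefined test. Metric pairs use
pairwise-complete deletion; metrics observed at fewer than 10 sites are
skipped with a warning.

On simulated independent fields sharing a 3000 km autocorrelation range the
corrected test holds its size (≈0.05 at α = 0.05) while the naive test
rejects more than half the time; on iid fields the mean M̂/n stays near 1.

## Ordination

Bray–Curtis distances are computed on variance-stabilised abundances;
because the VST can dip below zero at low counts, matrices are shifted by
the global minimum first (clamping is the configurable alternative). PCoA
is the Gower double-centring −½ J D² J; negative eigenvalues (Bray–Curtis
is semimetric) are reported but their axes dropped, and total inertia is
the sum of positive eigenvalues, so constrained + residual = total holds to
machine precision on every run. dbRDA regresses the PCoA coordinates
jointly on centred climate covariates (collinear columns dropped by pivoted
QR with a warning); the permutation test permutes covariate rows and uses
the add-one convention p = (1 + #{F* ≥ F})/(1 + n_perm) with 999
permutations by default. Constrained axes are reported vegan-style
(constrained eigenvalues first, then residual axes). Biogeographic realm
labels are consumed from the manifest, and per-realm centroids carry 1-SD
ellipses from the 2×2 score covariance.

## Grid and smoothing

The equal-area grid splits the sphere into latitude rings subdivided into
longitudinal sectors. Ring counts come from an equal-colatitude template,
adjusted to sum exactly to the requested cell count; ring boundaries are
then re-derived so each band's area is exactly its sector count times
4πR²/n — every cell has *identical* area, and 65,612 cells on the 6371 km
sphere give 7,773.95 km² each. Containment is a two-step lookup (ring by
sin(latitude), sector by longitude) with half-open boundaries, so every
point maps to exactly one cell. This is a behavioural stand-in for a
hexagonal discrete global grid: the analysis needs only the equal-area
partition and point-in-cell lookup, not hexagon adjacency.

Field interpolation is Nadaraya–Watson with a Gaussian kernel on
great-circle distance — a pragmatic replacement for a spline-on-the-sphere
smoother that keeps predictions inside the observed range (convex weights)
and tends to the global mean at large bandwidth. Prediction points with no
observation within 5 bandwidths are masked as unsupported, mirroring the
exclusion of severely undersampled regions; the bandwidth can be chosen by
leave-one-out cross-validation. Match-ratio maps use a continuity-corrected
natural log, ln((matched + ½)/(unmatched + ½)), finite at zero counts and
antisymmetric; base and correction are configurable since neither is pinned
down by convention.

## The synthetic-data generator

`synthio` emulates the statistical structure the analysis assumes, not any
particular organismal reality:

* **Taxonomy and marker sequences.** A balanced kingdom/family/genus/
  species tree; per family a random ancestor sequence of length uniform on
  30–143 nt (the P6 envelope narrowed so post-primer inserts pass the 20 bp
  filter), genus ancestors at 0.20 substitutions/site from the family
  ancestor and species at 0.10 from the genus ancestor. These defaults put
  congeners well below the 97% clustering/species threshold, so the default
  scenario has fully distinguishable species. The real P6 loop often cannot
  separate congeners (e.g. in large grass and composite genera); that
  harder regime is reachable by lowering the within-genus rate, and passing
  tests on the default scenario says nothing about it. No indels are
  simulated within families.
* **Reads.** Amplicon = barcode + primer + insert + rc(primer) + rc(same
  barcode), padded with a fixed adapter; both mates are the first 150 nt of
  their strand, so inserts shorter than ~95 nt produce the outie/palindrome
  geometry and longer ones the innie geometry. Substitution errors are iid
  per base (0.5% default); per-pair quality levels are drawn so a
  configurable fraction (5% default) fails the mean-Q30 rule. Barcodes are
  random 8-mers with pairwise Hamming distance ≥ 3, so 1-mismatch
  demultiplexing cannot be ambiguous by construction.
* **Landscape.** Sites uniform over a European-scale window (35–70°N,
  −10–40°E). MAT = 30 − 0.6·|lat| + N(0, 4.0²) — the anomaly term stands in
  for continentality and topography, and its scale matters: with a
  near-deterministic latitudinal MAT, the Dutilleul correction correctly
  reports only a handful of effective samples no matter how many sites are
  added, and no climate correlation can reach significance. Log richness is
  β₀ + β₁·MAT + β₂·MAP + η with defaults (2.5, 0.08, 0) and η a Gaussian
  field with exponential great-circle covariance (range 1500 km, SD 0.3).
  Communities are assembled by thermal niches (Gaussian weights around
  per-species MAT optima, σ = 6 °C, Gumbel top-k), giving climate-driven
  compositional turnover for the ordination; abundances are lognormal with
  a floor of 3 reads so genuinely present species survive singleton
  exclusion. Occurrence tables detect each present species with fixed
  probability; independent richness-estimate columns are noisy, smoothed
  transforms of true richness.
* **What it does not emulate:** PCR amplification bias, chimera formation
  (constructed chimeras exist only in the cluster tests), indel sequencing
  error, contamination, shared species pools between distant realms, or
  reference databases with intraspecific variation. Green tests on this
  generator validate the *machinery* — bookkeeping, thresholds, estimators,
  calibration — not field performance on real soil eDNA.

## Problem sizes and numerical choices

The integration fixtures use 24–72 species, 12 sites and ~60–120 read pairs
per site; the end-to-end recovery and correlation checks use 150 sites,
which is where the spatially corrected test has comfortable power for the
simulated effect. Calibration suites use 200 replicates (type-I error,
permutation calibration) and 2000×50 count matrices (VST), all seeded.
Cholesky factorisations add 1e-9 to the diagonal; PCoA eigenvalues below
1e-12 of the largest are treated as zero; the ESS clamp is (2 + 1e-9, n].
One master seed fans out to per-stage child seeds via a seed sequence, so
every pipeline rerun is byte-identical.

## Known limitations

* The greedy clusterer is O(uniques × centroids) alignments — desk-scale by
  design; it has no k-mer prefilter and is not meant for millions of reads.
* The internal similarity search is all-vs-all and serves as the
  BLAST-free oracle for synthetic data; real studies should feed external
  tabular hits through `load_hits`.
* The Dutilleul correction assumes second-order stationarity; strongly
  trended fields yield very small effective sample sizes, which is the
  method behaving as designed rather than failing.
* dbRDA covariates are tested jointly; marginal per-covariate tests and
  partial (conditioned) models are not implemented.
* The equal-area grid preserves area exactly but not shape; cells near the
  poles are long thin sectors, which is irrelevant for point-in-cell
  aggregation but unsuitable for neighbourhood analyses.
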