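# Methods

This note documents the statistical models behind `cropgs`, the choices
made where the design was genuinely open, what the synthetic-data
generator does and does not emulate, and the numerical details that
affect results.

## Synthetic data

### Populations

`simulate_populations` draws ancestral allele frequencies Uniform(0.05,
0.95) and diverges each population from them with a Balding–Nichols Beta
draw: population frequency ~ Beta(p(1−F)/F, (1−p)(1−F)/F), where F is
the target fixation index. Under this model the expected Hudson F̂_ST
(ratio of averages) between two populations each diverged at F equals F,
which is what the calibration tests check (0.1 ± 0.02 at 100 samples per
population and 5,000 loci). Wild accessions are heterozygous
Hardy–Weinberg diploids; cultivated lines are fully inbred (dosage 0 or
2 — no residual heterozygosity, which keeps hybrid construction exact).
An optional `wild_subgroups` parameter adds within-wild substructure via
a second Balding–Nichols layer; it is off by default so the pairwise
F_ST calibration holds exactly.

Selective sweeps are frequency pushes, not coalescent simulations: inside
each designated window the cultivated frequency moves a fraction
`sweep_push` (default 0.95) of the way to the nearer fixation point.
At the default strength this depresses cultivated window diversity
roughly 13-fold, comfortably beyond the tenfold contract the scan is
meant to flag, and simultaneously inflates window F_ST — the joint
signature the outlier rule looks for. What a push cannot emulate is the
haplotype structure of a real sweep (no excess LD, no skewed SFS beyond
the frequency shift), so passing sweep-recovery tests demonstrates the
scan arithmetic, not power against realistic sweep genealogies.

### Parental pools and hybrids

`simulate_parent_panel` produces fully inbred B- and R-labelled lines.
With `group_fst > 0` the two pools are diverged around the ancestral
frequencies, emulating separated maintainer/restorer breeding pools;
between-pool crosses then segregate at more loci, and with directional
(positive) dominance effects this produces genuine heterotic-group
structure that the clustering step can rediscover. `make_hybrids` sets
the hybrid dosage to the parental mean; a dosage of 1 marks loci where
the parents carry different homozygotes, which is exactly the dominance
indicator Z_D.

### Genetic architecture and phenotypes

The trait architecture is 500 causal loci by default (configurable) with
exponential-magnitude, random-sign additive effects; dominance effects,
when requested, are exponential-magnitude and positive (directional
dominance), scaled so the dominance-to-additive variance ratio over
causal loci equals `dominance_ratio`. The count and the exponential law
are conventions for a polygenic yield-like trait, not estimates.

`simulate_phenotypes` generates one record per genotype × environment ×
replication, with environments forming a year × stress grid (defaults: 2
years × 3 stress regimes × 2 replications, the layout of a managed
drought-stress trial). Genetic values are standardised to variance
σ²_g; year/stress main effects, G×Y, G×S, G×Y×S, block and residual
terms are i.i.d. normal draws. Blocks are balanced and nested in
replications — a deliberate simplification of an alpha-lattice layout;
it preserves the variance structure the estimators consume but not
incomplete-block recovery. The residual variance is solved from the
target line-mean heritability

    h² = σ²_G / (σ²_G + σ²_GY/y + σ²_GS/s + σ²_GYS/(ys) + σ²_e/(ysr)),

so the realized heritability matches the target in expectation (the
ANOVA estimator's sampling s.d. is ≈0.05 at 300 genotypes, which is why
calibration tests average a few replicates). Requesting h² = 1 together
with a positive residual variance is rejected as inconsistent.

All generators are pure functions of (parameters, seed): one
`numpy.random.default_rng` stream per call, no global state.

### K-mer coverage

`simulate_reads_kmer` defaults to the per-k-mer Poisson-depth model:
each of the genome's L−k+1 k-mers receives a Poisson(depth) count. This
is the model under which "genome size = total k-mers / peak depth" is
exact, and it is fast. A literal read-sampling mode (`mode="reads"`)
draws fixed-length reads and counts canonical k-mers. Sequencing errors
are out of scope; the low-depth error-peak cutoff in
`estimate_genome_size` (default 3) exists for real histograms where
error k-mers dominate depths 1–2.

## Diversity scan

Per-site diversity is the unbiased heterozygosity 2p̂(1−p̂)·n/(n−1) over
the site's called alleles; inbred samples contribute two identical
alleles (an option to count them as one haploid allele is available via
the allele-count interface). Watterson's θ uses each site's own allele
number in the harmonic correction; Tajima's D uses the window's median
allele count, the 1989 constants, and is reported as missing (never 0)
when S = 0. Hudson's F_ST is aggregated per window as a ratio of
averages — Σnum/Σden over sites — which the tests assert against the
per-site decomposition. Weir–Cockerham is deliberately not the default:
with two populations of unequal structure (inbred vs outbred), Hudson's
estimator has the cleaner per-site decomposition.

Windows are 1-based inclusive, default 100 kb, non-overlapping (the step
is configurable); a variant at the exact window end belongs to that
window. Per-bp statistics divide by the window's effective (non-N)
length when one is supplied, else by the window size. The diversity
ratio is −log₁₀(π_cult/π_wild) — base 10 so that 1 means a tenfold
loss — and is undefined (excluded, never clamped to ±∞) when either
diversity is zero. Outlier thresholds are empirical type-7 quantiles
over windows where both statistics are defined; a window is flagged only
if it exceeds both thresholds, and adjacent flagged windows merge into
regions. Under independence the joint flag rate is (1−q)², which the
null test checks.

LD decay computes r² as the squared Pearson correlation of dosages —
exact haplotype r² for inbred lines, an approximation for heterozygous
samples — bins it by physical distance, and reports the first
linear-interpolated crossing of the binned means below the threshold
(default 0.2), anchored at r² = 1 at distance zero. The p-distance is an
allele-sharing distance on dosages (mean |Δdosage|/2 over mutually called
sites), since the pipeline is VCF-only and has no sequence alignment;
neighbor joining is delegated to scikit-bio with negative branch lengths
clamped to zero. PCA mean-imputes missing dosages, column-centers, and
uses the SVD; variance explained is relative to the total, so it is
non-increasing and sums to at most 1.

## Genomic prediction

The GRM follows the frequency-centered formula with allele frequencies
taken from the analysed sample itself (no external reference panel).
Monomorphic markers are dropped before the GRM — they contribute nothing
to the numerator and would not change W, but dropping them keeps the
denominator interpretable. With missing data, each pairwise entry uses
only the markers called in both samples with a pair-specific
denominator; this reduces exactly to the dense formula when nothing is
missing (asserted). Positive-semidefiniteness is repaired, when a solve
fails, by a 1e-8 diagonal jitter rather than eigenvalue truncation, to
stay as close as possible to the defining formula.

Single-kernel REML is computed in the eigenbasis of G: the likelihood is
profiled on the variance ratio and optimised by bounded Brent search —
exact REML at a cost of one symmetric eigendecomposition. The fitted
model gives μ̂ by GLS and ĝ = σ²_g G V⁻¹(y − 1μ̂); the σ²_e → 0 limit is
handled exactly (ĝ = y − 1μ̂) instead of through a tiny ridge, which
would lose six digits to ill-conditioning. G-BLUP is checked against
marker-space ridge regression with λ = σ²_e/σ²_u on every random
instance the suite draws.

Cross-validation partitions samples into k random folds without
stratification, refits on each training set, and scores each held-out
fold by the Pearson correlation between predictions and observations
within that fold, averaging folds within a run. Correlating within the
test set (rather than pooling predictions across folds) avoids the
negative bias that fold-specific training means would otherwise induce;
the null calibration test demonstrates a mean accuracy of ~0 under pure
noise. Variance components are estimated once on the full data by
default (configurable by passing them explicitly); re-estimating inside
every fold changes accuracies negligibly at these sizes but multiplies
cost. Standardised accuracy divides by √h², with h² an input — it is a
data-derived quantity (the pipeline can estimate it via REML), not a
constant of the method.

## Hybrid prediction

The A+D model is solved in its kernel (dual) form: V = σ²_a Z_AZ_A′ +
σ²_d Z_DZ_D′ + σ²_e I, μ̂ by GLS, then marker effects â = σ²_a Z_A′α and
d̂ = σ²_d Z_D′α with α = V⁻¹(y − 1μ̂). This is algebraically the
ridge-penalised (λ_A = σ²_e/σ²_a, λ_D = σ²_e/σ²_d) mixed-model solution,
asserted against the explicit two-kernel BLUP in the tests, and it
reduces to single-kernel G-BLUP when σ²_d = 0. Candidate crosses are
ranked descending with ties broken by enumeration order (deterministic);
`select_top` takes k = ceil(fraction·N) with all ties at the cutoff
value included. For a 580-line panel, ceil(0.001 × 167,910) = 168.

Heterotic groups come from average-linkage (configurable) hierarchical
clustering of the rows of the symmetric predicted-performance matrix,
Euclidean metric; selfs are excluded and missing pairs imputed with row
means. The inter-group gain is 100 × (mean inter-group prediction /
mean over all crosses − 1). Note the denominator includes the
inter-group crosses themselves: with two equal groups, half of all
crosses are inter-group, so a planted bonus b on inter-group crosses is
measured as gain (1+b)/(1+b·f)−1 with f the inter-group fraction — the
calibration tests plant b accordingly.

## Trial models, GWAS and multiplicity

General variance-component models use EM-REML on the kernel form of each
random factor: non-negative by construction, matching closed-form ANOVA
estimates on balanced designs to 1e-6 (asserted). EM converges only
geometrically near the zero boundary and near flat optima, so two
accelerations are applied: components that decay monotonically with an
Aitken-extrapolated limit at zero are snapped to the (absorbing)
boundary, and if the EM loop reaches its iteration cap (default 100) the
still-positive components are polished by L-BFGS-B on the
log-parametrised restricted likelihood with analytic gradients. BLUEs
are the GLS genotype coefficients at the converged components
(cell-mean parametrisation; other fixed factors baseline-coded; numeric
covariates — e.g. flowering time as a cofactor — enter unchanged).

GWAS models each SNP as an additive dosage covariate (1 df) next to the
block fixed effect — the conventional coding for biallelic markers;
per-SNP missing dosages are excluded casewise. P-values are 1-df F
tests; multiplicity is handled by Benjamini–Hochberg q-values with the
two reporting thresholds q ≤ 0.001 and p < 1e-10, and the QQ calibration
reports the genomic inflation factor as the median observed 1-df χ²
over its null median.

Heritability ratios (`heritability_line_mean`, `heritability_broad`,
`repeatability`) are pure functions of variance components and design
counts and are guaranteed to lie in [0, 1] for non-negative inputs; the
line-mean form uses divisors y, s, ys, ysr — the standard line-mean
construction for a genotype × year × stress × replication trial.

## Problem sizes and limitations

The test-suite simulations run at desk scale — hundreds of samples,
thousands of loci, hundreds of 100-kb windows — chosen so each
statistical contract is testable with comfortable Monte-Carlo margins.
The estimators themselves are dense-matrix implementations; they are
comfortable to a few thousand samples and records but are not engineered
for biobank-scale data. Other known limitations: the scan has no
haplotype-based statistics (XP-CLR, iHS are out of scope); GWAS has no
kinship correction (the QQ check is the guard, as in block-design panels
with weak structure); the LD r² is a dosage approximation for
heterozygous material; and the phenotype generator's balanced blocks do
not emulate spatial field trends or incomplete-block designs.
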