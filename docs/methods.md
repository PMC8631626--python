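# Methods

## The two-isoform coverage model and the distal ratio

The *SERPINA1* 3′UTR is a single exon on the minus strand of chr14. The
package's default region definition is built from the transcript-coordinate
region table of the reference mRNA (NM_000295) mapped through the anchor
1519 ↔ chr14:94378451: proximal region 79 nt
(chr14:94,378,372–94,378,451, 0-based half-open) and distal region 1602 nt
(chr14:94,376,749–94,378,351), tiled by subregions Region1–Region4 of 398,
400, 400 and 404 nt. The table's *printed genomic* column is internally
inconsistent with its transcript column (Region 1 spans 399 genomic vs 398
transcript nt; Region 4, 411 vs 404; adjacent printed rows overlap by 2
nt). The converter never silently repairs printed coordinates —
`validate_printed_table` reports the mismatches, and the default spec
trusts the transcript column, which tiles exactly. All internal coordinates
are 0-based half-open on the + strand; 1-based inclusive (and descending
minus-strand) conventions are converted at the I/O boundary.

The distal ratio r = (D/L_d)/(D/L_d + P/L_p) uses summed depth over each
region, counting zero-depth positions as zeros. Because the long isoform
also covers the proximal region, r estimates L/(S+2L) < 0.5; published
tissue ratios near or above 0.5 therefore cannot be produced by this
estimand and should be read as a different normalization. When depths are
integers the ratio is computed as a reduced integer fraction, making it
*exactly* invariant under scaling all depths by a common factor. A sample
with zero depth in both regions yields a missing ratio and is dropped
listwise from comparisons.

Group comparisons use the two-sided Mann–Whitney U test — distribution-free
and consistent with a fold-change-of-medians effect size on skewed ratio
distributions. The exact null distribution is used when both groups have
≤ 8 tie-free observations; otherwise the normal approximation with tie
correction. Ordinal (GOLD-stage) trends use Spearman rank correlation;
constant-ratio inputs are reported as (ρ = 0, p = 1) with a degenerate
flag rather than NaN. Strata with fewer than 2 samples in a group are
reported but flagged low-power. Single-cell ratios apply the same formula
per cell with a default minimum of 3 region reads; a pooled mode
(sum counts per cluster, then ratio) is provided because sparse per-cell
ratios are noisy and the per-cell/pooled choice is genuinely open.

## PolyA-site calling and motif scans

Peak calling from 3′-end counts is deliberately simple: non-zero positions
within `merge_window` (default 8 nt) of the previous one join a cluster;
clusters with fewer than `min_count` (default 10) reads are dropped; the
summit is the argmax with ties broken toward the 3′ side in transcript
direction, matching the sharp 3′ cliff of real cleavage signal. Reads are
conserved: kept plus discarded cluster totals equal the track total.

PAS scanning reports every 6-mer within 40 nt upstream of the cleavage
position at Hamming distance ≤ 1 from AAUAAA (canonical first, then
variants nearest the cleavage site). The variant set is all Hamming-1
neighbours rather than a curated list — AUUAAA is one of them, while the
engineered proximal-site mutation AUCAAG (distance 2) is correctly not a
PAS. The G/U-rich element is the best G+U fraction over 10-nt windows in
the 40 nt downstream (positive at ≥ 0.6); the thresholds are the package's
own defaults since only the qualitative feature is established. DNA input
(T) is treated as U everywhere.

The bipartite QKI element NACUAAY-N(1,20)-UAAY is scanned with a
shortest-spacer, non-overlapping greedy policy by default (each half-site
claimed once), with an exhaustive mode reporting every valid pairing; both
are verified against a brute-force enumeration oracle.

## The deletion-construct translation model

Normalized luminescence is modelled with no intercept as
y = Σ t_i x_i with x_i = 1 when region i is *deleted*. This is the only
parameterization under which a no-intercept model is consistent with the
full-length (Long) construct being the dimmest: Long (no deletions)
predicts 0 and Short (all deleted) predicts Σt. Each replicate is one
observation in an unweighted OLS; construct means are used only for R²,
computed as the squared Pearson correlation of predicted vs observed means
(the predicted-vs-measured convention). Normalization divides each batch
by its Short-construct mean (values above 1 are clipped and flagged);
min-max normalization is available as an option since the 0–1 scaling
procedure is not otherwise pinned down.

The default eight-construct design honours the two documented constraints
of the original deletion series — Deletion 1 removes regions 2, 3 and 4;
Deletions 5 and 6 retain regions 3 and 4 — and fills the remaining freedom
so the membership matrix has full column rank (Del2={1}, Del3={3},
Del4={4}, Del5={1,2}, Del6={2} deleted). A naive reading in which no
construct separates regions 3 and 4 makes t₃ and t₄ unidentifiable, so
identifiability was the deciding criterion; rank-deficient user designs
are rejected with the unidentifiable regions named. Variance attribution
for a region subset is Σ_{i∈subset} t_i / Σ_i t_i, defined only for
non-negative coefficients.

qPCR stability uses ΔCT = CT_target − CT_reference and relative level
2^(−ΔCT); two decay trajectories are "similar" when mean ΔCT profiles
agree within 1 cycle at every shared timepoint.

## RBP volcano scoring

Axes are raw (no standardization): dx = log₂ disease fold change,
dy = knockdown distal ratio − control ratio, because the plot this mirrors
uses raw axes; a z-scored mode would be a sensitivity analysis, not the
default. Direction: dx·dy > 0 → the RBP decreases the distal ratio in
disease; < 0 → increases; 0 → null. (Knockdown shows what *less* protein
does; dx < 0 means less protein in disease, so the disease effect carries
dy's sign, and dx > 0 flips it.) The quadrant-colour sentence in the
figure legend this rule mirrors is self-contradictory; the rule here is
derived from the unambiguous worked example (QKI: dx = −0.13,
kd ratio 0.036 below control → decrease) and the underlying biology.

The effect score is s·log₂(d) with d = √(dx²+dy²) and s = ±1 by direction
(0 at the centre). The sign is applied *after* the log, so for distances
below 1 (log₂ d < 0) a "decrease" protein carries a positive score; the
selection and ranking use |log₂ d|, which is unaffected. Selection keeps
records with BH-adjusted knockdown p < α, adjusted DE p < α and
|log₂ d| > 1; note |log₂ d| > 1 admits both d > 2 and d < ½, a literal
reading of the published filter. Knockdown p-values are BH-adjusted across
the supplied record set; DE p-values are expected already adjusted, as DE
pipelines emit them.

## Structure metrics

Reactivity classes use the standard SHAPE colour thresholds 0.4 and 0.85
(boundaries owned by the upper class); both are configurable. Entropy uses
log base 10 and, by default, excludes the unpaired-probability term — the
common convention for structure-entropy tracks; an `include_unpaired`
variant exists because the convention is toolchain-dependent, so absolute
entropies are comparable only within one convention. Motif accessibility
is the median reactivity over the site (requiring ≥ 50% of positions with
data), accessible at ≥ 0.4 — the intermediate-reactivity boundary, chosen
because no numeric criterion is otherwise established.

## Synthetic data: what it emulates, and what it does not

Coverage noise is per-base negative binomial in the mean–dispersion
parameterization (var = μ + φμ², default φ = 0.1, φ = 0 → Poisson),
drawn independently per base as a gamma–Poisson mixture. Cohorts draw
control ratios from Beta(4, 76) (median ≈ 0.046, CV ≈ 0.5) — a low,
right-skewed lung-like distal-ratio distribution tight enough that a
2-fold median shift at n = 82/64 is strongly detectable, as the reported
cohort significance implies; case ratios are the same draws scaled by the
planted fold, capped at 0.45 (the estimand's ceiling is 0.5), and inverted
to abundances via L = r, S = 1 − 2r. 3′-end reads are assigned to sites
multinomially with rounded Gaussian jitter (counts conserved);
luminescence replicates are Σ t_i x_i + N(0, σ) truncated at 0; RBP tables
mix origin-centred nulls with uniform raw p-values and planted effects
with vanishing p-values, the DE column BH-adjusted across the table.

Not emulated: positional autocorrelation of real coverage (read length,
mappability), 5′UTR isoform complexity, fragment-level reads, covariate
structure in DE, or batch effects beyond the reporter batches. Passing
recovery tests therefore demonstrates estimator correctness under the
stated noise model, not robustness to alignment artefacts or confounding.

### Estimator precision under per-base overdispersion

The ratio's sampling error is dominated by the short (79 nt) proximal
region. By the delta method, sd(r) ≈ r(1−r)·√(CV_P² + CV_D²) with
CV_P² = (1/μ_p + φ)/L_p for region-mean depth μ_p over L_p bases. At
mean depth 1000, S = L (r = ⅓) and φ = 0.1 this gives sd(r) ≈ 0.008, so
|r − ⅓| < 0.01 holds in only ≈ 78% of simulations — the dispersion term
φ/L_p does not shrink with depth, only with region length. Under Poisson
noise (φ = 0) the same check passes essentially always; the suite
therefore tests estimator *consistency* at φ = 0, isolating the estimator
from the generator's noise floor, while the acceptance check at φ = 0.1
reports the honest (lower) calibration rate.

## Problem sizes and determinism

All generators take explicit integer seeds (numpy `default_rng`); no
global random state. The acceptance script and suite use: 200 simulations
for coefficient recovery (σ = 0.03, 4 replicates × 8 constructs), 500
seeds for ratio calibration at mean depth 1000, 1000 null plus 200
alternative cohort simulations at n = 82/64 and mean depth 100, a 224-row
RBP table (216 nulls + 8 planted), and 1000 random sequences (length
≤ 500) for scanner-vs-oracle equivalence. These sizes give Monte-Carlo
standard errors comfortably below the tolerances being checked while the
whole suite runs in well under a minute.
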