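# Methods

This note documents the models, estimators, numerical choices and known
limitations of popscan, in enough detail that every default can be judged
and every result reproduced.

## Estimators

### Nucleotide diversity

Per site, with `j` alternate alleles among `n` called alleles in a
population, the unbiased mean pairwise difference is
`pi_s = 2 j (n - j) / (n (n - 1))`; sites with fewer than two called
alleles are skipped. Window diversity is `sum(pi_s) / L` with `L` the full
window length in bp — monomorphic and uncalled bases count in the
denominator, the convention of windowed-diversity tools, so values are
per-bp and comparable across windows regardless of SNP content. Windows
default to 50 kb sliding by 10 kb; trailing windows that do not fit the
chromosome are dropped unless explicitly requested, avoiding
length-normalization artifacts at chromosome ends.

### Weir–Cockerham F_ST

Per site, for two populations indexed i with `n_i` called diploids, allele
frequency `p_i` and observed heterozygote fraction `h_i` (r = 2):

    n_bar = (n1 + n2)/2
    n_c   = (2 n_bar - (n1^2 + n2^2)/(2 n_bar))
    p_bar = (n1 p1 + n2 p2) / (2 n_bar)
    s^2   = (n1 (p1-p_bar)^2 + n2 (p2-p_bar)^2) / n_bar
    h_bar = (n1 h1 + n2 h2) / (2 n_bar)
    a = (n_bar/n_c) [ s^2 - ( p_bar q_bar - s^2/2 - h_bar/4 ) / (n_bar - 1) ]
    b = (n_bar/(n_bar-1)) [ p_bar q_bar - s^2/2 - h_bar (2 n_bar - 1)/(4 n_bar) ]
    c = h_bar / 2

The windowed weighted estimate is `sum(a) / sum(a+b+c)`. Sites require at
least one called diploid per population and more than two in total (the
component denominators need `n_bar > 1`). Windows whose denominator sums to
zero are reported missing, not zero. Negative estimates are kept as
computed; downstream quantile ranking operates on reported values. An
independent Hudson-estimator cross-check lives in the test suite, never in
the analysis path.

### Linkage disequilibrium

Inputs are unphased, so LD is the composite (genotype) r²: the squared
Pearson correlation of alt-allele counts over samples called at both sites.
Composite r² carries a positive O(1/n) sampling bias, which is why every
comparison in the inversion verification uses backgrounds computed on the
same sample set (see below). Decay curves bin all within-`max_dist` pairs
by physical distance (100-bp bins by default); when the pair count exceeds
a cap the anchor sites are deterministically thinned. The binned means are
smoothed by a monotone-decreasing isotonic regression weighted by pair
counts, and the half-maximum distance is where the smoothed curve first
reaches half its maximum, linearly interpolated between the bracketing bin
midpoints (a tie at exactly half resolves to the smaller distance). A
curve that never reaches half its maximum returns a "not reached" sentinel
rather than a number.

### Chromosome-group comparison

Groups of chromosomes (typically Z vs autosomes) are compared on any window
statistic by mean ± 2.58 × SE over windows (the 99% normal interval);
groups are "different" only when the intervals are disjoint. The ratio of
group means is reported alongside. Windows are treated as exchangeable
units; autocorrelation between overlapping sliding windows makes the
intervals anti-conservative, which is acceptable for the descriptive use
here but should not be read as a calibrated test.

## The sweep scan

A sweep in the focal population depresses its diversity and elevates its
differentiation. Per chromosome (chromosomes differ in baseline diversity
and differentiation, so each is ranked independently), a window is a
pair-scan outlier when it lies in the top tail (default q = 0.05) of
*both* the pairwise Weir–Cockerham F_ST and the pi ratio, defined as
`pi_reference / pi_focal` so the top tail means focal diversity loss. The
quantile cut is the value at rank `ceil(q W)` from the top with ties
included, W counting windows that carry both statistics. Two pair scans
against different reference populations are intersected window-wise, which
removes drift artifacts private to one comparison; surviving windows are
merged into maximal regions so region counts are robust to the sliding
grid.

Within the combined regions, SNPs are retained when they are missense,
have overall maf strictly above 0.05, and show differential
differentiation: site-level F_ST(focal, reference) strictly exceeds
F_ST(reference1, reference2) for **both** references. The conservative
"both" reading is the default; an "either" mode exists behind a flag.
Site-level F_ST uses the same variance components as windows, evaluated at
single sites. Genes whose interval, expanded by 1 bp, contains a retained
SNP are candidates; term enrichment (when a gene→term map is supplied)
uses the one-sided hypergeometric distribution with universe = genes in
the map, Benjamini–Hochberg adjustment, and significance at adjusted
p < 0.05.

**Specificity is high but not exactly zero.** Under the null, the focal
population's drift realization couples all four ranked tails (low focal
diversity raises both pi ratios and both pairwise F_STs), so the 4-way
intersection fires by chance in a small fraction of genomes, and the
site-level filters pass the occasional missense SNP inside such a window —
including SNPs whose three near-zero F_ST estimates happen to order the
"right" way by noise. Users should treat isolated single-window hits with
few supporting SNPs accordingly.

## Local PCA and inversion calling

Each chromosome is cut into non-overlapping windows of 100 SNPs; each
window's mean-centered genotype matrix (missing calls mean-imputed per
site) gives a sample×sample covariance normalized by its trace, summarized
by its top k = 2 eigenpairs. Windows are compared by the Frobenius
distance between rank-k reconstructions `sum_l lambda_l v_l v_l^T` — a true
metric on the summaries, chosen as a faithful, implementable notion of
"how different are these windows' PCAs"; it is isolated behind one function
so alternatives can be swapped. The window distance matrix is embedded by
classical (Torgerson) MDS: double-center −D²/2, take the top eigenpairs;
axes with non-positive eigenvalues are zeroed, and a warning is raised
when negative spectral mass exceeds half the positive mass (double
centering guarantees it can never exceed the positive mass, so the alarm
compares the two directly).

Candidate regions are runs of MDS outliers: per axis, windows deviating
from the median by more than 4 raw MADs, in runs of at least 3 windows
tolerating one-window interior gaps. These defaults are deliberately
conservative; they replace the manual region selection a human would do on
an MDS plot.

Candidate regions are genotyped by PCA over all SNPs in the region: PC1 is
split into three groups by **exact 1-D 3-means** — optimal 1-D partitions
are contiguous in sorted order, so the global optimum is found by
enumerating the two breakpoints with prefix sums. This replaced
quantile-seeded Lloyd iterations, which converged to a poor local optimum
whenever the three clusters were very unbalanced (e.g. a rare inverted
homozygote class); the exact solver is deterministic and initialization-
free. The call succeeds only when the middle cluster (by PC1 center) has
the maximal mean observed heterozygosity — the diagnostic signature of
inversion heterozygotes. Orientation (which homozygote cluster is 1/1) is
resolved by calling the rarer homozygote class the inverted arrangement,
and the choice is recorded on the call.

Verification tiles the region into 50-kb windows and compares mean
between-window composite r² computed twice — all samples vs non-carriers
(called 0/0) — against genome-background r² from distant SNP pairs
computed **for the same sample set** (the composite-r² baseline scales
like 1/n, so cross-set comparisons would be biased). Verification passes
when the all-sample mean exceeds 2× its background while the non-carrier
mean stays within 1.5× its own; both factors are configurable. The
window-pair matrix is returned with all-sample values in the upper
triangle and non-carrier values in the lower, the layout of an LD heatmap
figure.

## The synthetic-data generator

The generator emulates a small set of diverged populations with planted,
recoverable signals; it is a Balding–Nichols system, not a coalescent, so
every expectation is available in closed form:

* ancestral frequencies p0 from density ∝ 1/x on [eps, 1−eps]
  (eps = 0.01), reproducing an excess of rare alleles while keeping all
  sites polymorphic; the mean ancestral heterozygosity is
  `E[2 p0 (1−p0)] = (1−2 eps)/ln((1−eps)/eps)` ≈ 0.213;
* population frequencies `p_k ~ Beta(p0 (1−F_k)/F_k, (1−p0)(1−F_k)/F_k)`,
  giving `E[p_k] = p0`, `Var = F_k p0 (1−p0)`, expected heterozygosity
  `2 p0 (1−p0)(1−F_k)` and, for two equally drifted populations,
  `E[F_ST] ≈ F`; F = 0 is handled as the exact degenerate limit;
* sweeps: inside the region the target population redraws with `F_sweep`,
  so the expected within/outside diversity ratio is
  `(1−F_sweep)/(1−F_bg)`;
* Z chromosome: diversity reduction is implemented as SNP-density scaling
  (default ×0.75), not frequency rescaling, because per-bp pi is linear in
  density — the expected Z/autosome ratio is then the scaling factor
  exactly;
* inversions: each sample draws `g ~ Binomial(2, q)` inverted copies; a
  fraction (default 0.25) of region SNPs are markers whose haplotype
  alleles equal the inversion allele, each flipped independently with a
  small error probability — yielding the three-cluster PC1 geometry,
  elevated heterozygote-class heterozygosity, and a region-wide LD block
  carried by the markers; regions with fewer than 20 SNPs are rejected;
* LD: "independent" mode draws `Binomial(2, p_k)` per site (exact
  Hardy–Weinberg); "copula" mode builds each haplotype from a latent
  AR(1) Gaussian in physical distance, correlation `exp(−d/lambda)`,
  thresholded at each site's marginal frequency — correlations between any
  two sites multiply along the chain, so the model is a genuine
  exponential-decay field;
* missingness is off by default and injectable uniformly to exercise the
  filters; missense status is Bernoulli per SNP (default 0.02).

Default densities and drift values mirror the study system the package
was built around: SNP density 0.01/bp (a ~36× resequencing study of three
moth populations called ~6.3M SNPs on a 518-Mb genome) and background
F ≈ 0.15, the genome-wide differentiation scale among those populations.

**What the generator does not emulate** — and therefore what passing
recovery tests do not demonstrate about real data: linked selection and
hitchhiking (sweeps here are drift-parameter changes, not trajectories),
demography-driven site-frequency distortions, inversion age structure and
flux, sequencing/calling error models, and any non-uniform recombination
landscape. The tests demonstrate that the estimators are exact and that
the scan recovers signals of the planted geometry and strength; field data
should be interpreted with the usual caution.

## Problem sizes and test geometry

Recovery suites run at desk scale, sized so each completes in seconds
while keeping the statistical structure honest:

* drift recovery: 2 × 50 diploids, ~2 × 10⁴ independent SNPs per F value;
* Z/autosome calibration: two 10-Mb chromosomes, 50 diploids, >10⁵ sites;
* sweep recovery: three populations × 15 diploids on two 3-Mb chromosomes,
  140-kb sweeps (F_sweep = 0.9 on F = 0.15). Each sweep spans 10 full
  windows — about two thirds of the 15-window per-chromosome top-5% budget
  — so recovery is not confounded by quantile-budget saturation, which
  would otherwise cap sensitivity below 1 even for perfect signals;
* inversion recovery: 60 diploids, a 2-Mb inversion (q = 0.3, 1% marker
  error) on a 6-Mb chromosome plus a null chromosome.

## Known limitations

* MDS outlier detection needs the anomalous windows to be a minority on
  their chromosome: an inversion covering ~half the windows corrupts the
  median/MAD baseline and escapes detection. Inversions spanning most of a
  chromosome need a different detector (e.g. inter-chromosome
  comparisons).
* The sweep scan's quantile rule always selects a top tail, so on a truly
  neutral genome the pair scans are nonempty by construction; specificity
  comes from the intersection and the SNP-level filters, and is high but
  not exactly zero (see above).
* The 99% CI group comparison ignores window autocorrelation.
* Site depth filters use INFO/DP or mean FORMAT/DP per site; per-genotype
  depth masking is out of scope.
* Multiallelic records are dropped, not decomposed.
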