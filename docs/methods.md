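# Methods

## Model and procedure

`contourbin` bins assembled metagenomic scaffolds in a two-dimensional
feature space: logit-transformed GC content and FPKM. The underlying
assumptions are that (a) scaffolds from one source genome share a
characteristic GC composition, (b) scaffolds from one source population
receive sequencing coverage proportional to that population's abundance,
so their FPKM values concentrate around a common value, and (c) each
genome's cloud of scaffolds in this plane is approximately bivariate
normal, with scatter dominated by the binomial sampling of GC over finite
scaffold length and the Poisson sampling of fragment counts.

All statistics are length-weighted (wᵢ = lᵢ/Σlⱼ): the object of interest
is the distribution of features over nucleotides, not over scaffolds, so
a 1 Mb scaffold should count a thousand times more than a 1 kb one.

The procedure is: feature computation → weighted binned KDE → contour
thresholding → connected-component labeling → weighted Gaussian-mixture
EM (one extra component for scattered scaffolds) → posterior-threshold
hard assignment.

### GC logit

GC proportions are mapped to the real line with a half-count correction,
logit((g+½)/(L+1)), where g is the GC count and L the number of
unambiguous bases. A plain logit is undefined for all-AT or all-GC
scaffolds; the correction keeps every value finite and converges to the
plain logit as L grows. Ambiguity codes (N etc.) are excluded from both
numerator and denominator.

### FPKM and the coverage filter

FPKMᵢ = cᵢ·10⁹/(lᵢ·T). When every fragment maps to a retained scaffold,
Σᵢ FPKMᵢ·lᵢ = 10⁹ identically, and FPKM is invariant under rescaling all
counts and the total together. Scaffolds whose FPKM exceeds the 0.99
length-weighted quantile are masked from bandwidth selection, the KDE and
the initial binning — extreme coverage outliers (collapsed repeats,
plasmids, rRNA operons) otherwise inflate the plug-in bandwidth — but
they stay in the feature table and enter the EM in the extra component,
so they can still end up in a bin if the fitted model supports it.

The weighted quantile uses plotting positions pᵢ = C₍ᵢ₋₁₎/(S−wₙ) on the
value-sorted sample (C = cumulative weight, wₙ = weight of the largest
value), which reduces exactly to the Hyndman–Fan type-7 (linear
interpolation) convention under equal weights. Whether a length-weighted
or unweighted quantile is "correct" here is genuinely open; the weighted
form was chosen for consistency with the nucleotide-level weighting used
everywhere else.

The FPKM axis is left untransformed by default (only GC is logit
transformed); `log_fpkm` switches the second feature to log10(FPKM+1e-6)
for communities whose abundances span many orders of magnitude.

### Bandwidths and the binned KDE

Per-axis bandwidths come from the two-stage direct plug-in construction:
a normal-scale pilot for ψ₈, kernel functional estimates of ψ₆ then ψ₄,
and h = [R(K)/(μ₂(K)² ψ₄ n_eff)]^{1/5} with the Gaussian kernel. All
moments and pairwise functionals are weighted, and the sample size is
replaced by the effective size n_eff = 1/Σwᵢ². Duplicated support points
are merged (weights summed) before n_eff is computed: the weighted sample
is a measure, and its representation — one point of weight w versus two
coincident points of weight w/2 — must not change the bandwidth. If a
functional estimate comes out with the wrong sign (possible on tiny or
pathological samples), the selector falls back to the normal-scale rule
(4/3)^{1/5} σ̂ n_eff^{-1/5} with a warning.

The 2-D estimate linearly bins the weights onto a 256×256 grid spanning
the unmasked data range padded by three bandwidths per axis, then
convolves with the product Gaussian kernel (FFT, kernel truncated at
5 bandwidths). Against a brute-force exact KDE the binned estimate agrees
to well under 1% of the peak at this resolution, and its trapezoidal mass
is 1 to within the truncation loss.

### Contour initialization

The super-level set {density ≥ level} is labeled with 8-connectivity —
4-connectivity splits visually contiguous blobs at diagonal saddle
cells — and components are numbered by descending contained density mass.
Each unmasked scaffold inherits the label of its nearest grid cell.

The level is the one genuinely manual choice in this design; the default
automates it by scanning 10 log-spaced levels between 1% and 90% of the
peak and taking the smallest level that attains the maximal observed
group count (the smallest such level keeps the most scaffolds inside
components). An explicit `--level` reproduces a manual choice. The scan
is deliberately coarse; see Limitations.

### Weighted EM

G is set to the number of initial groups plus one. Responsibilities start
one-hot from the initial binning; scaffolds with no initial group
(including coverage-masked outliers) start in the extra component. The
first step is an M-step, so the initial labels directly determine the
first parameter estimates. Iteration stops when the relative change of
the weighted observed-data log-likelihood Σᵢ wᵢ log Σₖ τₖφₖ(xᵢ) falls
below 1e-8 (default) or after 500 iterations. Convergence is monitored on
the observed-data likelihood because EM's monotonicity theorem applies to
it; the complete-data log-likelihood Σᵢₖ zᵢₖwᵢ log[τₖφₖ(xᵢ)] is reported
alongside.

Numerical choices:

- Densities are evaluated through Cholesky factorizations (no explicit
  inverses); responsibilities are computed in log space with
  max-subtraction. A point underflowing in every component gets a uniform
  responsibility row with a warning.
- Components that lose all responsibility are dropped, G decremented and
  τ renormalized (logged). An initialization with zero groups is an
  error pointing the user at the contour level.
- Covariance eigenvalues are floored at 1e-5 × max(tr(Σₖ)/2, 1e-4).
  Below roughly this scale, float64 round-off in the closed-form M-step
  is amplified by the ~1/λ curvature of the log-likelihood and EM's
  monotone-likelihood guarantee is lost in practice; empirically a much
  smaller ridge still admitted likelihood decreases of order 1e-5 when a
  component collapsed onto a near-degenerate point set. The absolute term
  keeps a component collapsed onto exactly identical points positive
  definite.
- When the floor binds, the M-step additionally compares the component's
  Q-term against the previous iteration's parameters and keeps the old
  (μₖ, Σₖ) if the floored update would lower it. This is a generalized-EM
  safeguard: every accepted step increases the complete-data Q, so the
  observed-data likelihood is non-decreasing by construction even while a
  component degenerates. Measured over a thousand random-initialization
  EM runs, the worst observed decrease is at machine precision (~1e-15).
- Hard assignment requires the best non-noise posterior to reach 0.5 and
  to exceed the noise component's posterior; ties break to the lower
  component index. Both rules exist for reproducibility, not statistical
  optimality.

The extra component is an ordinary Gaussian, not a uniform background:
the model adds one more component of the same family, which in practice
fits a broad, low-τ envelope under the scattered scaffolds.

## Synthetic communities

The simulator generates exactly the structure the model assumes, no more:

- genomes are i.i.d. base sequences at a target GC (P(G)=P(C)=gc/2) —
  no codon structure, k-mer bias or repeats, since only GC enters the
  feature space;
- scaffold lengths are lognormal (default meanlog = log 8000, sdlog 0.5,
  ~5–20 kb typical) truncated below at 1 kb, partitioning each genome
  exactly;
- fragment counts are Poisson with E[cᵢ] = T·aₛlᵢ/Σⱼaₛ₍ⱼ₎lⱼ, so all
  scaffolds of a species share one expected FPKM; an optional
  overdispersion parameter switches to gamma-Poisson for robustness
  probing.

Two presets ship: `taihu9`, nine species whose GC targets
(33.95–68.5%) and relative abundances (0.5–31.6%) mirror a real
Microcystis-colony community, and `wu10`, ten species with GC spread
evenly over 30–70.5% and a geometric abundance gradient (~2–25%,
1.32× steps) interleaved so GC-adjacent species differ at least twofold
in expected coverage. Preset genome lengths are drawn uniformly in
0.5–1 Mb; validation runs use 2×10⁶ total fragments, giving communities
of roughly 400–800 scaffolds — sizes at which every stage of the pipeline
runs in seconds while each species still contributes 50–100 scaffolds.

Because the generator realizes the model's own assumptions, passing
recovery tests demonstrates the estimation machinery (KDE initialization,
weighted EM, assignment) works as designed; it does not demonstrate
robustness to real-data violations — chimeric scaffolds, strain mixtures,
GC heterogeneity along a genome, mapping artifacts, or coverage
covariation between samples.

Evaluation matches bins to species greedily by descending overlapping bp
(a simple, reproducible rule; optimal matching would only matter for
badly fragmented solutions). Length-weighted accuracy is correctly
assigned bp over all bp placed in non-noise bins; noise-assigned
scaffolds are reported separately as the unbinned fraction.

## Pathway complementation

The complementation ratio of a pathway in a group is
|present ∩ required| / |required| on exact ortholog-identifier matches
(KO/EC-style tokens, no hierarchy expansion). Union ratios over group
subsets, and the inclusion-minimal subsets reaching ratio 1, are
enumerated exhaustively up to a subset-size cap (default 3) to bound the
combinatorics. Pathway definitions are user input: which genes a pathway
"requires" is a curation decision outside this package's scope.

## Known limitations

- Two species close in both GC and abundance (logit-GC gap ≲ the KDE
  bandwidth and coverage ratio ≲ 2) merge into one initial component; the
  mixture inherits the merge because G is tied to the initial group
  count. On the ten-species preset this occurs in roughly one seed in
  five, where 9 bins are recovered instead of 10. A finer level scan or a
  manual `--level` sometimes separates such pairs.
- The raw-FPKM axis compresses low-abundance species when one member
  dominates; `log_fpkm` mitigates this but changes the geometry the
  defaults were chosen for.
- The level scan assumes the best binning maximizes the component count,
  which a noisy density surface with spurious bumps could game; the
  contour plot (`plot_density`) exists precisely so the choice can be
  inspected.
- SAM fragment counting counts first-in-pair primary records, so a pair
  whose first mate is unmapped contributes nothing even if the second
  mate maps.
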