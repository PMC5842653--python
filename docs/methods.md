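# Methods

## Model

Methylation within an estimation region with R CpG sites is a binary vector
X with the inhomogeneous 1D Ising PMF

    P(x) = (1/Z) exp{ Σ_{n=1..R} a_n (2x_n−1) + Σ_{n=2..R} c_n (2x_n−1)(2x_{n−1}−1) }.

The per-site field a_n captures the intrinsic propensity of site n to be
methylated; the coupling c_n captures the processivity-driven correlation
between neighboring sites, decaying with their genomic distance. Within a
region the potentials are tied to covariates by five parameters
θ = (α′, α, α″, β, γ):

    a_1 = α′ + β ρ_1,   a_R = α″ + β ρ_R,   a_n = α + β ρ_n (interior),
    c_n = γ / d_n,

with ρ_n the CpG density (count of CpG sites within ±500 bp of site n,
including n itself, divided by the 1000-bp window) and d_n the bp distance
between the cytosines of sites n−1 and n. The boundary fields α′/α″ replace
α at the region's first and last site: regions are modeled as statistically
independent, and the boundary fields absorb the coupling lost by cutting
the chain at region borders. Self-inclusion in ρ keeps the density strictly
positive (an isolated CpG has ρ = 0.001), so the field parameterization has
no degenerate zero-density sites.

A single-site region degenerates to a Bernoulli with field α′ + βρ_1; such
regions never survive the eligibility filters.

## Chain computations

Everything reduces to transfer-style message passing along the chain, done
in log domain (forward/backward messages, log-sum-exp steps) or in linear
domain with per-step rescaling (the level-PMF dynamic program). The
contract, enforced by tests, is relative agreement to 1e−10 with explicit
enumeration over all 2^R states for R ≤ 12 for: the partition function,
state probabilities, site marginals, block marginal likelihoods, and level
PMFs. No arbitrary-precision arithmetic is needed under this scheme.

The marginal likelihood of a read observing one contiguous run of sites is
exact: forward message into the run, energy along the run, backward message
out, minus log Z. A read whose observed sites are non-contiguous is split
into maximal contiguous runs and scored by the product of the exact run
marginals. This product is an approximation (exact when the runs are
uncoupled); it mirrors the estimation procedure the method defines, and in
WGBS practice almost all reads observe contiguous site runs.

The level PMF of a GU is computed by a dynamic program over (site,
methylated-count) across the GU's sites after exact marginalization of the
region's flanking sites — the GU distribution is the marginal of the region
model, not conditioned on anything. Exact ancestral sampling (X_1 from its
marginal, then each X_n from the exact chain conditional given X_{n−1},
using backward messages) drives the simulator.

## Estimation

θ̂ maximizes the average marginalized log-likelihood
(1/M) Σ_m ln P(observed sites of read m | θ) over the box
(α′, α, α″) ∈ [−10, 10], β ∈ [−100, 100], γ ∈ [−20, 20]. Rationale for the
box: |a| ≈ 10 already saturates a site's marginal beyond any observable
difference, and γ/d with d ≥ 2 keeps couplings moderate. The search is
derivative-free and global — scipy's deterministic DIRECT algorithm over
the box, followed by a bounded Nelder-Mead polish — within a default budget
of 5000 objective evaluations and a 1e−5 absolute improvement tolerance.

The objective carries a tiny ridge term (1e−4 · ‖θ‖², configurable). This is
a numerical tie-break, not a prior: directions the marginal likelihood
leaves flat — the boundary field of a site no read observed, or the α/β
split where the density is locally constant — would otherwise drift to the
box bounds and saturate the corresponding marginals arbitrarily. Against
any data-constrained direction the term is negligible (it shifts well-
identified optima by far less than estimation noise); reported
log-likelihoods are always the unpenalized values.

Regions are fitted only if they have ≥ 10 CpG sites, at least 2/3 of the
sites observed by ≥ 1 read, and ≥ 2.5 site-observations per CpG on average;
reads spanning a region boundary are split at it, each fragment counting as
one observation of its region (consistent with region independence).
"Observed" for the 2/3 filter means observed at least once.

For model criticism the unconstrained Ising model (one field per site, one
coupling per pair; 2R−1 parameters) is fitted on the same marginal
likelihood (Powell search started from the constrained fit's potentials;
regions with R > 25 are skipped as a complexity guard), and the two models
are compared by AIC with the standard Akaike-weight probability.

## Single-sample and differential statistics

MML is E[L] (identically the mean of the per-site marginals); NME is the
Shannon entropy of the level PMF normalized by log₂(N+1) so that the
uniform level distribution scores exactly 1 for any N. The 7-way level
classification and 5-way entropy classification use threshold rules on the
tail masses p_low = Pr[L ≤ 0.25], p_high = Pr[L ≥ 0.75] and on NME bins
symmetric about 0.5; the exact published cut points are not derivable from
the statistics, so the defaults here are explicit, symmetric stand-ins and
every cut point is configurable. One deliberate consequence of the rule
order: a PMF with ≥ 0.4 mass in each tail is bistable even when it is the
uniform PMF on ≤ 5 levels (tiny GUs), since the bistable rule precedes the
mixed rules.

Two-sample statistics per GU: dMML = E[L_t] − E[L_r], dNME = h_t − h_r, the
full PMF of D_L = L_t − L_r by cross-convolution under independence (exact
rational support, equal differences merged), and the Jensen-Shannon
distance (base-2, square root of the Jensen-Shannon divergence). When the
two samples model a GU with different K, both PMFs are embedded on the
union of their exact rational level grids — two levels align only if
k_t/K_t = k_r/K_r — which preserves both identities JSD(P,P) = 0 and
JSD = 1 for disjoint supports. The differential classifications use
symmetric threshold rules analogous to the single-sample ones (all
configurable).

## DMR detection

Per-GU JSD is smoothed per chromosome by Nadaraya-Watson regression with a
Gaussian kernel whose quartiles sit at ±0.25·bandwidth (the R `ksmooth`
convention), so σ = 0.25·bandwidth/0.6745; a 50-kb bandwidth therefore
means σ ≈ 18.5 kb. The smoother is evaluated at GU centers only; kernel
weights are truncated at 8σ (numerically irrelevant beyond that), and
smoothing never crosses chromosomes.

The null for the smoothed signal is either (a) empirical: the pooled sJSD
values of all replicate-reference pair comparisons, with plus-one-corrected
one-sided exceedance p-values p = (1 + #{null ≥ obs})/(1 + #null), which
guarantees p > 0; or (b) logit-normal: a two-component Gaussian mixture is
fitted by EM to logit(sJSD) (values clipped to [1e−6, 1−1e−6] first;
responsibilities initialized from a two-quantile split; degenerate fits
retried with fresh seeded initializations up to 50 times, then a hard
error), and the component with the smaller mean is the null, regardless of
the weights. p-values are one-sided upper tails.

All modeled GUs form a single genome-wide family adjusted by
Benjamini-Yekutieli (valid under dependence) at FDR 0.01. SQS = −10 log₁₀(q),
capped at 300. Significant GUs are closed morphologically: on one
chromosome, significant GUs whose bp gap is strictly smaller than the
structuring element (default: the smoothing bandwidth) are connected; on
the uniform GU grid this interval-merging is exactly binary closing, and it
extends unchanged to partial trailing GUs. Each DMR is scored by the sum of
the SQS of its significant GUs and DMRs are ranked by score.

## Gene ranking

Promoters are strand-agnostic 4-kb windows centered at each transcript's
TSS (truncated at the chromosome start when necessary); a GU belongs to a
window if they overlap by ≥ 1 bp. Without replicate references a promoter
scores the mean JSD of its modeled GUs; with replicates, per-GU empirical
p-values from the *raw* JSD null (not sJSD) are combined by Fisher's method
(−2 Σ ln p against χ² with 2m df) — used strictly as a ranking score, since
GU independence does not hold exactly. Per gene only the best-ranked
promoter is kept; genes with no modeled GU in any promoter are omitted.
Rankings from several comparisons merge by the rank product (geometric mean
of per-list ranks; a gene missing from a list gets rank list-length + 1;
ties break by mean rank, then gene id). Rank-product permutation p-values
are out of scope — the output is a ranking.

## Simulator

The generator reproduces the study conditions the differential assessment
is defined on: isolated 3-kb CpG islands of 200 uniformly spaced CpG sites
(15-bp spacing, interior density ρ = 0.067) separated by 100-kb CpG-free
gaps; 300-bp reads placed uniformly at random over the genome at 15× mean
coverage; island states drawn from the island's Ising model with chosen
(a, c). Each read draws its own complete latent island state — a read is
one cell's molecule — and reports the exact states of the CpG sites it
covers; this is what makes within-read correlation carry the coupling
signal. Reads starting in a gap but reaching into the next island report
its leading sites, so island edges have no systematic coverage hole; the
chromosome's very first bases still show the physical alignment-edge
coverage ramp. No bisulfite-conversion failures, sequencing errors, or
biological replicate variability are modeled; consequently, passing the
simulation study demonstrates the statistical machinery (estimation from
incomplete reads, distributional testing, FDR control) under the model's
own assumptions, not robustness to error modes of real WGBS libraries.
Everything is deterministic given the seed.

The desk-scale default is 50 islands per sample (the full-scale design uses
5000); at 50 islands one study arm is ~5.15 Mb of genome, ~260k reads, and
~1000 modeled GUs, which keeps a full three-delta assessment within a few
minutes on one CPU while leaving the per-GU statistics at their full-scale
operating point (same coverage, read length, island geometry).

In the differential assessment both conditions use a = 0, so every CpG site
has marginal methylation probability exactly 1/2 in both samples and the
conditions differ only in the order of the joint distribution (c = 0 versus
c = δ) — the regime where marginal, mean-based methods are structurally
blind. Sensitivity and specificity are scored per modeled GU against the
island truth labels, a GU counting as called when it lies inside a detected
DMR after closing. The reference/reference runs reuse the replicate-pair
empirical null, mirroring how replicate references are used on real data.

## Numerical choices and degenerate inputs

- Empty observation sets have marginal probability 1 by convention (logged
  at the call site, never fitted: the depth filter removes such regions).
- 0·log 0 ≡ 0 throughout entropy and KL computations; KL is +∞ where
  P > 0, Q = 0 (JSD never hits this: the mixture dominates both arguments).
- sJSD values of exactly 0 or 1 are clipped to [1e−6, 1−1e−6] before the
  logit transform.
- Fisher combination clips p = 0 to 1e−300.
- q = 0 maps to the SQS cap (default 300).
- Ties in classification rules resolve in the documented rule order.
- GUs with no CpG site, and GUs of unmodeled regions, emit no statistics
  (track gaps), rather than placeholder values.

## Known limitations

- The product-of-runs marginal for non-contiguous reads is an approximation
  (exact only for uncoupled runs).
- At the smallest coupling difference (δ = 0.4) the detection margin is
  finite-sample limited: in island fragments fitted from only ~70–90 reads,
  the maximum-likelihood coupling of an uncoupled sample occasionally comes
  out mildly positive, shrinking those GUs' JSD toward the replicate-null
  tail; isolated GU runs can then fall just short of the q ≤ 0.01 bar, so
  perfect sensitivity at δ = 0.4 is typical but not guaranteed for every
  random realization. Specificity is unaffected.
- The logit-normal null assumes the lower-mean mixture component is pure
  null; with few alternatives the forced two-component fit splits the null
  itself, making the tail conservative.
- The level/entropy classification cut points are package defaults, not
  canonically published values; treat class tracks as qualitative.
- No within-group biological variance model beyond the replicate-pair
  empirical null; no paired-sample designs; at most two samples per
  comparison (use rank products across comparisons).
- BAM ingestion is deferred to an external converter producing the
  observation TSV; CpH methylation and strand-specific analyses are out of
  scope.
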