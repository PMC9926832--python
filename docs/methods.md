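# Methods

`ulcgwas` reimplements, as a tested library, the analysis chain used to run
a genome-wide association study on ultra-low-coverage whole-genome
sequencing (ulcWGS, mean depth ~0.04x) of preimplantation genetic testing
(PGT) embryo biopsies: pooled-read population SNV calling, ancestral-
haplotype genotype imputation, INFO/HWE/MAF site filtering, a
coverage x sample-size accuracy benchmark, a dosage score-test GWAS with
batch covariates, and LD clumping into genomic risk loci. Real PGT data of
this kind are not publicly deposited, so every stage runs on synthetic
cohorts whose generator is itself first-class, tested code.

## Synthetic cohorts

**Haplotype panel.** A founder-mosaic copying process, not a coalescent:
`n_founders` founder haplotypes are drawn site-wise Bernoulli(f_m) with
f_m from a configurable allele-frequency spectrum (default Uniform(0.05,
0.95), a common-variant spectrum appropriate for MAF >= 0.01 pipelines);
each of `n_hap` panel haplotypes copies one founder at a time and switches
to a uniformly drawn founder with per-bp probability `recomb_rate`. This
gives LD that decays with physical distance, exact ground truth and
bit-reproducibility under a seed.

With `n_blocks > 1` the region is split into equal blocks by deterministic
recombination hotspots: every haplotype re-draws its founder at block
boundaries, so LD is strong within a block and absent between blocks. This
matters because a single recombination-free founder set gives a genotype
matrix of rank `n_founders - 1`; principal components computed from such a
matrix span essentially all genotype variation and absorb any association
signal. Blocks raise the genome-wide rank (here ~15) the way independent
loci across a real genome do, while leaving local LD strong enough for
imputation at 0.04x.

**Cohorts and families.** Each family draws two parental haplotype pairs
from the panel; every sib inherits one whole haplotype from each parent
(no meiotic recombination inside the simulated region — at the 1.5-Mbp
desk scale the expected number of crossovers is negligible). Sibling
sharing therefore follows the expected 50% per parent, and the generator's
family concordance property is tested. Each sample carries a batch label:
one of 3 whole-genome-amplification kits x 4 sequencing platforms.

**Read pileups.** Per sample per site the read count is
Poisson(`coverage`); each read copies one of the two true alleles with
probability 1/2 and is substituted to a uniformly chosen other base with
the batch's error probability e in (0, 0.75] (so P(b|a) = 1-e if b=a,
else e/3 — exactly the likelihood the calling stage assumes). The default
batch error profile spreads deterministically over [0.002, ~0.005].

**Phenotype.** y = sum_j beta_j g_j + clinical-covariate terms + batch
shifts + Gaussian noise, then z-scored (ddof=1). Clinical covariates are 6
continuous Gaussians and 2 Bernoulli indicators, mirroring the eight
recorded clinical variables (maternal age, BMI, fetal sex, ... ) whose
real distributions are not published. `noise_sd = 0` is allowed for
noiseless limiting cases.

## Population SNV calling

All reads at a site are pooled across the cohort. The likelihood of an
alt-allele frequency f is `L(f) = prod_r [f P(b_r|alt) + (1-f) P(b_r|ref)]`;
log L is concave, and the MLE is found by golden-section search on [0, 1]
to 1e-6 (checked against a 1e-5-step grid scan to 1e-4). Polymorphism is
tested by the likelihood ratio `Lambda = 2(log L(f_hat) - log L(0))`
against chi-square(1); the chi-square(1) reference (rather than the
boundary mixture ½chi2_0 + ½chi2_1) is conservative. The calling alpha
defaults to 1e-6 and is configurable, the corresponding cutoff not being
printed in the source analysis. The alt allele is the non-ref base whose
two-allele model attains the highest maximized likelihood (ties broken
A<C<G<T); a site is flagged multi-allelic when a second non-ref base also
passes the per-allele LRT. Region filters (problematic-alignment and
mappability tracks in the original; generic exclusions here) are expressed
as 0-based half-open BED intervals — the specific hs37d5 resources are not
bundled. Phred qualities convert as e = 10^(-Q/10), floored at 1e-4 and
capped at 0.75.

## Genotype imputation

A diploid Li & Stephens copying model with K ancestral haplotypes
(published setting K=20, nGen=2000, 10-kbp grids, diploid mode; desk
default K=6). Sites are binned into physical grids of `grid_size` bp; all
sites in a grid share the hidden state, the ordered pair of ancestral
haplotypes being copied. Between adjacent occupied grids each chromosome
switches with `rho = 1 - exp(-nGen * r * d)` (d = center distance, r a
per-bp rate, default 1e-8), jumping to a uniformly drawn haplotype.
Uniform jumps keep the transition kernel parameter-free, so the EM below
is exact. Ancestral haplotype k carries an alt dosage theta[k, m] per
site; a read emits `P(b|k1,k2) = ½ B(b;theta[k1,m]) + ½ B(b;theta[k2,m])`
with `B(b;t) = t P(b|alt) + (1-t) P(b|ref)`.

The state space is stored as ordered K x K pairs. The unordered
K(K+1)/2 representation is mathematically identical (emissions are
symmetric); the ordered form was chosen because the forward-backward
recursion then factorizes into two per-chromosome rank-1 updates that
vectorize over all samples at once in numpy, which costs less in practice
than the 2x state saving.

**EM.** theta is initialized Beta-perturbed around the pooled per-site AF
estimates (seed-controlled); pi starts uniform. The E-step is an exact
forward-backward per sample; the M-step updates theta from expected
alt-allele read assignments (each read is attributed to a chromosome and
an allele by exact conditional responsibilities) and pi from the
initial-grid state marginals. Both steps are exact, so the total
log-likelihood is nondecreasing — asserted in the tests to 1e-6 relative.
theta updates are box-clipped to [1e-4, 1-1e-4]: the per-parameter
objective is concave, so the clip is the exact constrained maximizer
(monotonicity survives) and degenerate theta in {0,1} cannot veto read
evidence downstream. EM stops at `n_em_iters` (desk default 30) or a
relative log-likelihood change below 1e-6. Per-sample recombination or
error-rate updating is not implemented, and no reference panel is used
for seeding (at large N the published analysis found the panel's benefit
insignificant).

**Genotype posteriors.** The allele pair at a site is drawn per chromosome
from the copied haplotype's theta and conditioned on the site's own reads,
each read choosing a chromosome uniformly. For read-free sample-site cells
this reduces to a quadratic form in the state posterior; read-bearing
cells get an exact 4-configuration correction. Note one deliberate
approximation inherited from the emission model: within the grid-level
emission, reads are treated as independent draws from theta (two reads at
one site may "see" different alleles), while the genotype posterior
conditions a single allele pair on all of that site's reads. The
enumeration oracle in the tests mirrors exactly this semantics. A
consequence worth knowing: each read contributes at most 2:1 evidence for
het vs hom under the half-mixture, so very deep reads on one sample cannot
overturn a confidently wrong haplotype prior from a badly underfit model —
visible only far outside the ulcWGS regime the model targets.

Certainty per site is the IMPUTE2-style INFO score,
`1 - sum_i(f_i - e_i^2) / (2N theta(1-theta))` with e = p1 + 2 p2,
f = p1 + 4 p2, defined as 1 when theta-hat is 0 or 1 and clamped to [0,1].

**Windows.** Regions longer than `window_size` (5 Mbp) are imputed in
windows with 500-kbp overlap; in overlap zones each site is taken from the
window whose center is nearer (ties to the left window). At desk scale a
region fits one window; the stitching logic is tested on synthetic
window results.

## Site QC and accuracy metrics

Hard calls are argmax posteriors (ties to the lower genotype). HWE is the
exact conditional test on hard-call counts — enumeration over all
same-parity heterozygote counts with fixed allele totals, computed with a
gammaln table and validated against an exact-rational oracle to 1e-12.
MAF comes from mean dosage (smoother than hard calls at ultra-low
coverage). The GWAS input filter is the published combination: known-
catalog membership (emulated by flagging a configurable fraction of
sites), MAF >= 0.01, INFO >= 0.4, HWE p > 1e-6.

Genotype accuracy is hard-call concordance with truth; allele accuracy
relaxes zygosity and only asks whether the presence of a non-reference
allele agrees. INFO is a *model-based* certainty measure: it is calibrated
only when the copying model itself is adequately fit. Under a badly
underfit model (very small cohorts) confidently wrong sites can score
high, and the filter-benefit pattern — filtered accuracy at least matching
unfiltered — genuinely inverts; the property tests therefore assert it at
model-adequate operating points, mirroring the original single
well-fit benchmark configuration. Trend and filter properties are evaluated over all
simulated samples (the synthetic truth is known for everyone), which makes
the monotonicity checks structural rather than hostage to one sample's
binomial noise; the benchmark grid itself scores the single injected truth
sample, as the original HG005 design does.

## Benchmark

For each cohort size s one cohort is simulated at its own coverage
(0.04x), population-called, and EM-fitted once; a single truth individual
is sequenced once at the highest grid coverage, and every lower coverage
is a nested Poisson thinning of that one read set, imputed under the
fixed per-size model (truth reads never enter the callset or the fit).
Fixing the model per size and nesting the read sets mirrors the original
design — one embryo cohort, one truth sample whose raw reads are
subsampled per coverage — and makes information content monotone along
both grid axes instead of leaving the coverage trend hostage to
independent re-draws of a single genome.
The evaluation set is the PASS callset (MAF >= 0.01). The desk grid is
{0.01, 0.04, 0.1}x x {500, 2000}; the published 10x8 grid is available as
the study-scale preset. Accuracy over the grid is summarized by OLS of
genotype accuracy on (c, s, 1); at desk scale the fit domain drops the
published s >= 4000 restriction because desk cohorts are smaller.

## GWAS

Phenotypes are z-scored. Covariates are an intercept, the top principal
components of the standardized dosage matrix (MAF >= 0.05 sites, centered
by 2 theta-hat, scaled by sqrt(2 theta-hat (1-theta-hat)), sign-fixed on
the largest loading) and the 8 clinical covariates. The desk preset uses
2 PCs: the published 8 PCs are computed genome-wide, where they carry a
negligible share of genotype variance; on a ~15-axis desk genome 8 PCs
would absorb roughly half of every dosage vector, including the causal
signal — 2 PCs is the scale-faithful analogue, and the study-scale preset
restores 8.

Each site is screened by the score test U = e'r/sigma^2,
V = e'Me/sigma^2, chi2 = U^2/V ~ chi-square(1), where e is the
posterior-mean dosage, r and sigma^2 come from the covariate-only fit and
M is its residual projector. A site is tested only when at least
`min_high` = 15 samples have max posterior >= 0.9 (the high-credibility
cutoff is configurable; the upstream tool leaves it implicit). Effect
sizes are the dosage coefficient of OLS on [X, dosage], computed by
Frisch-Waugh residualization and validated against statsmodels. Genome-
wide significance is Bonferroni alpha/n_tested — the published level
4.515e-8 is exactly 0.05/1,107,198 (to the printed precision; the source
itself prints 4.515e-8 in the text and 4.526e-8 in a table caption).
Inflation is summarized by median-based genomic control
lambda_GC = median(chi2)/0.45494 plus the mean chi-square; LDSC intercept
estimation is out of scope (it requires an external LD reference).
Sibling relatedness is not corrected for in association, matching the
source procedure; with whole families of siblings the score test's
effective N is smaller than the nominal N.

## Risk loci

LD is the squared Pearson correlation of the cohort's own dosage vectors
(standing in for an external reference panel). Greedy ascending-p
selection (position as tie-break) yields independent significant SNPs
(pairwise r^2 < 0.6), then lead SNPs (r^2 < 0.1); candidates are the
independents plus SNPs with p < 0.05 linked at r^2 >= 0.6. Each candidate
joins its nearest lead, lead regions span their members, and regions
closer than 250 kbp (a configurable stand-in for the unpublished merge
rule) merge iteratively to a fixed point. Positional gene mapping reports
genes whose (BED-interval) span extended by 10 kbp contains a candidate
SNP.

## Desk preset and problem sizes

The desk preset renders the study conditions at laptop scale: 3 LD blocks
x 1200 sites over 1.5 Mbp (1 site per 1.25 kbp; the real callset averages
~1 common site per 100 bp, and since per-site coverage fixes reads-per-
sample proportional to site count, realistic density is what keeps the
HMM informed at 0.04x), 6 founders per block, 300 panel haplotypes,
N = 1744 with 3 sibs per family, coverage 0.04x, K = 6, 30 EM iterations.
One end-to-end run takes ~30 s on one CPU; the benchmark grid ~30 s.
Under these conditions genotype accuracy is ~0.9, INFO median ~0.75, and
a planted beta = 0.35, MAF-0.3 causal SNP is recovered inside a single
risk locus in essentially every seed.

## What the generator does not emulate

No WGA amplification-bias waveforms, PCR duplicates, alignment artifacts,
aneuploidy, chromosome X, indels or multi-nucleotide variants; batch
effects enter only through substitution-error rates and phenotype shifts;
no population stratification beyond founder structure. Passing tests
therefore demonstrate correctness of the algorithms and calibrated
behavior under the stated generative model — not performance on real PGT
data, whose accuracy ceiling at 0.04x (printed at 0.48-0.7) reflects
artifacts this generator deliberately omits.

## Numerical choices

Forward-backward is normalized per grid with accumulated log scalings;
posteriors renormalize to 1e-9. Golden-section tolerance 1e-6; EM
relative tolerance 1e-6; theta box [1e-4, 1-1e-4]; degenerate score-test
variance cutoff 1e-10 (flagged, not tested); HWE observed-probability
comparison uses a 1+1e-12 relative slack; argmax ties resolve to the
lower genotype; stitching ties to the left window; clumping ties by
position.
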