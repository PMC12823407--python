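# Methods

This note documents the models behind `specdrift`, the parameter choices
that matter, the numerical strategies, and what the synthetic-data
results do and do not show about real data.

## Selection model and equilibrium spectra

Stabilizing selection on a polygenic phenotype is approximated by a
one-locus scheme in which both homozygotes have relative fitness 1 and
heterozygous carriers of the derived allele have fitness 1 − s_het, with
s_het equal to the variant's total squared trait effect Σ_t α_t² (for a
gene's LoFs, Σ_t γ_t²).  The reference population is 20,000 diploids
(two_N = 40,000 haploid genomes) with per-site mutation rate
μ = 1.25 × 10⁻⁸ and symmetric recurrent mutation.  Spectra are computed
for the discrete-time Wright–Fisher chain conditioned so the derived
allele cannot fix: the fixation state is deleted and transition rows
renormalized ("ancestral allele known").

**The fixation attractor.**  Taken literally at all frequencies the
scheme is underdominant, so the conditioned chain has a second,
biologically meaningless quasi-stationary lump just below fixation.  For
two_N·s_het ≳ 10 the exact stationary vector concentrates there behind a
probability barrier of order exp(two_N·s_het/4), while every allele in
the modelled process arises by mutation from the ancestral state and
essentially never crosses that barrier.  `compute_equilibrium_afs`
therefore uses two regimes ("auto" backend):

- **two_N·s_het ≤ 10** — the chain mixes across the interior; the exact
  stationary distribution is obtained by a sparse direct solve of
  πP = π.
- **two_N·s_het > 10** — the mutation-origin metastable equilibrium is
  computed as the stationary law of the chain restricted (reflected by
  row renormalization) to the bottom basin, counts ≤ two_N/2, further
  truncated where the equilibrium bound exp(−2·s_het·k) falls below
  ~10⁻²⁴ relative.  Truncation error is of order exp(−two_N·s_het/2).
  Plain forward iteration from the monomorphic state converges to the
  same law (`backend="forward"`, kept as a cross-check; it is slow in
  the moderate-selection band where probability leaks toward the
  attractor on exponentially long timescales).

Each solve ends with a residual check (‖πP − π‖₁ ≤ 10⁻⁸).

**Desk scaling.**  Spectra are computed on chains small enough to solve
while preserving the drift-scaled parameters two_N·μ and two_N·s_het of
the reference population.  Because the strong-selection equilibrium is
confined to a small basin (~14/s_het counts), those spectra are solved
at, or near, full reference size; only weakly selected points are
rescaled down (default floor: 2,000 haploids).  This matters: rescaling
a strongly selected model distorts the per-copy selection coefficient
toward O(1) and suppresses segregation probabilities many-fold.  The
default grid is 50 s_het values log-spaced on [10⁻⁷, 0.05]; it builds in
roughly half a minute and is cached per process.

**Diffusion cross-check.**  The independent oracle is Wright's
stationary density for the same scheme,
φ(f) ∝ exp(−c·f(1−f))·[f(1−f)]^(θ−1) with c = 2·two_N·s_het and
θ = 2·two_N·μ, optionally weighted by the eventual-loss probability
q(f) = ∫_f^1 e^{c·x(1−x)}dx / ∫_0^1 e^{c·x(1−x)}dx, the diffusion
analogue of the no-fixation conditioning.  The "auto" conditioning
mirrors the chain's backend split (unconditioned in the mixing regime,
loss-conditioned in the metastable regime).  Boundary cells are
integrated with the substitution u = f^θ (and its mirror), which
represents the integrable boundary singularities exactly even where f
underflows.  Agreement with the chain is asserted on minor-allele
summaries — folded mean and E[p(1−p)] — because the unfolded mean of the
conditioned chain is dominated by a non-diffusive boundary layer at weak
selection; measured agreement is within ~4% across two_N·s_het ∈ [1,
100] at both θ = 10⁻³ and θ = 0.2.  The closed form E[p] = μ/s_het holds
in the selection-dominated regime (guarded at s_het ≥ 100μ; asserted for
two_N·s_het ≥ 30, within 10%).

## Pleiotropic effect sizes

A variant's squared-effect vector over T = 18 traits is drawn as
α² ~ (10⁻⁷/f) · exp{3f · MVN(0, p·I + (1−p)·11ᵀ)}, elementwise, with
f = 0.33 and p = 0.5 by default.  The off-diagonal covariance of the
latent Gaussian is 1 − p, so p = 1 gives independent traits and p = 0
perfectly correlated ones; f controls the spread of total effects (the
latent Gaussian is realized as √p·iid + √(1−p)·shared, which is exact).
The exponent coefficient is 3·f: the alternative reading 3/f puts four
decades of log-sd on each entry, under which ultra-rare huge-effect
variants dominate every simulated hit ranking and the hit-pleiotropy
quartile patterns invert; with 3·f the simulated per-trait hit counts,
and all three quartile contrasts, reproduce the intended study patterns
(verified over 40 seeds).  Selection against a variant is the L1 norm of
its squared-effect vector, and specificity for trait t is that trait's
share, Ψ_t = α_t²/Σ_k α_k²; every trait is analysed as its own study
trait.

**Gene panels.**  Genes draw γ² vectors with the same machinery,
rescaled so Σγ² is log-uniform on (10⁻⁴, 0.05) — the range of inferred
human gene-level selection coefficients — with the focal-trait share
optionally re-planted (default Ψ_G ~ Beta(0.5, 2), spanning fully
specific to highly pleiotropic).  The mutational-target proxy μL
(expected unique LoF sites) is log-uniform on (6.25 × 10⁻⁷,
6.25 × 10⁻⁵), i.e. 50–5,000 potential LoF positions at μ = 1.25 × 10⁻⁸,
drawn independently of effects so length and importance are uncorrelated
by construction.  Cis-variant effects β are log-normal (median 1, log-sd
1.25 in the flattening analysis) — the β law is a free modelling knob
the analyses only use relatively.

## Association simulators

Phenotypes are variance-standardized and covariate-free, so the sampling
SE of a per-allele estimate at minor allele frequency q is
1/√(2·n·q(1−q)).  GWAS estimates are Normal about the signed square root
of the squared effect (fair random sign; downstream statistics square
the estimate) with N_eff = 10⁷; significance uses z² against the χ²₁
tail, P values carried in log10 space, hit threshold t = 10⁻⁵ for
simulations and 5 × 10⁻⁸ for real-scale data.  Burden tests draw each
gene's per-site frequencies from the spectrum nearest its Σγ² on the log
scale, drop sites above a 1% frequency mask, aggregate carriers as
p_LoF = 1 − Π(1−p_i), and use a 400,000-diploid sample (exome-study
scale); genes whose included sites carry no frequency are flagged
untestable rather than raised.  Subsampling to n of N inflates SEs by
√(N/n) (variance 1/n scaling; the literal ×N/n reading is available via
`se_mode="literal"`), with conditional mean the full-sample estimate and
conditional variance ((N−n)/n)·SE².

The realized-heritability experiment simulates 50,000 unlinked variants
(1,000 log-spaced s_het values on [10⁻⁷, 2.3 × 10⁻⁴] × 50 variants),
draws GWAS sample frequencies as Binomial(600,000, f)/600,000, sets
h² = 2·s_het·f̃(1−f̃) (all variants equally specific, so α² ∝ s_het), and
max-scales both axes, which removes the unstated proportionality
constant.  The decoupling statistic is the Spearman correlation among
sample-segregating variants with scaled squared effect > 0.25.

## Hit-pleiotropy analysis

For each trait, hits are split into P-value quartiles (quartile 1 most
significant; ties broken by MAF then input order is irrelevant because
quartiles are recomputed from sorted values).  Each quartile reports
mean MAF relative to the trait's overall hit mean, mean number of traits
hit (focal included), and, in simulations, mean true Ψ.  The real-data
inclusion rule (≥100 hits per trait) is a data filter; at the desk-scale
default of 10⁶ positions each simulated trait lands near 10–40 hits, so
the simulation profiles all traits with a floor of 10 and the acceptance
contrasts aggregate across the 18 traits.  Positions drawn monomorphic
never become hits; positions whose total effect exceeds the strongest
grid spectrum are clipped to it by default (`beyond_grid="drop"` treats
them as never segregating).

## Estimators, enrichment and flattening

γ̂² − SE² is the unbiased importance estimator; negative values are kept
so averages stay unbiased.  Gene bins are contiguous equal-size splits
after sorting by the key with id tie-breaks (100 bins of ~184 genes at
the default panel size).  Heritability enrichment per bin uses z² − 1 as
the proportional heritability proxy: per trait, bin means relative to
the all-gene mean, with empirical SEs (within-bin SD/√n), inverse-
variance-weighted across traits, renormalized to average to one (burden
convention) or sum to one (heritability-partitioning convention); traits
with non-positive overall z² − 1 carry no signal and are dropped with a
warning.

The flattening analysis computes, per variant, the expected heritability
contribution 2α²·E[p(1−p)] with s_het = α² (fully specific variants),
using the loss-conditioned diffusion density for E[p(1−p)] — smooth in
s, which matters because gene totals integrate across the drift-to-
selection crossover — extended by the exact balance limit μ/s beyond the
desk-scalable range.  β draws are shared across the γ grid (common
random numbers isolate the γ effect).  Per-variant contributions rise
and then plateau near 2μ; per-gene totals keep rising with γ because a
broad β distribution keeps recruiting weak cis variants across the
contribution threshold.  With a narrow β spread the totals can dip
slightly past the crossover (the conditioned equilibrium overshoots the
2μ plateau by ~25% before settling), which is why the default β log-sd
is 1.25.

## Locus algebra

Coordinates are 0-based, half-open.  Hits are grouped per chromosome
from most to least significant: the top unassigned hit seeds a locus,
all unassigned hits within 1 Mb join, and expansion repeats to a fixed
point (so the output is independent of input order); the locus span is
the member range padded by half the window per side (`span_pad`
configurable — the ±1 Mb reading of the window is available).  Genes are
assigned by half-open interval overlap.  Ranking is by minimum P (or by
largest significant |effect|, excluding loci with no significant
member); ties break by (chromosome, span start).  Power matching walks
loci in rank order taking each locus's burden-significant genes, else
its single smallest-burden-P gene, until the burden discovery count is
reached.  LD-block comparison takes per-block minima and drops any block
whose minimizing burden gene also minimizes another block.  Default
thresholds: GWAS 5 × 10⁻⁸, burden 2.7 × 10⁻⁶ (0.05/18,524 genes).

## Specificity proxies

Expression specificity is focal-tissue TPM over the sum across all
tissues, computed for genes with focal TPM strictly above 10; quintile
bins use breakpoints from the score distribution pooled across
trait–tissue pairs, ties to the lower bin.  ATAC peaks are "present" in
a tissue when strictly more than 5% of samples contain them; peaks
present in the focal tissue get a sharing count over the 19 tissues,
binned 1–2 / 3–8 / 9–15 / 16–18 / 19, and an intensity (focal presence
fraction) binned into groups sized to match the sharing bins, highest
intensity paired with the most specific sharing bin.

## Reproducibility

All randomness flows through `numpy.random.Generator`s; every public
simulator takes a seed or generator.  The pipeline derives per-stage
streams from the master seed keyed by stage name (SeedSequence spawn
keys), so inserting a stage does not perturb the others, and identical
config + seed reproduces outputs byte for byte (manifest recorded as
JSON).

## Problem sizes

Defaults were chosen so the full test suite runs in a few minutes on one
CPU: selection-grid chains of 2,000 haploids at the weak end (full
40,000 at the strong end), 10⁶ simulated GWAS positions, gene panels of
3,000–18,400, 10⁵-replicate estimator checks.  The pleiotropy quartile
contrasts, balance/diffusion agreements and estimator recovery are
asserted at these sizes.

## What the synthetic results do not show

The generator has no linkage disequilibrium (sites and variants are
unlinked, and "clumped" GWAS hits are assumed independent), no realistic
gene structure, demography, dominance beyond the stated scheme, or real
tissue ontologies; phenotypes are Gaussian and covariate-free, so
nothing here speaks to case–control traits or confounding.  Passing
tests show the *mechanisms* — frequency–effect coupling, length-driven
power, drift-scrambled rankings, the flattening plateau — behave as the
theory predicts in a world where the theory's assumptions hold exactly;
they do not validate those assumptions in human data.  Real-data
quantities that depend on biobank inputs (overlap percentages, rank
correlations between study designs) are outside what synthetic runs can
reproduce.
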