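# Methods

## Setting and model

The package implements two-sample Mendelian randomization (MR) on GWAS
summary statistics. A SNP *j* is an instrument for an exposure *X* if it is
associated with *X* (relevance), shares no confounder with the outcome *Y*
(independence), and affects *Y* only through *X* (exclusion restriction).
Under these assumptions the per-SNP Wald ratio
θ̂<sub>j</sub> = β̂<sub>yj</sub>/β̂<sub>xj</sub> estimates the causal effect
of *X* on *Y*, and the estimators combine the J ratios:

- **IVW**: β̂ = Σw<sub>j</sub>θ̂<sub>j</sub>/Σw<sub>j</sub> with
  w<sub>j</sub> = 1/se(θ̂<sub>j</sub>)² and the first-order SE
  se(θ̂<sub>j</sub>) = σ<sub>yj</sub>/|β̂<sub>xj</sub>|. The fixed-effects
  SE is (Σw<sub>j</sub>)^(−1/2); the multiplicative random-effects SE
  inflates it by max(1, √(Q/(J−1))) where Q is Cochran's heterogeneity
  statistic. The default `auto` policy uses random effects when Q has
  p < 0.05, mirroring the practice of switching models under persistent
  heterogeneity. With one SNP the estimate is the Wald ratio itself.
  Wald/IVW inference is normal; a binary outcome's log-odds estimate is
  reported on the OR scale as exp(β̂) with exponentiated CI bounds.
- **MR-Egger**: weighted least squares of β̂<sub>y</sub> on β̂<sub>x</sub>
  with weights 1/σ<sub>y</sub>², free intercept, pairs oriented so
  β̂<sub>x</sub> ≥ 0. The slope is the causal estimate; the intercept
  estimates directional pleiotropy. Inference for both uses the
  WLS-estimated residual scale and the t distribution with J−2 df. The
  estimated scale is essential: under balanced pleiotropy the residual
  variance exceeds σ<sub>y</sub>², and a fixed-scale test would grossly
  over-reject (the estimated-scale test is what keeps the measured type-I
  error near its nominal level — see the calibration experiment).
- **Weighted median**: order θ̂<sub>j</sub>, form normalized weights
  w′<sub>j</sub> and ranks p<sub>j</sub> = Σ<sub>k≤j</sub>w′<sub>k</sub> −
  w′<sub>j</sub>/2, and interpolate the quantile function at 0.5. It is
  consistent while valid instruments carry > 50% of the weight. The SE is
  the SD of the estimate over n_boot (default 1000) parametric resamples
  (effects redrawn normal around observed values with observed SEs) under
  an explicit seed recorded in the result.

## Instrument processing

Selection keeps SNPs with p < 5×10⁻⁵ (strict inequality), the threshold
used when genome-wide significance would leave too few instruments for
molecular traits. Greedy LD clumping repeatedly takes the lowest-p
unclaimed SNP (ties broken by lower chromosome/position for determinism)
and discards unclaimed SNPs within 10,000 kb on the same chromosome with
r² ≥ 0.001 against it; LD is consumed as a precomputed pairwise table
(absent pair ⇒ r² = 0) — computing r² from a reference panel is out of
scope, which keeps the artifact download-free. Instrument strength uses
the t-approximation R² = t²/(t² + n − 2), F = R²(n−2)/(1−R²) (algebraically
t²), and SNPs with F < 10 are dropped.

Harmonization matches records by SNP id, removes palindromic (A/T, C/G)
variants unconditionally — no allele-frequency rescue — and aligns the
outcome onto the exposure's effect allele, flipping β and EAF when the
alleles are swapped, after attempting strand-complement reconciliation;
irreconcilable pairs are dropped and counted.

Steiger filtering keeps a SNP only if it explains strictly more variance in
the exposure than in the outcome (ties drop, a conservative deterministic
policy); the two-sided Steiger p compares Fisher-z-transformed |r| values
with variance 1/(n<sub>x</sub>−3) + 1/(n<sub>y</sub>−3). The pipeline
applies it before estimation (configurable), which is what lets reverse-MR
rows and mediator instrument sets shed variants whose association is
driven through the other trait.

## Sensitivity analysis and outlier handling

Cochran's Q (with df J−1 and a chi-square upper tail) is computed once and
shared with the IVW random-effects inflation. Funnel and leave-one-out
tables are emitted as points, not figures.

The pleiotropy/outlier test follows the MR-PRESSO recipe: the observed
statistic is RSS = Σ<sub>j</sub>(β̂<sub>yj</sub> −
θ̂<sub>(−j)</sub>β̂<sub>xj</sub>)² with θ̂<sub>(−j)</sub> the leave-one-out
IVW estimate; its null distribution comes from n_sim (default 5000)
parametric draws β<sub>x</sub>* ~ N(β̂<sub>x</sub>, σ<sub>x</sub>),
β<sub>y</sub>* ~ N(θ̂<sub>(−j)</sub>β̂<sub>xj</sub>, σ<sub>y</sub>), each
re-evaluated with its own leave-one-out ratios. Empirical p-values use
(1+k)/(n_sim+1), so they are floored at 1/(n_sim+1). Per-SNP outlier
p-values are Bonferroni-corrected across the J SNPs; the distortion test is
omitted (only detection and re-evaluation are needed here). The screening
pipeline runs this audit *before* estimation and reports every estimate on
the outlier-cleaned instrument set ("outliers removed for re-evaluation");
the pre-removal IVW and the flagged SNPs are kept in the output.

## Two-step mediation

For exposure→mediator→outcome, *a* is estimated with the exposure's
instruments, *b* with the mediator's instruments (univariable two-step MR,
not multivariable MR), *c* with the exposure's instruments against the
outcome. The direct effect is derived, c′ = c − a·b, so c = c′ + a·b holds
exactly by construction, and the proportion mediated is 100·a·b/c,
computed on the estimation scale (log-odds for a binary outcome; the scale
is recorded in the ledger). No SE is attached to the proportion by default
(point percentages only). A mediator is *eligible* only when all three
paths are significant at α (default 0.05) and sign(a·b) = sign(c): a
mediator pushing the outcome opposite to the total effect cannot carry it,
it can only mask it. Ineligible pairs stay in the ledger with the first
failed condition named. The reverse mediator→exposure MR is run and
reported for every pair so mediator-caused-exposure configurations are
visible.

## Synthetic data generator

Summary statistics are simulated directly — no individual-level genotypes —
because the analysis only ever consumes summary data and direct simulation
makes the sampling-error formula an exact oracle: a standardized per-allele
estimate from a study of size n at minor-allele frequency f has
se = 1/√(2f(1−f)n). Observed effects are true effects plus N(0, se²) noise;
p-values are two-sided normal.

Three disjoint instrument sets are drawn: exposure instruments with
γ<sub>j</sub> ~ N(0, γ_sd²); mediator instruments with direct mediator
effects δ<sub>j</sub> ~ N(0, γ_sd²) reaching the outcome only through *b*;
and outcome instruments affecting only the outcome. Per-SNP truth obeys
β_out = c′γ + b(aγ + δ) + η, where η carries pleiotropy and the outcome
instruments' effects. Without mediator-specific instruments the
mediator→outcome leg would be unidentifiable from the generated data
(every mediator-associated SNP would act through the exposure, with Wald
ratio c/a); with them, Steiger filtering plus outlier re-evaluation
recovers *b* — this mirrors real screens, where inflammatory-protein
instruments are largely cis protein QTLs not shared with metabolite loci.

Directional pleiotropy is defined on the exposure-increasing allele:
η<sub>j</sub> = sign(γ<sub>j</sub>)·N(pleio_mean, pleio_sd) for the
pleiotropic fraction. Defining it relative to an arbitrary allele coding
would cancel under MR-Egger's β<sub>x</sub> ≥ 0 orientation and make a
directional mean unrecoverable by construction.

Optional block LD: within a block each SNP carries the index SNP's signal
scaled by √(ld_r2) and appears in the emitted LD table at r² = ld_r2.
Sampling noise is drawn independently per SNP — a simplification (real LD
also correlates estimation errors) that is adequate for exercising
clumping. Mediator and outcome tables are emitted with randomly swapped
and strand-flipped allele codings so harmonization is exercised on every
run. A binary outcome reuses the Gaussian effect model on the log-odds
scale (no liability-threshold simulation) — sufficient for estimator
testing, and a documented limitation for absolute-risk realism. Other
unmodelled features of real data: allele-frequency/effect-size coupling,
population stratification, sample overlap between the two samples, and
real genome LD maps; conclusions from the tests are about estimator
mechanics under the stated model, not about those artifacts.

## Defaults and problem sizes

| Parameter | Default | Why |
| --- | --- | --- |
| instrument p-threshold | 5×10⁻⁵ | molecular-trait screen with few genome-wide hits |
| clump window / r² | 10,000 kb / 0.001 | long-range conservative pruning |
| F threshold | 10 | conventional weak-instrument cut-off |
| α (significance / gate) | 0.05 | raw screen calls; FDR available behind a flag, off by default |
| effects model | auto | random effects only under detected heterogeneity |
| n_boot | 1000 | weighted-median bootstrap |
| presso n_sim | 5000 (1000 in experiments) | empirical-p resolution vs runtime |
| γ_sd | 0.15 | ≈1% exposure variance per instrument at intermediate MAF, typical of metabolite hits |
| maf_range | (0.1, 0.5) | common variants |
| n per study | 50,000 | reference recovery conditions |
| a, b, c′ | 0.4, 0.5, 0.3 | planted decomposition: c = 0.5, 40% mediated |
| palindromic_frac / pleio | 0 | off unless an experiment exercises them |

The characterization experiments use 200 replicates (500 for Egger
calibration, 100 for spike detection) at J = 50 instruments (20 for the
outlier experiments), sizes at which each experiment completes in seconds
to tens of seconds on one core while Monte-Carlo errors remain small
enough to resolve the tested properties.

## Numerical and degenerate-input policy

P-values are floored at 1e-300 to stay within (0, 1]; a Wald ratio with
β̂<sub>x</sub> = 0 raises rather than returning ±inf; empty filter results
return None and batch screens degrade to flagged rows (`no_instruments`)
instead of aborting; clumping and harmonization order their outputs by
(chromosome, position, id) so equal inputs give byte-identical outputs.
All stochastic components (bootstrap, outlier simulations, generator) take
explicit seeds, recorded in their outputs.

## Known limitations

Univariable two-step mediation only (no multivariable-MR direct effects,
no joint multi-mediator decomposition); no mode-based or
contamination-mixture estimators; LD is an input, not computed; the
generator's binary-trait and LD simplifications above. Proportions
mediated are computed on the log-odds scale; percentages from analyses on
other scales are not directly comparable.
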