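# Methods

This note documents the models, estimators and numerical choices behind
`coevoscan`, what the synthetic-data generator does and does not emulate,
and the package's known limitations.

## Evolutionary model

Species relationships are a rooted phylogeny with non-negative branch
lengths. All comparative statistics assume **Brownian motion** on that tree:
a trait's expected covariance between two tips equals the branch length
shared on their root-to-tip paths (the depth of their most recent common
ancestor). `phylocomp.brownian_cov` builds that matrix; it is symmetric PSD
by construction, with root-to-tip distances on the diagonal.

The joint evolution of the log substitution-rate ratio (log ω) with log
brain size, log gyrification index and log body mass is a 4-dimensional
Brownian motion with diffusion matrix Σ (`synthdata.EvolScenario`). Off-
diagonal entries of Σ encode co-evolution; the rate attached to a branch is
`exp` of the mean of its endpoint log-ω states, matching the branch-
averaging of a Brownian rate process. Traits are kept on log scale
throughout (brain size and body mass are conventionally log2 kg and GI a
log ratio; the base only rescales and never changes a correlation).

For multi-gene studies the trait history must be *shared* across genes while
each gene's rate process has its own linkage to it.
`synthdata.simulate_rate_on_traits` therefore simulates a gene's log-ω
conditionally on a given trait realisation: per branch, the log-ω increment
is ρ times the standardized trait increment plus independent Gaussian noise,
so the increment correlation equals ρ exactly.

### PGLS

`phylocomp.pgls_fit` fits y = Xβ + ε, ε ~ N(0, σ²C) by maximum likelihood:
whiten by the Cholesky factor of C, solve least squares, profile σ² out
analytically. ML (not REML) is used deliberately so likelihood-ratio tests
between nested fixed-effect models are valid; the LRT statistic is referred
to χ² with df equal to the parameter difference. Residual R² is
1 − GRSS(full)/GRSS(null) with both generalized residual sums of squares
computed under the same covariance — 0 for identical fits, 1 for a perfect
fit, and monotone in signal-to-noise. With C ∝ I the whole machinery
reduces exactly to OLS (verified to 1e−8 in the tests).

Numerical guards: zero-length branches receive ε = 1e−8 before covariance
or contrast computation; the ML variance estimate is floored at 1e−24 times
the mean squared whitened response so that numerically perfect fits yield
stable, comparable likelihoods (identical models then give LRT statistic 0,
p = 1, rather than float noise); a singular covariance raises an error
suggesting a ridge rather than silently regularising.

### Independent contrasts

`pic_correlation` computes Felsenstein contrasts for both traits and
correlates them **through the origin** (contrast signs are arbitrary).
Multifurcations are resolved by sequential pairing, which preserves the
contrast count and independence under Brownian motion. The default p-value
is a t-test on n−1 contrasts; a sign-flip permutation p is available. Under
a joint Brownian model the contrast correlation estimates the diffusion
correlation, which is why the generator's ρ is recovered directly.

### Partial correlations

Partial correlations come from the inverse of the correlation matrix:
r_ij·rest = −P_ij/√(P_ii P_jj). The tests verify this against the
brute-force definition (correlation of residuals after regressing out all
remaining variables) to 1e−8 on random PD matrices.

### Permutation null

For a focal element's trait association, `permutation_null` refits the PGLS
(trait ~ activity, LRT against intercept-only) after substituting resampled
activity vectors. The default scheme draws a non-focal element uniformly
from the pool and randomly permutes its species assignment; pool-wide
resampling without permutation and species-label permutation of the focal
vector are selectable. The empirical p is reported both as k/n (the count
convention matching "k of n random combinations were as significant") and as
(k+1)/(n+1), which is never exactly zero. The implementation whitens once
and refits all permutations vectorised, so 10³–10⁵ permutations are cheap.

### Ranking

`rank_focal` reports the percentile of the focal gene among pooled controls:
(number of genes, focal included, with statistic ≥ focal) / (controls + 1)
× 100, ties counted against the focal gene. The statistic enters only
through its order, so the percentile is invariant to monotone transforms.

### MCMC trace post-processing

Bayesian rate–trait samplers are driven externally; this package only
post-processes their traces. Burn-in (default 1000 cycles) is dropped per
run. The posterior probability of a positive correlation is the fraction of
samples > 0; for display it is folded to max(pp, 1−pp) so support is
comparable across signs. Convergence: the between-run relative difference
is the largest absolute difference in run means scaled by the pooled
posterior SD (an approximation chosen because the source tool's manual-level
definition is not restated anywhere convenient; documented as such), and the
effective sample size uses Geyer's initial-positive-sequence truncation of
FFT-estimated autocorrelations. A parameter passes at reldiff < 0.3 and
ESS > 50. For iid draws ESS ≈ n; for an AR(1) chain with coefficient ρ it
approaches n(1−ρ)/(1+ρ).

## MPRA quantification

Reads are structured barcode + 20-base constant region (the start of the
reporter ORF). A read counts iff every barcode base has Phred ≥ 10, the
constant region matches with zero mismatches, and the barcode matches a
known barcode exactly; each rejection reason is tallied. Tiles detected
(count > 0) in fewer than two of the three plasmid replicates are dropped —
"detected" means any nonzero count because no threshold is defined by the
assay itself; the threshold is configurable. CPM totals are computed after
the detection filter (configurable to pre-filter totals). Tile activity is
the ratio of RNA-replicate median CPM to plasmid-replicate median CPM;
tiles whose plasmid median is 0 are flagged undefined, never imputed as 0.

Region reconstruction: for each base covered by ≥ 1 defined tile, the mean
of a_i/l_i over covering tiles, summed over bases. The implementation works
on breakpoint intervals; a per-base loop is retained as the test oracle and
the two agree to 1e−9 relative on randomized tilings with dropout and
partial coverage. Uncovered bases contribute zero; a region with no defined
tile is reported missing, not zero. A single full-length tile reproduces its
own activity exactly, and increasing any tile's activity never decreases the
region's.

Replicate QC computes pairwise Pearson correlations on log1p-CPM within each
(material, cell line) group and flags replicates whose mean correlation to
peers falls below 0.5 (no threshold is canonical; flagging is advisory
unless auto-exclusion is enabled).

## Control-gene construction

Candidates are filtered sequentially: single coding exon → human CDS length
in [291, 999] nt (closed) → an orthologue in every species → every
orthologue length in [50%, 200%) of the human length (half-open above).
Orthologue acceptance is reciprocal-best: candidate sequences are scored by
semi-global alignment (BLOSUM62, gap opening 3, extension 1 per base, free
end gaps) of the best forward reading frame against the human protein —
eligible at ≥ 30% query coverage — and the back-aligned best hit must
overlap ≥ 10% of the original CDS positions; score ties are accepted only
when the tied sequences are identical. Scoring the three forward frames of
a provided target is deliberately narrower than a six-frame genome search,
which is out of scope here.

Alignment information content: per column, λ_i is the total branch length
of the subtree induced by the non-gap species (dangling branches fully
pruned, including an internal branch left dangling by pruning — the
fully-pruned convention); columns with < 2 non-gap species contribute 0.
The statistic is mean(λ_i/λ_t) with λ_t the full tree's branch length: 1
iff gapless, non-increasing as gaps accumulate.

dN/dS uses Nei–Gojobori (1986) counting: per-position synonymous site
fractions (mutations to stops counted as nonsynonymous for sites, so
S + N = 3 per codon), equal-weight pathway averaging for multi-position
codon differences with stop-containing pathways excluded, Jukes–Cantor
correction, ω = dN/dS with an explicit undefined flag at dS = 0. This is a
desk-scale counting estimator, not a maximum-likelihood codon model; on
two-sequence simulations at 5000 codons and moderate divergence it recovers
the simulated ω within 25% relative for ω ∈ {0.2, 1, 2}. The log(dS)
outlier filter drops genes ≥ 3 SD from the mean in a **single pass** (mean
and SD computed once, outliers included; the filter is not iterated).

## Proliferation model

Counts are successes (Ki67+GFP+) out of binomial trials (GFP+ totals) —
the "weights" of a proportion-response logistic regression are exactly the
trial counts. The fit is IRLS with step-halving, so the deviance is
non-increasing across iterations (asserted in tests); convergence at
relative deviance change < 1e−8; coefficients agree with an independent GLM
implementation to 1e−6. The model is parameterised without an intercept
(one coefficient per condition; batch dummies against the first batch), so
each condition's rate back-calculates directly as expit(β_i) with batch at
the reference level (evaluation at the mean batch effect is selectable).
Without a batch term this reproduces the pooled per-condition proportions
exactly. Batch is retained iff the LRT p < 0.05 (threshold configurable).
Complete separation (a condition with all or no successes) is reported as
an error naming the condition rather than returning divergent coefficients.

Pairwise condition contrasts use the single-step max-|z| adjustment over the
joint multivariate normal of the contrast statistics, approximated by
seeded Monte-Carlo (10⁵ draws by default; Bonferroni as the deterministic
fallback). A single contrast reduces to the unadjusted two-sided normal
test up to Monte-Carlo error. The link to phenotypes delegates to the PGLS
machinery, one model per trait, Benjamini–Hochberg adjusted across the
trait family.

## What the generator emulates — and what it does not

Emulated: a pure-birth ultrametric phylogeny standing in for the fixed
mammalian tree; joint Brownian trait/rate histories; codon alignments whose
branch-wise nonsynonymous/synonymous substitution ratio follows the
simulated ω (uniform proposals over single-nucleotide codon neighbours,
synonymous acceptance min(1, 1/ω), nonsynonymous min(1, ω), stops always
rejected); tiled 94/40 reporter libraries with barcodes constrained to
contain all four bases, no 4-homopolymer, no KpnI/XbaI site (forward strand;
the miRNA-seed exclusion list is taken as an input because seed collections
are database-version dependent); negative-binomial barcode counts with a
shared dispersion (a standard overdispersion model for barcode counts) for
three plasmid replicates and per-line RNA replicates, with per-replicate
dropout; binomial proliferation counts with additive log-odds batch
effects over 7–12 replicates per condition.

Not emulated: realistic codon substitution models (GTR/MG94 exchange­
abilities, codon frequencies), indels, sequencing-error profiles beyond the
injected low-quality/mismatch fixture reads, cell-line batch structure
beyond replicate medians, regulatory-element turnover (gain/loss of
elements across lineages), and measurement error in the trait data. Passing
tests therefore demonstrate the estimators' correctness and calibration
under the stated models, not robustness to these real-data complications.

## Default parameters of the synthetic study

| parameter | default | rationale |
|---|---|---|
| species | 30 | size of the trait-complete species panel |
| controls | 124 | control cohort size after all filters |
| diffusion variances (log ω, brain, GI, body) | 0.04, 0.25, 0.04, 0.36 | rate varies within roughly e^±0.4 over the tree; body mass most, GI least variable |
| focal ω–brain diffusion correlation | 0.8 | a strong, detectable co-evolution signal |
| trait–trait correlations (brain–GI 0.6, brain–body 0.7, GI–body 0.4) | | traits are mutually correlated, which is what makes partial correlations informative |
| tile size / step | 94 / 40 | oligo-synthesis limit and overlap of the tiling design |
| plasmid replicates | 3; detection requires ≥ 2 | the detection filter needs a majority |
| sequencing depth | 10⁶ | typical per-library read budget |
| NB dispersion | 0.05 | moderate overdispersion of barcode counts |
| permutations | 1000 | resolution 0.001 for the empirical p |
| codons per gene (study stage) | 300 | a short single-exon protein; pairwise divergence is rescaled to ≈ 0.3 proposals per codon so counting estimators stay in their informative range |
| proliferation | 5 conditions, rates 0.3–0.7, 200 cells × 10 replicates, 3 batches (log-odds 0, ±0.3) | spans the assay's dynamic range with realistic replication |

The acceptance script runs this study at its defaults; the test suite
additionally runs the calibration studies (1000 null LRTs, 500 × 500
permutation experiments, 1000 familywise-error simulations, 50 replicate
ranking studies) at the sizes stated in the tests themselves.

## Known limitations

- The PIC-based correlation is a stand-in for full Bayesian joint inference
  of rates and traits; it uses leaf states of the simulated rate process
  rather than reconstructing rates from sequences, and carries no
  divergence-time uncertainty.
- The NG86 estimator saturates at high divergence (Jukes–Cantor correction
  diverges as p → 3/4) and inherits a small downward ω bias from mutations
  to stop codons being counted as nonsynonymous sites but never occurring.
- The single-step contrast adjustment is Monte-Carlo, so adjusted p-values
  carry sampling noise of order (p(1−p)/draws)^½; use the Bonferroni
  fallback when determinism matters more than power.
- `brownian_cov` and the pairwise MRCA search are O(n²·depth); adequate for
  tens-to-hundreds of species, not for thousands.
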