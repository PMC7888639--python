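# Methods

This note documents the models, estimators and numerical choices behind
`durumdiv`, and what the synthetic-panel experiments do and do not show.

## The synthetic panel generator

The generator produces diploid biallelic SNP panels with island-model
differentiation, following the Balding–Nichols construction:

* each locus draws an ancestral frequency `p ~ Uniform(lo, hi)` (default
  bounds 0.1–0.9, so the MAF filter does not decimate a simulated panel
  and the post-QC locus count stays predictable);
* each deme k draws its frequency from
  `Beta(p(1−F)/F, (1−p)(1−F)/F)`, which has mean `p` and variance
  `F·p(1−p)` — the divergence parameter F is therefore the expected
  fixation index between demes;
* genotypes are drawn per individual and locus from the deme frequency
  with an inbreeding coefficient `F_IS` (default 0.95): with probability
  `F_IS` the individual's two allele copies are identical by descent (one
  draw, duplicated), otherwise independent. Expected heterozygosity of
  calls is `(1−F_IS)·2pq`, about 2% at the default — the residual level
  typical of a predominantly selfing crop such as durum wheat.
  `F_IS = 0` recovers Hardy–Weinberg `Binomial(2, p)` sampling;
* with `admixture_alpha > 0` each individual receives Dirichlet deme
  weights and each independent allele-copy draw first samples its deme of
  origin from those weights (autozygous copies share one draw);
* missing calls are injected completely at random (default 2%; no
  missingness mechanism is modelled beyond MCAR);
* loci are independent — no linkage disequilibrium is simulated, and none
  of the downstream analyses uses LD.

The inbreeding coefficient matters beyond realism. The AMOVA here (like
the codominant-genotypic convention of the standard software) operates on
squared dosage distances, so its Φ statistic estimates the intraclass
correlation of the *genotype* variable. Under Hardy–Weinberg sampling
that converges to `2F/(1+F)` (≈ 0.32 at F = 0.19), not F; under full
selfing it converges to F exactly, and at `F_IS = 0.95` the asymptote
`4F / (4F + 2(1−F)(1+F_IS))` is within 0.005 of F across the range used
here. Parameter recovery of F by AMOVA is therefore a property of inbred
panels, which is the intended regime of this package. For outbred data
the Φ estimate remains a valid genotypic fixation index; it simply is not
numerically equal to the allele-frequency F of the island model.

Two presets mirror the structure of a real durum panel: `sp_like`
(2 demes of 207 + 78 accessions, F = 0.19) and `etdwl_like` (4 demes of
45/27/47/96, F = 0.24), both defaulting to 1000 loci — scaled down from
the ~12k SNPs of a real array panel purely for run time; none of the
estimators' expectations depend on locus count, only their variances.

All stochastic draws stream from a single `numpy` generator seeded by
`SimConfig.seed`; a config object fully determines its panel.

What passing recovery tests shows: the estimators are unbiased at the
panel sizes and divergence levels of the emulated study, under MCAR
missingness, free of LD, with exactly biallelic, error-free calls. What
they do not show: robustness to genotyping error, ascertainment bias of
array SNPs, LD between markers, or non-random missingness — real-panel
properties the generator deliberately omits.

## QC

Per-locus statistics use non-missing calls only: allele frequency
`p = (2n₂ + n₁) / (2·n_called)`, `MAF = min(p, 1−p)`, heterozygosity
`n₁/n_called`, `PIC = 1 − (p² + q²) − 2p²q²` (the standard biallelic
form, maximum 0.375 at p = 0.5). Filters are conjunctive and strict at
the boundary: a locus is dropped iff MAF < 0.05 *or* missing > 0.10 *or*
het > 0.125, so boundary values survive. The heterozygosity filter is
marker-wise (in a selfing crop an elevated per-marker het rate indicates
a paralogous/mis-clustered assay rather than true outbreeding).
Reason codes report the first failing filter in the fixed order MAF,
missing, het; the kept set is order-independent. Filters are computed
before any imputation.

Imputation is a deliberately naive, seeded `Binomial(2, p̂)` draw at the
locus allele frequency — adequate because every downstream statistic here
depends on allele frequencies only, and swappable where haplotype-aware
imputation is required. Loci without any call cannot be imputed and must
be filtered first.

## Admixture model and sampler

The model is the classic admixture formulation with uncorrelated cluster
frequencies: individual i has ancestry `q_i ~ Dirichlet(α·1_K)`, cluster
k has per-locus alternate-allele frequency `p_kl ~ Beta(λ, λ)`, and every
observed allele copy picks a latent origin `z ~ Categorical(q_i)` and
then its allele from `p_zl`. α is *fixed* (default 1.0) rather than
sampled — this keeps the sampler pure Gibbs (no Metropolis step), at the
cost of one fewer inferred parameter; α is a setting when a different
prior strength is wanted. Missing allele copies contribute nothing to
counts or likelihood.

One sweep: (i) every allele copy's z is redrawn given (Q, P); (ii) each
`q_i` is redrawn from `Dirichlet(α + copy counts)`; (iii) each `p_kl`
from `Beta(λ + alt copies, λ + ref copies)`. Post-burn-in sweeps record
the observed-data log-likelihood and accumulate posterior means of Q and
P. The per-K model score is `LnP(D) ≈ mean(lnL) − var(lnL)/2` — the
standard approximation, not a true marginal likelihood; it is used only
inside the ΔK criterion, which is a heuristic on exactly this quantity.

Numerical implementation: the sweep kernel is `numba`-compiled. The
per-copy categorical draws use an inline xorshift64* generator (the
library Mersenne Twister remains the stream for the conjugate
Dirichlet/Beta updates); reference-copy weights reuse
`q_ik − q_ik·p_kl`, the likelihood uses `s₀ = 1 − s₁` (Q rows sum to 1),
and per-copy log terms accumulate as batched products flushed through a
single `log` every 64 cells (safe against underflow since each factor is
a genotype probability well above 1e-4 in practice). A run is fully
reproducible from its seed.

Replicate handling: per-run seeds are spawned from the experiment seed;
the replicate with the highest score at the chosen K provides Q for hard
assignment (no CLUMPP-style label alignment across replicates — label
switching makes naive Q-averaging meaningless). Hard assignment is the
row argmax with ties to the smallest cluster index; the maximum q is kept
as an admixture-confidence value.

Evanno ΔK: `ΔK(K) = |mean_L(K+1) − 2·mean_L(K) + mean_L(K−1)| / sd_L(K)`
with the sample standard deviation over replicates. ΔK exists only for
interior K with positive sd; zero-sd rows are flagged and excluded from
the argmax; exact ties resolve to the smallest K, and an all-flat profile
is flagged uninformative. ΔK cannot select the boundary K values by
construction — in particular it cannot return K = 1; a panel without
structure manifests as an uninformative/flat profile instead.

Run design defaults mirror common practice (10,000 burn-in / 100,000
sweeps, K = 1..10, 5 replicates); the test scale (500 / 2000, 3
replicates) is used in the recovery experiments, where the posterior is
sharply concentrated because hundreds of informative loci are available.

A caveat that the recovery experiments make quantitative: ΔK detects the
*uppermost* level of structure, and on panels simulated under the flat
island model it is biased toward K = 2. With K_true demes all at the
same divergence F from a common ancestor, every pairwise deme distance
is equal in expectation, so the model-score increments `L(K) − L(K−1)`
decay like the costs of successively cheaper merges and the second
difference is largest at K = 2 whenever the first split removes the most
variance. On the four-deme preset (demes 45/27/47/96 at F = 0.24, 300
informative loci) the converged increments are ≈ 7600 / 3800 / 2800 /
300, giving |L″| ≈ 3700 at K = 2 versus ≈ 2550 at K = 4 — the likelihood
elbow is plainly at 4, but ΔK selects 2, consistently across replicate
experiments, chain lengths (verified against 3× longer chains) and prior
strengths (α = 0.1–1.0). The two-deme preset is immune because its true
K *is* the uppermost level. This mirrors the well-known K = 2 tendency
of the Evanno criterion on real data; recovering a four-subgroup panel
by ΔK requires unequal between-subgroup divergences (hierarchical
structure), which this generator deliberately does not simulate. When
ΔK picks a suspiciously small K, inspect `mean_lnpd` directly — the
full table is always reported alongside the chosen K for exactly this
reason.

## AMOVA, Φ and gene flow

Squared genotype distance per locus is `(g_i − g_j)²` — equivalently half
the squared Euclidean distance between allele-count vectors (identical
genotypes 0, homozygote–heterozygote 1, opposite homozygotes 4) — summed
over loci called in both individuals and rescaled by `L/L_ij` so pairs
with missing data are comparable (average-distance completion; AMOVA can
also be run on an imputed matrix instead).

Two-level decomposition from the distance matrix:
`SS_total = (1/N)·Σ_{i<j} d²`, `SS_within = Σ_pops (1/n_p)·Σ_{i<j∈p} d²`,
`SS_between` by subtraction (additivity is exact by construction);
`σ²_within = MS_within`, `σ²_between = (MS_between − σ²_within)/n₀` with
`n₀ = (N − Σn_p²/N)/(k−1)` for unequal sizes. A negative between
component is truncated to zero for Φ and the percentage partition; the
raw value is always retained in the output for auditability.

The permutation test shuffles individuals freely among populations (the
only exchangeable level in a two-level design) and uses
`p = (1 + #{Φ* ≥ Φ_obs}) / (1 + n_perm)`. The permutation statistic is
the *raw* (untruncated) Φ: truncation would pile permuted values onto an
atom at zero, creating spurious ties with the observed statistic and a
conservatively inflated p (observed empirically as a mean null p of
~0.64 instead of ~0.5). Reported Φ remains the truncated one.

Gene flow uses the island-model relation `Nm = [(1/F_ST) − 1]/4`, always
computed from the unrounded Φ estimate (computing it from a 2-decimal
Φ visibly shifts Nm, e.g. 0.19 → 1.066 vs an unrounded 0.196 → 1.024).

## Distances and trees

Allele-sharing dissimilarity: `d = 1 − shared/(2L_ij)` with per-locus
shared copies `2 − |g_i − g_j|`; pairs with no commonly-called locus are
an error rather than a silent NaN. Nei's standard distance between
populations uses the mean-over-loci identity sums
`D = −ln(J_XY/√(J_X·J_Y))`; disjoint allele sets give +∞ with a warning.

Neighbor joining follows the Saitou–Nei agglomeration with the
rate-corrected criterion `(m−2)d_ij − r_i − r_j`. Ties resolve to the
lexicographically smallest label pair (an internal node carries the
smallest leaf label of its clade), making runs reproducible. Negative
branch lengths are clamped to zero with the deficit moved to the sibling
branch (preserving the pair's path length); clamps are logged. The final
two nodes' connecting edge is split evenly across the (arbitrary,
unrooted) root so path lengths are preserved. On additive inputs the
leaf-to-leaf path lengths of the output reproduce the input exactly
(checked to 1e-9), and the implementation agrees with an independent NJ
implementation on perturbed matrices.

## Diversity indices

Per population, allele frequencies come from that population's
non-missing calls. Per-locus values — Shannon `I = −Σ Pi ln Pi` (zero
frequencies contribute 0), `He = 1 − ΣPi²`, `uHe = [n/(n−1)]·He` — are
averaged over *all* loci retained by QC, including loci monomorphic
within the population (contributing zeros); this is how PPL < 100%
coexists with the averaged indices. The uHe correction uses each locus's
own number of called individuals (missingness varies by locus); the
allele-copies convention `2n/(2n−1)` is available via
`correction="allele_copies"` since reporting software differs on this
point, and the choice is recorded in the pipeline manifest. A locus is
polymorphic for PPL when both alleles are observed at least once in the
population (no frequency threshold).

## Pipeline

`run_pipeline` chains the stages with one seed: the structure stage
defaults to the PIC-selected marker subset (mirroring marker selection
for model-based clustering, where uninformative markers only add noise),
while AMOVA and diversity default to the full filtered panel; both are
configurable. Outputs are TSV/Newick/HapMap text plus a JSON manifest
recording versions, seeds, settings and every design flag in force; the
manifest determines the outputs byte-for-byte (the only manifest field
that may differ between equivalent runs is the output path itself).
If ΔK selects K = 1 the AMOVA stage is skipped with a warning rather
than failing the run.

## Known limitations

* The admixture sampler fixes α and uses uncorrelated frequencies; panels
  whose structure is only detectable under the correlated-frequencies
  prior will look flatter here.
* `LnP(D)` is an approximation; its absolute value should not be compared
  across datasets, only across K within one dataset.
* AMOVA recovery of the island-model F presumes a highly inbred panel
  (see above); Φ on outbred data is a genotypic, not allelic, index.
* The imputer ignores haplotype structure by design.
* No LD, genotyping error, or ascertainment bias is simulated; recovery
  experiments quantify estimator behaviour, not robustness to array
  artefacts.
* Experiment problem sizes (1000-loci AMOVA panels; 250–300 informative
  loci and 500/2000-sweep chains for model selection; 5 replicate seeds)
  were chosen so the full validation suite runs on a single CPU in tens
  of minutes while keeping Monte-Carlo noise well inside the stated
  tolerances.
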