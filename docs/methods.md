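# Methods

## The observation model

A biallelic SNP with reference-allele frequency *p* is observed in each
individual as a pair of read counts (ref, alt) with total depth *k*.
Homozygotes are assumed to be read without error; a true heterozygote at
depth *k* shows *only* reference (equally, only alternate) reads with
probability *K*, and both alleles with probability 1 − 2*K*.  The three
allele-sampling families are

| family | parameter | K(k) | notes |
|---|---|---|---|
| binomial | — | 1/2^k | reads independent and fair |
| beta-binomial | α > 0 | Γ(k+α)Γ(2α) / (Γ(k+2α)Γ(α)) | read fraction q ~ Beta(α, α), then Binomial(k, q); → binomial as α → ∞ |
| modified-p | p′ ∈ [0.5, 1) | ½·p′^(k−1) | Markovian reads: first read fair, later reads repeat the previous allele with probability p′; p′ = 0.5 is binomial |

Every family satisfies K(1) = ½ and K non-increasing in k.  Depth-0 cells
are missing; K is undefined there.  The beta-binomial K is evaluated in
log-gamma space and clipped into (0, ½] against round-off at k = 1 and
underflow at extreme depth; a lookup table to k_max = 500 (closed form
beyond) makes per-SNP evaluation cheap without changing results.

Sequencing error (base miscalls) is deliberately outside the model: an
apparent heterozygote is taken as truly heterozygous, and homozygote calls
can only be wrong in the heterozygote-hidden direction.

## Genotype calls, frequencies, filters

Apparent dosage g counts reference alleles: 2 if only reference reads,
0 if only alternate, 1 if both seen, missing at depth 0.  Allele
frequencies are pooled read-count ratios over the chosen individual group
(combined, or per subpopulation), used consistently everywhere downstream;
the theory treats them as known, and in practice they come from hundreds
of individuals.  Two SNP filters are applied before any parentage
statistic: Hardy-Weinberg disequilibrium d = (observed hom-ref call
fraction) − p², discarding SNPs with d strictly below −0.05 (deep-coverage
SNPs at strongly negative d are collapsed duplicated loci — the "fin
plot" table the pipeline writes shows d against minor allele frequency),
and a minor-allele-frequency bound whose default 0 discards exactly the
monomorphic SNPs.  Whether d should use read-count or call-based p is not
settled; this implementation uses the read-count estimate (a single
frequency definition package-wide), which slightly shifts d at low depth
but not the far-negative tail the filter targets.  Monomorphic SNPs are
excluded from every relatedness/mismatch sum regardless of `maf_min`,
since p ∈ {0, 1} produces degenerate 0/0 terms.

## Relatedness

Pairwise: r̂ᵢⱼ = Σₛ(gᵢₛ−2pₛ)(gⱼₛ−2pₛ) / Σₛ2pₛ(1−pₛ) over SNPs non-missing
in both members — denominators are pair-specific, which keeps the
estimator unbiased under arbitrary missingness.  Because E[g | true
genotype] equals the true dosage for every symmetric read model, the
off-diagonal never involves K and is bit-identical across model families.

Self-relatedness estimates 1+F.  A true heterozygote observed
single-allele at depth k inflates (g−2p)² by 2K, so the diagonal subtracts
2K/(1−2K) at each apparent-heterozygous cell; the per-SNP correction then
has expectation 2K·P(true het) exactly, making the diagonal unbiased under
the chosen read model *without* a Hardy-Weinberg assumption.  Cells with
k = 1 are excluded from the diagonal: there K = ½, the correction is
undefined, and a single read carries no heterozygosity information.

Estimates are relative to the allele-frequency base population: with
diverged subpopulations pooled, within-group relatedness is inflated and
can exceed pedigree ranges.  No base-population rescaling is attempted
(the pipeline instead offers per-subpopulation frequencies); PCA of the
double-centered GRM (scores v·√λ, variance shares λ/Σλ⁺) is provided to
diagnose such structure.

## Mismatch rates and EMM

Raw rates treat apparent genotypes as true.  A pair mismatches only as
opposing homozygotes; a trio mismatches when the apparent triple is
Mendelian-impossible: offspring opposing-homozygous to either parent,
heterozygous offspring with both parents homozygous for the same allele,
or homozygous offspring from apparently opposing-homozygous parents (the
last is implied by the first but kept explicit).  Raw and expected rates
are averaged over exactly the same SNP set — every member with depth ≥ 1
and the SNP polymorphic — because mixing sets would bias their difference.

Expected rates condition on the offspring's apparent class and all
members' depths, assuming a randomly mating non-inbred population at HWE
with known p.  Closed forms in (p, K_o, K_f, K_m) are used for the three
offspring classes, with P(mismatch | apparent het) ≡ 0 for single parents
and the all-alternate class given by the all-reference class under
p → 1−p.  The test suite verifies these forms against exhaustive
enumeration over all true-genotype combinations and observation outcomes
to 1e-12.  The conditioning is on the offspring class only (not
re-weighted by the parents' observed classes), matching the derivation of
the closed forms.

EMM = raw − expected.  For true parentage its expectation is zero at any
depth profile, so it needs no depth filtering; wrong parents push it up.
Negative values are legitimate noise.

## Assignment strategy and codes

Per offspring and sex: rank candidates by relatedness (descending,
deterministic id tie-break; an option ranks by EMM instead); veto the
best candidate on r̂ ≥ `rel_min` (0.4) and pair EMM ≤ `emm_max` (0.01) —
comparisons inclusive, a convention fixed here since thresholds are used
descriptively in the field; when the runner-up is within
`closeness_window` (0.05), require bootstrap support ≥ `bootstrap_min`
(0.99) over `n_boot` (1000) SNP resamples.  Bootstrap replicates keep the
full-data allele frequencies fixed (they come from a large sample;
resampling them would add cost without changing candidate ranking) and
resample SNP indices from one seeded stream, so results are reproducible
given (seed, n_boot); ties count ½.

With both sexes provisionally assigned, the trio is checked jointly: trio
EMM ≤ `trio_emm_max` (0.02 — looser than the pair bound because any of
three genotypes can generate a mismatch) and r_FM − 2F_O ≤
`inbreeding_diff_max` (0.2).  For a true trio the offspring's inbreeding
is half the parents' relatedness, so a large positive excess flags the
typical error — a relative of one true parent standing in for the other;
only the upper bound is enforced.  On failure, pairings of the top
`n_alternates` (2) candidates per sex that pass the pair-level checks are
evaluated and the lowest-trio-EMM pairing that passes everything is
assigned.  All pair-level checks are re-required for alternates.

Codes: `Y` best pair passed everything; `A` an alternate pairing was
assigned; `E`/`I` both sexes passed singly but every pairing failed the
trio checks (`E` trio EMM, `I` inbreeding-consistency only); `F`/`M` only
the sire/dam survived; `N` neither.  An individual cannot be assigned as
both parents, and self-comparisons are skipped.  Codes are a pure
function of the recorded metrics and the thresholds snapshot written into
every report row.  Thresholds are never inferred automatically; the
pipeline emits binned metric distributions for tuning by inspection.
EMM is computed only for the leading candidates per sex — relatedness,
which is much cheaper, ranks the full set first.

## Overdispersion fitting

Real GBS data often shows clustered allele recruitment (PCR artifacts),
inflating raw rates above binomial expectations even for true trios.  The
extra parameter (α or p′) is fitted on trios accepted under the binomial
model — the conservative choice, since binomial expectations are lowest —
by minimizing Σ(raw − expected(θ))² with bounded scalar (Brent-style)
search, tolerance 1e-6: α on a log₁₀ scale over [0.1, 1e6], p′ over
[0.5, 0.999].  The brackets span strong overdispersion to the binomial
limit.  Per-trio (class, depth, p) records are cached once so each
candidate θ only re-evaluates K.  An optimum at a bracket edge warns; on
truly binomial data the optimum drifts to a large finite α whose K is
numerically binomial.  `compare_families` fits both families and
recommends the lower objective, flagging low confidence below two trios.

## The simulator

`simulate` draws founder genotypes at HWE from frequencies uniform on
[0.05, 0.95] (optionally with founder inbreeding via IBD allele copying,
and Balding-Nichols drift per subpopulation with an F_ST-like parameter),
mates uniformly random sires and dams, and generates reads per cell with
Poisson depth and the chosen allele-sampling family.  The modified-p
generator simulates the Markov chain read by read — an implementation
independent of the closed-form K, so the empirical single-allele fraction
cross-checks the analytic model.  Defaults describe the study conditions
used throughout the tests: 20 sires, 200 dams, 300 offspring, 3,000
independent SNPs, mean depth 2 (a deliberately hard, low-depth panel);
the model-consistency and dispersion analyses use 10,000 SNPs at mean
depth 3 with 30–50 trios whose parents are drawn from pools large enough
that trios rarely share a parent.  Same seed, byte-identical output.

What the simulator does not emulate: linkage disequilibrium between SNPs,
sequencing error, depth-genotype correlation, and sample contamination.
Passing tests therefore demonstrate correctness of the statistics under
the stated model, not robustness to those real-data artifacts; on real
data the Hardy-Weinberg filter (duplicated loci) and the overdispersion
families (clustered reads) absorb the two that matter most in practice.

## Numerical and edge-case choices

Pairs with no shared usable SNPs get an undefined relatedness and are
dropped from ranking; offspring with no usable candidates get code `N`
with the reason recorded.  An undefined offspring inbreeding (no depth ≥ 2
cells) skips the inbreeding check with a warning rather than failing the
trio.  Allele frequencies at exactly 0 or 1 are rejected by the expected-
mismatch formulas by design — such SNPs must be filtered first.  The
assignment batch never aborts on a single offspring's failure.

## Known limitations

Relatedness and EMM both assume the allele frequencies of an appropriate
base population; with strongly structured populations, run per
subpopulation.  The diagonal correction assumes the chosen read model —
a misspecified model biases 1+F̂ (though never the off-diagonal).
Dispersion estimates degrade below ~10 accepted trios.  Likelihood-based
relationship classification and sibship reconstruction are out of scope.
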