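# Methods

## Model

`famlr` evaluates evidence for a pairwise genetic relationship from
genotypes at unlinked autosomal loci. A non-inbred pair's relationship is
summarised by the IBD-sharing coefficients `(k0, k1, k2)` — the
probabilities of sharing 0, 1 or 2 alleles identical by descent at a locus:

| relationship     | k0    | k1   | k2  | kinship ψ |
|------------------|-------|------|-----|-----------|
| parent–offspring | 0     | 1    | 0   | 1/4       |
| sibling          | 1/4   | 1/2  | 1/4 | 1/4       |
| half-sibling     | 1/2   | 1/2  | 0   | 1/8       |
| first cousin     | 3/4   | 1/4  | 0   | 1/16      |
| second cousin    | 15/16 | 1/16 | 0   | 1/64      |
| unrelated        | 1     | 0    | 0   | 0         |

Background relatedness within a population is modelled with the coancestry
coefficient θ through the sequential Dirichlet ("urn") construction: the
i-th founder allele drawn from the population is allele `A` with probability
`(m_A θ + (1 − θ) p_A) / (1 + (m − 1) θ)`, where `m_A` counts prior founder
draws of `A` among `m` total. The joint probability of an unordered
genotype pair mixes over the latent IBD state `j ~ (k0, k1, k2)`: `4 − j`
founder alleles are drawn sequentially and the `j` shared alleles are copied
to both individuals; the pair probability sums urn-sequence probabilities
over every ordered draw sequence and IBD-allele assignment consistent with
the observed pair. This is the canonical θ-corrected genotype-pair model of
forensic genetics; at θ = 0 it reduces to Hardy–Weinberg/Mendelian algebra
(e.g. the paternity index `1/(4p_a)` for an `(ab, ac)` parent–offspring
pair). An exhaustive-enumeration oracle in the test suite verifies
normalization over the full pair-state space and agreement with classical
closed forms.

The likelihood ratio for a relationship versus unrelated multiplies across
loci; all inference happens on `ln LR`.

## Confidence intervals on ln LR

Observed allele frequencies are estimates subject to sampling variance and
to evolutionary variance across populations. Both are captured by one
covariance model, `Cov(p̂ᵢ, p̂ⱼ) = c (pᵢ δᵢⱼ − pᵢ pⱼ)` with
`c = θ_CI + (1 − θ_CI)/(2n)` (Dirichlet drift plus binomial sampling for a
diploid sample of `n` individuals). The variance of `ln LR` follows by the
delta method per locus: the gradient of each locus's `ln LR` with respect to
its frequency vector is taken by component-wise central differences (step
1e-6, no simplex renormalisation — the covariance annihilates the all-ones
direction, so off-simplex gradient components are harmless), and contracted
with the covariance. Only the ≤ 4 alleles observed in the pair carry
non-zero gradient. Since 13+ unlinked loci contribute additively, `ln LR`
is treated as normal:

```
lcl, ucl = ln LR ∓ z_{1−α/2} √Var,  default α = 0.05.
```

Bootstrapping over genotypes is deliberately absent: the uncertainty lives
in the frequency estimates, not in resampled genotypes. A Monte-Carlo
sampler of the Dirichlet+multinomial frequency model exists only as a test
oracle; the delta-method variance agrees with it within 15% at the tested
conditions (sibling pairs, 13 ten-allele loci, θ_CI = 0.01, n = 200).

Known limitation: `ln LR` evaluated at estimated frequencies is biased
upward (Jensen; ≈ 0.6 at the conditions above) because the locus LR is
convex in the frequencies of shared alleles. The symmetric interval does
not correct for this, so empirical coverage of the true-frequency `ln LR` is
≈ 92% for related-truth pairs and ≈ 96% for unrelated-truth pairs at
nominal 95% (≈ 94% over the equal mixture the pipeline actually scores).
This is a property of the plug-in method itself, shared by standard forensic
practice, and is why the lower confidence limit (LCL) — not the point
estimate — is used as the conservative identification statistic.

Zero-probability numerators (e.g. a parent–offspring hypothesis with no
shared allele at a locus) make `ln LR = −∞`; this propagates as an explicit
degenerate state, never as a large negative float, and such pairs are
excluded from distribution moments but counted as non-detections.

## Parameters and defaults

- `theta_assumed` (default 0.01): θ in the genotype-pair probabilities.
  A SWGDAM-style conservative correction; 0.01–0.03 are the values used in
  casework depending on population. Changing it rescales LRs but not the
  comparative trends.
- `theta_ci` (default 0.01, conventionally equal to `theta_assumed`): θ in
  the frequency-covariance model. The parameter sweep ties `theta_ci` to
  each `theta_assumed` value, since "the assumed coancestry" means one θ
  used throughout a calculation.
- `n`: diploid sample size behind each population's frequencies; enters
  only through `c`.
- frequency floor (default `1/(2n+1)`): cross-population scoring routinely
  meets alleles unseen in the assumed sample; observed alleles are floored
  and the vector renormalised, and flooring events are counted on the
  calculator. The floor must stay below `1/#alleles`.
- `alpha` (default 0.05, two-sided; one-sided mode available).

## Simulators

Two samplers generate genotype pairs, matching the two study regimes:

- θ_true = 0: founder genotypes drawn i.i.d. from the panel and dropped
  through the standard non-inbred pedigrees (sibling; half-siblings sharing
  one parent; first cousins via sibling parents; second cousins via
  first-cousin parents; spouses are founders). Lineage tags record the
  realised IBD state per locus for diagnostics only.
- θ_true > 0: per locus, draw the IBD state from `(k0, k1, k2)` and the
  `4 − j` founder alleles sequentially with the urn rule. At θ = 0 the two
  samplers are distributionally identical (χ²-tested); empirical pair-state
  frequencies match the enumerated probabilities.

Reproducibility: one seed per simulation config; per-pair substreams are
spawned deterministically (numpy `SeedSequence`), so pair *i* is identical
regardless of how many pairs are requested and parallel execution would
reproduce serial output.

## Synthetic panels

The generator emulates published forensic frequency tables. Equi-frequent
panels provide the two marker archetypes (ten-allele STR-like, two-allele
SNP-like). Structured panels derive populations from a common base by
drawing locus frequencies from `Dirichlet(p_base (1 − F)/F)` — the same
parameterisation as the CI covariance, keeping one population model across
modules. Expected derived frequencies equal the base; per-allele variance
is `F p (1 − p)`; Weir–Cockerham FST between two independently derived
populations averages ≈ F (≈ F/2 against the undrifted base, since only one
side drifts).

The built-in fixture (`codis_like_fixture`) is a deterministic
five-population, 13-locus, ten-allele panel: four populations diverge from a
moderately even base at F ∈ {0, 0.015, 0.02, 0.04}, and a fifth,
low-diversity population (concentrated base, H̄ ≈ 0.69 vs 0.86–0.89) sits at
F = 0.07. Making the low-diversity population also the most diverged
mirrors the structure of real CODIS panels, where the same sample plays both
roles. Realised pairwise FST spans ≈ 0.004–0.14.

What the synthetic panels do *not* emulate: real STR allele ladders and
mutation structure, within-population substructure or admixture, genotyping
error, and linkage. Passing trends on these panels therefore demonstrate
properties of the statistics under the model's own assumptions — clean
random mating at θ_true, exact panel frequencies — not performance on any
actual population.

## Distinguishability and decision curves

For one cell (relationship × true population × assumed population), the LCL
samples of related and unrelated pairs are compared by
`D = (m_R − m_U)²/(s²_R + s²_U)` (unbiased sample variances; analogous to a
non-centrality parameter). D needs ≥ 2 finite values per sample — for
parent–offspring hypotheses on unrelated pairs nearly every LCL is −∞, so D
is flagged not-estimable rather than computed. Power and false-positive
rate at threshold `t` count LCLs strictly above `t` (ties conservatively
non-detections; −∞ below every threshold); the default grid is 101 even
points over the pooled finite LCL range plus a −∞ sentinel.

## Numerical and design choices

- Ratio-of-sums combination for multi-locus, multi-allele FST (standard
  Weir–Cockerham practice); within-population heterozygosity at its
  Hardy–Weinberg expectation `2p(1−p)` because only frequency tables, not
  genotype counts, are available. Negative estimates are reported as 0 in
  tables; the raw value is retained. A shared monomorphic locus makes the
  denominator 0 → explicit not-estimable flag.
- Gene diversity is the plug-in `1 − Σ p̂²` without small-sample correction;
  published two-decimal values cannot discriminate the variants.
- Load-time renormalisation tolerates published rounding up to 0.01 in the
  per-locus frequency sum; larger deviations are validation errors.
- Per-(locus, genotype-pair) caching in the profile calculator: a grid run
  costs one enumeration per *distinct* pair per assumed population, not per
  replicate.
- Grid and sweep sizes: the full study design is 10,000 pairs per cell; the
  shipped acceptance script uses 1,000 (grid) and 2,000 (sweeps) per cell,
  and the test suite 400–2,000, sizes at which every tested trend is stable
  across seeds.

## Known limitations

Inbred relationships, linked loci, mutation/genotyping error, mixtures and
low-template profiles are out of scope. The population model is a small set
of discrete homogeneous groups — the same coarse model used in forensic
practice, and the reason the misspecification analysis exists. D's absolute
scale depends on the CI parameters through the LCL; comparative statements
(across populations, marker counts, relationships, θ) are the robust output.
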