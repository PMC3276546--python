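# famlr

Kinship likelihood ratios for familial identification, with coancestry
correction and confidence intervals — and the simulation machinery to ask
how well the statistic actually separates relatives from unrelated
individuals across structured populations.

Familial searching infers that a crime-scene profile belongs to a *relative*
of a database entrant from a partial profile match. The strength of evidence
for a relationship is a likelihood ratio over unlinked autosomal loci

```
LR = P(G | related, θ) / P(G | unrelated, θ) = Π_l LR_l,
```

where `G` is the observed genotype pair, the relationship enters through the
IBD-sharing probabilities `(k0, k1, k2)` (e.g. siblings `(¼, ½, ¼)`, first
cousins `(¾, ¼, 0)`), and the coancestry coefficient θ corrects genotype
probabilities for background relatedness via the sequential Dirichlet ("urn")
rule. Because the allele frequencies behind the LR are estimates, `famlr`
puts a delta-method confidence interval on `ln LR` under a Dirichlet model of
frequency uncertainty, `Cov(p̂ᵢ, p̂ⱼ) = c (pᵢδᵢⱼ − pᵢpⱼ)` with
`c = θ_CI + (1 − θ_CI)/(2n)`; the lower 95% confidence limit (LCL) is the
conservative identification statistic. Given simulated relative and
unrelated pairs, the separation of their LCL distributions is summarised by
the distinguishability

```
D = (m_R − m_U)² / (s²_R + s²_U),
```

together with empirical power and false-positive-rate curves over LCL
decision thresholds. Pairwise population differentiation is measured with
the Weir–Cockerham (1984) FST estimator, and panel informativeness with gene
diversity `h = 1 − Σ pᵢ²` and profile entropy.

The library targets forensic statisticians and population geneticists who
want to evaluate familial-searching behaviour on their own frequency panels
— in particular how distinguishability degrades for low-diversity
populations and when the wrong population's frequencies are assumed.

## Worked example

Frequency panels are long-format CSV/TSV
(`population,locus,allele,frequency,sample_size`), loaded with
`famlr.read_panel`; a deterministic five-population synthetic panel (13
ten-allele loci, divergences bracketing typical forensic FST values, one
low-diversity population, `POP5`) ships as `famlr.codis_like_fixture()`.

```python
from famlr import codis_like_fixture, run_population_grid

panel = codis_like_fixture()
grid = run_population_grid(panel, relationship="sibling", reps=500, seed=42)
print(grid.d_matrix.round(2))
```

prints (rows: assumed population, columns: true population):

```
       POP1   POP2   POP3  POP4  POP5
POP1  10.07   9.86  10.27  8.36  5.22
POP2   9.87  10.06   9.96  8.24  4.98
POP3   9.80   9.51  10.45  7.67  5.02
POP4   9.12   8.60   9.35  9.01  4.32
POP5   7.44   6.72   7.64  6.67  6.30
```

Each cell is the distinguishability D between the sibling and unrelated LCL
distributions when pairs are simulated from the column population and scored
with the row population's frequencies. Two features matter: the
low-diversity population's own diagonal value (6.30) is the smallest on the
diagonal — its loci carry less identifying information — and its column
degrades further (mean 4.88) when any other population's frequencies are
assumed. The `examples/` directory walks through the other capabilities one
at a time: panel summaries and FST (`01`), a single LR with its confidence
interval (`02`), simulated allele sharing by relationship (`03`), this grid
(`04`), and the marker-count sweep (`05`); each prints the numbers it
computes and a line on how to read them.

A thin CLI mirrors the pipeline: `famlr grid`, `famlr sweep`,
`famlr panel-stats`, `famlr make-panel` (`famlr --help` for options).

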