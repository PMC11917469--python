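# crossuse

Is picking crosses by their **usefulness** worth it, compared with picking
them by their predicted mean?

In a breeding program that can make large families (strawberry and other
clonally propagated crops are the motivating case), the best cross is the one
whose *best* offspring are best — not the one with the best average
offspring. The usefulness criterion scores a cross j as

    UC_j = mu_j + i * sigma_j

where `mu_j` and `sigma_j` are the mean and standard deviation of offspring
breeding values and `i` is the within-family selection intensity
(`i = phi(Phi^-1(1-p))/p` for a selected fraction `p`; `i(0.20) = 1.40`,
`i(0.01) = 2.67`). Predicting `mu_j` is easy; predicting `sigma_j` for
outbred parents requires phased haplotypes, a meiosis model, and estimated
marker effects — and whether that machinery ever changes which crosses you
make is an empirical question.

`crossuse` is a simulation framework for answering it, end to end, on
synthetic populations:

- **synthetic populations** — diploid outbred panels with distance-decaying
  LD from shared ancestry, parent-offspring trios, an optional genotyping
  error floor; VCF / genetic-map TSV / pedigree TSV I/O;
- **meiosis** — count-location model (Poisson crossover counts, uniform
  positions; Haldane map function emerges), gametes, full-sib families, and
  haplotype switch-error injection;
- **phasing QC** — trio-based genotyping-error estimation and two-locus
  parent-offspring inconsistency curves, binned by cM distance, compared
  against curves simulated under known switch-error rates;
- **genomic prediction** — RR-BLUP (kernel REML) and BayesC (spike-and-slab
  Gibbs), trained with the causal markers excluded;
- **cross prediction** — family mean/SD from simulated offspring, or from
  the *gamete-sum* shortcut (`mu_jl = mu_j + mu_l`,
  `sigma^2_jl = sigma^2_j + sigma^2_l`) that makes all n(n-1)/2 crosses
  affordable; the t ratio `var(sigma)/var(mu)` and its independent-loci
  bound `1/(4L)`; the parental-heterozygosity proxy for family SD;
- **selection** — greedy non-overlapping cross selection on mean or UC,
  one-stage vs two-stage (elite-restricted) designs, expected genetic gain
  in units of the additive SD;
- **experiment** — a driver that sweeps heritability x QTL-count grids with
  replicates and writes tidy per-report CSVs.

## Worked example

`examples/` contains one narrative script per capability. For instance,
`python examples/05_cross_prediction.py` builds a 200-parent panel, a
64-QTL additive trait, and prints:

```
200 parents -> 19900 candidate crosses (gamete-sum, one gamete set per parent)
gamete-sum vs offspring simulation over 60 crosses: cor(mu) = 0.9932, cor(sd) = 0.954
t = var(sigma)/var(mu) = 0.0299 (independent-loci bound 1/(4x64) = 0.0039)
small t: family means dominate usefulness rankings
parental heterozygosity vs true family SD: r = 0.101 (a marker-only proxy needing no phenotypes)
```

The first line is the point of the gamete-sum method: family means computed
two independent ways agree to r > 0.99, so one simulated gamete set per
parent stands in for simulating every family. The t line is the reason
usefulness is rarely useful: with 64 QTL the spread of family SDs is tiny
relative to the spread of family means, so `mu + i*sigma` and `mu` rank
crosses almost identically. `python examples/06_selection_strategies.py`
closes the loop, comparing expected genetic gain across the four selection
strategies (one-/two-stage x mean/usefulness).

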