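# nichefit

Maximum-likelihood niche models for binary food webs.

A binary food web over `S` species is an `S×S` connection matrix `A` in
which `A[i, j] = 1` means consumer `i` eats resource `j`.  The classic
niche model explains such webs by placing every species at a position
`n` on a one-dimensional trophic axis and giving each consumer a diet
interval of width `r` centred at `c`.  That model is generative only: it
cannot be confronted with an observed web species by species.

`nichefit` implements the *probabilistic* niche model (PNM), which makes
the link rule stochastic so that standard likelihood machinery applies.
The probability that consumer `i` eats resource `j` is a Gaussian in
niche distance,

```
P_ij = a · exp( −((n_j − c_i) / (r_i / 2))² ),        a = 0.9999
```

and the fit maximizes the Bernoulli log-likelihood over all `S²` matrix
entries,

```
lnL(θ | A) = Σ_ij [ A_ij ln P_ij + (1 − A_ij) ln(1 − P_ij) ],
```

by simulated annealing.  Producers (no prey) have `c = 0, r → 0` pinned;
single-prey specialists have `r → 0` pinned with `c` free.  Around the
full 3S-parameter model the package provides the model family usually
compared by AIC = 2k − 2·lnL:

| name           | coupling                         | k      |
|----------------|----------------------------------|--------|
| `pnm`          | n, c, r all free                 | 3S     |
| `anm`          | n fixed at normalized log body mass (allometric niche model) | 2S |
| `r_of_c`       | r = r0·exp(r1·c)                 | 2S + 2 |
| `r_of_n`       | r = r0 + r1·n                    | 2S + 2 |
| `c_of_n`       | c = c0 + c1·n                    | 2S + 2 |
| `c_and_r_of_n` | c and r both linear in n         | S + 4  |
| `random`       | one uniform link probability, closed form | 1 |

Post-fit tooling computes expected-prediction goodness of fit (the
fraction of observed links and of all matrix entries predicted
correctly, per species and overall), Kolmogorov–Smirnov tests of the
classic niche-model distributional assumptions (`n` uniform, `r`
exponential, `c′ = c/n` uniform below 1), Spearman correlations of
parameters with body mass under Benjamini–Hochberg FDR control, and a
PCA of the standardized parameter triples.  A synthetic generator
produces classic niche-model webs, Bernoulli realizations of any PNM
parameter set, and allometrically consistent body masses, so the whole
pipeline can be exercised end to end with known ground truth.

It is intended for ecologists studying food-web topology who want to go
beyond forward simulation and estimate niche-model traits for each
species in an observed web.

## Worked example

Simulate a 20-species niche-model web, compare the random baseline with
the full probabilistic model, and diagnose the fitted parameters:

```sh
nichefit simulate --S 20 --C 0.22 --seed 4 --masses --out sim
# niche web: S=20 L=107 C=0.268

nichefit compare --web sim/web.csv --models random,pnm \
    --stages 80 --restarts 5 --seed 1 --out cmp
#  model  params         lnL        AIC   links  entries
# random       1 -232.302559 466.605118 0.26750 0.608113
#    pnm      60  -32.982100 185.964199 0.86775 0.938620
```

The random model, constrained only to match the web's connectance,
predicts 27% of the links correctly; the fitted niche model predicts
87% of the links and 94% of all matrix entries, and wins decisively on
AIC (186 vs 467) despite its 60 parameters.

```sh
nichefit fit --web sim/web.csv --model pnm --stages 80 --restarts 5 \
    --seed 1 --out fit
nichefit diagnose --params fit/params.csv --masses sim/masses.csv --out diag
# n-uniform p=0.002; r-exponential beta=0.306 p=0.002; c'-uniform p=0.322 (1 excluded)
```

`diag/correlations.csv` then holds the Spearman table; on this web the
fitted niche position correlates strongly with (simulated) body mass
(ρ = 0.88, significant after FDR control), as expected when masses are
generated allometrically from the niche axis.

The same operations are available as library functions
(`nichefit.fit`, `nichefit.gof_report`, `nichefit.correlation_table`,
…) on `FoodWeb`/`ParamSet` objects.

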