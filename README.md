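# hwturnover

Protein turnover rate constants and half-lives from heavy-water (²H₂O)
metabolic labelling, for proteomics studies that track the decay of the
unlabelled monoisotopic peak (M0) of identified peptides over a labelling
time course — for example comparing turnover between the collagen-rich
fascicular matrix (FM) and glycoprotein-rich interfascicular matrix (IFM)
of tendon.

## The model

When an animal drinks heavy water, body-water deuterium enrichment rises
with first-order kinetics to a plateau,

```
p(t) = pss · (1 − e^(−kp·t))
```

(fitted from serum GC-MS measurements). Newly synthesised protein
incorporates ²H at `N` exchange-accessible sites per peptide, so the
relative abundance of the peptide's monoisotopic isotopomer decays from its
natural value `a` (a function of elemental composition) toward the
fully-labelled plateau `a·(1 − pss)^N`. With first-order turnover at rate
`k`, the non-steady-state solution is

```
A0(t) = a · [ e^(−k·t) + k · ∫₀ᵗ e^(−k·(t−s)) · (1 − p(s))^N ds ]
```

which accounts for the initial delay in deuterium uptake. `k` is fitted per
peptide by nonlinear least squares (closed-form binomial expansion of the
integral for integer `N`, Gauss–Legendre quadrature otherwise). Peptides
are accepted if observed at ≥ 4 distinct time points and the fit has
R² ≥ 0.8 or a standard error of estimate ≤ 0.05. Protein turnover is the
median (± median absolute deviation) of its accepted peptides' `k`, with
half-life `ln 2 / k`. FM-vs-IFM differences are tested with paired t,
Wilcoxon matched-pairs, or Mann–Whitney tests, selected by
Kolmogorov–Smirnov normality checks and pairing.

A seeded synthetic-data generator produces complete two-phase studies
(serum curves, peptide M0 series or full M0–M5 envelopes, ground-truth k)
so every stage is testable without raw LC-MS data.

## Worked example

```bash
hwturnover simulate --out-dir demo --seed 20200512 \
    --n-proteins 8 --peptides-per-protein 4 --n-shared-peptides 12
hwturnover run --peptides demo/peptides.csv --serum demo/serum.csv \
    --out-dir demo/results
```

prints

```
precursor: kp = 0.7582, pss = 0.0562
peptides fitted: 44 (accepted: 44)
proteins summarised: 14
phase comparison (Wilcoxon matched pairs, n=12): median k FM = 0.0011, IFM = 0.0025, p = 0.000488
```

The serum fit recovers the body-water enrichment kinetics (rate ≈ 0.76/day
toward a ≈ 5.6% plateau); 44 peptide M0 time series pass the acceptance
filter and are condensed into per-protein medians
(`demo/results/protein_turnover.csv`, e.g. `PROT001,FM` has median
k = 0.039/day, half-life 17.7 days, versus 0.066/day and 10.5 days in the
IFM); the paired comparison on the 12 peptides shared between phases
detects the faster IFM turnover (p < 0.001).

The same stages are available as library functions (`fit_precursor`,
`fit_k_nss`, `aggregate_protein`, `compare_phases`, `simulate_study`, …)
and as the subcommands `simulate`, `fit-precursor`, `fit-turnover`,
`aggregate`, `compare` and `run`.

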