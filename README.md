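# microdose

Microdosimetry-guided analysis of cell-population dose distributions and
single-cell differential-gene screening.

## The problem

At low absorbed doses (≲ 100 mGy) the energy a photon field deposits in
individual cell nuclei is strongly stochastic: two cells in the same dish
receive very different *specific energies* z = ε/m even though the
macroscopic dose D is a single number. The population distribution f(z, D)
carries this heterogeneity, and its statistical width shrinks as the
cumulative dose grows — each cell averages over more independent events.
The same signature (a per-cell quantity whose distribution is roughly
normal and whose dispersion decreases with dose) can be looked for in
single-cell RNA-seq data, and used as an additional, physics-motivated
filter when screening for radiation-responsive genes.

`microdose` implements both halves for researchers in radiation biology and
biodosimetry:

1. **Specific-energy distributions.** Given a single-event spectrum f₁(z)
   (from a Monte-Carlo transport code, or the package's own synthetic
   sampler), predict the multi-event spectrum at cumulative dose D = v·D₁ as
   the v-fold convolution f_v(z) = f₁ ∗ f₁ ∗ … ∗ f₁, and characterize any
   f(z, D) by its dispersion σ/z̄ and by the RMSE between the binned
   distribution and a normal distribution with the same mean and standard
   deviation:

   RMSE = √( Σᵢ (f_ref,i − f_i)² / N ).

2. **Gene screening.** For each gene, divide every cell's count by the
   gene's mean count in the unirradiated control ("expression difference"),
   then select genes that (a) pass a conventional fold-change/p-value filter
   (FC ≥ 1.2 two-sided, Welch p < 0.05 — the *statistic merge*), (b) show
   expression-difference dispersion strictly decreasing from 10 mGy to
   100 mGy (the *microdosimetric merge*), and (c) rank best (smallest) on
   RMSE-to-normal. The top-ranked genes are the *multi-filtered* set.

A synthetic-data module generates both inputs with known ground truth:
per-cell doses (v events per cell, lognormal cell-mass variation — mass
heterogeneity sets a dispersion floor that event averaging cannot remove)
and negative-binomial count matrices (~23,517 genes × ~10,000 cells per
group at 0/10/100/1000 mGy by default) with planted gene classes.

## Worked example

```bash
microdose run-all --config demo/config.yaml --out demo/run
cat demo/run/dose_summary.tsv
```

with a demo configuration (seed 11; 20,000 cells, 3 replicate runs, gamma
single-event spectrum with D₁ = 5 mGy; 2,000 genes × 300 cells per group)
prints:

```
v    macroscopic_dose_mGy  mean_mGy      std_mGy      dispersion_percent  rmse_to_normal
1    5                     6.009635282   4.273601597  71.11249512         0.007657721767
4    20                    24.00009003   8.45350593   35.22280925         0.001648917747
20   100                   120.1275023   18.92171701  15.75136139         0.0003487057022
100  500                   600.2176476   42.45164421  7.072708437         0.0001148581134
```

Read: the mean nucleus specific energy is 1.2× the macroscopic dose (the
nucleus-to-medium dose ratio of the simulator); the dispersion falls from
71% at 5 mGy to 7.1% at 500 mGy, close to the 1/√v law (71.1%/√100 = 7.1%);
and every distribution is close to its matched normal (RMSE ≤ 0.008),
increasingly so at higher dose. The same run writes 10x-style matrices and
the screen report: of 2,000 simulated genes, 241 pass the statistic merge,
1,077 the microdosimetric merge, 169 qualify as candidates and the 50
best-ranked by RMSE-to-normal are selected (`screen/screen_summary.json`).

Single steps are available as `microdose spectrum | convolve | compare |
simulate-dose | simulate-sc | scdiff | screen`; for example

```bash
microdose spectrum --samples demo/run/cell_doses_5mGy.csv --bin-width 0.5 --out f1.csv
microdose convolve --f1 f1.csv --dose 500 --d1 5 --rebin 100 --out f100.csv
# -> v=100 mean=600.961 mGy std=44.3622 mGy dispersion=7.382%
```

The same operations are importable from Python (`microdose.build_distribution`,
`convolve`, `summarize`, `rmse`, `run_screen_from_groups`, …).

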