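# relic

Dye-bias correction for Illumina two-color DNA methylation BeadChips
(HumanMethylation450 / MethylationEPIC), built around **regression on
logarithms of internal control probes**, together with the standard
comparator corrections and a benchmarking protocol on synthetic
dilution-series data with known truth.

## The problem

Infinium arrays read CpG methylation in two dye channels (Cy3 green, Cy5
red). The channels perform differently — green intensities are typically
compressed relative to red — which biases the methylation estimate
(beta value)

```
beta = M / (M + U + c),      c = 100 by default
```

directly, because Type II probes measure the methylated allele in green
and the unmethylated allele in red. Each array carries paired
normalization control probes (NORM_A/NORM_T read in red, NORM_G/NORM_C in
green; 93 pairs on 450K, 85 on EPIC) targeting the same CpG-free regions,
so absent dye bias each pair's red/green ratio would be ~1.

The log intensities of the two channels are linearly related across the
control pairs, and the red/green ratio grows with intensity — the bias is
*not* a constant factor. The correction therefore fits, per sample, an
ordinary least-squares regression of `log(red)` on `log(green)` over the
control pairs and maps **every** green-channel intensity through

```
I_adj = exp(b1 * log(I) + b0)
```

leaving red intensities untouched. The map is strictly increasing and
positive, and its implied correction factor varies with intensity —
unlike the scaling family (GenomeStudio-style, methylumi-style, ASMN,
simple scaling), which applies one constant per channel per sample and so
under-adjusts large and over-adjusts small intensities when the bias is
intensity-dependent.

Also included: between-channel quantile normalization over all probes
jointly, beta-value computation with KDE distribution-mode estimation, a
synthetic dilution-series generator (known methylation levels, log-linear
dye bias, lognormal noise), and an evaluation module (absolute mode
deviations, per-level summaries, one-sided paired t-tests). The smooth
quantile variant of the lumi package is not implemented, so evaluation
tables compare five correction methods plus raw data.

## Worked example

```python
from relic import (SimulationConfig, simulate_dataset, relic_correct,
                   control_ratio_diagnostic, density_mode)

config = SimulationConfig(n_probes_typeII=3000, n_probes_typeI_red=800,
                          n_probes_typeI_grn=400,
                          methylation_levels=(0.2, 0.8), replicates=(1, 1),
                          seed=11)
data, controls, truth = simulate_dataset(config)
result = relic_correct(data, controls)
for fit in result.fits:
    print(fit.sample_id, round(fit.beta0, 3), round(fit.beta1, 3))
raw = density_mode(control_ratio_diagnostic(controls).to_numpy().ravel())
adj = density_mode(control_ratio_diagnostic(controls, result.fits).to_numpy().ravel())
print(round(raw, 2), "->", round(adj, 2))
```

prints

```
m020_r01 -0.111 1.241
m080_r01 -0.191 1.252
4.04 -> 0.97
```

Each sample gets its own fitted intercept/slope (the slope sits slightly
below the simulated 1.3 because measurement noise on the predictor
attenuates OLS), and the mode of the control-pair red/green ratio density
moves from ~4 before correction to ~1 after — the signature of a
corrected array. The scripts in `examples/` walk through correction,
beta-mode estimation of dilution samples, and the full method benchmark;
on the default benchmark the regression correction reaches a mean
absolute mode deviation of ~0.017 versus ~0.13 for uncorrected data and
~0.03 for constant-ratio scaling, with one-sided paired t-test p-values
between 1e-14 and 4e-3.

A thin CLI mirrors the library:

```
relic simulate --out-dir sim --seed 5
relic correct --method relic --meth sim/meth.tsv --unmeth sim/unmeth.tsv \
              --manifest sim/manifest.csv --controls sim/controls.tsv \
              --out-prefix sim/relic
relic beta --meth sim/relic_meth.tsv --unmeth sim/relic_unmeth.tsv \
           --manifest sim/manifest.csv --out sim/betas.tsv
relic mode --betas sim/betas.tsv --out sim/modes.tsv
relic benchmark --seed 9 --methods raw,relic,illumina,ssn --out report/
```

Binary IDAT files are out of scope: decode them first (e.g. with
methylprep in Python or illuminaio in R) and feed the resulting
intensity/control tables in the documented TSV/CSV formats.

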