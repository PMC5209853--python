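"""Estimate methylation levels of dilution-series samples via beta modes.

Simulates laboratory standard-control samples at known methylation
fractions, corrects the dye bias, computes beta values, and compares each
sample's beta-distribution mode against its expected level — the accuracy
metric for standard-control data, where beta distributions are skewed and
the mode is a better level estimate than the mean.
"""

from relic import (
    SimulationConfig,
    abs_mode_deviation,
    compute_beta,
    relic_correct,
    sample_modes,
    simulate_dilution_series,
)

config = SimulationConfig(
    n_probes_typeII=3000, n_probes_typeI_red=800, n_probes_typeI_grn=400, seed=23
)
data, controls, truth = simulate_dilution_series(
    levels=(0.0, 0.1, 0.4, 0.8, 1.0), replicates=(2, 2, 2, 2, 2), config=config
)

betas_raw = compute_beta(data)  # offset 100 regularizes low intensities
betas_cor = compute_beta(relic_correct(data, controls).corrected)

modes_raw = sample_modes(betas_raw)
modes_cor = sample_modes(betas_cor)
print(f"{'sample':<10} {'expected':>8} {'raw mode':>9} {'corrected':>9}")
for sample in data.sample_ids:
    print(
        f"{sample:<10} {truth.expected_level[sample]:>8.2f} "
        f"{modes_raw[sample]:>9.3f} {modes_cor[sample]:>9.3f}"
    )

dev_raw = abs_mode_deviation(betas_raw, truth.expected_level)
dev_cor = abs_mode_deviation(betas_cor, truth.expected_level)
print(f"\nmean |mode - expected|: raw {dev_raw.mean():.4f}, "
      f"corrected {dev_cor.mean():.4f}")
# The green-channel compression inflates raw beta values away from the
# known mixture fractions; after correction the modes track the expected
# levels to within the KDE grid and noise.
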