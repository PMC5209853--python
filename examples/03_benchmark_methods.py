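"""Benchmark dye-bias correction methods on a simulated dilution series.

Runs the full protocol: simulate once, correct with each method, score the
per-sample absolute mode deviation from the expected methylation level,
and compare methods with one-sided paired t-tests.
"""

from relic import SimulationConfig, run_benchmark

config = SimulationConfig(
    n_probes_typeII=3000, n_probes_typeI_red=800, n_probes_typeI_grn=400, seed=37
)
report = run_benchmark(
    config, methods=("raw", "relic", "illumina", "methylumi", "asmn", "nanet", "ssn")
)

print("mean absolute mode deviation (39 samples, lower is better):")
for method, value in report.per_sample_abs_dev.mean().sort_values().items():
    print(f"  {method:<10} {value:.4f}")

print("\none-sided paired t-test p-values, regression correction vs others:")
for other in report.methods:
    if other != "relic":
        print(f"  relic < {other:<10} p = {report.pairwise_p.loc['relic', other]:.2e}")

print("\nmean deviation by methylation level (rows) and method (columns):")
print(report.per_level_mean_abs_dev.round(3).to_string())
# Constant-ratio scaling corrects the average bias but, because the true
# red/green ratio grows with intensity, misses the intensity-dependent
# part; the between-channel quantile method fails badly at extreme levels
# where methylated and unmethylated distributions genuinely differ.
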