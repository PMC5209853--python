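"""Benchmarking protocol for dye-bias correction methods.

For dilution-series (standard-control) data the accuracy metric is the
absolute deviation of each sample's beta-distribution mode from the
sample's expected methylation level; per-level summaries average the
per-replicate deviations.  Against a per-probe gold standard (here the
simulator's known truth) the metric is the absolute beta difference over a
probe subset.  Methods are compared with one-sided paired Student t-tests
on the per-sample deviations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .beta import BetaMatrix, beta_mode, compute_beta, sample_modes
from .comparators import (
    ReferentChoice,
    quantile_between_channels,
    scale_normalize,
    simple_scaling,
)
from .core import (
    ControlPairTable,
    CorrectionResult,
    DegenerateTestError,
    IntensitySet,
    ParameterError,
)
from .correction import relic_correct
from .simulate import SimulatedTruth, SimulationConfig, simulate_dataset

#: Correction methods the benchmark knows, in report order.
METHOD_NAMES = ("raw", "relic", "illumina", "methylumi", "asmn", "nanet", "ssn")


def apply_method(
    method: str, data: IntensitySet, controls: ControlPairTable
) -> CorrectionResult:
    """Dispatch a correction method by name (``raw`` is the identity)."""
    if method == "raw":
        return CorrectionResult(corrected=data.copy(), fits=[], method_name="raw")
    if method == "relic":
        return relic_correct(data, controls)
    if method == "illumina":
        return scale_normalize(data, controls, ReferentChoice("first_sample"))
    if method == "methylumi":
        return scale_normalize(
            data, controls, ReferentChoice("min_channel_difference")
        )
    if method == "asmn":
        return scale_normalize(data, controls, ReferentChoice("all_sample_mean"))
    if method == "nanet":
        return quantile_between_channels(data)
    if method == "ssn":
        return simple_scaling(data, controls)
    raise ParameterError(
        f"unknown method {method!r}; valid methods: {', '.join(METHOD_NAMES)}"
    )


@dataclass
class EvaluationReport:
    """Benchmark output.

    ``per_sample_abs_dev`` — absolute mode deviation, samples x methods;
    ``per_level_mean_abs_dev`` — mean deviation per methylation level group;
    ``pairwise_p`` — one-sided paired t-test p-values, entry (a, b) testing
    whether method *a*'s deviations are smaller than *b*'s (NaN diagonal).
    """

    per_sample_abs_dev: pd.DataFrame
    per_level_mean_abs_dev: pd.DataFrame
    pairwise_p: pd.DataFrame
    methods: list[str] = field(default_factory=list)


def abs_mode_deviation(
    betas: BetaMatrix, expected_level: pd.Series | Sequence[float]
) -> pd.Series:
    """Per-sample ``|mode(beta column) - expected level|``."""
    expected = pd.Series(expected_level)
    if not isinstance(expected_level, pd.Series):
        expected.index = betas.sample_ids
    if ((expected < 0) | (expected > 1)).any():
        raise ParameterError("expected levels must lie in [0, 1]")
    modes = sample_modes(betas)
    return (modes - expected.loc[modes.index]).abs().rename("abs_dev")


def per_level_mean(
    deviations: pd.Series, expected_level: pd.Series
) -> pd.Series:
    """Average per-sample deviations within each expected-level group."""
    return deviations.groupby(expected_level.loc[deviations.index]).mean()


def abs_error_vs_truth(
    betas: BetaMatrix,
    truth: SimulatedTruth,
    probe_subset: Sequence[str],
) -> np.ndarray:
    """Flattened ``|beta - true_beta|`` over a probe subset, all samples.

    The simulator's known per-probe methylation fractions stand in for an
    external gold-standard assay of those probes.
    """
    missing = [p for p in probe_subset if p not in betas.values.index]
    if missing:
        raise LookupError(f"probes not in beta matrix: {missing}")
    observed = betas.values.loc[list(probe_subset)]
    expected = truth.true_beta.loc[list(probe_subset), observed.columns]
    return np.abs(observed.to_numpy() - expected.to_numpy()).ravel()


def paired_one_sided_t(
    dev_a: np.ndarray, dev_b: np.ndarray
) -> float:
    """One-sided paired Student t-test of ``mean(dev_a) < mean(dev_b)``.

    Returns ``p = P(T_{n-1} <= t)`` for the paired t statistic on
    ``d = dev_a - dev_b``; small p means method *a*'s deviations are
    significantly smaller.  Identical non-zero constant differences have no
    sampling variance and return the limiting p (0 or 1); all-zero
    differences are degenerate.
    """
    a = np.asarray(dev_a, dtype=float)
    b = np.asarray(dev_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ParameterError("deviation vectors must be 1-D and equal length")
    n = a.size
    if n < 3:
        raise ParameterError(f"paired test needs n >= 3, got {n}")
    d = a - b
    sd = d.std(ddof=1)
    if sd == 0.0:
        if d[0] == 0.0:
            raise DegenerateTestError(
                "all paired differences are zero; test undefined"
            )
        return 1.0 if d[0] > 0 else 0.0
    t = d.mean() / (sd / np.sqrt(n))
    return float(stats.t.cdf(t, df=n - 1))


def run_benchmark(
    sim_config: SimulationConfig,
    methods: Sequence[str] = METHOD_NAMES,
    offset: float = 100.0,
    pool_replicates: bool = False,
    assay_type: str | None = None,
) -> EvaluationReport:
    """Simulate once, correct with each method, and score accuracy.

    Per method: compute beta values (offset 100), the per-sample mode
    deviation from the expected level, per-level means, and all pairwise
    one-sided paired t-tests on the per-sample deviations across levels.
    With ``pool_replicates=True`` the per-level summary pools each level's
    beta values into a single mode instead of averaging per-replicate
    modes.  ``assay_type`` (``"I"`` or ``"II"``) restricts scoring to one
    probe chemistry.  Deterministic given ``sim_config.seed``.
    """
    for m in methods:
        if m not in METHOD_NAMES:
            raise ParameterError(
                f"unknown method {m!r}; valid methods: {', '.join(METHOD_NAMES)}"
            )
    if assay_type not in (None, "I", "II"):
        raise ParameterError("assay_type must be None, 'I' or 'II'")
    data, controls, truth = simulate_dataset(sim_config)
    expected = truth.expected_level

    per_sample = {}
    per_level = {}
    for method in methods:
        result = apply_method(method, data, controls)
        betas = compute_beta(result.corrected, offset=offset)
        if assay_type is not None:
            keep = result.corrected.annotations["assay_type"] == assay_type
            betas = BetaMatrix(betas.values.loc[keep], offset=betas.offset)
        dev = abs_mode_deviation(betas, expected)
        per_sample[method] = dev
        if pool_replicates:
            pooled = {}
            for level in sorted(set(expected)):
                cols = expected.index[expected == level]
                pooled[level] = abs(
                    beta_mode(betas.values[cols].to_numpy().ravel()) - level
                )
            per_level[method] = pd.Series(pooled)
        else:
            per_level[method] = per_level_mean(dev, expected)

    per_sample_df = pd.DataFrame(per_sample, columns=list(methods))
    per_level_df = pd.DataFrame(per_level, columns=list(methods))
    per_level_df.index.name = "expected_level"

    pairwise = pd.DataFrame(
        np.nan, index=list(methods), columns=list(methods), dtype=float
    )
    if len(methods) > 1:
        for a in methods:
            for b in methods:
                if a == b:
                    continue
                try:
                    pairwise.loc[a, b] = paired_one_sided_t(
                        per_sample_df[a].to_numpy(), per_sample_df[b].to_numpy()
                    )
                except DegenerateTestError:
                    pairwise.loc[a, b] = np.nan
    return EvaluationReport(
        per_sample_abs_dev=per_sample_df,
        per_level_mean_abs_dev=per_level_df,
        pairwise_p=pairwise,
        methods=list(methods),
    )
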