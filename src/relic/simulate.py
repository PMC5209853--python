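"""Synthetic Infinium-like datasets with known methylation truth.

The generator emulates a dilution-series experiment: fully methylated and
unmethylated DNA mixed to known proportions, assayed on a two-color array
whose green channel suffers a log-linear dye bias.  The default design
mirrors a laboratory standard-control series: nine methylation levels
(0, 5, 10, 20, 40, 50, 60, 80, 100%) with replicate counts
(10, 3, 2, 3, 3, 2, 3, 3, 10) for 39 samples in total, and 93 normalization
control pairs as on a 450K array (85 on EPIC).

Bias model
----------
A *true* (unbiased) green intensity ``g`` is observed as

    g_obs = exp((log(max(g, 1)) - bias_beta0) / bias_beta1) * noise

so that the power-law adjustment ``exp(beta1 * log(I) + beta0)`` with the
true coefficients inverts the bias exactly.  The same map is applied to
every green-channel value — array probes and control probes alike — which
is the regime in which regression on control pairs is exactly the right
correction.  Red-channel values receive only the multiplicative lognormal
noise.  ``bias_beta1 > 1`` compresses the green-channel distribution, the
pattern seen on real arrays.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .core import (
    ControlPairTable,
    INTENSITY_FLOOR,
    IntensitySet,
    ParameterError,
)

#: Dilution-series design: methylation fractions and replicate counts.
DILUTION_LEVELS = (0.0, 0.05, 0.10, 0.20, 0.40, 0.50, 0.60, 0.80, 1.0)
DILUTION_REPLICATES = (10, 3, 2, 3, 3, 2, 3, 3, 10)

#: Control pair counts on the two array generations.
N_CONTROL_PAIRS_450K = 93
N_CONTROL_PAIRS_EPIC = 85


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic dilution-series generator.

    Probe counts default to a 20,000-probe array with the Type II / Type I
    red / Type I green proportions of a 450K chip (roughly 72% / 18% / 10%).
    ``log_total_mean``/``log_total_sd`` parameterize the lognormal total
    intensity per locus (defaults give a median near 3,000 fluorescence
    units); ``noise_log_sd`` is multiplicative measurement noise on the log
    scale; ``probe_level_sd`` is per-probe biological scatter of the true
    methylation fraction around the sample's mixture level (clipped to
    [0, 1]).  ``bias_probe_jitter_sd`` perturbs the bias intercept per probe
    (a mis-specification knob, off by default).
    """

    n_probes_typeII: int = 14400
    n_probes_typeI_red: int = 3700
    n_probes_typeI_grn: int = 1900
    n_control_pairs: int = N_CONTROL_PAIRS_450K
    bias_beta0: float = -0.5
    bias_beta1: float = 1.3
    log_total_mean: float = 8.0
    log_total_sd: float = 0.8
    noise_log_sd: float = 0.1
    probe_level_sd: float = 0.05
    methylation_levels: Sequence[float] = DILUTION_LEVELS
    replicates: Sequence[int] = DILUTION_REPLICATES
    bias_probe_jitter_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_probes_typeII", "n_probes_typeI_red", "n_probes_typeI_grn"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be positive")
        if self.n_control_pairs < 3:
            raise ParameterError("n_control_pairs must be at least 3")
        if self.bias_beta1 <= 0:
            raise ParameterError("bias_beta1 must be positive")
        if self.noise_log_sd < 0 or self.probe_level_sd < 0:
            raise ParameterError("noise parameters must be non-negative")
        if len(self.methylation_levels) == 0:
            raise ParameterError("methylation_levels must be non-empty")
        if len(self.methylation_levels) != len(self.replicates):
            raise ParameterError(
                f"{len(self.methylation_levels)} levels but "
                f"{len(self.replicates)} replicate counts"
            )
        if any(not 0.0 <= p <= 1.0 for p in self.methylation_levels):
            raise ParameterError("methylation levels must lie in [0, 1]")
        if any(r <= 0 for r in self.replicates):
            raise ParameterError("replicate counts must be positive")

    @property
    def n_probes(self) -> int:
        return self.n_probes_typeII + self.n_probes_typeI_red + self.n_probes_typeI_grn

    @property
    def n_samples(self) -> int:
        return int(sum(self.replicates))


@dataclass
class SimulatedTruth:
    """Ground truth accompanying a simulated dataset.

    ``true_beta`` are the per-probe methylation fractions actually realized
    (after biological scatter), ``true_meth``/``true_unmeth`` the pre-bias,
    pre-noise intensities, and ``expected_level`` the mixture fraction each
    sample was built to have.
    """

    true_beta: pd.DataFrame
    true_meth: pd.DataFrame
    true_unmeth: pd.DataFrame
    expected_level: pd.Series
    config: SimulationConfig

    @property
    def true_green(self) -> dict[str, pd.DataFrame]:
        """Pre-bias green-channel intensities, keyed by matrix."""
        return {"meth": self.true_meth, "unmeth": self.true_unmeth}


def _bias_green(values: np.ndarray, beta0, beta1) -> np.ndarray:
    """Observed green intensity before noise: the inverse of the adjustment."""
    floored = np.maximum(values, INTENSITY_FLOOR)
    return np.exp((np.log(floored) - beta0) / beta1)


def _annotations(config: SimulationConfig) -> pd.DataFrame:
    n2, nr, ng = (
        config.n_probes_typeII,
        config.n_probes_typeI_red,
        config.n_probes_typeI_grn,
    )
    ids = (
        [f"cg2_{i:06d}" for i in range(n2)]
        + [f"cg1r_{i:06d}" for i in range(nr)]
        + [f"cg1g_{i:06d}" for i in range(ng)]
    )
    return pd.DataFrame(
        {
            "assay_type": ["II"] * n2 + ["I"] * (nr + ng),
            "channel": [None] * n2 + ["Red"] * nr + ["Grn"] * ng,
        },
        index=pd.Index(ids, name="probe_id"),
    )


def _sample_ids(config: SimulationConfig) -> tuple[list[str], np.ndarray]:
    ids: list[str] = []
    levels: list[float] = []
    for level, nrep in zip(config.methylation_levels, config.replicates):
        for r in range(nrep):
            ids.append(f"m{int(round(level * 100)):03d}_r{r + 1:02d}")
            levels.append(level)
    return ids, np.asarray(levels)


def _control_probe_ids(n_pairs: int) -> tuple[list[str], list[str], list[str]]:
    pair_ids = [f"pair_{k + 1:03d}" for k in range(n_pairs)]
    red_ids = [
        f"{'NORM_A' if k % 2 == 0 else 'NORM_T'}.{k + 1}" for k in range(n_pairs)
    ]
    green_ids = [
        f"{'NORM_G' if k % 2 == 0 else 'NORM_C'}.{k + 1}" for k in range(n_pairs)
    ]
    return pair_ids, red_ids, green_ids


def simulate_dataset(
    config: SimulationConfig,
) -> tuple[IntensitySet, ControlPairTable, SimulatedTruth]:
    """Generate one dilution-series dataset with known truth.

    Per sample with mixture level *p*: each probe's true methylation
    fraction is ``clip(p + Normal(0, probe_level_sd), 0, 1)``; a lognormal
    total intensity splits into methylated and unmethylated parts; the dye
    bias map is applied to every green-channel value and multiplicative
    lognormal noise to every value.  Control pairs share one true intensity
    per pair per sample, observed unbiased in red and biased in green.
    Fully reproducible from ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    annotations = _annotations(config)
    sample_ids, expected = _sample_ids(config)
    n_probes, n_samples = config.n_probes, len(sample_ids)

    true_beta = np.clip(
        expected[None, :]
        + rng.normal(0.0, config.probe_level_sd, size=(n_probes, n_samples)),
        0.0,
        1.0,
    )
    total = rng.lognormal(
        config.log_total_mean, config.log_total_sd, size=(n_probes, n_samples)
    )
    true_meth = true_beta * total
    true_unmeth = (1.0 - true_beta) * total

    meth_green, unmeth_green = _green_masks(annotations)
    beta0 = config.bias_beta0
    if config.bias_probe_jitter_sd > 0:
        beta0_meth = beta0 + rng.normal(
            0.0, config.bias_probe_jitter_sd, size=(int(meth_green.sum()), 1)
        )
        beta0_unmeth = beta0 + rng.normal(
            0.0, config.bias_probe_jitter_sd, size=(int(unmeth_green.sum()), 1)
        )
    else:
        beta0_meth = beta0_unmeth = beta0

    meth_obs = true_meth.copy()
    unmeth_obs = true_unmeth.copy()
    meth_obs[meth_green, :] = _bias_green(
        true_meth[meth_green, :], beta0_meth, config.bias_beta1
    )
    unmeth_obs[unmeth_green, :] = _bias_green(
        true_unmeth[unmeth_green, :], beta0_unmeth, config.bias_beta1
    )
    if config.noise_log_sd > 0:
        meth_obs *= np.exp(
            rng.normal(0.0, config.noise_log_sd, size=meth_obs.shape)
        )
        unmeth_obs *= np.exp(
            rng.normal(0.0, config.noise_log_sd, size=unmeth_obs.shape)
        )

    data = IntensitySet(
        meth=pd.DataFrame(meth_obs, index=annotations.index, columns=sample_ids),
        unmeth=pd.DataFrame(
            unmeth_obs, index=annotations.index, columns=sample_ids
        ),
        annotations=annotations,
    )

    pair_ids, red_ids, green_ids = _control_probe_ids(config.n_control_pairs)
    t = rng.lognormal(
        config.log_total_mean,
        config.log_total_sd,
        size=(config.n_control_pairs, n_samples),
    )
    red_ctrl = t.copy()
    green_ctrl = _bias_green(t, config.bias_beta0, config.bias_beta1)
    if config.noise_log_sd > 0:
        red_ctrl = red_ctrl * np.exp(
            rng.normal(0.0, config.noise_log_sd, size=t.shape)
        )
        green_ctrl = green_ctrl * np.exp(
            rng.normal(0.0, config.noise_log_sd, size=t.shape)
        )
    index = pd.Index(pair_ids, name="pair_id")
    controls = ControlPairTable(
        red=pd.DataFrame(red_ctrl, index=index, columns=sample_ids),
        green=pd.DataFrame(green_ctrl, index=index, columns=sample_ids),
        red_probe_ids=pd.Series(red_ids, index=index),
        green_probe_ids=pd.Series(green_ids, index=index),
        floor=True,
    )

    truth = SimulatedTruth(
        true_beta=pd.DataFrame(
            true_beta, index=annotations.index, columns=sample_ids
        ),
        true_meth=pd.DataFrame(
            true_meth, index=annotations.index, columns=sample_ids
        ),
        true_unmeth=pd.DataFrame(
            true_unmeth, index=annotations.index, columns=sample_ids
        ),
        expected_level=pd.Series(expected, index=sample_ids, name="expected_level"),
        config=config,
    )
    return data, controls, truth


def _green_masks(annotations: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    assay = annotations["assay_type"].to_numpy()
    chan = annotations["channel"].to_numpy(dtype=object)
    type1_grn = (assay == "I") & (chan == "Grn")
    return (assay == "II") | type1_grn, type1_grn


def simulate_dilution_series(
    levels: Sequence[float],
    replicates: Sequence[int],
    config: SimulationConfig | None = None,
) -> tuple[IntensitySet, ControlPairTable, SimulatedTruth]:
    """Simulate with an explicit dilution design, overriding the config's."""
    if len(levels) != len(replicates):
        raise ParameterError(
            f"{len(levels)} levels but {len(replicates)} replicate counts"
        )
    if len(levels) == 0:
        raise ParameterError("levels must be non-empty")
    base = config if config is not None else SimulationConfig()
    cfg = replace(base, methylation_levels=tuple(levels), replicates=tuple(replicates))
    return simulate_dataset(cfg)
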