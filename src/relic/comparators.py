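"""Alternative dye-bias correction methods used for benchmarking.

Implements the control-probe scaling family (GenomeStudio-style with three
referent choices), between-channel quantile normalization over all probes
jointly, and a simple per-sample scaling of the green channel.  All methods
share the :class:`~relic.core.CorrectionResult` output contract.

The scaling family assumes a *constant* red/green ratio per sample: each
channel is divided by its control-probe mean and rescaled to a referent.
When the true bias varies with intensity magnitude these methods
under-adjust large intensities and over-adjust small ones — the failure
mode the log-log regression correction avoids.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .core import (
    ControlPairTable,
    CorrectionResult,
    IntensitySet,
    ParameterError,
    ValidationError,
)

REFERENT_MODES = ("first_sample", "min_channel_difference", "all_sample_mean")


@dataclass(frozen=True)
class ReferentChoice:
    """How the scaling family picks its referent.

    * ``first_sample`` — GenomeStudio convention: the first sample.
    * ``min_channel_difference`` — methylumi convention: the sample whose
      control red/green channel means are closest.
    * ``all_sample_mean`` — all-sample-mean normalization (ASMN): the
      across-sample average of the control channel means.
    """

    mode: str
    referent_sample_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.mode not in REFERENT_MODES:
            raise ParameterError(
                f"referent mode must be one of {REFERENT_MODES}, got "
                f"{self.mode!r}"
            )


def control_channel_means(controls: ControlPairTable) -> pd.DataFrame:
    """Per-sample arithmetic mean control intensity for each channel.

    Returns a DataFrame indexed by sample with columns ``mean_red`` and
    ``mean_green``.
    """
    return pd.DataFrame(
        {
            "mean_red": controls.red.mean(axis=0),
            "mean_green": controls.green.mean(axis=0),
        }
    )


def _check_coverage(data: IntensitySet, controls: ControlPairTable) -> None:
    missing = [s for s in data.sample_ids if s not in controls.sample_ids]
    if missing:
        raise ValidationError(f"samples missing from control table: {missing}")


def _channel_scaled(
    data: IntensitySet, red_factor: np.ndarray, green_factor: np.ndarray
) -> IntensitySet:
    """Multiply each channel of each sample by its scale factor."""
    meth_green, unmeth_green = data.green_masks()
    meth = data.meth.to_numpy(dtype=float).copy()
    unmeth = data.unmeth.to_numpy(dtype=float).copy()
    meth[meth_green, :] *= green_factor
    meth[~meth_green, :] *= red_factor
    unmeth[unmeth_green, :] *= green_factor
    unmeth[~unmeth_green, :] *= red_factor
    return IntensitySet(
        meth=pd.DataFrame(meth, index=data.meth.index, columns=data.meth.columns),
        unmeth=pd.DataFrame(
            unmeth, index=data.unmeth.index, columns=data.unmeth.columns
        ),
        annotations=data.annotations.copy(),
    )


def scale_normalize(
    data: IntensitySet,
    controls: ControlPairTable,
    referent: ReferentChoice,
) -> CorrectionResult:
    """Control-probe channel scaling with a configurable referent.

    Each sample's intensities are first divided, per channel, by that
    channel's control-probe mean — this is the dye-bias correction step,
    which equalizes the two channels of every sample — and then rescaled to
    a single channel-pooled referent target so values stay on the
    fluorescence scale.  The target is the mean of the referent sample's
    two channel means (modes ``first_sample`` and ``min_channel_difference``)
    or the grand mean of all samples' channel means (``all_sample_mean``).
    Equivalently, every value in channel *c* of sample *s* is multiplied by
    ``target / mean_c(s)``.  A single constant per channel per sample means
    the method assumes a constant red/green ratio: it under-adjusts large
    and over-adjusts small intensities when the true bias is
    intensity-dependent.
    """
    _check_coverage(data, controls)
    means = control_channel_means(controls).loc[data.sample_ids]
    if (means <= 0).any().any():
        bad = means.index[(means <= 0).any(axis=1)][0]
        raise ValidationError(
            f"sample {bad!r} has a non-positive control channel mean"
        )
    if referent.mode == "all_sample_mean":
        target = float(means.to_numpy().mean())
        name = "asmn"
    else:
        if referent.mode == "first_sample":
            ref_id = referent.referent_sample_id or data.sample_ids[0]
            name = "illumina"
        else:
            diff = (means["mean_red"] - means["mean_green"]).abs()
            ref_id = referent.referent_sample_id or diff.idxmin()
            name = "methylumi"
        target = float(means.loc[ref_id].mean())
    red_factor = target / means["mean_red"].to_numpy(dtype=float)
    green_factor = target / means["mean_green"].to_numpy(dtype=float)
    corrected = _channel_scaled(data, red_factor, green_factor)
    return CorrectionResult(corrected=corrected, fits=[], method_name=name)


def _quantile_match(values: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Assign sorted ``target`` values to ``values`` by rank, averaging ties."""
    order = np.argsort(values, kind="mergesort")
    assigned = np.empty_like(target, dtype=float)
    assigned[order] = target
    # tied input values share the mean of their assigned targets
    sorted_vals = values[order]
    boundaries = np.flatnonzero(np.diff(sorted_vals) != 0) + 1
    groups = np.split(np.arange(values.size), boundaries)
    if len(groups) != values.size:
        assigned_sorted = target.copy()
        for grp in groups:
            if grp.size > 1:
                assigned_sorted[grp] = assigned_sorted[grp].mean()
        assigned[order] = assigned_sorted
    return assigned


def quantile_between_channels(data: IntensitySet) -> CorrectionResult:
    """Quantile-normalize methylated against unmethylated, all probes jointly.

    Per sample, each value in the methylated and unmethylated vectors is
    replaced by the mean of the two channel values at its within-channel
    rank, so the two empirical distributions become identical.  This is the
    all-probe ("nanet"-style) variant of between-channel quantile
    normalization; tied values share the average of their target values.
    """
    if data.n_probes < 2:
        raise ParameterError("quantile normalization needs at least 2 probes")
    meth = data.meth.to_numpy(dtype=float).copy()
    unmeth = data.unmeth.to_numpy(dtype=float).copy()
    for j in range(data.n_samples):
        target = (np.sort(meth[:, j]) + np.sort(unmeth[:, j])) / 2.0
        meth[:, j] = _quantile_match(meth[:, j], target)
        unmeth[:, j] = _quantile_match(unmeth[:, j], target)
    corrected = IntensitySet(
        meth=pd.DataFrame(meth, index=data.meth.index, columns=data.meth.columns),
        unmeth=pd.DataFrame(
            unmeth, index=data.unmeth.index, columns=data.unmeth.columns
        ),
        annotations=data.annotations.copy(),
    )
    return CorrectionResult(corrected=corrected, fits=[], method_name="nanet")


def simple_scaling(
    data: IntensitySet, controls: ControlPairTable
) -> CorrectionResult:
    """Scale each sample's green channel by one constant control-probe ratio.

    An approximation of lumi's simple scaling normalization: per sample the
    green intensities are multiplied by ``mean_red / mean_green`` of that
    sample's control probes; red intensities are unchanged.
    """
    _check_coverage(data, controls)
    means = control_channel_means(controls).loc[data.sample_ids]
    if (means["mean_green"] <= 0).any():
        bad = means.index[means["mean_green"] <= 0][0]
        raise ValidationError(
            f"sample {bad!r} has a non-positive green control mean"
        )
    green_factor = (means["mean_red"] / means["mean_green"]).to_numpy(dtype=float)
    red_factor = np.ones_like(green_factor)
    corrected = _channel_scaled(data, red_factor, green_factor)
    return CorrectionResult(corrected=corrected, fits=[], method_name="ssn")
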