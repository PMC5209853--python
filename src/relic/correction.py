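"""RELIC: regression on logarithms of internal control probes.

Paired normalization control probes (NORM_A/NORM_T read in red, NORM_G/NORM_C
read in green) target the same CpG-free regions, so absent dye bias each
pair would report a red/green ratio near 1.  Empirically the log intensities
of the two channels are linearly related, which motivates the correction:
for each sample independently, ordinary least squares of ``log(red)`` on
``log(green)`` over the control pairs yields coefficients ``(beta0, beta1)``,
and every green-channel intensity ``I`` on the array is then mapped through

    I_adj = exp(beta1 * log(I) + beta0)

Red-channel intensities are left untouched.  Because the map is a power law
with positive exponent it is strictly increasing and always positive, and —
unlike constant-ratio scaling — the implied red/green correction factor
varies with intensity magnitude.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .core import (
    ChannelFit,
    ControlPairTable,
    CorrectionResult,
    DegenerateFitError,
    IntensitySet,
    ParameterError,
    ValidationError,
    floor_intensities,
)


def fit_log_regression(
    red: np.ndarray,
    green: np.ndarray,
    sample_id: str = "",
    robust: bool = False,
) -> ChannelFit:
    """OLS fit of ``log(red)`` on ``log(green)`` over control pairs.

    The green channel is the independent variable.  With ``robust=True`` the
    slope/intercept come from the Theil–Sen estimator instead of OLS; the
    default is plain OLS.

    Raises
    ------
    DegenerateFitError
        if ``log(green)`` has zero variance.
    FitRejectedError
        if the fitted slope is not positive (raised by :class:`ChannelFit`).
    """
    red = np.asarray(red, dtype=float)
    green = np.asarray(green, dtype=float)
    if red.shape != green.shape or red.ndim != 1:
        raise ParameterError("red and green must be 1-D vectors of equal length")
    if red.size < ControlPairTable.MIN_PAIRS:
        raise ParameterError(
            f"need at least {ControlPairTable.MIN_PAIRS} control pairs, "
            f"got {red.size}"
        )
    if (red <= 0).any() or (green <= 0).any():
        raise ValidationError(
            "control intensities must be positive; apply the floor policy first"
        )
    x = np.log(green)
    y = np.log(red)
    if np.ptp(x) == 0.0:
        raise DegenerateFitError(
            f"sample {sample_id!r}: zero variance in log green control "
            "intensities"
        )
    if robust:
        res = stats.theilslopes(y, x)
        beta1, beta0 = float(res.slope), float(res.intercept)
    else:
        beta1, beta0 = np.polyfit(x, y, 1)
        beta1, beta0 = float(beta1), float(beta0)
    resid = y - (beta0 + beta1 * x)
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r_squared = 1.0 if ss_tot == 0.0 else max(0.0, min(1.0, 1.0 - ss_res / ss_tot))
    return ChannelFit(
        beta0=beta0,
        beta1=beta1,
        n_pairs=red.size,
        r_squared=r_squared,
        sample_id=sample_id,
    )


def apply_green_adjustment(values: np.ndarray, fit: ChannelFit) -> np.ndarray:
    """Map green intensities through ``exp(beta1 * log(I) + beta0)``.

    Inputs at or below zero are floored first (shared floor policy), so the
    output is always strictly positive.
    """
    values, _ = floor_intensities(values)
    out = np.exp(fit.beta1 * np.log(values) + fit.beta0)
    if not np.isfinite(out).all():
        idx = int(np.argwhere(~np.isfinite(out.ravel()))[0][0])
        raise ValidationError(
            f"adjustment overflowed for input value {values.ravel()[idx]!r} "
            f"(sample {fit.sample_id!r})"
        )
    return out


def relic_correct(
    data: IntensitySet,
    controls: ControlPairTable,
    robust: bool = False,
) -> CorrectionResult:
    """Correct dye bias on every green-channel intensity, sample by sample.

    For each sample a :func:`fit_log_regression` on that sample's control
    pairs defines the adjustment; it is applied to Type II methylated
    intensities and to both intensities of Type I green-channel loci.  All
    red-channel values are returned bit-identical to the input.
    """
    missing = [s for s in data.sample_ids if s not in controls.sample_ids]
    if missing:
        raise ValidationError(
            f"samples missing from control table: {missing}"
        )
    meth_green, unmeth_green = data.green_masks()
    meth_out = data.meth.to_numpy(dtype=float).copy()
    unmeth_out = data.unmeth.to_numpy(dtype=float).copy()
    fits: list[ChannelFit] = []
    for j, sample in enumerate(data.sample_ids):
        red, green = controls.sample(sample)
        fit = fit_log_regression(red, green, sample_id=sample, robust=robust)
        fits.append(fit)
        meth_out[meth_green, j] = apply_green_adjustment(
            meth_out[meth_green, j], fit
        )
        unmeth_out[unmeth_green, j] = apply_green_adjustment(
            unmeth_out[unmeth_green, j], fit
        )
    corrected = IntensitySet(
        meth=data.meth.__class__(
            meth_out, index=data.meth.index, columns=data.meth.columns
        ),
        unmeth=data.unmeth.__class__(
            unmeth_out, index=data.unmeth.index, columns=data.unmeth.columns
        ),
        annotations=data.annotations.copy(),
    )
    return CorrectionResult(corrected=corrected, fits=fits, method_name="relic")


def control_ratio_diagnostic(
    controls: ControlPairTable,
    fits: Optional[Sequence[ChannelFit]] = None,
) -> "pd.DataFrame":
    """Red/green intensity ratio per control pair per sample.

    With ``fits`` given (one per sample, in sample order) the green
    intensities are first mapped through each sample's adjustment, so the
    ratios describe the post-correction state.  A well-corrected sample has
    a ratio distribution with a single mode close to 1.
    """
    import pandas as pd

    green = controls.green.to_numpy(dtype=float)
    red = controls.red.to_numpy(dtype=float)
    if fits is not None:
        if len(fits) != len(controls.sample_ids):
            raise ParameterError(
                f"{len(fits)} fits for {len(controls.sample_ids)} samples"
            )
        green = green.copy()
        for j, fit in enumerate(fits):
            green[:, j] = apply_green_adjustment(green[:, j], fit)
    return pd.DataFrame(
        red / green, index=controls.red.index, columns=controls.red.columns
    )
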