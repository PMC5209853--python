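"""Beta values and beta-distribution mode estimation.

The methylation level at a CpG is summarized by the beta value
``M / (M + U + c)`` where ``M`` and ``U`` are the methylated and
unmethylated intensities and ``c`` (default 100) regularizes loci where
both are small.  For laboratory standard samples, whose beta distributions
are typically skewed, the distribution *mode* is a more faithful estimate
of the shared methylation level than the mean; it is estimated here as the
argmax of a Gaussian kernel density evaluated on a fixed grid over [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from .core import IntensitySet, ParameterError, RelicError

DEFAULT_OFFSET = 100.0
MODE_GRID_SIZE = 512
MIN_MODE_SAMPLES = 10


class InsufficientDataError(RelicError):
    """Too few beta values to estimate a distribution mode."""


@dataclass
class BetaMatrix:
    """Beta values (probe x sample) with the offset used to compute them."""

    values: pd.DataFrame
    offset: float = DEFAULT_OFFSET

    def __post_init__(self) -> None:
        vals = self.values.to_numpy()
        if ((vals < 0) | (vals > 1)).any():
            raise ParameterError("beta values must lie in [0, 1]")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


def compute_beta(data: IntensitySet, offset: float = DEFAULT_OFFSET) -> BetaMatrix:
    """Elementwise ``M / (M + U + offset)``."""
    if offset < 0:
        raise ParameterError(f"offset must be non-negative, got {offset}")
    meth = data.meth.to_numpy(dtype=float)
    unmeth = data.unmeth.to_numpy(dtype=float)
    denom = meth + unmeth + offset
    with np.errstate(invalid="ignore"):
        beta = np.where(denom > 0, meth / np.where(denom > 0, denom, 1.0), 0.0)
    return BetaMatrix(
        values=pd.DataFrame(
            beta, index=data.meth.index, columns=data.meth.columns
        ),
        offset=offset,
    )


def beta_mode(
    betas: np.ndarray,
    bandwidth: float | str = "silverman",
    grid_size: int = MODE_GRID_SIZE,
) -> float:
    """Mode of a beta-value sample via Gaussian KDE on a fixed [0, 1] grid.

    ``bandwidth`` is passed to :class:`scipy.stats.gaussian_kde`
    (``"silverman"`` rule by default, or a float factor).  Plateau ties
    resolve to the smallest grid point, so the estimate is deterministic.
    A degenerate sample (all values identical) returns that value directly.
    """
    values = np.asarray(betas, dtype=float).ravel()
    if values.size < MIN_MODE_SAMPLES:
        raise InsufficientDataError(
            f"need at least {MIN_MODE_SAMPLES} beta values, got {values.size}"
        )
    if ((values < 0) | (values > 1)).any() or not np.isfinite(values).all():
        raise ParameterError("beta values must be finite and in [0, 1]")
    if np.ptp(values) == 0.0:
        return float(values[0])
    kde = gaussian_kde(values, bw_method=bandwidth)
    grid = np.linspace(0.0, 1.0, grid_size)
    density = kde(grid)
    return float(grid[int(np.argmax(density))])


def density_mode(
    values: np.ndarray,
    bandwidth: float | str = "silverman",
    grid_size: int = MODE_GRID_SIZE,
) -> float:
    """KDE argmax of an arbitrary-range sample (e.g. red/green ratios).

    Like :func:`beta_mode` but the evaluation grid spans the observed data
    range instead of [0, 1].
    """
    vals = np.asarray(values, dtype=float).ravel()
    if vals.size < MIN_MODE_SAMPLES:
        raise InsufficientDataError(
            f"need at least {MIN_MODE_SAMPLES} values, got {vals.size}"
        )
    if not np.isfinite(vals).all():
        raise ParameterError("values must be finite")
    if np.ptp(vals) == 0.0:
        return float(vals[0])
    kde = gaussian_kde(vals, bw_method=bandwidth)
    grid = np.linspace(vals.min(), vals.max(), grid_size)
    return float(grid[int(np.argmax(kde(grid)))])


def sample_modes(
    betas: BetaMatrix,
    bandwidth: float | str = "silverman",
    grid_size: int = MODE_GRID_SIZE,
) -> pd.Series:
    """Beta-distribution mode for every sample column."""
    return pd.Series(
        {
            sample: beta_mode(
                betas.values[sample].to_numpy(), bandwidth, grid_size
            )
            for sample in betas.sample_ids
        },
        name="mode",
    )
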