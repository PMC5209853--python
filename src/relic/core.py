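"""Domain types for two-color methylation array intensities.

The Illumina Infinium platform measures CpG methylation with two chemistries:

* **Infinium I** — two bead types per locus (methylated and unmethylated
  probe), *both* read in the same dye channel.  The manifest records which
  channel (``Red`` or ``Grn``) each Type I locus uses.
* **Infinium II** — one bead type per locus; the methylated allele is read
  in the green (Cy3) channel and the unmethylated allele in the red (Cy5)
  channel.

The containers below keep the methylated/unmethylated intensity matrices
aligned with per-probe design metadata so that correction methods can
locate every value that lives in the green channel.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import pandas as pd

#: Intensities at or below zero are replaced by this value before any
#: logarithm is taken.  One fluorescence unit is negligible against the
#: thousands-of-units scale of real bead intensities but keeps log finite.
INTENSITY_FLOOR = 1.0

ASSAY_TYPES = ("I", "II")
CHANNELS = ("Red", "Grn")

#: Control probe families: A/T single-base extensions are read in the red
#: channel, G/C extensions in the green channel.
RED_CONTROL_FAMILIES = ("NORM_A", "NORM_T")
GREEN_CONTROL_FAMILIES = ("NORM_G", "NORM_C")


class RelicError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(RelicError):
    """An input table does not match the documented column layout."""


class AlignmentError(RelicError):
    """Two tables that must share sample or probe ordering do not."""


class ValidationError(RelicError):
    """A value violates a container invariant (negative, non-finite, ...)."""


class InsufficientControlsError(RelicError):
    """Fewer control-probe pairs than the minimum needed for a regression."""


class DegenerateFitError(RelicError):
    """The regression design is degenerate (zero variance in the predictor)."""


class FitRejectedError(RelicError):
    """A fitted slope is non-positive, so the adjustment map is not monotone."""


class DegenerateTestError(RelicError):
    """A paired test cannot be computed (all differences identical at zero)."""


class ParameterError(RelicError):
    """A user-supplied parameter is out of its documented range."""


def floor_intensities(values: np.ndarray) -> tuple[np.ndarray, int]:
    """Replace values ``<= 0`` by :data:`INTENSITY_FLOOR`.

    Returns the floored array (a copy when anything changed) and the number
    of floored entries.
    """
    arr = np.asarray(values, dtype=float)
    mask = arr <= 0
    n = int(mask.sum())
    if n:
        arr = arr.copy()
        arr[mask] = INTENSITY_FLOOR
    return arr, n


@dataclass(frozen=True)
class ProbeAnnotation:
    """Design metadata for one probe.

    For Type I probes ``channel`` names the single dye channel in which both
    the methylated and unmethylated bead intensities are read.  For Type II
    probes the channel assignment is fixed by the chemistry (methylated →
    green, unmethylated → red) and ``channel`` is ``None``.
    """

    probe_id: str
    assay_type: str
    channel: Optional[str] = None

    def __post_init__(self) -> None:
        if self.assay_type not in ASSAY_TYPES:
            raise ValidationError(
                f"probe {self.probe_id!r}: assay_type must be one of "
                f"{ASSAY_TYPES}, got {self.assay_type!r}"
            )
        if self.assay_type == "I" and self.channel not in CHANNELS:
            raise ValidationError(
                f"Type I probe {self.probe_id!r} must declare channel Red or "
                f"Grn, got {self.channel!r}"
            )


def annotations_frame(annotations: Iterable[ProbeAnnotation]) -> pd.DataFrame:
    """Tabulate annotations as a DataFrame indexed by probe id."""
    anns = list(annotations)
    ids = [a.probe_id for a in anns]
    if len(set(ids)) != len(ids):
        raise ValidationError("duplicate probe_id in annotations")
    return pd.DataFrame(
        {
            "assay_type": [a.assay_type for a in anns],
            "channel": [a.channel for a in anns],
        },
        index=pd.Index(ids, name="probe_id"),
    )


@dataclass
class IntensitySet:
    """Paired methylated/unmethylated intensity matrices (probes x samples).

    ``meth`` and ``unmeth`` are DataFrames sharing index (probe ids, in
    manifest order) and columns (sample ids).  ``annotations`` is aligned to
    the rows.
    """

    meth: pd.DataFrame
    unmeth: pd.DataFrame
    annotations: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.meth.shape != self.unmeth.shape:
            raise AlignmentError(
                f"meth shape {self.meth.shape} != unmeth shape "
                f"{self.unmeth.shape}"
            )
        if not self.meth.index.equals(self.unmeth.index):
            raise AlignmentError("meth and unmeth probe orderings differ")
        if not self.meth.columns.equals(self.unmeth.columns):
            raise AlignmentError("meth and unmeth sample orderings differ")
        if not self.meth.index.equals(self.annotations.index):
            raise AlignmentError("annotations not aligned to intensity rows")
        for name, frame in (("meth", self.meth), ("unmeth", self.unmeth)):
            values = frame.to_numpy()
            if not np.isfinite(values).all():
                raise ValidationError(f"non-finite value in {name} matrix")
            if (values < 0).any():
                r, c = np.argwhere(values < 0)[0]
                raise ValidationError(
                    f"negative intensity in {name} at probe "
                    f"{frame.index[r]!r}, sample {frame.columns[c]!r}"
                )

    @property
    def probe_ids(self) -> list[str]:
        return list(self.meth.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.meth.columns)

    @property
    def n_probes(self) -> int:
        return self.meth.shape[0]

    @property
    def n_samples(self) -> int:
        return self.meth.shape[1]

    def green_masks(self) -> tuple[np.ndarray, np.ndarray]:
        """Boolean row masks ``(meth_is_green, unmeth_is_green)``.

        Type II methylated intensities and both intensities of Type I green
        loci live in the green channel; everything else is red.
        """
        assay = self.annotations["assay_type"].to_numpy()
        chan = self.annotations["channel"].to_numpy(dtype=object)
        type1_grn = (assay == "I") & (chan == "Grn")
        meth_green = (assay == "II") | type1_grn
        unmeth_green = type1_grn
        return meth_green, unmeth_green

    def red_masks(self) -> tuple[np.ndarray, np.ndarray]:
        """Boolean row masks ``(meth_is_red, unmeth_is_red)``."""
        meth_green, unmeth_green = self.green_masks()
        return ~meth_green, ~unmeth_green

    def copy(self) -> "IntensitySet":
        return IntensitySet(
            meth=self.meth.copy(),
            unmeth=self.unmeth.copy(),
            annotations=self.annotations.copy(),
        )


@dataclass
class ControlPairTable:
    """Matched red/green intensities for the normalization control pairs.

    Each row is one control pair: a red-channel probe (NORM_A/NORM_T family)
    and its green-channel partner (NORM_G/NORM_C family) targeting the same
    CpG-free region.  Absent dye bias the two members of a pair report the
    same intensity.

    ``red`` and ``green`` are DataFrames (pair x sample) sharing index and
    columns.  Values must be strictly positive; use ``floor=True`` to apply
    the shared intensity floor at construction.
    """

    red: pd.DataFrame
    green: pd.DataFrame
    red_probe_ids: pd.Series
    green_probe_ids: pd.Series
    n_floored: int = 0

    MIN_PAIRS = 3

    def __init__(
        self,
        red: pd.DataFrame,
        green: pd.DataFrame,
        red_probe_ids: pd.Series,
        green_probe_ids: pd.Series,
        floor: bool = True,
    ) -> None:
        if red.shape != green.shape:
            raise AlignmentError("red and green control matrices differ in shape")
        if not red.index.equals(green.index):
            raise AlignmentError("red and green control pair orderings differ")
        if not red.columns.equals(green.columns):
            raise AlignmentError("red and green control sample orderings differ")
        if red.index.has_duplicates:
            raise ValidationError("duplicated pair_id in control table")
        if len(red) < self.MIN_PAIRS:
            raise InsufficientControlsError(
                f"{len(red)} control pairs; at least {self.MIN_PAIRS} required "
                "for a meaningful regression"
            )
        n_floored = 0
        if floor:
            red_vals, n1 = floor_intensities(red.to_numpy())
            grn_vals, n2 = floor_intensities(green.to_numpy())
            n_floored = n1 + n2
            red = pd.DataFrame(red_vals, index=red.index, columns=red.columns)
            green = pd.DataFrame(grn_vals, index=green.index, columns=green.columns)
        for name, frame in (("red", red), ("green", green)):
            vals = frame.to_numpy()
            if not np.isfinite(vals).all():
                raise ValidationError(f"non-finite value in {name} control matrix")
            if (vals <= 0).any():
                raise ValidationError(
                    f"non-positive value in {name} control matrix after floor"
                )
        self.red = red
        self.green = green
        self.red_probe_ids = red_probe_ids
        self.green_probe_ids = green_probe_ids
        self.n_floored = n_floored

    @property
    def pair_ids(self) -> list[str]:
        return list(self.red.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.red.columns)

    @property
    def n_pairs(self) -> int:
        return len(self.red)

    def sample(self, sample_id: str) -> tuple[np.ndarray, np.ndarray]:
        """Return ``(red, green)`` intensity vectors for one sample."""
        if sample_id not in self.red.columns:
            raise AlignmentError(
                f"sample {sample_id!r} not present in control table"
            )
        return (
            self.red[sample_id].to_numpy(dtype=float),
            self.green[sample_id].to_numpy(dtype=float),
        )


@dataclass(frozen=True)
class ChannelFit:
    """Per-sample regression coefficients defining the green-channel map.

    The adjustment applied to a green intensity ``I`` is
    ``exp(beta1 * log(I) + beta0)``; ``beta1 > 0`` guarantees the map is
    strictly increasing.
    """

    beta0: float
    beta1: float
    n_pairs: int
    r_squared: float
    sample_id: str = ""

    def __post_init__(self) -> None:
        if self.n_pairs < ControlPairTable.MIN_PAIRS:
            raise ValidationError(
                f"fit for sample {self.sample_id!r} used {self.n_pairs} pairs; "
                f"minimum is {ControlPairTable.MIN_PAIRS}"
            )
        if not 0.0 <= self.r_squared <= 1.0 + 1e-12:
            raise ValidationError(
                f"r_squared {self.r_squared} outside [0, 1] for sample "
                f"{self.sample_id!r}"
            )
        if self.beta1 <= 0:
            raise FitRejectedError(
                f"sample {self.sample_id!r}: fitted slope {self.beta1:.4g} "
                "is not positive; the adjustment map would not be monotone"
            )


@dataclass
class CorrectionResult:
    """Output of a dye-bias correction method.

    ``corrected`` has the shape and ordering of the input set; ``fits``
    holds one :class:`ChannelFit` per sample for regression-based methods
    and is empty otherwise.
    """

    corrected: IntensitySet
    fits: list[ChannelFit] = field(default_factory=list)
    method_name: str = ""
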