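"""Readers and writers for intensity, manifest, and control-probe tables.

File formats (all plain text):

* **Intensity matrices** — TSV, first column ``probe_id``, remaining columns
  one per sample; one file for methylated, one for unmethylated intensities.
* **Manifest subset** — CSV with Illumina's column names
  ``IlmnID,Infinium_Design_Type,Color_Channel`` (design type ``I``/``II``;
  channel ``Red``/``Grn``, empty for Type II).
* **Control table** — TSV with columns
  ``pair_id,red_probe_id,green_probe_id`` followed by ``<sample>.red`` and
  ``<sample>.grn`` column pairs.

Binary IDAT decoding is out of scope: decode with methylprep (Python) or
illuminaio (R) first and feed the resulting tables in.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .core import (
    AlignmentError,
    ControlPairTable,
    FormatError,
    GREEN_CONTROL_FAMILIES,
    IntensitySet,
    InsufficientControlsError,
    RED_CONTROL_FAMILIES,
    ValidationError,
)

logger = logging.getLogger(__name__)

MANIFEST_COLUMNS = ("IlmnID", "Infinium_Design_Type", "Color_Channel")
CONTROL_KEY_COLUMNS = ("pair_id", "red_probe_id", "green_probe_id")


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read a manifest subset CSV into an annotation frame.

    Returns a DataFrame indexed by probe id with columns ``assay_type`` and
    ``channel`` (``None`` for Type II rows).
    """
    raw = pd.read_csv(path, dtype=str)
    for col in MANIFEST_COLUMNS:
        if col not in raw.columns:
            raise FormatError(f"manifest {path} is missing column {col!r}")
    if raw["IlmnID"].duplicated().any():
        dup = raw["IlmnID"][raw["IlmnID"].duplicated()].iloc[0]
        raise ValidationError(f"manifest {path}: duplicate probe id {dup!r}")
    channel = raw["Color_Channel"].where(raw["Color_Channel"].notna(), None)
    ann = pd.DataFrame(
        {
            "assay_type": raw["Infinium_Design_Type"].to_numpy(),
            "channel": channel.to_numpy(dtype=object),
        },
        index=pd.Index(raw["IlmnID"], name="probe_id"),
    )
    bad_type = ~ann["assay_type"].isin(["I", "II"])
    if bad_type.any():
        pid = ann.index[bad_type][0]
        raise FormatError(
            f"manifest {path}: probe {pid!r} has Infinium_Design_Type "
            f"{ann.loc[pid, 'assay_type']!r} (expected I or II)"
        )
    type1 = ann["assay_type"] == "I"
    bad_chan = type1 & ~ann["channel"].isin(["Red", "Grn"])
    if bad_chan.any():
        pid = ann.index[bad_chan][0]
        raise FormatError(
            f"manifest {path}: Type I probe {pid!r} must declare "
            "Color_Channel Red or Grn"
        )
    ann.loc[~type1, "channel"] = None
    return ann


def write_manifest(annotations: pd.DataFrame, path: str | Path) -> None:
    out = pd.DataFrame(
        {
            "IlmnID": annotations.index,
            "Infinium_Design_Type": annotations["assay_type"].to_numpy(),
            "Color_Channel": [
                c if c is not None else "" for c in annotations["channel"]
            ],
        }
    )
    out.to_csv(path, index=False)


def _read_matrix(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t")
    if frame.columns[0] != "probe_id":
        raise FormatError(
            f"{path}: first column must be 'probe_id', got "
            f"{frame.columns[0]!r}"
        )
    frame = frame.set_index("probe_id")
    return frame.astype(float)


def read_intensity_set(
    meth_path: str | Path,
    unmeth_path: str | Path,
    manifest_path: str | Path,
) -> IntensitySet:
    """Load methylated/unmethylated TSV matrices restricted to the manifest.

    Rows are restricted to probes present in both matrices *and* the
    manifest, in manifest order; the count of dropped probes is logged.
    """
    meth = _read_matrix(meth_path)
    unmeth = _read_matrix(unmeth_path)
    if list(meth.columns) != list(unmeth.columns):
        raise AlignmentError(
            f"sample IDs differ between {meth_path} ({list(meth.columns)}) "
            f"and {unmeth_path} ({list(unmeth.columns)})"
        )
    ann = read_manifest(manifest_path)
    keep = [p for p in ann.index if p in meth.index and p in unmeth.index]
    dropped = len(ann) - len(keep)
    if dropped:
        logger.warning(
            "dropped %d manifest probes absent from the intensity matrices",
            dropped,
        )
    extra = len(meth.index.difference(ann.index))
    if extra:
        logger.warning("dropped %d matrix probes absent from the manifest", extra)
    for name, frame in (("meth", meth), ("unmeth", unmeth)):
        sub = frame.loc[keep]
        vals = sub.to_numpy()
        if (vals < 0).any():
            r, c = np.argwhere(vals < 0)[0]
            raise ValidationError(
                f"negative intensity in {name} matrix at probe "
                f"{sub.index[r]!r}, sample {sub.columns[c]!r}"
            )
    return IntensitySet(
        meth=meth.loc[keep], unmeth=unmeth.loc[keep], annotations=ann.loc[keep]
    )


def write_intensity_set(
    data: IntensitySet,
    meth_path: str | Path,
    unmeth_path: str | Path,
    manifest_path: str | Path | None = None,
) -> None:
    """Write an intensity set back to the TSV/CSV formats read above."""
    for frame, path in ((data.meth, meth_path), (data.unmeth, unmeth_path)):
        out = frame.copy()
        out.index.name = "probe_id"
        out.to_csv(path, sep="\t", float_format="%.6g")
    if manifest_path is not None:
        write_manifest(data.annotations, manifest_path)


def read_control_pairs(path: str | Path) -> ControlPairTable:
    """Read a control-pair TSV into a validated :class:`ControlPairTable`.

    Zero or negative intensities are floored to the shared intensity floor;
    the number of floored entries is logged.
    """
    frame = pd.read_csv(path, sep="\t", dtype={c: str for c in CONTROL_KEY_COLUMNS})
    for col in CONTROL_KEY_COLUMNS:
        if col not in frame.columns:
            raise FormatError(f"control table {path} is missing column {col!r}")
    value_cols = [c for c in frame.columns if c not in CONTROL_KEY_COLUMNS]
    red_cols = [c for c in value_cols if c.endswith(".red")]
    grn_cols = [c for c in value_cols if c.endswith(".grn")]
    samples = [c[: -len(".red")] for c in red_cols]
    grn_samples = [c[: -len(".grn")] for c in grn_cols]
    if samples != grn_samples:
        raise FormatError(
            f"control table {path}: red columns imply samples {samples} but "
            f"green columns imply {grn_samples}"
        )
    if not samples:
        raise FormatError(f"control table {path} has no <sample>.red/.grn columns")
    if frame["pair_id"].duplicated().any():
        dup = frame["pair_id"][frame["pair_id"].duplicated()].iloc[0]
        raise ValidationError(f"control table {path}: duplicated pair_id {dup!r}")
    if len(frame) < ControlPairTable.MIN_PAIRS:
        raise InsufficientControlsError(
            f"control table {path} has {len(frame)} pairs; at least "
            f"{ControlPairTable.MIN_PAIRS} required"
        )
    index = pd.Index(frame["pair_id"], name="pair_id")
    red = pd.DataFrame(
        frame[red_cols].to_numpy(dtype=float), index=index, columns=samples
    )
    green = pd.DataFrame(
        frame[grn_cols].to_numpy(dtype=float), index=index, columns=samples
    )
    table = ControlPairTable(
        red=red,
        green=green,
        red_probe_ids=pd.Series(frame["red_probe_id"].to_numpy(), index=index),
        green_probe_ids=pd.Series(frame["green_probe_id"].to_numpy(), index=index),
        floor=True,
    )
    if table.n_floored:
        logger.warning(
            "floored %d non-positive control intensities in %s",
            table.n_floored,
            path,
        )
    return table


def write_control_pairs(table: ControlPairTable, path: str | Path) -> None:
    out = pd.DataFrame(
        {
            "pair_id": table.pair_ids,
            "red_probe_id": table.red_probe_ids.to_numpy(),
            "green_probe_id": table.green_probe_ids.to_numpy(),
        }
    )
    for sample in table.sample_ids:
        out[f"{sample}.red"] = table.red[sample].to_numpy()
        out[f"{sample}.grn"] = table.green[sample].to_numpy()
    out.to_csv(path, sep="\t", index=False, float_format="%.6g")


def _numeric_suffix(probe_id: str) -> tuple[int, str]:
    """Sort key: trailing integer if present, then the full name."""
    match = re.search(r"(\d+)$", probe_id)
    return (int(match.group(1)) if match else -1, probe_id)


def pair_controls_from_manifest(
    control_probes: Iterable[tuple[str, str]],
) -> list[tuple[str, str]]:
    """Pair red-family and green-family control probes by rank.

    Illumina manifests list NORM_A/T/G/C control probes without an explicit
    pair key, so pairs are formed deterministically: red-family (NORM_A and
    NORM_T) and green-family (NORM_G and NORM_C) probe names are each sorted
    by numeric suffix and paired by rank.  Unbalanced families are truncated
    to the shorter list with a logged warning.
    """
    red_family: list[str] = []
    green_family: list[str] = []
    for probe_id, control_type in control_probes:
        if control_type in RED_CONTROL_FAMILIES:
            red_family.append(probe_id)
        elif control_type in GREEN_CONTROL_FAMILIES:
            green_family.append(probe_id)
        else:
            raise ValidationError(
                f"probe {probe_id!r}: unknown control type {control_type!r} "
                f"(expected one of "
                f"{RED_CONTROL_FAMILIES + GREEN_CONTROL_FAMILIES})"
            )
    red_family.sort(key=_numeric_suffix)
    green_family.sort(key=_numeric_suffix)
    n = min(len(red_family), len(green_family))
    if len(red_family) != len(green_family):
        logger.warning(
            "unbalanced control families (%d red, %d green); truncating to %d pairs",
            len(red_family),
            len(green_family),
            n,
        )
    return list(zip(red_family[:n], green_family[:n]))


def write_fits(fits: Sequence, path: str | Path) -> None:
    """Write per-sample regression coefficients as a TSV."""
    pd.DataFrame(
        {
            "sample_id": [f.sample_id for f in fits],
            "beta0": [f.beta0 for f in fits],
            "beta1": [f.beta1 for f in fits],
            "n_pairs": [f.n_pairs for f in fits],
            "r_squared": [f.r_squared for f in fits],
        }
    ).to_csv(path, sep="\t", index=False)
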