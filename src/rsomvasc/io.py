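"""Volume and feature-table I/O plus the dual-band composite rendering.

Volumes are stored either as a single multi-page TIFF / 4D NIfTI holding both
frequency bands, or as two paired single-band files.  Feature tables are CSV;
the canonical layout is long format with one row per
(subject, timepoint, feature).
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import tifffile

from .core import (
    COVARIATE_NAMES,
    FEATURE_NAMES,
    TIMEPOINTS,
    CohortTable,
    DualBandVolume,
    ValidationError,
    VolumeFormatError,
    logger,
)

_SPACING_KEY = "spacing_um"


# ---------------------------------------------------------------------------
# Volumes
# ---------------------------------------------------------------------------

def write_volume(volume: DualBandVolume, path, format: str | None = None) -> None:
    """Write both bands to one file (TIFF stores a (2, z, y, x) page stack,
    NIfTI a (z, y, x, 2) array with the voxel spacing in the header zooms)."""
    path = Path(path)
    fmt = format or _infer_format(path)
    stack = np.stack([volume.low, volume.high])
    if fmt == "tiff":
        tifffile.imwrite(
            path,
            stack,
            description=json.dumps({_SPACING_KEY: list(volume.spacing)}),
        )
    elif fmt == "nifti":
        data = np.moveaxis(stack, 0, -1)  # (z, y, x, 2)
        img = nib.Nifti1Image(data, affine=np.diag([*volume.spacing, 1.0]))
        img.header.set_zooms((*volume.spacing, 1.0))
        nib.save(img, path)
    else:
        raise VolumeFormatError(f"unknown volume format {fmt!r}")


def read_volume(path, format: str | None = None,
                spacing: tuple[float, float, float] | None = None) -> DualBandVolume:
    """Read a dual-band volume.

    ``path`` may be a single two-channel file or a ``(low_path, high_path)``
    pair of single-band files.  ``spacing`` overrides any header spacing.
    """
    if isinstance(path, (tuple, list)):
        if len(path) != 2:
            raise VolumeFormatError("paired input must be (low_path, high_path)")
        low, sp_l = _read_single(Path(path[0]), format)
        high, sp_h = _read_single(Path(path[1]), format)
        if low.shape != high.shape:
            raise VolumeFormatError("paired band files have different shapes")
        header_spacing = sp_l or sp_h
        stack = np.stack([low, high])
    else:
        path = Path(path)
        fmt = format or _infer_format(path)
        if fmt == "tiff":
            with tifffile.TiffFile(path) as tif:
                arr = tif.asarray()
                header_spacing = _tiff_spacing(tif)
        elif fmt == "nifti":
            img = nib.load(path)
            arr = np.asarray(img.dataobj)
            if arr.ndim == 4:
                arr = np.moveaxis(arr, -1, 0)
            header_spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
        else:
            raise VolumeFormatError(f"unknown volume format {fmt!r}")
        if arr.ndim != 4 or arr.shape[0] != 2:
            raise VolumeFormatError(
                f"expected two co-registered bands, got array of shape {arr.shape}"
            )
        stack = arr
    final_spacing = spacing or header_spacing or (10.0, 10.0, 10.0)
    if any(s <= 0 for s in final_spacing):
        raise ValidationError(f"non-positive voxel spacing {final_spacing}")
    return DualBandVolume(stack[0], stack[1], tuple(final_spacing))


def _infer_format(path: Path) -> str:
    suffixes = "".join(path.suffixes).lower()
    if suffixes.endswith((".tif", ".tiff")):
        return "tiff"
    if suffixes.endswith((".nii", ".nii.gz")):
        return "nifti"
    raise VolumeFormatError(f"cannot infer volume format from {path.name!r}")


def _read_single(path: Path, format: str | None):
    fmt = format or _infer_format(path)
    if fmt == "tiff":
        with tifffile.TiffFile(path) as tif:
            return tif.asarray(), _tiff_spacing(tif)
    img = nib.load(path)
    return np.asarray(img.dataobj), tuple(float(z) for z in img.header.get_zooms()[:3])


def _tiff_spacing(tif) -> tuple[float, float, float] | None:
    desc = tif.pages[0].description
    try:
        meta = json.loads(desc)
        return tuple(float(s) for s in meta[_SPACING_KEY])
    except (TypeError, ValueError, KeyError):
        return None


# ---------------------------------------------------------------------------
# Composite rendering
# ---------------------------------------------------------------------------

def render_composite(volume: DualBandVolume, projection_axis: int = 1) -> np.ndarray:
    """Green–yellow–red maximum-intensity-projection composite.

    The low band (larger microvessels) drives the red channel, the high band
    (smaller microvessels) the green channel; voxels where both bands project
    render yellow.  Each channel is min–max scaled independently, so the
    rendering is invariant to a common positive intensity rescaling.
    """
    if projection_axis not in (1, 2):
        raise ValueError("projection_axis must be a lateral axis (1 or 2)")
    red = volume.low.max(axis=projection_axis)
    green = volume.high.max(axis=projection_axis)
    rgb = np.zeros((*red.shape, 3), dtype=np.float64)
    rgb[..., 0] = _minmax(red)
    rgb[..., 1] = _minmax(green)
    return rgb


def _minmax(img: np.ndarray) -> np.ndarray:
    lo, hi = float(img.min()), float(img.max())
    if hi <= lo:
        return np.zeros_like(img)
    return (img - lo) / (hi - lo)


# ---------------------------------------------------------------------------
# Feature tables
# ---------------------------------------------------------------------------

_LONG_COLUMNS = ["subject", "group", *COVARIATE_NAMES, "timepoint", "feature", "value"]


def write_feature_table(table: CohortTable, path, wide: bool = False) -> None:
    """Write a cohort table to CSV (long format canonical; wide optional)."""
    path = Path(path)
    if wide:
        df = table.features.reset_index()
        df.columns = ["subject", "timepoint", *FEATURE_NAMES]
        df = df.merge(table.covariates.reset_index(names="subject"), on="subject")
        df.to_csv(path, index=False, float_format="%.17g")
        return
    rows = table.features.stack(future_stack=True).rename("value").reset_index()
    rows.columns = ["subject", "timepoint", "feature", "value"]
    cov = table.covariates.reset_index(names="subject")
    long = rows.merge(cov, on="subject")[_LONG_COLUMNS]
    long.to_csv(path, index=False, float_format="%.17g")


def read_feature_table(path) -> CohortTable:
    """Read a long-format feature CSV back into a validated CohortTable."""
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in _LONG_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"feature table missing columns: {missing}")
    unknown = sorted(set(df["feature"]) - set(FEATURE_NAMES))
    if unknown:
        raise ValidationError(f"unknown feature column(s): {unknown}")
    features = (
        df.pivot_table(index=["subject", "timepoint"], columns="feature",
                       values="value", aggfunc="first", dropna=False)
        .reindex(columns=list(FEATURE_NAMES))
    )
    # restore protocol ordering of the timepoint level
    features = features.reindex(
        pd.MultiIndex.from_product(
            [features.index.get_level_values(0).unique(), TIMEPOINTS],
            names=["subject", "timepoint"],
        )
    )
    present = df.groupby("subject")["timepoint"].apply(lambda s: set(s))
    bad = [s for s, tps in present.items() if tps != set(TIMEPOINTS)]
    if bad:
        raise ValidationError(
            f"subject(s) {bad} lack the full six-timepoint protocol"
        )
    cov = (
        df[["subject", "group", *COVARIATE_NAMES]]
        .drop_duplicates("subject")
        .set_index("subject")
    )
    table = CohortTable(features=features, covariates=cov)
    logger.debug("read cohort of %d subjects from %s", len(table.subjects), path)
    return table
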