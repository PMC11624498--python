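"""Epidermis surface detection and dermis (DE) / vessel segmentation.

The dermis — the vascularised layer of the skin — is the analysis volume for
all features.  The epidermis is handled as a fixed-thickness band below the
detected skin surface (a reproducible stand-in for signal-based
dermo-epidermal junction detection); the DE band extends a configurable depth
below it.  Depth is measured along the z axis only, adequate for the small
surface tilt at mesoscopy scale.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .core import DualBandVolume, SkinMask, ValidationError, logger

#: Fraction of the peak smoothed depth-profile intensity that counts as a
#: "sustained rise" when locating the skin surface.
_RISE_FRACTION = 0.25
_SUSTAIN_VOXELS = 2


def detect_surface(volume: DualBandVolume, smooth_window: float = 50.0) -> np.ndarray:
    """Per-column depth (um) of the first sustained intensity rise.

    The summed-band volume is smoothed along depth; each lateral column is
    scanned for the first run of ``_SUSTAIN_VOXELS`` voxels above a fraction
    of the global profile maximum.  Columns with no signal are filled from
    their nearest detected neighbour, then the map is median-smoothed
    laterally over ``smooth_window`` micrometres.
    """
    combined = volume.combined()
    if not np.any(combined > 0):
        raise ValidationError("cannot detect a surface in an all-zero volume")
    dz, dy, dx = volume.spacing
    smoothed = ndimage.uniform_filter1d(combined, size=3, axis=0)
    thr = _RISE_FRACTION * smoothed.max()
    above = smoothed > thr
    # sustained rise: above threshold here and for the next m-1 voxels
    sustained = above.copy()
    for k in range(1, _SUSTAIN_VOXELS):
        shifted = np.zeros_like(above)
        shifted[:-k] = above[k:]
        sustained &= shifted if k else sustained
    hit = sustained.any(axis=0)
    first = np.where(hit, sustained.argmax(axis=0), -1)
    if not hit.any():
        raise ValidationError("no column shows a sustained intensity rise")
    # the depth smoothing smears intensity one voxel upward; refine each
    # column to the first voxel whose raw value clears the threshold
    raw_above = combined > thr
    ny, nx = hit.shape
    iy, ix = np.meshgrid(np.arange(ny), np.arange(nx), indexing="ij")
    for _ in range(2):
        idx = np.clip(first, 0, combined.shape[0] - 1)
        advance = hit & ~raw_above[idx, iy, ix] & (first < combined.shape[0] - 1)
        if not advance.any():
            break
        first = first + advance
    first = first.astype(float)
    first[~hit] = -1.0
    if (~hit).any():
        # fill empty columns from nearest detected neighbour
        _, (iy, ix) = ndimage.distance_transform_edt(
            ~hit, sampling=(dy, dx), return_indices=True
        )
        first = first[iy, ix]
        logger.debug("surface: filled %d empty columns", int((~hit).sum()))
    win_y = max(1, int(round(smooth_window / dy)) | 1)
    win_x = max(1, int(round(smooth_window / dx)) | 1)
    first = ndimage.median_filter(first, size=(win_y, win_x), mode="nearest")
    # voxel-centre convention: keeps the epidermis band boundary aligned with
    # the (index + 0.5) depth grid used by segment_dermis
    return (first + 0.5) * dz


def segment_dermis(
    volume: DualBandVolume,
    surface_depth: np.ndarray,
    epidermis_thickness: float = 100.0,
    de_depth: float = 500.0,
) -> SkinMask:
    """Mask the DE band: depths in (surface + epidermis, surface + epidermis + de_depth]."""
    dz = volume.spacing[0]
    nz = volume.shape[0]
    z = (np.arange(nz) + 0.5) * dz
    top = surface_depth + epidermis_thickness
    bottom = top + de_depth
    de_mask = (z[:, None, None] > top[None, :, :]) & (z[:, None, None] <= bottom[None, :, :])
    if (bottom > nz * dz).any():
        logger.warning(
            "DE band exceeds volume depth for %d columns; clipped",
            int((bottom > nz * dz).sum()),
        )
    return SkinMask(surface_depth=surface_depth, de_mask=de_mask)


def segment_vessels(
    volume: DualBandVolume,
    mask: SkinMask,
    method: str = "otsu_band",
    percentile: float = 95.0,
    min_size: int = 27,
) -> np.ndarray:
    """Segment vessel voxels inside the DE band.

    A threshold is computed per frequency band from the in-band intensities
    within the DE mask (Otsu by default, a fixed upper percentile otherwise);
    the two band masks are unioned and connected components smaller than
    ``min_size`` voxels are removed.  Both methods are relative, so the
    segmentation is invariant to global positive intensity scaling.
    """
    de = mask.de_mask
    if not de.any():
        raise ValidationError("empty DE mask")
    vessel = np.zeros(de.shape, dtype=bool)
    for band in (volume.low, volume.high):
        vals = band[de]
        if np.ptp(vals) == 0:
            continue  # constant band inside the DE carries no vessel signal
        if method == "otsu_band":
            thr = threshold_otsu(vals)
            # a band with no vessels is pure noise; Otsu then splits the
            # noise itself.  Require the threshold to clear the noise floor
            # of the sub-threshold population (scale-free check).
            below = vals[vals <= thr]
            if below.size and thr <= below.mean() + 5.0 * below.std():
                logger.debug("segment_vessels: band below noise floor; skipped")
                continue
        elif method == "fixed_percentile":
            thr = np.percentile(vals, percentile)
        else:
            raise ValidationError(f"unknown segmentation method {method!r}")
        vessel |= de & (band > thr)
    if min_size > 1 and vessel.any():
        labels, n = ndimage.label(vessel, structure=np.ones((3, 3, 3), dtype=bool))
        if n:
            sizes = np.bincount(labels.ravel())
            small = np.flatnonzero(sizes < min_size)
            vessel &= ~np.isin(labels, small[small > 0])
    mask.vessel_mask = vessel
    return vessel
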