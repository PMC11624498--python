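"""Shared domain types, feature registry, timeline constants and configuration.

The package analyses raster-scan optoacoustic mesoscopy (RSOM) volumes of
human skin acquired during a post-occlusive reactive hyperemia (PORH) test:
one volume per minute — a baseline scan, three scans under brachial cuff
occlusion, and two scans after cuff release.  Every imaging stage consumes a
:class:`DualBandVolume`: two co-registered intensity grids reconstructed from
the low (10–40 MHz, larger microvessels) and high (40–120 MHz, smaller
microvessels) ultrasound frequency bands.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("rsomvasc")


class VolumeFormatError(ValueError):
    """Raised when a volume file does not contain two co-registered bands."""


class ValidationError(ValueError):
    """Raised when a domain object violates one of its invariants."""


# ---------------------------------------------------------------------------
# PORH timeline
# ---------------------------------------------------------------------------

#: Protocol order of the six per-minute acquisitions.
TIMEPOINTS: tuple[str, ...] = ("baseline", "occl1", "occl2", "occl3", "hyp1", "hyp2")

#: The five post-baseline timepoints for which percentage changes are defined.
POST_TIMEPOINTS: tuple[str, ...] = TIMEPOINTS[1:]


# ---------------------------------------------------------------------------
# Feature registry: the 18 dermal microvascular features
# ---------------------------------------------------------------------------

FEATURE_NAMES: tuple[str, ...] = (
    "avg_junction_angle",        # f1, degrees
    "avg_vessel_length",         # f2, um
    "avg_tortuosity",            # f3, unitless >= 1
    "length_to_width_ratio",     # f4, unitless
    "avg_vessel_diameter",       # f5, um
    "avg_vessel_volume",         # f6, um^3
    "num_vessels",               # f7, count
    "junction_density",          # f8, mm^-3
    "vascular_density",          # f9, fraction of DE voxels
    "junctions_to_vessels_ratio",  # f10, unitless
    "num_j2j_branches",          # f11, count
    "num_j2e_branches",          # f12, count
    "num_junctions",             # f13, count
    "de_thickness",              # f14, um
    "total_vessel_area",         # f15, mm^2 (en-face projection)
    "mean_signal_vessels",       # f16, a.u.
    "mean_signal_de",            # f17, a.u.
    "de_area",                   # f18, mm^2 (side projection)
)

FEATURE_UNITS: dict[str, str] = {
    "avg_junction_angle": "deg",
    "avg_vessel_length": "um",
    "avg_tortuosity": "1",
    "length_to_width_ratio": "1",
    "avg_vessel_diameter": "um",
    "avg_vessel_volume": "um^3",
    "num_vessels": "count",
    "junction_density": "mm^-3",
    "vascular_density": "1",
    "junctions_to_vessels_ratio": "1",
    "num_j2j_branches": "count",
    "num_j2e_branches": "count",
    "num_junctions": "count",
    "de_thickness": "um",
    "total_vessel_area": "mm^2",
    "mean_signal_vessels": "a.u.",
    "mean_signal_de": "a.u.",
    "de_area": "mm^2",
}

#: Scale-of-detail classes.  Microscale: single-vessel parameters.  Mesoscale:
#: network-organisation parameters.  Macroscale: whole-layer parameters.
#: Overridable via :class:`PipelineConfig.scale_map`.
DEFAULT_SCALE_MAP: dict[str, str] = {
    **{f: "micro" for f in FEATURE_NAMES[0:6]},
    **{f: "meso" for f in FEATURE_NAMES[6:13]},
    **{f: "macro" for f in FEATURE_NAMES[13:18]},
}

SCALES: tuple[str, ...] = ("micro", "meso", "macro")

#: Per-subject covariate columns carried alongside the group label.
COVARIATE_NAMES: tuple[str, ...] = (
    "age", "sex", "bmi", "hypertension", "smoking", "hyperlipidemia", "diabetes",
)


# ---------------------------------------------------------------------------
# Volumes
# ---------------------------------------------------------------------------

@dataclass
class DualBandVolume:
    """Co-registered low/high frequency-band intensity grids.

    Axis convention: axis 0 is depth ``z`` increasing into the skin, axes 1-2
    are the lateral scan axes ``(y, x)``.  ``spacing`` is ``(dz, dy, dx)`` in
    micrometres.  Intensities are non-negative and stored as float64.
    """

    low: np.ndarray
    high: np.ndarray
    spacing: tuple[float, float, float] = (10.0, 10.0, 10.0)

    def __post_init__(self) -> None:
        self.low = np.asarray(self.low, dtype=np.float64)
        self.high = np.asarray(self.high, dtype=np.float64)
        self.spacing = tuple(float(s) for s in self.spacing)
        if self.low.ndim != 3 or self.low.shape != self.high.shape:
            raise ValidationError(
                f"bands must be 3D with equal shapes, got {self.low.shape} "
                f"and {self.high.shape}"
            )
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValidationError(f"spacing must be three positive values, got {self.spacing}")
        if (self.low < 0).any() or (self.high < 0).any():
            raise ValidationError("intensities must be non-negative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.low.shape

    def combined(self) -> np.ndarray:
        """Summed-band intensity, used for surface detection and signal features."""
        return self.low + self.high

    def voxel_volume_um3(self) -> float:
        dz, dy, dx = self.spacing
        return dz * dy * dx


@dataclass
class SkinMask:
    """Epidermis surface depth map plus dermis (DE) and vessel masks.

    ``surface_depth`` gives, per lateral column ``(y, x)``, the depth of the
    skin surface in micrometres.  ``de_mask`` marks the dermis band and
    ``vessel_mask`` the segmented vasculature inside it.
    """

    surface_depth: np.ndarray
    de_mask: np.ndarray
    vessel_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.de_mask = np.asarray(self.de_mask, dtype=bool)
        if self.vessel_mask is not None:
            self.vessel_mask = np.asarray(self.vessel_mask, dtype=bool)
            if self.vessel_mask.shape != self.de_mask.shape:
                raise ValidationError("vessel_mask and de_mask shapes differ")
            if (self.vessel_mask & ~self.de_mask).any():
                raise ValidationError("vessel_mask must be a subset of de_mask")


# ---------------------------------------------------------------------------
# Cohort table
# ---------------------------------------------------------------------------

@dataclass
class CohortTable:
    """Subjects x timepoints x features, plus group label and covariates.

    ``features``: DataFrame indexed by ``(subject, timepoint)`` with one column
    per feature in :data:`FEATURE_NAMES`.  ``covariates``: DataFrame indexed by
    subject with a binary ``group`` column (0 healthy, 1 patient) and the
    :data:`COVARIATE_NAMES` columns.
    """

    features: pd.DataFrame
    covariates: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        feats = self.features
        if list(feats.columns) != list(FEATURE_NAMES):
            unknown = [c for c in feats.columns if c not in FEATURE_NAMES]
            if unknown:
                raise ValidationError(f"unknown feature columns: {unknown}")
            missing = [c for c in FEATURE_NAMES if c not in feats.columns]
            raise ValidationError(f"missing feature columns: {missing}")
        if feats.index.nlevels != 2:
            raise ValidationError("features must be indexed by (subject, timepoint)")
        for subject, sub in feats.groupby(level=0, sort=False):
            tps = list(sub.index.get_level_values(1))
            if sorted(tps) != sorted(TIMEPOINTS):
                raise ValidationError(
                    f"subject {subject!r} has timepoints {tps}; expected the "
                    f"six-phase protocol {list(TIMEPOINTS)}"
                )
        cov_required = ["group", *COVARIATE_NAMES]
        missing_cov = [c for c in cov_required if c not in self.covariates.columns]
        if missing_cov:
            raise ValidationError(f"missing covariate columns: {missing_cov}")
        subj_f = set(feats.index.get_level_values(0))
        subj_c = set(self.covariates.index)
        if subj_f != subj_c:
            raise ValidationError(
                f"feature/covariate subject mismatch: {sorted(subj_f ^ subj_c)}"
            )

    @property
    def subjects(self) -> list:
        return list(self.covariates.index)

    @property
    def groups(self) -> pd.Series:
        return self.covariates["group"]

    def at_timepoint(self, timepoint: str) -> pd.DataFrame:
        """Feature matrix (subjects x features) at one timepoint."""
        out = self.features.xs(timepoint, level=1)
        return out.loc[self.subjects]


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Tunable parameters of the imaging pipeline, round-trippable to YAML."""

    spacing_um: tuple[float, float, float] = (10.0, 10.0, 10.0)
    epidermis_um: float = 100.0
    de_um: float = 500.0
    band_threshold_um: float = 30.0       # mean branch radius separating bands
    threshold_method: str = "otsu_band"   # or "fixed_percentile"
    threshold_percentile: float = 95.0
    min_component_size: int = 27
    prune_len_um: float = 50.0
    tangent_k: int = 3
    surface_smooth_um: float = 50.0
    scale_map: dict = field(default_factory=lambda: dict(DEFAULT_SCALE_MAP))

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["spacing_um"] = list(d["spacing_um"])
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            d = yaml.safe_load(fh) or {}
        if "spacing_um" in d:
            d["spacing_um"] = tuple(d["spacing_um"])
        return cls(**d)


def feature_series(values: dict[str, float] | Sequence[float]) -> pd.Series:
    """Build a feature vector (pandas Series over :data:`FEATURE_NAMES`)."""
    if isinstance(values, dict):
        s = pd.Series({k: float(v) for k, v in values.items()}, dtype=float)
        unknown = [k for k in s.index if k not in FEATURE_NAMES]
        if unknown:
            raise ValidationError(f"unknown features: {unknown}")
        return s.reindex(FEATURE_NAMES)
    arr = np.asarray(list(values), dtype=float)
    if arr.shape != (len(FEATURE_NAMES),):
        raise ValidationError(f"expected {len(FEATURE_NAMES)} values, got {arr.shape}")
    return pd.Series(arr, index=list(FEATURE_NAMES))
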