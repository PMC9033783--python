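"""Analysis configuration.

A single :class:`AnalysisConfig` object travels through the whole pipeline
so that every policy decision (papillary accounting, slice-interval choice,
base direction, ...) is stated once and recorded in output headers.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .errors import ConfigurationError

#: Canonical contour-type vocabulary.
CONTOUR_NAMES = ("lv_endo", "lv_myo", "rv_endo", "lv_papillary")

#: Contour types that enter the metric tables (papillary muscles are an
#: accounting choice, not a reported column).
REPORTED_CONTOURS = ("lv_endo", "lv_myo", "rv_endo")

PAPILLARY_POLICIES = ("papillary_in_cavity", "papillary_in_mass")
SLICE_INTERVAL_POLICIES = ("auto", "thickness", "spacing")
BASE_DIRECTIONS = ("auto", "low", "high")


@dataclass
class AnalysisConfig:
    """Pipeline-wide policy settings.

    Parameters
    ----------
    contour_aliases
        Maps vendor or reader-specific contour names onto the canonical
        vocabulary, e.g. ``{"sax_lv_endo": "lv_endo"}``.
    papillary_policy
        ``papillary_in_cavity``: papillary contours are ignored for volumes
        and mass (the cavity includes the papillary muscles).
        ``papillary_in_mass``: papillary area is subtracted from the LV
        cavity and papillary volume times density is added to the mass.
    myocardial_density
        Tissue density in g/ml used to turn myocardial volume into mass.
    slice_interval_policy
        ``auto``: use SpacingBetweenSlices when present, else
        SliceThickness; ``thickness``/``spacing`` force one source.
    base_direction
        Which end of the slice stack is basal: ``low``/``high`` slice
        location, or ``auto`` (the end with the larger end-diastolic LV
        cavity area).
    densify_mm
        Maximum boundary-segment length (mm) before discrete Hausdorff
        computation.
    slice_group_tolerance_mm
        Slice locations closer than this are treated as one slice.
    allow_unknown_contours
        Pass through unrecognised contour names instead of raising.
    """

    contour_aliases: dict[str, str] = field(default_factory=dict)
    papillary_policy: str = "papillary_in_cavity"
    myocardial_density: float = 1.05
    slice_interval_policy: str = "auto"
    base_direction: str = "auto"
    densify_mm: float = 0.5
    slice_group_tolerance_mm: float = 0.5
    allow_unknown_contours: bool = False

    def __post_init__(self) -> None:
        if self.papillary_policy not in PAPILLARY_POLICIES:
            raise ConfigurationError(
                f"papillary_policy must be one of {PAPILLARY_POLICIES}, "
                f"got {self.papillary_policy!r}")
        if self.slice_interval_policy not in SLICE_INTERVAL_POLICIES:
            raise ConfigurationError(
                f"slice_interval_policy must be one of "
                f"{SLICE_INTERVAL_POLICIES}, got {self.slice_interval_policy!r}")
        if self.base_direction not in BASE_DIRECTIONS:
            raise ConfigurationError(
                f"base_direction must be one of {BASE_DIRECTIONS}, "
                f"got {self.base_direction!r}")
        if self.myocardial_density <= 0:
            raise ConfigurationError("myocardial_density must be > 0")
        if self.densify_mm <= 0:
            raise ConfigurationError("densify_mm must be > 0")
        if self.slice_group_tolerance_mm < 0:
            raise ConfigurationError("slice_group_tolerance_mm must be >= 0")

    def resolve_contour_name(self, name: str) -> str:
        """Map a raw contour name onto the canonical vocabulary."""
        return self.contour_aliases.get(name, name)

    def hash(self) -> str:
        """Short stable digest of the configuration, for file headers."""
        payload = json.dumps(asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)
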