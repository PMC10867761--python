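"""NV / VO area ratios from externally produced pathology masks.

Neovascularization (NV) and vaso-obliteration (VO) masks are produced
upstream (e.g. by a dedicated deep-learning segmenter); this module only
turns them into area fractions and records expert manual overrides.  The
denominator defaults to the whole image (the operative region of a cropped
flat-mount leaflet); an optional retina-region mask refines it.

Automated VO calls on normoxic retinas are a known failure mode (light
pigmentation read as avascularity); the override mechanism exists so an
expert can zero such ratios while keeping full provenance of the original
value and the reason.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ValidationError
from .mask_io import BinaryMask

__all__ = ["PathologyRatios", "Override", "area_ratio", "apply_override"]


@dataclass(frozen=True)
class Override:
    """Provenance record of one manual override."""

    which: str  # "nv" or "vo"
    original_value: float
    new_value: float
    reason: str


@dataclass(frozen=True)
class PathologyRatios:
    """NV and VO area fractions of one image, with override provenance."""

    image_id: str
    nv_ratio: float
    vo_ratio: float
    overrides: tuple[Override, ...] = ()

    def __post_init__(self) -> None:
        for name, v in (("nv_ratio", self.nv_ratio), ("vo_ratio", self.vo_ratio)):
            if not (0.0 <= v <= 1.0):
                raise ValidationError(f"{name} must be in [0, 1], got {v}")

    @property
    def nv_overridden(self) -> bool:
        return any(o.which == "nv" for o in self.overrides)

    @property
    def vo_overridden(self) -> bool:
        return any(o.which == "vo" for o in self.overrides)


def area_ratio(
    pathology: BinaryMask, denominator: BinaryMask | None = None
) -> float:
    """Fraction of the denominator region covered by the pathology mask.

    With ``denominator=None`` the denominator is the whole image.  With a
    region mask, the ratio is |pathology ∩ region| / |region|.
    """
    if denominator is None:
        denom_n = pathology.pixels.size
        inter = int(pathology.pixels.sum())
    else:
        if pathology.shape != denominator.shape:
            raise ValidationError(
                f"shape mismatch: {pathology.shape} vs {denominator.shape}"
            )
        denom_n = int(denominator.pixels.sum())
        if denom_n == 0:
            raise ValidationError("denominator mask is empty")
        inter = int(np.logical_and(pathology.pixels, denominator.pixels).sum())
    return inter / denom_n


def apply_override(
    ratios: PathologyRatios, override_value: float, which: str, reason: str
) -> PathologyRatios:
    """Replace one ratio with an expert-supplied value, recording provenance."""
    which = which.lower()
    if which not in ("nv", "vo"):
        raise ValidationError(f"which must be 'nv' or 'vo', got {which!r}")
    if not (0.0 <= override_value <= 1.0):
        raise ValidationError(f"override value must be in [0, 1], got {override_value}")
    if not reason or not reason.strip():
        raise ValidationError("an override requires a non-empty reason")
    original = ratios.nv_ratio if which == "nv" else ratios.vo_ratio
    rec = Override(
        which=which, original_value=original, new_value=override_value, reason=reason
    )
    kwargs = {f"{which}_ratio": override_value, "overrides": ratios.overrides + (rec,)}
    return replace(ratios, **kwargs)
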