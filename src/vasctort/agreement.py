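"""Inter-grader segmentation agreement via the Dice coefficient.

Dice = 2|A ∩ B| / (|A| + |B|), the pixel-overlap agreement between two
binary segmentations of the same image.  With k graders the all-pairs
comparison yields k(k-1)/2 coefficients per image.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .mask_io import BinaryMask

__all__ = ["DiceResult", "dice_coefficient", "pairwise_dice"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DiceResult:
    image_id: str
    grader_a: str
    grader_b: str
    dice: float


def dice_coefficient(a: BinaryMask, b: BinaryMask) -> float:
    """Dice coefficient between two same-shape binary masks.

    Two empty masks agree vacuously and return 1.0 (with a warning: an
    all-empty pair is usually an input error rather than real agreement).
    """
    if a.shape != b.shape:
        raise ValidationError(f"mask shapes differ: {a.shape} vs {b.shape}")
    na = int(a.pixels.sum())
    nb = int(b.pixels.sum())
    if na + nb == 0:
        logger.warning(
            "dice_coefficient: both masks empty (%s, %s); returning 1.0",
            a.image_id,
            b.image_id,
        )
        return 1.0
    inter = int(np.logical_and(a.pixels, b.pixels).sum())
    return 2.0 * inter / (na + nb)


def pairwise_dice(
    masks: list[BinaryMask], graders: list[str], image_id: str = ""
) -> list[DiceResult]:
    """Dice coefficients for every unordered grader pair on one image."""
    if len(masks) < 2:
        raise ValidationError("pairwise_dice needs at least 2 masks")
    if len(masks) != len(graders):
        raise ValidationError("one grader label per mask is required")
    iid = image_id or masks[0].image_id
    results = []
    for (i, ga), (j, gb) in itertools.combinations(enumerate(graders), 2):
        results.append(
            DiceResult(
                image_id=iid,
                grader_a=ga,
                grader_b=gb,
                dice=dice_coefficient(masks[i], masks[j]),
            )
        )
    return results
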