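"""Registration-quality metrics: dice overlap, fiducial error, sensitivity.

Dice treats any pixel with intensity above 0 as tissue (there is no
separate noise segmentation for the moving modality).  FRE is the root
mean squared distance between corresponding landmark points, converted to
millimetres by the pixel spacing.  The sensitivity sweep probes a trained
similarity scorer with graded rotations and axis translations.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .simulate import _rotate, _translate
from .types import FiducialSet, ValidationError

log = logging.getLogger("massreg")


def dice(fixed: np.ndarray, transformed: np.ndarray) -> float:
    """Dice overlap 2|A.B| / (|A| + |B|) after binarising at intensity > 0.

    1 means complete overlap, 0 means no pixels in common.  Two empty masks
    are defined to agree perfectly (returns 1, with a log note).
    """
    fixed = np.asarray(fixed, float)
    transformed = np.asarray(transformed, float)
    if fixed.shape != transformed.shape:
        raise ValidationError(
            f"shape mismatch: {fixed.shape} vs {transformed.shape}"
        )
    a = fixed > 0
    b = transformed > 0
    total = int(a.sum()) + int(b.sum())
    if total == 0:
        log.warning("dice of two empty masks: defined as 1")
        return 1.0
    return 2.0 * int((a & b).sum()) / total


def fre(fids: FiducialSet) -> float:
    """Fiducial registration error in millimetres.

    RMS of the Euclidean distances between corresponding points, scaled by
    the pixel spacing.
    """
    d2 = ((fids.points_fixed - fids.points_moved) ** 2).sum(axis=1)
    return float(np.sqrt(d2.mean()) * fids.pixel_spacing_mm)


def sensitivity_sweep(
    scorer,
    masks: list[np.ndarray],
    rot_grid=tuple(range(3, 13)),
    trans_grid=tuple(range(0, 11)),
) -> pd.DataFrame:
    """Mean similarity score versus applied misalignment magnitude.

    For each grid value on each axis (rotation in degrees, x- and
    y-translation in pixels) every mask is transformed, paired with its
    original, scored by `scorer(fixed, moved)`, and the scores are averaged
    across masks.  Returns a tidy table with columns axis, magnitude,
    mean_score.
    """
    if not len(masks):
        raise ValidationError("sensitivity sweep needs at least one mask")
    if not len(rot_grid) and not len(trans_grid):
        raise ValidationError("empty sweep grid")
    from .siamese import SiameseNet, predict_similarity

    if isinstance(scorer, SiameseNet):
        model = scorer
        scorer = lambda f, m: predict_similarity(model, f, m)  # noqa: E731
    rows = []
    for r in rot_grid:
        scores = [scorer(m, _rotate(m, float(r))) for m in masks]
        rows.append(("rotation", float(r), float(np.mean(scores))))
    for t in trans_grid:
        scores = [scorer(m, _translate(m, (0, int(t)))) for m in masks]
        rows.append(("translation_x", float(t), float(np.mean(scores))))
    for t in trans_grid:
        scores = [scorer(m, _translate(m, (int(t), 0))) for m in masks]
        rows.append(("translation_y", float(t), float(np.mean(scores))))
    return pd.DataFrame(rows, columns=["axis", "magnitude", "mean_score"])
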