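"""M-mode seashore / stratosphere classification.

On M-mode, normal pleural sliding scatters granular speckle below the
pleural line (the seashore sign), while pneumothorax freezes the
sub-pleural field into horizontal lines (the stratosphere or barcode
sign). The pipeline finds the most hyperechoic contiguous line on the
screen, then scores the texture beneath it with the per-row temporal
coefficient of variation (cv = std/mean along the sweep): rows that are
constant in time have cv ~ 0, speckled rows have cv near the Rayleigh
value ~0.52. The ``barcode_fraction`` — the fraction of sub-pleural rows
with cv below ``cv_threshold`` — drives the call. cv is scale-free, so the
scores are invariant under global intensity rescaling.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Optional

import numpy as np

from .bmode import PleuralLineFit, PtxCall
from .errors import InsufficientDepthError
from .imaging import INDETERMINATE, MModeImage, NEGATIVE, POSITIVE


@dataclass(frozen=True)
class MModeParams:
    """Tunable thresholds of the M-mode pipeline."""

    line_threshold: float = 1.5  # pixel >= threshold * region mean counts as line
    min_contiguity: float = 0.6
    brightness_floor: float = 0.02
    margin_rows: int = 5  # skin-reverberation guard: top rows never host the line
    subpleural_gap: int = 3  # rows skipped below the line before texture scoring
    cv_threshold: float = 0.1  # a row with temporal cv below this reads as barcode
    barcode_threshold: float = 0.6  # barcode_fraction at/above this -> positive
    mean_floor: float = 0.02  # rows dimmer than this score cv = 0
    min_subpleural_rows: int = 8


@dataclass(frozen=True)
class MModeTextureScores:
    """granularity = mean per-row temporal cv; barcode_fraction = share of
    sub-pleural rows whose temporal cv falls below the threshold."""

    granularity: float
    barcode_fraction: float


def detect_pleural_line_mmode(
    image: MModeImage, params: Optional[MModeParams] = None
) -> PleuralLineFit:
    """Find the most hyperechoic contiguous horizontal line.

    Candidate rows start below ``margin_rows`` (near-field skin
    reverberations are never accepted as the pleura). A row qualifies when
    the fraction of time columns at or above ``line_threshold`` times the
    search-region mean meets ``min_contiguity``; the brightest qualifying
    row wins. The threshold reference is floored so a blank image yields
    no line.
    """
    params = params or MModeParams()
    px = image.pixels
    H, W = px.shape
    start = min(params.margin_rows, H - 1)
    region = px[start:, :]
    threshold = params.line_threshold * max(float(region.mean()), params.brightness_floor)
    best: Optional[tuple[float, int, float]] = None
    for r in range(start, H):
        row = px[r]
        contiguity = float((row >= threshold).mean())
        if contiguity >= params.min_contiguity:
            brightness = float(row.mean())
            if best is None or brightness > best[0]:
                best = (brightness, r, contiguity)
    if best is None:
        return PleuralLineFit(found=False, lateral_span=(0, W))
    brightness, row, contiguity = best
    return PleuralLineFit(
        found=True,
        depth_row=row,
        lateral_span=(0, W),
        brightness=brightness,
        contiguity=contiguity,
    )


def score_subpleural_texture(
    image: MModeImage,
    line: PleuralLineFit,
    params: Optional[MModeParams] = None,
) -> MModeTextureScores:
    """Per-row temporal coefficient of variation below the pleural line.

    Rows with mean below ``mean_floor`` (effectively black) score cv = 0 —
    an echo-free region cannot show granular motion, so it reads as
    barcode. Requires at least ``min_subpleural_rows`` rows below
    ``depth_row + subpleural_gap``.
    """
    params = params or MModeParams()
    px = image.pixels
    r0 = line.depth_row + params.subpleural_gap
    sub = px[r0:, :]
    if sub.shape[0] < params.min_subpleural_rows:
        raise InsufficientDepthError(
            f"need >= {params.min_subpleural_rows} rows below the pleural line; "
            f"got {sub.shape[0]}"
        )
    means = sub.mean(axis=1)
    stds = sub.std(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(means < params.mean_floor, 0.0, stds / np.maximum(means, 1e-12))
    return MModeTextureScores(
        granularity=float(cv.mean()),
        barcode_fraction=float((cv < params.cv_threshold).mean()),
    )


def classify_mmode(image: MModeImage, params: Optional[MModeParams] = None) -> PtxCall:
    """Three-valued M-mode call.

    No pleural line -> indeterminate (extends the B-mode rule); barcode
    fraction at or above the threshold -> positive (stratosphere sign);
    otherwise -> negative (seashore sign).
    """
    params = params or MModeParams()
    snapshot = asdict(params)
    line = detect_pleural_line_mmode(image, params)
    evidence: dict = {"pleural_line": line, "texture": None}
    if not line.found:
        return PtxCall(
            label=INDETERMINATE,
            evidence=evidence,
            params=snapshot,
            reason="pleural_line_not_found",
        )
    try:
        scores = score_subpleural_texture(image, line, params)
    except InsufficientDepthError:
        return PtxCall(
            label=INDETERMINATE,
            evidence=evidence,
            params=snapshot,
            reason="insufficient_subpleural_depth",
        )
    evidence["texture"] = scores
    label = POSITIVE if scores.barcode_fraction >= params.barcode_threshold else NEGATIVE
    return PtxCall(label=label, evidence=evidence, params=snapshot)
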