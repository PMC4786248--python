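"""B-mode pneumothorax detection pipeline.

The pipeline mirrors how a sonographer reads an intercostal view, stage by
stage:

1. :func:`detect_rib_shadows` — find dark posterior-shadow columns below
   the bright rib caps on the temporal median frame.
2. :func:`locate_intercostal_space` — the widest gap between two rib
   shadows, shrunk by a safety margin.
3. :func:`detect_pleural_line` — the brightest contiguous horizontal band
   strictly below the rib caps within the space.
4. :func:`measure_sliding` — integer-shift normalized cross-correlation of
   a thin sub-pleural strip between consecutive frames; "to and fro"
   requires at least one sign change in the displacement sequence, so a
   monotone drift never counts as sliding.
5. :func:`detect_reverberation` — vertical sub-pleural artifact bands
   (B-line / comet-tail-like) whose echoes penetrate to the bottom edge.

:func:`classify_bmode` combines the evidence by a fixed three-way rule:
no pleural line -> indeterminate; sliding or reverberation (signs of
apposed, aerated lung) -> negative; otherwise -> positive for
pneumothorax. Clinically, horizontal A-line reverberations accompany
pneumothorax while vertical B-lines exclude it; this pipeline follows the
rule that treats detected pleural-line reverberation as a negative
indicator and therefore models reverberation as vertical B-line bands.

All thresholds are repo-chosen defaults collected in :class:`BModeParams`.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Optional

import numpy as np

from .errors import TooFewFramesError
from .imaging import BModeClip, INDETERMINATE, NEGATIVE, POSITIVE

ColumnInterval = tuple[int, int]


@dataclass(frozen=True)
class BModeParams:
    """Tunable thresholds of the B-mode pipeline (all distances in px)."""

    shadow_factor: float = 0.5  # shadow column mean < factor * deep-half mean
    min_shadow_width: int = 8
    min_space_width: int = 20
    space_margin: int = 4  # shrink applied to each side of the rib gap
    line_threshold: float = 1.5  # pixel >= threshold * region mean counts as line
    min_contiguity: float = 0.6
    brightness_floor: float = 0.02  # guards the line test on near-black clips
    strip_offset: int = 2  # strip starts this many rows below the line
    strip_height: int = 6
    max_shift: int = 10
    amp_threshold: float = 1.5  # px of half peak-to-peak excursion
    artifact_threshold: float = 0.5  # vs pleural-line brightness
    min_penetration: float = 0.6  # fraction of sub-pleural rows echoing
    min_band_width: int = 3
    subpleural_gap: int = 4  # rows skipped below the line before scoring


@dataclass(frozen=True)
class RibShadow:
    """One posterior acoustic shadow: columns [start, stop), cap row, contrast."""

    start: int
    stop: int
    cap_depth_row: int
    shadow_contrast: float


@dataclass(frozen=True)
class RibShadowSet:
    shadows: tuple[RibShadow, ...]

    def __len__(self) -> int:
        return len(self.shadows)

    @property
    def intervals(self) -> list[ColumnInterval]:
        return [(s.start, s.stop) for s in self.shadows]

    @property
    def max_cap_depth(self) -> int:
        return max((s.cap_depth_row for s in self.shadows), default=0)


@dataclass(frozen=True)
class PleuralLineFit:
    found: bool
    depth_row: int = -1
    lateral_span: ColumnInterval = (0, 0)
    brightness: float = 0.0
    contiguity: float = 0.0


@dataclass(frozen=True)
class SlidingResult:
    """Per-pair lateral displacements (px, signed) and the to-and-fro call."""

    displacements: tuple[int, ...]
    amplitude_px: float
    sign_changes: int
    sliding_detected: bool


@dataclass(frozen=True)
class ReverbResult:
    """Per-column penetration scores over the space, and artifact bands."""

    penetration: tuple[float, ...]
    artifact_bands: tuple[ColumnInterval, ...]
    reverberation_detected: bool


@dataclass(frozen=True)
class PtxCall:
    """Three-valued pneumothorax call with per-stage evidence attached."""

    label: str
    evidence: dict
    params: dict
    reason: Optional[str] = None


def _true_runs(mask: np.ndarray) -> list[ColumnInterval]:
    """Maximal half-open runs of True in a 1-D boolean mask."""
    runs = []
    start = None
    for i, v in enumerate(mask):
        if v and start is None:
            start = i
        elif not v and start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, len(mask)))
    return runs


def detect_rib_shadows(
    clip: BModeClip, params: Optional[BModeParams] = None
) -> RibShadowSet:
    """Find posterior acoustic shadows on the temporal median frame.

    A shadow is a maximal run of columns (width >= ``min_shadow_width``)
    whose mean intensity over the deep half of the image falls below
    ``shadow_factor`` times the deep-half global mean. Each shadow's cap row
    is the brightest row above the deep half within the run.
    """
    params = params or BModeParams()
    med = clip.median_frame()
    H = med.shape[0]
    deep = med[H // 2 :, :]
    col_mean = deep.mean(axis=0)
    global_mean = float(deep.mean())
    mask = col_mean < params.shadow_factor * global_mean
    shadows = []
    for a, b in _true_runs(mask):
        if b - a < params.min_shadow_width:
            continue
        above = med[: H // 2, a:b].mean(axis=1)
        cap_row = int(np.argmax(above))
        inside = float(col_mean[a:b].mean())
        outside_cols = np.ones(med.shape[1], dtype=bool)
        outside_cols[a:b] = False
        outside = float(col_mean[outside_cols].mean()) if outside_cols.any() else 0.0
        contrast = max(0.0, 1.0 - inside / outside) if outside > 0 else 0.0
        shadows.append(RibShadow(a, b, cap_row, contrast))
    return RibShadowSet(shadows=tuple(shadows))


def locate_intercostal_space(
    shadows: RibShadowSet,
    image_width: int,
    params: Optional[BModeParams] = None,
) -> Optional[ColumnInterval]:
    """Widest gap between consecutive rib shadows, shrunk by the margin.

    Two discrete rib shadows are required; returns ``None`` when fewer
    exist or when the shrunk gap is narrower than ``min_space_width``.
    """
    params = params or BModeParams()
    ivs = sorted(shadows.intervals)
    if len(ivs) < 2:
        return None
    gaps = [(ivs[i][1], ivs[i + 1][0]) for i in range(len(ivs) - 1)]
    a, b = max(gaps, key=lambda g: g[1] - g[0])
    a += params.space_margin
    b -= params.space_margin
    if b - a < params.min_space_width:
        return None
    return (max(0, a), min(image_width, b))


def detect_pleural_line(
    clip: BModeClip,
    space: ColumnInterval,
    shadows: RibShadowSet,
    params: Optional[BModeParams] = None,
) -> PleuralLineFit:
    """Fit the pleural line within the intercostal space.

    Scans rows strictly below the deepest rib cap on the median frame. A
    row qualifies when its contiguity — the fraction of space columns at or
    above ``line_threshold`` times the search-region mean intensity — meets
    ``min_contiguity``; among qualifying rows the brightest wins. The
    threshold reference is floored at ``brightness_floor`` so an all-black
    clip yields no line rather than a degenerate fit.
    """
    params = params or BModeParams()
    med = clip.median_frame()
    H = med.shape[0]
    a, b = space
    start_row = shadows.max_cap_depth + 1
    if start_row >= H or b <= a:
        return PleuralLineFit(found=False, lateral_span=space)
    region = med[start_row:, a:b]
    threshold = params.line_threshold * max(float(region.mean()), params.brightness_floor)
    best: Optional[tuple[float, int, float]] = None
    for r in range(start_row, H):
        row = med[r, a:b]
        contiguity = float((row >= threshold).mean())
        if contiguity >= params.min_contiguity:
            brightness = float(row.mean())
            if best is None or brightness > best[0]:
                best = (brightness, r, contiguity)
    if best is None:
        return PleuralLineFit(found=False, lateral_span=space)
    brightness, row, contiguity = best
    return PleuralLineFit(
        found=True,
        depth_row=row,
        lateral_span=space,
        brightness=brightness,
        contiguity=contiguity,
    )


def _best_shift(a: np.ndarray, b: np.ndarray, max_shift: int) -> int:
    """Integer lateral shift of ``b`` relative to ``a`` maximizing NCC.

    Ties break toward the smallest |shift| (then toward the negative one),
    and strips without variance correlate to zero, so static or blank
    strips report zero displacement.
    """
    w = a.shape[1]
    ref = a[:, max_shift : w - max_shift]
    ref = ref - ref.mean()
    ref_norm = float(np.sqrt((ref**2).sum()))
    best_d, best_c = 0, -np.inf
    for d in sorted(range(-max_shift, max_shift + 1), key=lambda d: (abs(d), d)):
        win = b[:, max_shift + d : w - max_shift + d]
        win = win - win.mean()
        win_norm = float(np.sqrt((win**2).sum()))
        if ref_norm == 0.0 or win_norm == 0.0:
            c = 0.0
        else:
            c = float((ref * win).sum()) / (ref_norm * win_norm)
        if c > best_c + 1e-12:
            best_c, best_d = c, d
    return best_d


def measure_sliding(
    clip: BModeClip,
    line: PleuralLineFit,
    space: ColumnInterval,
    params: Optional[BModeParams] = None,
) -> SlidingResult:
    """Estimate frame-to-frame lateral displacement just below the pleural line.

    For each consecutive frame pair a strip of ``strip_height`` rows,
    starting ``strip_offset`` rows below the fitted line and restricted to
    the space columns, is matched by integer-shift normalized
    cross-correlation over +-``max_shift`` px. Sliding is called when the
    half peak-to-peak excursion of the cumulative displacement reaches
    ``amp_threshold`` AND the displacement sequence reverses direction at
    least once — the to-and-fro requirement.
    """
    params = params or BModeParams()
    T = clip.n_frames
    if T < 3:
        raise TooFewFramesError(f"sliding analysis needs >= 3 frames; got {T}")
    H = clip.frames.shape[1]
    a, b = space
    r0 = min(line.depth_row + params.strip_offset, H - 1)
    r1 = min(r0 + params.strip_height, H)
    strips = clip.frames[:, r0:r1, a:b]
    max_shift = min(params.max_shift, max(1, (b - a - 2) // 4))
    displacements = [
        _best_shift(strips[t], strips[t + 1], max_shift) for t in range(T - 1)
    ]
    positions = np.concatenate([[0], np.cumsum(displacements)])
    amplitude = float(positions.max() - positions.min()) / 2.0
    signs = [int(np.sign(d)) for d in displacements if d != 0]
    sign_changes = sum(1 for s1, s2 in zip(signs, signs[1:]) if s1 != s2)
    detected = amplitude >= params.amp_threshold and sign_changes >= 1
    return SlidingResult(
        displacements=tuple(int(d) for d in displacements),
        amplitude_px=amplitude,
        sign_changes=sign_changes,
        sliding_detected=detected,
    )


def detect_reverberation(
    clip: BModeClip,
    line: PleuralLineFit,
    space: ColumnInterval,
    params: Optional[BModeParams] = None,
) -> ReverbResult:
    """Score vertical reverberation artifacts below the pleural line.

    On the median frame, each space column's penetration score is the
    fraction of rows between ``depth_row + subpleural_gap`` and the bottom
    edge whose intensity reaches ``artifact_threshold`` times the fitted
    line brightness. An artifact band is a run of at least
    ``min_band_width`` columns whose scores all exceed ``min_penetration``.
    """
    params = params or BModeParams()
    med = clip.median_frame()
    H = med.shape[0]
    a, b = space
    r0 = min(line.depth_row + params.subpleural_gap, H - 1)
    sub = med[r0:, a:b]
    threshold = params.artifact_threshold * line.brightness
    penetration = (sub >= threshold).mean(axis=0)
    mask = penetration > params.min_penetration
    bands = [
        (a + lo, a + hi)
        for lo, hi in _true_runs(mask)
        if hi - lo >= params.min_band_width
    ]
    return ReverbResult(
        penetration=tuple(float(p) for p in penetration),
        artifact_bands=tuple(bands),
        reverberation_detected=bool(bands),
    )


def label_from_evidence(
    line_found: bool, sliding_detected: bool, reverberation_detected: bool
) -> str:
    """Three-way decision rule.

    No pleural line -> indeterminate (dominates everything else); sliding
    or reverberation -> negative for pneumothorax; neither -> positive.
    """
    if not line_found:
        return INDETERMINATE
    if sliding_detected or reverberation_detected:
        return NEGATIVE
    return POSITIVE


def classify_bmode(clip: BModeClip, params: Optional[BModeParams] = None) -> PtxCall:
    """Run the full B-mode pipeline and return a three-valued call.

    Recoverable problems (no intercostal space, no pleural line, too few
    frames for motion analysis) yield an indeterminate call with a recorded
    reason rather than an exception.
    """
    params = params or BModeParams()
    snapshot = asdict(params)
    evidence: dict = {
        "rib_shadows": None,
        "intercostal_space": None,
        "pleural_line": None,
        "sliding": None,
        "reverberation": None,
    }

    shadows = detect_rib_shadows(clip, params)
    evidence["rib_shadows"] = shadows
    space = locate_intercostal_space(shadows, clip.shape[1], params)
    evidence["intercostal_space"] = space
    if space is None:
        return PtxCall(
            label=INDETERMINATE,
            evidence=evidence,
            params=snapshot,
            reason="no_intercostal_space",
        )
    line = detect_pleural_line(clip, space, shadows, params)
    evidence["pleural_line"] = line
    if not line.found:
        return PtxCall(
            label=INDETERMINATE,
            evidence=evidence,
            params=snapshot,
            reason="pleural_line_not_found",
        )
    try:
        sliding = measure_sliding(clip, line, space, params)
    except TooFewFramesError:
        return PtxCall(
            label=INDETERMINATE,
            evidence=evidence,
            params=snapshot,
            reason="too_few_frames",
        )
    evidence["sliding"] = sliding
    reverb = detect_reverberation(clip, line, space, params)
    evidence["reverberation"] = reverb
    label = label_from_evidence(
        line.found, sliding.sliding_detected, reverb.reverberation_detected
    )
    return PtxCall(label=label, evidence=evidence, params=snapshot)
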