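"""Image containers and file I/O for lung-ultrasound exams.

The canonical in-memory objects are :class:`BModeClip` (a time-ordered stack
of grayscale frames, depth x lateral) and :class:`MModeImage` (a single
depth x sweep-time image). Both store intensities normalized to [0, 1];
integer sources are rescaled by their dtype maximum so that detection
thresholds transfer across 8- and 16-bit exports. Row 0 is the skin surface
and depth increases with the row index.

On disk a B-mode clip is a multi-page grayscale TIFF or a directory of
zero-padded PNG frames; an M-mode image is a single grayscale PNG or TIFF.
Each exam carries a JSON metadata sidecar (:class:`ExamMetadata`).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Optional

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .errors import (
    DuplicateRatingError,
    EmptyClipError,
    FrameShapeMismatchError,
    ImageSizeError,
    IntensityRangeError,
    LabelVocabularyError,
    MetadataError,
    MissingPathError,
    MultiPageImageError,
    RatingsTableError,
)

POSITIVE = "positive"
NEGATIVE = "negative"
INDETERMINATE = "indeterminate"
LABELS = (POSITIVE, NEGATIVE, INDETERMINATE)

MODES = ("B", "M")
TRANSDUCERS = ("linear", "phased", "unknown")

#: Minimum analyzable M-mode size (depth rows, time columns).
MIN_MMODE_SHAPE = (8, 8)

_LUMA = np.array([0.299, 0.587, 0.114])


def _to_unit(arr: np.ndarray, *, what: str = "image") -> np.ndarray:
    """Convert a raw pixel array to float64 intensities in [0, 1].

    Integer dtypes are divided by the dtype maximum; float inputs must
    already lie in [0, 1] (out-of-range values raise rather than clamp).
    Color (RGB/RGBA) data is converted to luma.
    """
    arr = np.asarray(arr)
    src_dtype = arr.dtype
    if arr.ndim >= 3 and arr.shape[-1] in (3, 4):
        arr = arr[..., :3].astype(float) @ _LUMA  # luma keeps the source scale
    if np.issubdtype(src_dtype, np.integer):
        out = arr.astype(float) / float(np.iinfo(src_dtype).max)
    else:
        out = arr.astype(float)
    if out.size and (out.min() < -1e-9 or out.max() > 1.0 + 1e-9):
        raise IntensityRangeError(
            f"{what}: float intensities must lie in [0, 1]; "
            f"got range [{out.min():.4g}, {out.max():.4g}]"
        )
    return np.clip(out, 0.0, 1.0)


@dataclass
class BModeClip:
    """A time-ordered stack of B-mode frames.

    frames : float array of shape (T, H, W), intensities in [0, 1];
    row 0 is the skin surface.
    """

    frames: np.ndarray
    frame_rate_hz: float = 20.0
    exam_id: str = ""

    def __post_init__(self) -> None:
        frames = np.asarray(self.frames, dtype=float)
        if frames.ndim != 3:
            raise ImageSizeError(
                f"B-mode clip must be a (T, H, W) stack; got shape {frames.shape}"
            )
        if frames.shape[0] < 1:
            raise EmptyClipError("B-mode clip needs at least one frame")
        if frames.size and (frames.min() < 0.0 or frames.max() > 1.0):
            raise IntensityRangeError("clip intensities must lie in [0, 1]")
        if not self.frame_rate_hz > 0:
            raise ImageSizeError("frame_rate_hz must be positive")
        self.frames = frames

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])

    @property
    def shape(self) -> tuple[int, int]:
        """(H, W) of a single frame."""
        return int(self.frames.shape[1]), int(self.frames.shape[2])

    def median_frame(self) -> np.ndarray:
        """Temporal median frame, robust to sliding motion."""
        return np.median(self.frames, axis=0)


@dataclass
class MModeImage:
    """A single M-mode image: rows are depth, columns are sweep time."""

    pixels: np.ndarray
    sweep_seconds: Optional[float] = None
    exam_id: str = ""

    def __post_init__(self) -> None:
        pixels = np.asarray(self.pixels, dtype=float)
        if pixels.ndim != 2:
            raise ImageSizeError(
                f"M-mode image must be 2-D (depth, time); got shape {pixels.shape}"
            )
        if pixels.shape[0] < MIN_MMODE_SHAPE[0] or pixels.shape[1] < MIN_MMODE_SHAPE[1]:
            raise ImageSizeError(
                f"M-mode image must be at least {MIN_MMODE_SHAPE}; got {pixels.shape}"
            )
        if pixels.size and (pixels.min() < 0.0 or pixels.max() > 1.0):
            raise IntensityRangeError("M-mode intensities must lie in [0, 1]")
        if self.sweep_seconds is not None and not self.sweep_seconds > 0:
            raise ImageSizeError("sweep_seconds must be positive when set")
        self.pixels = pixels

    @property
    def shape(self) -> tuple[int, int]:
        return int(self.pixels.shape[0]), int(self.pixels.shape[1])


@dataclass
class ExamMetadata:
    """Per-exam sidecar: imaging mode, transducer, optional quality and label.

    ``quality_score`` uses the 5-point ACEP image-quality scale; scores of
    3 or more are considered diagnostic. Unset optionals stay ``None`` and
    are never silently defaulted to a label.
    """

    exam_id: str
    mode: str
    transducer: str = "unknown"
    quality_score: Optional[int] = None
    reference_label: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.exam_id:
            raise MetadataError("exam_id must be a non-empty string")
        if self.mode not in MODES:
            raise MetadataError(f"unknown mode {self.mode!r}; expected one of {MODES}")
        if self.transducer not in TRANSDUCERS:
            raise MetadataError(
                f"unknown transducer {self.transducer!r}; expected one of {TRANSDUCERS}"
            )
        if self.quality_score is not None:
            q = self.quality_score
            if not (isinstance(q, (int, np.integer)) and 1 <= int(q) <= 5):
                raise MetadataError(
                    f"quality_score must be an integer in 1..5; got {q!r}"
                )
            self.quality_score = int(q)
        if self.reference_label is not None and self.reference_label not in LABELS:
            raise MetadataError(
                f"reference_label {self.reference_label!r} not in {LABELS}"
            )


@dataclass(frozen=True)
class RatingRecord:
    """One rater's call on one exam, with an ACEP quality score."""

    exam_id: str
    rater_id: str
    label: str
    quality_score: Optional[int] = None


def read_bmode_clip(path) -> BModeClip:
    """Read a B-mode cine clip from a multi-page TIFF or a PNG directory.

    PNG frames in a directory are ordered by filename, so zero-padded
    indices (``frame_000.png`` ...) preserve acquisition order.
    """
    path = Path(path)
    if not path.exists():
        raise MissingPathError(f"no such file or directory: {path}")
    if path.is_dir():
        frame_files = sorted(p for p in path.iterdir() if p.suffix.lower() == ".png")
        if not frame_files:
            raise EmptyClipError(f"directory {path} contains no PNG frames")
        frames = [_to_unit(iio.imread(p), what=str(p)) for p in frame_files]
    else:
        raw = tifffile.imread(path)
        if raw.ndim == 2:
            raw = raw[None, ...]
        frames = [_to_unit(page, what=f"{path} page {i}") for i, page in enumerate(raw)]
    if not frames:
        raise EmptyClipError(f"{path}: zero readable frames")
    shapes = {f.shape for f in frames}
    if len(shapes) > 1:
        raise FrameShapeMismatchError(
            f"{path}: frames have mismatched shapes {sorted(shapes)}"
        )
    return BModeClip(frames=np.stack(frames), exam_id=path.stem)


def write_bmode_clip(clip: BModeClip, path) -> None:
    """Write a clip as an 8-bit multi-page grayscale TIFF."""
    data = np.rint(clip.frames * 255.0).astype(np.uint8)
    tifffile.imwrite(Path(path), data, photometric="minisblack")


def read_mmode_image(path) -> MModeImage:
    """Read a single grayscale PNG/TIFF as an M-mode image."""
    path = Path(path)
    if not path.exists():
        raise MissingPathError(f"no such file: {path}")
    if path.suffix.lower() in (".tif", ".tiff"):
        raw = tifffile.imread(path)
        if raw.ndim == 3 and raw.shape[-1] not in (3, 4):
            raise MultiPageImageError(
                f"{path} holds {raw.shape[0]} pages; use read_bmode_clip for cine data"
            )
    else:
        raw = iio.imread(path)
    return MModeImage(pixels=_to_unit(raw, what=str(path)), exam_id=path.stem)


def write_mmode_image(image: MModeImage, path) -> None:
    """Write an M-mode image as an 8-bit grayscale PNG."""
    data = np.rint(image.pixels * 255.0).astype(np.uint8)
    iio.imwrite(Path(path), data)


def read_metadata(path) -> ExamMetadata:
    """Read a JSON metadata sidecar."""
    path = Path(path)
    if not path.exists():
        raise MissingPathError(f"no such file: {path}")
    try:
        payload = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise MetadataError(f"{path}: malformed JSON ({exc})") from exc
    if not isinstance(payload, dict):
        raise MetadataError(f"{path}: sidecar must be a JSON object")
    for key in ("exam_id", "mode"):
        if key not in payload:
            raise MetadataError(f"{path}: missing required key {key!r}")
    return ExamMetadata(
        exam_id=str(payload["exam_id"]),
        mode=str(payload["mode"]),
        transducer=str(payload.get("transducer", "unknown")),
        quality_score=payload.get("quality_score"),
        reference_label=payload.get("reference_label"),
    )


def write_metadata(meta: ExamMetadata, path) -> None:
    payload = {k: v for k, v in asdict(meta).items() if v is not None}
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def read_ratings_table(path) -> list[RatingRecord]:
    """Read a per-exam, per-rater CSV of labels and quality scores.

    Required columns: exam_id, rater_id, label; optional: quality_score.
    Each (exam_id, rater_id) pair may appear only once.
    """
    path = Path(path)
    if not path.exists():
        raise MissingPathError(f"no such file: {path}")
    df = pd.read_csv(path, dtype={"exam_id": str, "rater_id": str})
    required = {"exam_id", "rater_id", "label"}
    missing = required - set(df.columns)
    if missing:
        raise RatingsTableError(f"{path}: missing columns {sorted(missing)}")
    bad = sorted(set(df["label"]) - set(LABELS))
    if bad:
        raise LabelVocabularyError(f"{path}: labels {bad} not in {LABELS}")
    dupes = df.duplicated(subset=["exam_id", "rater_id"], keep=False)
    if dupes.any():
        pairs = df.loc[dupes, ["exam_id", "rater_id"]].drop_duplicates()
        raise DuplicateRatingError(
            f"{path}: duplicate (exam, rater) pairs: {pairs.values.tolist()}"
        )
    records = []
    for row in df.itertuples(index=False):
        q = getattr(row, "quality_score", None)
        if q is not None and pd.isna(q):
            q = None
        if q is not None:
            q = int(q)
            if not 1 <= q <= 5:
                raise RatingsTableError(
                    f"{path}: quality_score {q} outside the 1..5 scale"
                )
        records.append(
            RatingRecord(
                exam_id=str(row.exam_id),
                rater_id=str(row.rater_id),
                label=str(row.label),
                quality_score=q,
            )
        )
    return records
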