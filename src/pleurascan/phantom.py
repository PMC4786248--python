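"""Seeded synthetic lung-ultrasound phantoms with full ground truth.

The generator renders the sonographic features a pneumothorax detector keys
on, in a rectangular (linear-probe) geometry:

* multiplicative Rayleigh speckle as the tissue background,
* bright rib caps with posterior acoustic shadowing below them,
* a bright, contiguous pleural line spanning the intercostal space,
* pleural sliding, modeled as rigid sinusoidal lateral translation of the
  sub-pleural speckle (supra-pleural tissue stays static),
* vertical B-line (comet-tail) artifacts running from the pleural line to
  the bottom edge, moving with the sliding pattern,
* M-mode seashore (independent sub-pleural speckle per time column) and
  stratosphere/barcode (each sub-pleural row constant in time) patterns.

Every output is a pure function of ``(config, seed)``: the same
:class:`PhantomConfig` renders bit-identical images on repeat. Ground truth
(the ``truth_label`` and the per-frame shift table) travels with the exam,
so detector stages can be scored against the generator's own bookkeeping.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Optional

import numpy as np

from .errors import PhantomConfigError
from .imaging import (
    BModeClip,
    ExamMetadata,
    MModeImage,
    NEGATIVE,
    POSITIVE,
    write_bmode_clip,
    write_metadata,
    write_mmode_image,
)

MMODE_PATTERNS = ("seashore", "stratosphere", "none")

#: Intensity of rib caps and of B-line artifacts (before shadowing).
RIB_CAP_BRIGHTNESS = 0.9
RIB_CAP_THICKNESS_PX = 3
BLINE_BRIGHTNESS = 0.85


@dataclass
class PhantomConfig:
    """Fully parameterized description of one synthetic exam.

    Defaults describe a typical adult intercostal view on a linear probe:
    a 128 x 192 px field with two ribs, the pleural line at 60 px depth,
    and ~4 px peak sliding over a 10-frame respiratory period.
    """

    height_px: int = 128
    width_px: int = 192
    n_frames: int = 16
    rib_centers_px: list[int] = field(default_factory=lambda: [40, 150])
    rib_width_px: int = 14
    rib_cap_depth_px: int = 30
    shadow_attenuation: float = 0.15
    pleural_depth_px: int = 60
    pleural_brightness: float = 0.95
    pleural_thickness_px: int = 2
    sliding_amplitude_px: float = 4.0
    sliding_period_frames: int = 10
    n_blines: int = 0
    bline_width_px: int = 3
    speckle_scale: float = 0.15
    mmode_pattern: str = "none"
    truth_label: str = NEGATIVE
    seed: int = 0

    def __post_init__(self) -> None:
        if self.height_px < 16 or self.width_px < 16:
            raise PhantomConfigError("field must be at least 16 x 16 px")
        if self.n_frames < 1:
            raise PhantomConfigError("n_frames must be >= 1")
        if not self.rib_centers_px:
            raise PhantomConfigError("at least one rib center is required")
        if self.rib_width_px < 1 or self.bline_width_px < 1:
            raise PhantomConfigError("rib and B-line widths must be positive")
        if not 0.0 <= self.shadow_attenuation <= 1.0:
            raise PhantomConfigError("shadow_attenuation must lie in [0, 1]")
        if not 0.0 < self.pleural_brightness <= 1.0:
            raise PhantomConfigError("pleural_brightness must lie in (0, 1]")
        if self.pleural_depth_px <= self.rib_cap_depth_px:
            raise PhantomConfigError("pleural line must lie below the rib caps")
        if self.pleural_depth_px + self.pleural_thickness_px >= self.height_px:
            raise PhantomConfigError("pleural line must lie above the bottom edge")
        if self.sliding_amplitude_px < 0:
            raise PhantomConfigError("sliding_amplitude_px must be >= 0")
        if self.sliding_period_frames < 1:
            raise PhantomConfigError("sliding_period_frames must be >= 1")
        if self.n_blines < 0:
            raise PhantomConfigError("n_blines must be >= 0")
        if self.speckle_scale <= 0:
            raise PhantomConfigError("speckle_scale must be positive")
        if self.mmode_pattern not in MMODE_PATTERNS:
            raise PhantomConfigError(
                f"mmode_pattern must be one of {MMODE_PATTERNS}"
            )
        if self.truth_label not in (POSITIVE, NEGATIVE):
            raise PhantomConfigError("truth_label must be positive or negative")
        has_negative_sign = self.sliding_amplitude_px > 0 or self.n_blines > 0
        if self.truth_label == NEGATIVE and not has_negative_sign:
            raise PhantomConfigError(
                "a negative exam needs sliding or B-lines (a sign of aerated lung)"
            )
        if self.truth_label == POSITIVE and has_negative_sign:
            raise PhantomConfigError(
                "a positive (pneumothorax) exam must have no sliding and no B-lines"
            )
        if self.mmode_pattern == "seashore" and self.truth_label != NEGATIVE:
            raise PhantomConfigError("seashore pattern implies a negative exam")
        if self.mmode_pattern == "stratosphere" and self.truth_label != POSITIVE:
            raise PhantomConfigError("stratosphere pattern implies a positive exam")

    # -- ground-truth geometry helpers -------------------------------------

    def rib_intervals(self) -> list[tuple[int, int]]:
        """Half-open lateral column intervals covered by each rib."""
        out = []
        for c in sorted(self.rib_centers_px):
            a = max(0, int(c) - self.rib_width_px // 2)
            b = min(self.width_px, a + self.rib_width_px)
            out.append((a, b))
        return out

    def intercostal_gap(self) -> tuple[int, int]:
        """Widest half-open gap between consecutive rib intervals.

        Falls back to the full width when fewer than two ribs exist.
        """
        ivs = self.rib_intervals()
        if len(ivs) < 2:
            return (0, self.width_px)
        gaps = [(ivs[i][1], ivs[i + 1][0]) for i in range(len(ivs) - 1)]
        return max(gaps, key=lambda g: g[1] - g[0])

    def bline_intervals(self) -> list[tuple[int, int]]:
        """Ground-truth B-line column intervals at zero sliding offset."""
        a, b = self.intercostal_gap()
        out = []
        for i in range(self.n_blines):
            center = a + int(round((b - a) * (i + 1) / (self.n_blines + 1)))
            lo = center - self.bline_width_px // 2
            out.append((lo, lo + self.bline_width_px))
        return out

    def shift_sequence(self, n_frames: Optional[int] = None) -> np.ndarray:
        """Ground-truth lateral offset (px) of the sub-pleural tissue per frame."""
        t = np.arange(self.n_frames if n_frames is None else n_frames)
        s = self.sliding_amplitude_px * np.sin(
            2.0 * math.pi * t / self.sliding_period_frames
        )
        return np.rint(s).astype(int)


@dataclass
class LabeledExam:
    """A rendered phantom plus its metadata and generating config."""

    payload: object  # BModeClip or MModeImage
    metadata: ExamMetadata
    config: PhantomConfig

    def __post_init__(self) -> None:
        if self.metadata.reference_label != self.config.truth_label:
            raise PhantomConfigError(
                "metadata reference_label must equal the config truth_label"
            )


def make_bmode_phantom(config: PhantomConfig) -> LabeledExam:
    """Render a B-mode cine clip from ``config``.

    Composition order per frame: static supra-pleural speckle and pleural
    band, laterally shifted sub-pleural speckle (with any B-lines baked
    into the moving field), rib caps, then posterior shadowing applied to
    the rib columns. No frame-wise noise is added on top, so a zero-sliding
    exam is pixel-identical below the pleural line across frames.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    H, W, T = cfg.height_px, cfg.width_px, cfg.n_frames
    sub_top = cfg.pleural_depth_px + cfg.pleural_thickness_px
    margin = int(math.ceil(cfg.sliding_amplitude_px)) + 1

    supra = np.clip(rng.rayleigh(cfg.speckle_scale, size=(sub_top, W)), 0.0, 1.0)
    sub_wide = np.clip(
        rng.rayleigh(cfg.speckle_scale, size=(H - sub_top, W + 2 * margin)), 0.0, 1.0
    )
    for lo, hi in cfg.bline_intervals():
        sub_wide[:, lo + margin : hi + margin] = BLINE_BRIGHTNESS

    ribs = cfg.rib_intervals()
    gap = cfg.intercostal_gap()
    rib_mask = np.zeros(W, dtype=bool)
    for a, b in ribs:
        rib_mask[a:b] = True
    cap_rows = slice(
        cfg.rib_cap_depth_px,
        min(cfg.rib_cap_depth_px + RIB_CAP_THICKNESS_PX, sub_top),
    )
    shadow_rows = slice(cfg.rib_cap_depth_px + RIB_CAP_THICKNESS_PX, H)
    pleura_rows = slice(cfg.pleural_depth_px, sub_top)

    shifts = cfg.shift_sequence()
    frames = np.empty((T, H, W))
    for t in range(T):
        s = int(shifts[t])
        frame = np.empty((H, W))
        frame[:sub_top] = supra
        frame[sub_top:] = sub_wide[:, margin - s : margin - s + W]
        frame[pleura_rows, ~rib_mask] = cfg.pleural_brightness
        for a, b in ribs:
            frame[cap_rows, a:b] = RIB_CAP_BRIGHTNESS
            frame[shadow_rows, a:b] *= cfg.shadow_attenuation
        frames[t] = frame

    exam_id = f"bmode-{cfg.seed}"
    clip = BModeClip(frames=frames, exam_id=exam_id)
    meta = ExamMetadata(
        exam_id=exam_id,
        mode="B",
        transducer="linear",
        reference_label=cfg.truth_label,
    )
    return LabeledExam(payload=clip, metadata=meta, config=cfg)


def make_mmode_phantom(config: PhantomConfig) -> LabeledExam:
    """Render an M-mode image (depth x sweep time) from ``config``.

    Above the pleural line: horizontally banded static layers. Below it:
    ``seashore`` draws independent speckle per (row, column); ``stratosphere``
    draws one speckle value per row and holds it across the sweep, giving
    zero temporal variance per row by construction.
    """
    cfg = config
    if cfg.mmode_pattern == "none":
        raise PhantomConfigError("make_mmode_phantom needs mmode_pattern != 'none'")
    rng = np.random.default_rng(cfg.seed)
    H, Wt = cfg.height_px, cfg.width_px
    sub_top = cfg.pleural_depth_px + cfg.pleural_thickness_px

    img = np.empty((H, Wt))
    rows = np.arange(cfg.pleural_depth_px)
    bands = 0.22 + 0.18 * np.sin(2.0 * math.pi * rows / 14.0)
    img[: cfg.pleural_depth_px] = np.clip(bands, 0.02, 0.6)[:, None]
    img[cfg.pleural_depth_px : sub_top] = cfg.pleural_brightness
    n_sub = H - sub_top
    if cfg.mmode_pattern == "seashore":
        img[sub_top:] = rng.rayleigh(cfg.speckle_scale, size=(n_sub, Wt))
    else:  # stratosphere: each row constant along the sweep
        img[sub_top:] = rng.rayleigh(cfg.speckle_scale, size=(n_sub, 1))
    img = np.clip(img, 0.0, 1.0)

    exam_id = f"mmode-{cfg.seed}"
    image = MModeImage(pixels=img, exam_id=exam_id)
    meta = ExamMetadata(
        exam_id=exam_id,
        mode="M",
        transducer="linear",
        reference_label=cfg.truth_label,
    )
    return LabeledExam(payload=image, metadata=meta, config=cfg)


def cohort_counts(n_positive: int, negative_ratio: float) -> tuple[int, int]:
    """Planned (positive, negative) exam counts for a ratio-sampled cohort."""
    if n_positive < 1:
        raise PhantomConfigError("n_positive must be >= 1")
    if negative_ratio <= 0:
        raise PhantomConfigError("negative_ratio must be positive")
    return n_positive, int(round(negative_ratio * n_positive))


def _jittered_config(
    base: PhantomConfig, truth_label: str, mode: str, rng: np.random.Generator
) -> PhantomConfig:
    """Draw per-exam nuisance parameters around ``base``.

    Jitters rib positions (+-6 px), rib cap depth (+-4 px), pleural depth
    (50..72 px), and speckle scale (0.10..0.22). Negative B-mode exams carry
    sliding, B-lines, or both; positive exams carry neither.
    """
    centers = [int(c + rng.integers(-6, 7)) for c in base.rib_centers_px]
    updates: dict = {
        "rib_centers_px": centers,
        "rib_cap_depth_px": int(base.rib_cap_depth_px + rng.integers(-4, 5)),
        "pleural_depth_px": int(rng.integers(50, 73)),
        "speckle_scale": float(rng.uniform(0.10, 0.22)),
        "truth_label": truth_label,
        "seed": int(rng.integers(0, 2**31)),
    }
    if truth_label == POSITIVE:
        updates.update(sliding_amplitude_px=0.0, n_blines=0)
        updates["mmode_pattern"] = "stratosphere" if mode == "M" else "none"
    else:
        profile = rng.choice(["sliding", "blines", "both"], p=[0.4, 0.3, 0.3])
        amp = float(rng.uniform(2.5, 6.0)) if profile in ("sliding", "both") else 0.0
        nbl = int(rng.integers(1, 3)) if profile in ("blines", "both") else 0
        updates.update(
            sliding_amplitude_px=amp,
            n_blines=nbl,
            sliding_period_frames=int(rng.integers(8, 13)),
        )
        updates["mmode_pattern"] = "seashore" if mode == "M" else "none"
    return replace(base, **updates)


def make_cohort(
    n_positive: int,
    negative_ratio: float,
    base_config: Optional[PhantomConfig] = None,
    seed: int = 0,
    mmode_fraction: float = 0.2,
) -> list[LabeledExam]:
    """Generate a labeled cohort with ratio-controlled prevalence.

    Returns ``n_positive`` positives plus ``round(negative_ratio *
    n_positive)`` negatives, each with independently jittered nuisance
    parameters, in an order randomized by the same seeded stream. A fraction
    of exams (default 0.2) is rendered in M-mode, the rest in B-mode;
    transducer and ACEP quality score are drawn as nuisance metadata.
    """
    n_pos, n_neg = cohort_counts(n_positive, negative_ratio)
    if base_config is None:
        base_config = PhantomConfig()
    rng = np.random.default_rng(seed)
    exams: list[LabeledExam] = []
    for i in range(n_pos + n_neg):
        truth = POSITIVE if i < n_pos else NEGATIVE
        mode = "M" if rng.random() < mmode_fraction else "B"
        cfg = _jittered_config(base_config, truth, mode, rng)
        exam = make_mmode_phantom(cfg) if mode == "M" else make_bmode_phantom(cfg)
        meta = replace(
            exam.metadata,
            exam_id=f"exam-{i:04d}",
            transducer="linear" if rng.random() < 0.6 else "phased",
            quality_score=int(rng.choice([3, 4, 5], p=[0.34, 0.51, 0.15])),
        )
        exam.payload.exam_id = meta.exam_id
        exams.append(LabeledExam(payload=exam.payload, metadata=meta, config=cfg))
    order = rng.permutation(len(exams))
    return [exams[i] for i in order]


def write_cohort(exams: list[LabeledExam], outdir) -> Path:
    """Write one directory per exam plus a manifest CSV; returns the manifest path.

    Each exam directory holds the image (``bmode.tiff`` or ``mmode.png``),
    its JSON sidecar, and the generating config. The manifest is written
    last, so a failed run never leaves a partial manifest behind.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for exam in exams:
        exam_dir = outdir / exam.metadata.exam_id
        exam_dir.mkdir(parents=True, exist_ok=True)
        if exam.metadata.mode == "B":
            image_name = "bmode.tiff"
            write_bmode_clip(exam.payload, exam_dir / image_name)
        else:
            image_name = "mmode.png"
            write_mmode_image(exam.payload, exam_dir / image_name)
        write_metadata(exam.metadata, exam_dir / "meta.json")
        cfg_path = exam_dir / "config.json"
        cfg_path.write_text(
            json.dumps(asdict(exam.config), indent=2, sort_keys=True) + "\n"
        )
        rows.append(
            {
                "exam_id": exam.metadata.exam_id,
                "truth_label": exam.config.truth_label,
                "mode": exam.metadata.mode,
                "transducer": exam.metadata.transducer,
                "quality_score": exam.metadata.quality_score,
                "image": f"{exam.metadata.exam_id}/{image_name}",
                "config": f"{exam.metadata.exam_id}/config.json",
            }
        )
    manifest = outdir / "manifest.csv"
    tmp = outdir / ".manifest.csv.tmp"
    with open(tmp, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(rows[0].keys()))
        writer.writeheader()
        writer.writerows(rows)
    tmp.replace(manifest)
    return manifest
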