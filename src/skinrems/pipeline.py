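"""Frame handling, ROI segmentation and differential feature extraction.

The extraction stage turns a time-lapse of forearm frames into one row of
differential colorimetric features per subject. Each feature is named
``<channel><statistic>_<time index>_<concentration code>``, e.g.
``Gmean_3_A`` = mean green, frame 3 (2.5 min), 0.1 M. Frame k (1-based)
carries timestamp (k - 0.5) x interval so that index 3 <-> 2.5 min and
index 6 <-> 5.5 min.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import imageio.v3 as iio
import numpy as np
from skimage import filters, measure, morphology

from .colors import ColorDescriptor, descriptor_stats, differential_features, roi_channel_values
from .config import PatchLayout, concentration_codes
from .errors import InputError, IntegrityError

logger = logging.getLogger(__name__)

FEATURE_KEY_RE = re.compile(
    r"^(?P<channel>[RGBHSV])(?P<stat>mean|median|mode|min|max|range)_(?P<index>\d+)_(?P<code>[A-Z])$"
)


def feature_key(channel: str, statistic: str, time_index: int, code: str) -> str:
    return f"{channel}{statistic}_{time_index}_{code}"


def parse_feature_key(key: str) -> Tuple[str, str, int, str]:
    m = FEATURE_KEY_RE.match(key)
    if not m:
        raise InputError(f"malformed feature key {key!r}")
    return m["channel"], m["stat"], int(m["index"]), m["code"]


@dataclass
class Frame:
    """One 8-bit RGB frame with its acquisition timestamp (s)."""

    pixels: np.ndarray
    timestamp: float

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise IntegrityError("frame must be an (H, W, 3) array")
        if self.pixels.dtype != np.uint8:
            raise IntegrityError("frame must be 8-bit (uint8)")
        if self.timestamp < 0:
            raise IntegrityError("timestamp must be >= 0")


@dataclass
class FrameSequence:
    """One subject x one concentration time-lapse."""

    subject_id: str
    concentration: float
    frames: List[Frame]

    def __post_init__(self):
        ts = np.array([f.timestamp for f in self.frames], dtype=float)
        if len(ts) == 0:
            raise InputError("empty frame sequence")
        if np.any(np.diff(ts) <= 0):
            raise IntegrityError("timestamps must be strictly increasing")
        if len(ts) > 2 and not np.allclose(np.diff(ts), ts[1] - ts[0]):
            raise IntegrityError("timestamps must be equally spaced")

    def __len__(self) -> int:
        return len(self.frames)


@dataclass
class RoiSet:
    """Boolean masks: one per niacin patch plus one control-skin mask."""

    patch_masks: List[np.ndarray]
    control_mask: np.ndarray

    def __post_init__(self):
        shape = self.control_mask.shape
        masks = [*self.patch_masks, self.control_mask]
        for m in masks:
            if m.shape != shape:
                raise IntegrityError("all masks must share the frame shape")
            if m.dtype != bool:
                raise IntegrityError("masks must be boolean")
            if not m.any():
                raise IntegrityError("every mask must be non-empty")
        total = np.zeros(shape, dtype=int)
        for m in masks:
            total += m
        if total.max() > 1:
            raise IntegrityError("masks must be pairwise disjoint")


def extract_frames(source, interval: float, duration: float) -> FrameSequence:
    """Load an ordered frame directory as a FrameSequence.

    ``source`` is a directory of PNG/TIFF frames named with zero-padded
    indices. Frame k is assigned timestamp (k - 0.5) * interval. The frame
    count must equal duration/interval exactly.
    """
    n = duration / interval
    if abs(n - round(n)) > 1e-9:
        raise InputError("interval must divide duration")
    n = int(round(n))
    source = Path(source)
    if source.is_file():
        raise InputError(
            "video container input is not supported; supply a frame directory"
        )
    if not source.is_dir():
        raise InputError(f"no such frame directory: {source}")
    paths = sorted(
        p for p in source.iterdir() if p.suffix.lower() in {".png", ".tif", ".tiff"}
    )
    if not paths:
        raise InputError(f"no frames found in {source}")
    if len(paths) != n:
        raise IntegrityError(f"expected {n} frames in {source}, found {len(paths)}")
    frames = []
    for k, p in enumerate(paths, start=1):
        img = np.asarray(iio.imread(p))
        if img.ndim == 3 and img.shape[2] == 4:  # drop alpha
            img = img[:, :, :3]
        frames.append(Frame(img.astype(np.uint8), (k - 0.5) * interval))
    return FrameSequence(subject_id=source.name, concentration=float("nan"), frames=frames)


def segment_rois(
    frame: Frame,
    layout: PatchLayout,
    override_masks: Optional[RoiSet] = None,
) -> RoiSet:
    """Locate the reaction patches (and a control area) in one frame.

    Automatic path: per-pixel colour deviation from the frame's median skin
    tone is smoothed, thresholded (Otsu) and cleaned with morphological
    opening/closing; connected components are matched to the layout prior's
    expected patch centres. If any expected patch has no matching component
    (e.g. no visible reaction), the layout-prior rectangles are returned
    with a logged warning — the automated analogue of drawing the ROI by
    hand. ``override_masks`` (manual correction) short-circuits everything
    and is returned verbatim.
    """
    if override_masks is not None:
        return override_masks
    img = frame.pixels.astype(float)
    if img.shape[:2] != layout.frame_shape:
        raise IntegrityError("frame shape does not match layout prior")
    median_color = np.median(img.reshape(-1, 3), axis=0)
    deviation = np.linalg.norm(img - median_color, axis=2)
    smoothed = filters.gaussian(deviation, sigma=1.0)
    masks: List[Optional[np.ndarray]] = [None] * layout.n_patches
    expected_area = layout.patch_size**2
    try:
        thr = filters.threshold_otsu(smoothed)
        binary = smoothed > thr
        binary = morphology.opening(binary, morphology.footprint_rectangle((3, 3)))
        binary = morphology.closing(binary, morphology.footprint_rectangle((3, 3)))
        labels = measure.label(binary)
        for i, (r, c) in enumerate(layout.patch_centers()):
            lbl = labels[r, c]
            if lbl > 0:
                component = labels == lbl
                area = int(component.sum())
                if 0.25 * expected_area <= area <= 4 * expected_area:
                    masks[i] = component
    except ValueError:
        pass  # e.g. constant image -> Otsu undefined -> fall back below
    prior = layout.patch_masks()
    if any(m is None for m in masks):
        logger.warning(
            "segmentation found %d/%d patches; falling back to layout-prior rectangles",
            sum(m is not None for m in masks),
            layout.n_patches,
        )
        masks = prior
    control = layout.control_mask()
    for m in masks:
        control &= ~m
    return RoiSet(patch_masks=[m.copy() for m in masks], control_mask=control)


def frame_differentials(
    frame: Frame, patch_mask: np.ndarray, control_mask: np.ndarray
) -> Dict[Tuple[str, str], float]:
    """Differential descriptors (patch minus control) for one frame."""
    patch_px = frame.pixels[patch_mask].astype(float)
    control_px = frame.pixels[control_mask].astype(float)
    patch_desc = descriptor_stats(roi_channel_values(patch_px))
    control_desc = descriptor_stats(roi_channel_values(control_px))
    return differential_features(patch_desc, control_desc)


def build_feature_table(
    sequences: Iterable[FrameSequence],
    rois: Mapping[str, RoiSet],
    concentrations: Optional[Sequence[float]] = None,
):
    """Compile the per-subject differential feature table.

    ``rois`` maps subject_id to that subject's RoiSet, whose patch masks
    are ordered by descending molarity (matching the physical column).
    Returns ``(DataFrame indexed by subject_id, exclusions)`` where
    exclusions lists (subject_id, reason) for subjects dropped because a
    sequence was missing or inconsistent; all retained subjects share an
    identical feature-key set.
    """
    import pandas as pd

    sequences = list(sequences)
    if concentrations is None:
        concentrations = sorted({s.concentration for s in sequences}, reverse=True)
    codes = concentration_codes(concentrations)
    rank = {c: i for i, c in enumerate(sorted(concentrations, reverse=True))}

    by_subject: Dict[str, Dict[float, FrameSequence]] = {}
    for seq in sequences:
        by_subject.setdefault(seq.subject_id, {})[seq.concentration] = seq

    n_frames = {len(s) for s in sequences}
    if len(n_frames) > 1:
        raise IntegrityError(f"sequences have differing frame counts: {sorted(n_frames)}")

    rows = {}
    exclusions: List[Tuple[str, str]] = []
    for sid in sorted(by_subject):
        seqs = by_subject[sid]
        missing = [c for c in concentrations if c not in seqs]
        if missing:
            reason = f"missing sequence(s) for concentration(s) {missing}"
            logger.warning("excluding subject %s: %s", sid, reason)
            exclusions.append((sid, reason))
            continue
        if sid not in rois:
            reason = "no ROI set"
            logger.warning("excluding subject %s: %s", sid, reason)
            exclusions.append((sid, reason))
            continue
        roi = rois[sid]
        row = {}
        for conc in concentrations:
            seq = seqs[conc]
            patch_mask = roi.patch_masks[rank[conc]]
            code = codes[conc]
            for k, frame in enumerate(seq.frames, start=1):
                diffs = frame_differentials(frame, patch_mask, roi.control_mask)
                for (channel, stat), value in diffs.items():
                    row[feature_key(channel, stat, k, code)] = value
        rows[sid] = row

    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "subject_id"
    return table, exclusions
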