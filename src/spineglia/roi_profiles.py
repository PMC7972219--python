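"""Line-ROI fluorescence profiles and area-fraction quantification.

The measurements in this package are all driven by 1D fluorescence intensity
profiles sampled along a hand-drawn (or synthetically generated) polyline ROI.
A profile is extracted from a maximum intensity projection, background
corrected, and then normalized either to the adjacent dendritic shaft (spine
analysis, shaft == 1) or to the background itself (microglia analysis,
background == 1).  Percent-area staining is a plain thresholded pixel count.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

#: Arc-length step between profile samples, in pixels.  Sub-pixel sampling by
#: bilinear interpolation keeps peak areas stable against vertex placement.
SAMPLING_STEP_PX: float = 0.5


@dataclass(frozen=True)
class LineROI:
    """Polyline region of interest in pixel coordinates (y, x), 0-based.

    ``dendrite_segment`` designates, as a half-open ``[start, end)`` range of
    profile sample indices, the stretch of the profile that runs over the
    adjacent dendrite and is used as the normalization reference.
    """

    vertices: tuple[tuple[float, float], ...]
    sampling_width: int = 3
    dendrite_segment: tuple[int, int] | None = None
    #: Optional traced length of the structure of interest in μm.  When the
    #: polyline includes stretches that are not part of the dendrite proper
    #: (e.g. a background spur), this carries the length used as the density
    #: denominator.  ``None`` means "use the polyline arc length".
    dendrite_length_um: float | None = None

    def __post_init__(self) -> None:
        verts = tuple((float(y), float(x)) for y, x in self.vertices)
        object.__setattr__(self, "vertices", verts)
        if len(verts) < 2:
            raise ValueError("LineROI needs at least 2 vertices")
        if self.sampling_width < 1 or self.sampling_width % 2 == 0:
            raise ValueError("sampling_width must be an odd integer >= 1")
        if self.arc_length_px() <= 0:
            raise ValueError("polyline has zero length")
        if self.dendrite_segment is not None:
            s, e = self.dendrite_segment
            if e <= s:
                raise ValueError("dendrite_segment must be a non-empty [start, end) range")

    def arc_length_px(self) -> float:
        v = np.asarray(self.vertices, dtype=float)
        return float(np.sum(np.hypot(*np.diff(v, axis=0).T)))

    def to_json(self) -> str:
        payload = {
            "vertices": [[y, x] for y, x in self.vertices],
            "sampling_width": self.sampling_width,
            "dendrite_segment": list(self.dendrite_segment) if self.dendrite_segment else None,
        }
        if self.dendrite_length_um is not None:
            payload["dendrite_length_um"] = self.dendrite_length_um
        return json.dumps(payload, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "LineROI":
        d = json.loads(text)
        seg = d.get("dendrite_segment")
        return cls(
            vertices=tuple((y, x) for y, x in d["vertices"]),
            sampling_width=int(d.get("sampling_width", 3)),
            dendrite_segment=tuple(seg) if seg else None,
            dendrite_length_um=d.get("dendrite_length_um"),
        )


@dataclass
class IntensityProfile:
    """Fluorescence along a polyline ROI, with its correction stages.

    ``positions`` are μm of arc length from the first vertex (strictly
    increasing, starting at 0).  ``corrected`` and ``normalized`` are filled
    by :func:`subtract_background` / the normalization functions.
    """

    positions: np.ndarray
    raw: np.ndarray
    pixel_size: float
    step_px: float = SAMPLING_STEP_PX
    background: float | None = None
    corrected: np.ndarray | None = None
    dendrite_reference: float | None = None
    normalized: np.ndarray | None = None
    dendrite_segment: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.raw = np.asarray(self.raw, dtype=float)
        if self.positions.shape != self.raw.shape:
            raise ValueError("positions and raw must have equal length")
        if len(self.positions) >= 2 and not np.all(np.diff(self.positions) > 0):
            raise ValueError("positions must be strictly increasing")

    @property
    def n_samples(self) -> int:
        return len(self.positions)

    @property
    def step_um(self) -> float:
        return self.step_px * self.pixel_size

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(
            {
                "position_um": self.positions,
                "raw": self.raw,
                "corrected": self.corrected if self.corrected is not None else np.nan,
                "normalized": self.normalized if self.normalized is not None else np.nan,
            }
        ).to_csv(path, index=False)


def max_intensity_projection(stack: np.ndarray) -> np.ndarray:
    """Per-pixel maximum over the z axis of a ``(z, H, W)`` stack.

    A 2D image is passed through unchanged, so the operation is idempotent.
    """
    stack = np.asarray(stack)
    if stack.ndim == 2:
        return stack
    if stack.ndim != 3 or stack.shape[0] < 1:
        raise ValueError("expected a (z, H, W) stack with at least one plane")
    return stack.max(axis=0)


def _resample_polyline(roi: LineROI) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sample points and unit normals at SAMPLING_STEP_PX arc spacing."""
    v = np.asarray(roi.vertices, dtype=float)
    seg = np.diff(v, axis=0)
    seg_len = np.hypot(seg[:, 0], seg[:, 1])
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    total = cum[-1]
    arcs = np.arange(0.0, total + 1e-9, SAMPLING_STEP_PX)
    arcs = arcs[arcs <= total + 1e-9]
    idx = np.clip(np.searchsorted(cum, arcs, side="right") - 1, 0, len(seg) - 1)
    t = (arcs - cum[idx]) / np.where(seg_len[idx] > 0, seg_len[idx], 1.0)
    pts = v[idx] + seg[idx] * t[:, None]
    tang = seg[idx] / seg_len[idx][:, None]
    normals = np.stack([-tang[:, 1], tang[:, 0]], axis=1)
    return arcs, pts, normals


def extract_profile(image: np.ndarray, roi: LineROI, pixel_size: float) -> IntensityProfile:
    """Sample the mean fluorescence across ``sampling_width`` perpendicular
    pixels at sub-pixel steps along the ROI polyline.

    Raises ``ValueError`` naming the first out-of-bounds vertex if the ROI
    leaves the image.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("extract_profile expects a 2D image (project stacks first)")
    if pixel_size <= 0:
        raise ValueError("pixel_size must be > 0")
    h, w = image.shape
    for i, (y, x) in enumerate(roi.vertices):
        if not (0 <= y <= h - 1 and 0 <= x <= w - 1):
            raise ValueError(f"ROI vertex {i} at (y={y}, x={x}) lies outside the image")

    arcs, pts, normals = _resample_polyline(roi)
    half = roi.sampling_width // 2
    offsets = np.arange(-half, half + 1)
    # (n_offsets, n_samples, 2) sample coordinates across the sampling width
    coords = pts[None, :, :] + offsets[:, None, None] * normals[None, :, :]
    values = ndimage.map_coordinates(
        image, [coords[..., 0].ravel(), coords[..., 1].ravel()], order=1, mode="nearest"
    ).reshape(len(offsets), len(arcs))
    raw = values.mean(axis=0)
    return IntensityProfile(
        positions=arcs * pixel_size,
        raw=raw,
        pixel_size=pixel_size,
        dendrite_segment=roi.dendrite_segment,
    )


def subtract_background(
    profile: IntensityProfile,
    background_estimator: str = "percentile",
    param: float = 5.0,
) -> IntensityProfile:
    """Estimate and subtract a scalar background from the raw profile.

    ``percentile`` (default) takes the given percentile of the ROI's own raw
    profile — self-contained and robust to field inhomogeneity.  ``roi_mean``
    uses ``param`` directly as a background level measured from a separate
    user-drawn background ROI.  Corrected values are floored at zero.
    """
    if background_estimator == "percentile":
        background = float(np.percentile(profile.raw, param))
    elif background_estimator == "roi_mean":
        background = float(param)
    else:
        raise ValueError(f"unknown background estimator {background_estimator!r}")
    if background >= profile.raw.max():
        warnings.warn(
            "background estimate is at or above the profile maximum; "
            "corrected profile will be identically zero",
            stacklevel=2,
        )
    corrected = np.maximum(profile.raw - background, 0.0)
    out = replace(profile)
    out.background = background
    out.corrected = corrected
    return out


def normalize_to_dendrite(
    profile: IntensityProfile,
    dendrite_segment: tuple[int, int] | None = None,
    statistic: str = "mean",
) -> IntensityProfile:
    """Normalize a background-corrected profile to the adjacent dendrite.

    The reference is the mean (or median) of the corrected values over the
    designated dendrite segment; after this step the dendritic shaft sits at
    1 "normalized dendrite unit", cancelling acquisition-to-acquisition gain
    differences.
    """
    seg = dendrite_segment or profile.dendrite_segment
    if seg is None:
        raise ValueError("no dendrite_segment given for normalization")
    if profile.corrected is None:
        raise ValueError("subtract background before normalizing")
    s, e = seg
    chunk = profile.corrected[s:e]
    if chunk.size == 0:
        raise ValueError("dendrite_segment selects no samples")
    if statistic == "mean":
        ref = float(np.mean(chunk))
    elif statistic == "median":
        ref = float(np.median(chunk))
    else:
        raise ValueError(f"unknown reference statistic {statistic!r}")
    if ref <= 0:
        raise ValueError(
            "dendrite reference is not positive; ROI is uninterpretable "
            "(dendrite segment may lie on background)"
        )
    out = replace(profile)
    out.dendrite_segment = seg
    out.dendrite_reference = ref
    out.normalized = profile.corrected / ref
    return out


def normalize_to_background(profile: IntensityProfile) -> IntensityProfile:
    """Divide the raw trace by its scalar background (background == 1).

    Used by the microglia pipeline, where soma and process metrics are read
    off a background-normalized trace rather than a dendrite-normalized one.
    """
    if profile.background is None:
        raise ValueError("estimate background before normalizing to it")
    if profile.background <= 0:
        raise ValueError("background must be positive to normalize to it")
    out = replace(profile)
    out.dendrite_reference = profile.background
    out.normalized = profile.raw / profile.background
    return out


def percent_area_stained(image: np.ndarray, threshold: float) -> float:
    """Percentage of image pixels strictly above ``threshold``."""
    image = np.asarray(image)
    if image.size == 0:
        raise ValueError("empty image")
    return 100.0 * float(np.count_nonzero(image > threshold)) / image.size
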