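"""Microglia soma and process morphometry from a single intensity profile.

The measurement is a deliberate 1D proxy: a line through the longest
dimension of the cell body and across the tips of the process arbor yields a
background-normalized trace (background == 1) on which the soma is the
dominant central excursion and each crossed process a smaller bump.  Soma
size = normalized soma peak x soma width; processes are peaks at least 25%
above background outside the soma span; process area sums the per-peak AUC;
process perimeter is the trace length (in pixels / scale) covered by peaks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _peaks
from .roi_profiles import (
    IntensityProfile,
    LineROI,
    extract_profile,
    max_intensity_projection,
    normalize_to_background,
    subtract_background,
)

PROCESS_THRESHOLD_FRAC = 0.25  # processes must exceed background by 25%


@dataclass
class MicrogliaMeasurement:
    """Soma and process metrics of one microglial cell."""

    cell_id: str
    soma_size: float  # normalized-unit · μm
    n_processes: int
    process_area: float  # normalized-unit · μm, summed over processes
    process_perimeter: float  # μm
    region: str = "hippocampus"
    genotype: str = ""
    treatment: str = ""
    params: dict = field(default_factory=dict)


def soma_size(profile: IntensityProfile, soma_span: tuple[int, int]) -> float:
    """Normalized soma peak height times the soma span width in μm."""
    if profile.normalized is None:
        raise ValueError("profile must be background-normalized")
    s, e = soma_span
    if e <= s or s < 0 or e > profile.n_samples:
        raise ValueError("soma_span is empty or outside the profile")
    peak = float(np.max(profile.normalized[s:e]))
    width = float(profile.positions[e - 1] - profile.positions[s])
    return peak * width


def detect_process_peaks(
    profile: IntensityProfile,
    threshold_frac: float = PROCESS_THRESHOLD_FRAC,
    soma_span: tuple[int, int] | None = None,
) -> list[_peaks.Peak]:
    """Process peaks: maxima >= 1 + threshold_frac outside the soma span.

    One peak per supra-threshold excursion, bounds at background (value 1)
    crossings clipped at inter-peak valleys.
    """
    if profile.normalized is None:
        raise ValueError("profile must be background-normalized")
    values = profile.normalized
    if soma_span is not None:
        # exclude the soma region from the trace: a process adjacent to the
        # cell body must not be swallowed by the soma's own excursion
        values = values.copy()
        s, e = soma_span
        values[max(s, 0):e] = 1.0
    return _peaks.find_peaks(
        values,
        profile.positions,
        threshold=1.0 + threshold_frac,
        exclude=soma_span,
    )


def process_area(peaks: list[_peaks.Peak], profile: IntensityProfile) -> float:
    """Summed area under each process peak above the background level."""
    if profile.normalized is None:
        raise ValueError("profile must be background-normalized")
    return float(
        sum(_peaks.peak_area(profile.normalized, profile.positions, p) for p in peaks)
    )


def process_perimeter(
    peaks: list[_peaks.Peak], scale: float, step_px: float = 0.5
) -> float:
    """Total pixels covered by detected peaks divided by ``scale`` (px/μm).

    Coverage is measured along the 1D trace: profile samples (spaced
    ``step_px`` pixels apart) lying within any peak's bounds, with
    overlapping peaks counted once.
    """
    if scale <= 0:
        raise ValueError("scale must be > 0 pixels/μm")
    if not peaks:
        return 0.0
    intervals = sorted((p.left_idx, p.right_idx) for p in peaks)
    merged: list[list[int]] = [list(intervals[0])]
    for lo, hi in intervals[1:]:
        if lo <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], hi)
        else:
            merged.append([lo, hi])
    covered_px = sum((hi - lo) * step_px for lo, hi in merged)
    return covered_px / scale


def measure_microglia(
    stack: np.ndarray,
    roi: LineROI,
    soma_span: tuple[int, int],
    pixel_size: float,
    cell_id: str = "cell",
    threshold_frac: float = PROCESS_THRESHOLD_FRAC,
    background_estimator: str = "percentile",
    background_param: float = 5.0,
    genotype: str = "",
    treatment: str = "",
    region: str = "hippocampus",
) -> MicrogliaMeasurement:
    """Full microglia pipeline on one image stack.

    MIP -> profile extraction -> background normalization -> soma size and
    process count/area/perimeter.  ``soma_span`` is the manually delineated
    (or ground-truth) index range of the trace belonging to the cell body.
    """
    image = max_intensity_projection(stack)
    profile = extract_profile(image, roi, pixel_size)
    profile = subtract_background(profile, background_estimator, background_param)
    profile = normalize_to_background(profile)
    peaks = detect_process_peaks(profile, threshold_frac, soma_span)
    area = process_area(peaks, profile)
    perimeter = process_perimeter(peaks, scale=1.0 / pixel_size, step_px=profile.step_px)
    return MicrogliaMeasurement(
        cell_id=cell_id,
        soma_size=soma_size(profile, soma_span),
        n_processes=len(peaks),
        process_area=area,
        process_perimeter=perimeter,
        genotype=genotype,
        treatment=treatment,
        region=region,
        params={
            "threshold_frac": threshold_frac,
            "background_estimator": background_estimator,
            "background_param": background_param,
            "pixel_size": pixel_size,
        },
    )
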