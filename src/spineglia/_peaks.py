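"""Excursion-based peak detection on normalized 1D profiles.

Shared engine for spine and process counting.  A peak is one supra-threshold
excursion of the profile; its bounds are the nearest crossings of the
baseline level on either side, clipped at the valley separating it from a
neighboring peak that shares the same above-baseline excursion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class Peak:
    """One detected fluorescence peak, indices into the profile arrays."""

    apex_idx: int
    left_idx: int
    right_idx: int  # inclusive
    position: float  # μm
    apex_value: float
    left_bound: float  # μm
    right_bound: float  # μm


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Contiguous True runs as (start, stop) half-open index pairs."""
    if not mask.any():
        return []
    padded = np.concatenate([[False], mask, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    return list(zip(edges[::2], edges[1::2]))


def find_peaks(
    values: np.ndarray,
    positions: np.ndarray,
    threshold: float,
    baseline: float = 1.0,
    exclude: tuple[int, int] | None = None,
) -> list[Peak]:
    """Detect one peak per supra-``threshold`` excursion of ``values``.

    Within a single above-``baseline`` excursion, separate supra-threshold
    runs are separate peaks split at the intervening valley; jagged maxima
    inside one supra-threshold run collapse to the single highest apex.
    Peaks whose apex falls inside the half-open ``exclude`` index range are
    dropped (used to mask the soma region in microglia traces).
    """
    values = np.asarray(values, dtype=float)
    positions = np.asarray(positions, dtype=float)
    peaks: list[Peak] = []
    for b_start, b_stop in _runs(values > baseline):
        runs = _runs(values[b_start:b_stop] >= threshold)
        apices = [b_start + s + int(np.argmax(values[b_start + s:b_start + e]))
                  for s, e in runs]
        for i, apex in enumerate(apices):
            # left bound: baseline crossing, or valley toward the previous apex
            if i > 0:
                lo = apices[i - 1]
                left = lo + int(np.argmin(values[lo:apex + 1]))
            else:
                left = b_start
            if i < len(apices) - 1:
                hi = apices[i + 1]
                right = apex + int(np.argmin(values[apex:hi + 1]))
            else:
                right = b_stop - 1
            if exclude is not None and exclude[0] <= apex < exclude[1]:
                continue
            peaks.append(
                Peak(
                    apex_idx=apex,
                    left_idx=left,
                    right_idx=right,
                    position=float(positions[apex]),
                    apex_value=float(values[apex]),
                    left_bound=float(positions[left]),
                    right_bound=float(positions[right]),
                )
            )
    return peaks


def peak_area(values: np.ndarray, positions: np.ndarray, peak: Peak,
              baseline: float = 1.0) -> float:
    """Trapezoidal area of ``max(values - baseline, 0)`` over the peak bounds."""
    if peak.right_idx < peak.left_idx:
        raise ValueError("peak bounds are inverted")
    if peak.right_idx == peak.left_idx:  # single-sample spike
        return 0.0
    sl = slice(peak.left_idx, peak.right_idx + 1)
    excess = np.maximum(np.asarray(values, dtype=float)[sl] - baseline, 0.0)
    return float(np.trapezoid(excess, np.asarray(positions, dtype=float)[sl]))
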