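"""Spatial expression quantification in antennal-lobe images.

Two procedures: (1) wide-line intensity profiles along an anatomical axis
(e.g. dorsomedial -> ventrolateral), min-max normalized per lobe per channel
and averaged across lobes after resampling to a common length; (2) per-
glomerulus mean intensity of a channel normalized to a reference channel
(e.g. Ncad) to correct for depth-dependent signal attenuation. Glomerulus
masks are user input (manual segmentation), not computed here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.measure import profile_line

from .errors import ValidationError


@dataclass
class ProfileRecord:
    """A min-max-normalized 1-D intensity profile on a [0, 1] axis."""

    positions: np.ndarray
    values: np.ndarray
    degenerate: bool = False
    source: str = ""

    def __post_init__(self) -> None:
        if len(self.positions) != len(self.values):
            raise ValidationError("positions and values must align")
        if np.any(np.diff(self.positions) <= 0):
            raise ValidationError("positions must be strictly increasing")

    @property
    def n_samples(self) -> int:
        return len(self.values)


def line_profile(
    channel: np.ndarray,
    start: tuple[float, float],
    end: tuple[float, float],
    width_px: int = 10,
) -> np.ndarray:
    """Mean intensity across a ``width_px``-wide straight line from start to end.

    ``start``/``end`` are (x, y) image coordinates. Sampling steps at unit
    spacing along the line with bilinear interpolation; at each step the
    profile value is the mean over ``width_px`` evenly spaced perpendicular
    offsets centered on the line.
    """
    if width_px < 1:
        raise ValidationError("width_px must be >= 1")
    (x0, y0), (x1, y1) = start, end
    if np.hypot(x1 - x0, y1 - y0) == 0:
        raise ValidationError("zero-length line")
    for x, y in (start, end):
        if not (0 <= y < channel.shape[0] and 0 <= x < channel.shape[1]):
            raise ValidationError(f"endpoint ({x}, {y}) outside the image")
    return np.asarray(
        profile_line(
            np.asarray(channel, dtype=float),
            (y0, x0),
            (y1, x1),
            linewidth=width_px,
            order=1,
            mode="nearest",
            reduce_func=np.mean,
        )
    )


def minmax_normalize(raw: np.ndarray, source: str = "") -> ProfileRecord:
    """(v - min) / (max - min); constant profiles are flagged degenerate (all zero)."""
    raw = np.asarray(raw, dtype=float)
    if raw.size < 2:
        raise ValidationError("profile needs at least 2 samples")
    positions = np.linspace(0.0, 1.0, raw.size)
    lo, hi = raw.min(), raw.max()
    if hi == lo:
        warnings.warn(f"degenerate profile (constant intensity){': ' + source if source else ''}")
        return ProfileRecord(positions=positions, values=np.zeros_like(raw),
                             degenerate=True, source=source)
    return ProfileRecord(positions=positions, values=(raw - lo) / (hi - lo), source=source)


def average_profiles(
    profiles: list[ProfileRecord], n_points: int = 100
) -> pd.DataFrame:
    """Pointwise mean +/- SEM after linear resampling to ``n_points`` on [0, 1]."""
    if len(profiles) < 2:
        raise ValidationError("need at least 2 profiles to average")
    grid = np.linspace(0.0, 1.0, n_points)
    resampled = np.vstack(
        [np.interp(grid, p.positions, p.values) for p in profiles]
    )
    mean = resampled.mean(axis=0)
    sem = resampled.std(axis=0, ddof=1) / np.sqrt(len(profiles))
    return pd.DataFrame({"position": grid, "mean": mean, "sem": sem})


def glomerular_intensity(
    channel: np.ndarray,
    reference: np.ndarray,
    roi_masks: np.ndarray,
    names: dict[int, str] | None = None,
) -> pd.DataFrame:
    """Per-ROI ratio of mean channel intensity to mean reference intensity.

    ``roi_masks`` is a labeled image (0 = background). ROIs with zero mean
    reference signal are flagged invalid (NaN normalized value).
    """
    if channel.shape != reference.shape or channel.shape != roi_masks.shape:
        raise ValidationError("channel, reference, and roi_masks must share shape")
    rows = []
    for lab in np.unique(roi_masks):
        if lab == 0:
            continue
        m = roi_masks == lab
        mean_ch = float(channel[m].mean())
        mean_ref = float(reference[m].mean())
        valid = mean_ref > 0
        if not valid:
            warnings.warn(f"ROI {lab} has zero reference mean; flagged invalid")
        rows.append(
            {
                "glomerulus": names.get(int(lab), str(int(lab))) if names else str(int(lab)),
                "label": int(lab),
                "mean_channel": mean_ch,
                "mean_reference": mean_ref,
                "normalized": mean_ch / mean_ref if valid else np.nan,
                "valid": valid,
            }
        )
    return pd.DataFrame(rows)
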