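"""Automated binding-image quantification.

Reproduces a confocal binding-assay macro: max-project the z-stack, segment
transfected cells by Otsu thresholding on the full-length receptor (FL)
channel, identify untransfected control cells from the nuclear channel after
subtracting the FL mask, dilate nuclear ROIs by ~1.25 um toward cell-body
extent, gate ROIs on area (7.8-23.4 um^2) and circularity (> 0.9), and
measure mean ectodomain (ECD) intensity per ROI.

Conventions: 8-connected components; circularity = 4*pi*area / perimeter^2
with the Crofton (multi-directional) perimeter estimator, under which a
rasterized disk of radius >= 10 px clears the 0.9 gate; area and circularity
gates are evaluated on the pre-dilation nuclear component (the dilated region
defines the measurement mask and the FL-overlap exclusion).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.measure import regionprops
from skimage.morphology import dilation, disk

import pandas as pd

from .containers import ImageStack
from .errors import ValidationError
from ._util import log

AREA_GATE_UM2 = (7.8, 23.4)
MIN_CIRCULARITY = 0.9
DILATION_UM = 1.25


@dataclass
class RoiRecord:
    """One segmented cell region and its per-channel mean intensities."""

    label: int
    roi_class: str                      # "transfected" | "control"
    pixel_count: int                    # pixels of the gated component
    area_um2: float
    circularity: float
    pixels: np.ndarray                  # (n, 2) row/col indices of the measurement mask
    mean_intensity: dict[str, float] = field(default_factory=dict)


def max_project(stack: ImageStack) -> ImageStack:
    """Per-pixel maximum over Z for each channel; identity for 2-D input."""
    if not stack.is_zstack:
        return ImageStack(
            channels={n: a.copy() for n, a in stack.channels.items()},
            pixel_size_um=stack.pixel_size_um,
            bit_depth=stack.bit_depth,
        )
    return ImageStack(
        channels={n: a.max(axis=0) for n, a in stack.channels.items()},
        pixel_size_um=stack.pixel_size_um,
        bit_depth=stack.bit_depth,
    )


def otsu_threshold(channel: np.ndarray, n_bins: int = 256) -> float:
    """Threshold maximizing between-class variance of the binned histogram.

    Foreground is ``channel > threshold``.
    """
    channel = np.asarray(channel)
    if np.unique(channel).size < 2:
        raise ValidationError("constant image: no foreground to threshold")
    return float(threshold_otsu(channel, nbins=n_bins))


def _component_records(
    mask: np.ndarray, pixel_size_um: float, roi_class: str
) -> tuple[np.ndarray, list[RoiRecord]]:
    labels = cc_label(mask, connectivity=2)
    records = []
    for prop in regionprops(labels):
        perim = prop.perimeter_crofton
        circ = 4.0 * np.pi * prop.area / perim**2 if perim > 0 else 0.0
        records.append(
            RoiRecord(
                label=int(prop.label),
                roi_class=roi_class,
                pixel_count=int(prop.area),
                area_um2=float(prop.area) * pixel_size_um**2,
                circularity=float(circ),
                pixels=np.asarray(prop.coords),
            )
        )
    return labels, records


def segment_transfected(
    fl_channel: np.ndarray, pixel_size_um: float
) -> tuple[np.ndarray, list[RoiRecord]]:
    """Label FL-positive (transfected) cells: Otsu mask, 8-connected components."""
    thr = otsu_threshold(fl_channel)
    mask = fl_channel > thr
    if not mask.any():
        warnings.warn("empty FL-positive mask; no transfected cells found")
        return np.zeros(fl_channel.shape, dtype=int), []
    return _component_records(mask, pixel_size_um, "transfected")


def segment_controls(
    nuclear_channel: np.ndarray,
    fl_mask: np.ndarray,
    pixel_size_um: float,
    *,
    dilation_um: float = DILATION_UM,
    area_range_um2: tuple[float, float] = AREA_GATE_UM2,
    min_circ: float = MIN_CIRCULARITY,
    gate_on: str = "nucleus",
) -> tuple[np.ndarray, list[RoiRecord]]:
    """Untransfected control ROIs from the nuclear channel.

    Otsu mask on the nuclear channel minus ``fl_mask``, labeled, each nuclear
    component dilated by ``round(dilation_um / pixel_size_um)`` px; components
    whose dilated footprint touches the FL mask are dropped; survivors are
    gated on area (within ``area_range_um2``, inclusive) and circularity
    (strictly above ``min_circ``). ``gate_on`` selects whether the gates read
    the pre-dilation nucleus (default) or the dilated ROI.
    """
    if gate_on not in ("nucleus", "dilated"):
        raise ValidationError("gate_on must be 'nucleus' or 'dilated'")
    thr = otsu_threshold(nuclear_channel)
    mask = (nuclear_channel > thr) & ~fl_mask.astype(bool)
    if not mask.any():
        warnings.warn("empty control mask; no control cells found")
        return np.zeros(nuclear_channel.shape, dtype=int), []
    labels, nuclei = _component_records(mask, pixel_size_um, "control")
    radius_px = int(round(dilation_um / pixel_size_um))
    if radius_px < 1:
        warnings.warn(
            f"dilation of {dilation_um} um is below one pixel at {pixel_size_um} um/px; skipping"
        )
    selem = disk(radius_px) if radius_px >= 1 else None
    kept: list[RoiRecord] = []
    out_labels = np.zeros_like(labels)
    for rec in nuclei:
        comp = labels == rec.label
        dilated = dilation(comp, selem) if selem is not None else comp
        if (dilated & fl_mask.astype(bool)).any():
            log.debug("control ROI %d overlaps FL mask after dilation; dropped", rec.label)
            continue
        if gate_on == "nucleus":
            gate_area, gate_circ = rec.area_um2, rec.circularity
        else:
            _, [drec] = _component_records(dilated, pixel_size_um, "control")
            gate_area, gate_circ = drec.area_um2, drec.circularity
        if not (area_range_um2[0] <= gate_area <= area_range_um2[1]):
            continue
        if not gate_circ > min_circ:
            continue
        rec = replace(rec, pixels=np.argwhere(dilated))
        kept.append(rec)
        out_labels[dilated] = rec.label
    return out_labels, kept


def measure_roi_intensity(
    rois: list[RoiRecord], channel: np.ndarray, channel_name: str = "ecd"
) -> list[RoiRecord]:
    """Arithmetic mean of ``channel`` over each ROI's measurement pixels."""
    out = []
    for rec in rois:
        rr, cc = rec.pixels[:, 0], rec.pixels[:, 1]
        if rr.max() >= channel.shape[0] or cc.max() >= channel.shape[1]:
            raise ValidationError(f"ROI {rec.label} extends beyond the image")
        mi = dict(rec.mean_intensity)
        mi[channel_name] = float(channel[rr, cc].mean())
        out.append(replace(rec, mean_intensity=mi))
    return out


def quantify_binding(
    stack: ImageStack,
    *,
    fl_channel: str = "fl",
    ecd_channel: str = "ecd",
    nuclear_channel: str = "nuclear",
    **control_kwargs,
) -> pd.DataFrame:
    """End-to-end quantification of one stack into a tidy per-ROI table."""
    proj = max_project(stack)
    fl = proj.channels[fl_channel]
    labels_t, transfected = segment_transfected(fl, proj.pixel_size_um)
    fl_mask = labels_t > 0
    _, controls = segment_controls(
        proj.channels[nuclear_channel], fl_mask, proj.pixel_size_um, **control_kwargs
    )
    rois = measure_roi_intensity(transfected + controls, proj.channels[ecd_channel], "ecd")
    return pd.DataFrame(
        {
            "label": [r.label for r in rois],
            "roi_class": [r.roi_class for r in rois],
            "pixel_count": [r.pixel_count for r in rois],
            "area_um2": [r.area_um2 for r in rois],
            "circularity": [r.circularity for r in rois],
            "mean_ecd": [r.mean_intensity["ecd"] for r in rois],
        }
    )


def summarize_binding(measurements: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-experiment group means plus a paired table for downstream statistics.

    ``measurements`` is long-format with columns ``experiment``, ``group``
    (transfected/control) and ``value`` (one row per cell). Experiments
    missing either group are excluded with a warning.
    """
    required = {"experiment", "group", "value"}
    if not required.issubset(measurements.columns):
        raise ValidationError(f"measurements needs columns {sorted(required)}")
    means = (
        measurements.groupby(["experiment", "group"], sort=True)["value"]
        .mean()
        .reset_index()
    )
    wide = means.pivot(index="experiment", columns="group", values="value")
    incomplete = wide[wide.isna().any(axis=1)].index.tolist()
    if incomplete:
        warnings.warn(f"experiment(s) missing a group, excluded: {incomplete}")
        wide = wide.dropna()
        means = means[~means["experiment"].isin(incomplete)]
    return means.reset_index(drop=True), wide.reset_index()
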