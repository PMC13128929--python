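"""Flatmount quantification: nucleus segmentation, cell classification,
background-corrected marker intensities, positive areas and TUNEL puncta.

The stage reproduces an automated microscopy workflow: nuclei are segmented
by IsoData thresholding of the DAPI channel followed by distance-transform
watershed; cells are classified from a solid CD31 (endothelial membrane)
mask and nuclear circularity; TUNEL puncta are segmented by Yen thresholding
plus watershed.  Background correction distinguishes nuclear markers
(background sampled inside the vessel mask, excluding nuclei) from membrane
markers (background sampled outside the mask).
"""

from __future__ import annotations

import warnings
from collections.abc import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage import filters, measure, morphology, segmentation
from skimage.feature import peak_local_max

from .types import (
    ENDOTHELIAL,
    EXTRAVASCULAR,
    INTACT_SEGMENT,
    OTHER_NON_ENDOTHELIAL,
    PERICYTE,
    AreaReport,
    FlatmountImage,
    NucleusRecord,
    PunctumRecord,
    QuantParams,
    VesselMask,
)

__all__ = [
    "build_vessel_mask",
    "segment_nuclei",
    "classify_cells",
    "quantify_nuclear_marker",
    "quantify_membrane_marker",
    "detect_tunel_puncta",
    "positive_area",
    "area_report",
    "aggregate_replicates",
]

_THRESHOLD_FUNCS = {
    "otsu": filters.threshold_otsu,
    "isodata": filters.threshold_isodata,
    "yen": filters.threshold_yen,
    "mean": filters.threshold_mean,
    "triangle": filters.threshold_triangle,
}


def _threshold(raster: np.ndarray, method: str) -> float:
    try:
        func = _THRESHOLD_FUNCS[method]
    except KeyError:
        raise ValueError(
            f"unknown threshold method {method!r}; available: {sorted(_THRESHOLD_FUNCS)}"
        ) from None
    return float(func(raster))


def build_vessel_mask(
    image: FlatmountImage,
    channel: str = "CD31",
    params: QuantParams | None = None,
    threshold: float | None = None,
) -> VesselMask:
    """Build a solid binary vessel mask from a membrane-marker channel.

    The channel is thresholded automatically (Otsu by default, configurable
    via ``params.mask_threshold_method`` or an explicit ``threshold``), then
    morphologically closed with a disc of ``mask_closing_radius_px``, holes
    are filled (vessel lumina belong to the footprint), and objects below
    ``min_mask_object_area_um2`` are removed.
    """
    params = params or QuantParams()
    raster = image.channel(channel)
    if raster.max() == raster.min():
        if raster.max() == 0:
            warnings.warn(
                f"channel {channel!r} is all-zero; returning an empty vessel mask",
                stacklevel=2,
            )
            return VesselMask(
                np.zeros(image.shape, bool), channel, image.pixel_size, fill_state=True
            )
        raise ValueError(f"channel {channel!r} is constant; cannot threshold")
    thr = _threshold(raster, params.mask_threshold_method) if threshold is None else threshold
    mask = raster > thr
    if params.mask_closing_radius_px > 0:
        footprint = morphology.disk(params.mask_closing_radius_px)
        mask = ndi.binary_erosion(
            ndi.binary_dilation(mask, footprint), footprint, border_value=1
        )
    mask = ndi.binary_fill_holes(mask)
    min_px = int(np.ceil(params.min_mask_object_area_um2 / image.pixel_size**2))
    if min_px > 1:
        labels, _ = ndi.label(mask)
        sizes = np.bincount(labels.ravel())
        sizes[0] = min_px  # background always kept out of removal logic
        mask = sizes[labels] >= min_px
        mask[labels == 0] = False
    return VesselMask(mask, channel, image.pixel_size, fill_state=True)


def _watershed_labels(
    binary: np.ndarray, min_separation_px: float
) -> np.ndarray:
    """Split touching objects by Euclidean-distance-transform watershed.

    Seeds are local maxima of the (lightly smoothed) distance transform with
    a minimum separation; smoothing breaks digitization plateaus so a convex
    object yields a single seed.
    """
    distance = ndi.distance_transform_edt(binary)
    smoothed = ndi.gaussian_filter(distance, sigma=1.0)
    min_dist = max(1, int(round(min_separation_px)))
    coords = peak_local_max(
        smoothed, min_distance=min_dist, labels=binary, exclude_border=False
    )
    markers = np.zeros(binary.shape, dtype=int)
    markers[tuple(coords.T)] = np.arange(1, len(coords) + 1)
    if markers.max() == 0:
        return measure.label(binary, connectivity=2)
    return segmentation.watershed(-smoothed, markers, mask=binary)


def _regions_to_records(
    labels: np.ndarray, pixel_size: float, min_area_um2: float
) -> list[tuple[np.ndarray, tuple[float, float], float, float]]:
    px_area = pixel_size**2
    out = []
    for region in measure.regionprops(labels):
        area = region.area * px_area
        if area < min_area_um2:
            continue
        out.append(
            (
                region.coords,
                tuple(region.centroid),
                area,
                region.perimeter * pixel_size,
            )
        )
    return out


def segment_nuclei(
    image: FlatmountImage,
    dapi_channel: str = "DAPI",
    params: QuantParams | None = None,
) -> list[NucleusRecord]:
    """Segment nuclei from the DAPI channel.

    IsoData global thresholding followed by distance-transform watershed;
    components smaller than ``min_nucleus_area_um2`` are discarded.  Each
    record carries area (µm²), perimeter (µm) and circularity 4πA/P²
    clipped to 1.
    """
    params = params or QuantParams()
    raster = image.channel(dapi_channel)
    if params.smoothing_sigma_px > 0:
        raster = ndi.gaussian_filter(raster, params.smoothing_sigma_px)
    if raster.max() == raster.min():
        return []
    thr = _threshold(raster, params.nuclear_threshold_method)
    binary = raster > thr
    if not binary.any():
        return []
    labels = _watershed_labels(
        binary, params.watershed_min_separation_um / image.pixel_size
    )
    records = []
    for i, (coords, centroid, area, perim) in enumerate(
        _regions_to_records(labels, image.pixel_size, params.min_nucleus_area_um2)
    ):
        circ = 1.0 if perim == 0 else min(1.0, 4.0 * np.pi * area / perim**2)
        records.append(
            NucleusRecord(
                nucleus_id=i,
                coords=coords,
                centroid=centroid,
                area_um2=area,
                perimeter_um=perim,
                circularity=circ,
            )
        )
    return records


def classify_cells(
    nuclei: Iterable[NucleusRecord],
    mask: VesselMask,
    params: QuantParams | None = None,
) -> list[NucleusRecord]:
    """Assign each nucleus to endothelial / pericyte / other_non_endothelial.

    A nucleus whose centroid lies inside the solid vessel mask is
    endothelial; outside the mask, elongated nuclei (circularity ≤ cutoff,
    default 0.6) are pericytes and the rest are other non-endothelial cells.
    Records are updated in place and returned.
    """
    params = params or QuantParams()
    if not mask.fill_state:
        raise ValueError("vessel mask must be solid (fill_state) before classification")
    nuclei = list(nuclei)
    nrow, ncol = mask.mask.shape
    for nuc in nuclei:
        r = min(nrow - 1, max(0, int(round(nuc.centroid[0]))))
        c = min(ncol - 1, max(0, int(round(nuc.centroid[1]))))
        if mask.mask[r, c]:
            nuc.cell_class = ENDOTHELIAL
        elif nuc.circularity <= params.circularity_cutoff:
            nuc.cell_class = PERICYTE
        else:
            nuc.cell_class = OTHER_NON_ENDOTHELIAL
    return nuclei


def quantify_nuclear_marker(
    image: FlatmountImage,
    marker_channel: str,
    nuclei: Sequence[NucleusRecord],
    mask: VesselMask,
    params: QuantParams | None = None,
    summary_class: str = ENDOTHELIAL,
) -> tuple[list[NucleusRecord], float]:
    """Background-corrected integrated nuclear-marker intensities.

    The background level is the mean marker intensity inside the vessel mask
    excluding all nuclear pixels.  Each nucleus gets integrated intensity
    ``sum(pixels) - background * n_pixels`` (negative values retained); the
    per-flatmount summary is the median over nuclei of ``summary_class``.
    """
    raster = image.channel(marker_channel)
    bg_region = mask.mask.copy()
    for nuc in nuclei:
        bg_region[tuple(nuc.coords.T)] = False
    if not bg_region.any():
        raise ValueError(
            "background region (vessel mask excluding nuclei) is empty; "
            "cannot estimate nuclear-marker background"
        )
    background = float(raster[bg_region].mean())
    values = []
    for nuc in nuclei:
        pix = raster[tuple(nuc.coords.T)]
        corrected = float(pix.sum() - background * pix.size)
        nuc.marker_intensities[marker_channel] = corrected
        if nuc.cell_class == summary_class or summary_class is None:
            values.append(corrected)
    summary = float(np.median(values)) if values else float("nan")
    return list(nuclei), summary


def quantify_membrane_marker(
    image: FlatmountImage,
    marker_channel: str,
    mask: VesselMask,
    params: QuantParams | None = None,
) -> float:
    """Background-corrected mean membrane-marker intensity per field.

    Result is ``mean(channel inside mask) - mean(channel outside mask)``;
    the outside-mask region provides the background estimate.
    """
    raster = image.channel(marker_channel)
    inside = mask.mask
    if not inside.any() or inside.all():
        raise ValueError(
            "vessel mask is degenerate (covers none or all of the image); "
            "cannot separate signal from background"
        )
    return float(raster[inside].mean() - raster[~inside].mean())


def detect_tunel_puncta(
    image: FlatmountImage,
    tunel_channel: str = "TUNEL",
    mask: VesselMask | None = None,
    params: QuantParams | None = None,
) -> list[PunctumRecord]:
    """Segment TUNEL puncta by Yen thresholding followed by watershed.

    Puncta with centroid outside the vessel mask are tagged extravascular;
    the rest are provisionally intravascular (``intact_segment``) until
    segment assignment.
    """
    params = params or QuantParams()
    raster = image.channel(tunel_channel)
    if params.smoothing_sigma_px > 0:
        raster = ndi.gaussian_filter(raster, params.smoothing_sigma_px)
    if raster.max() == raster.min():
        return []
    thr = _threshold(raster, params.puncta_threshold_method)
    binary = raster > thr
    if not binary.any():
        return []
    # puncta are small; a tight seed separation still splits touching spots
    labels = _watershed_labels(binary, min_separation_px=2)
    records = []
    nrow, ncol = raster.shape
    for i, (coords, centroid, area, _perim) in enumerate(
        _regions_to_records(labels, image.pixel_size, params.min_punctum_area_um2)
    ):
        loc = INTACT_SEGMENT
        if mask is not None:
            r = min(nrow - 1, max(0, int(round(centroid[0]))))
            c = min(ncol - 1, max(0, int(round(centroid[1]))))
            if not mask.mask[r, c]:
                loc = EXTRAVASCULAR
        records.append(
            PunctumRecord(
                punctum_id=i,
                coords=coords,
                centroid=centroid,
                area_um2=area,
                location_class=loc,
            )
        )
    return records


def positive_area(
    image: FlatmountImage,
    channel: str,
    params: QuantParams | None = None,
    threshold: float | None = None,
) -> float:
    """Marker-positive area of a channel in µm².

    The channel is thresholded (configurable method, Otsu default, or an
    explicit value) and the positive-pixel count converted with the squared
    pixel size.  An all-zero channel has zero positive area.
    """
    params = params or QuantParams()
    raster = image.channel(channel)
    if threshold is None:
        if raster.max() == raster.min():
            return 0.0
        threshold = _threshold(raster, params.mask_threshold_method)
    return float((raster > threshold).sum()) * image.pixel_size**2


def area_report(
    image: FlatmountImage,
    channels: Sequence[str],
    params: QuantParams | None = None,
    ratios: dict[str, tuple[str, str]] | None = None,
) -> AreaReport:
    """Positive areas for several channels plus requested area ratios."""
    report = AreaReport()
    for ch in channels:
        report.areas_um2[ch] = positive_area(image, ch, params)
    for name, (num, den) in (ratios or {}).items():
        report.add_ratio(name, num, den)
    return report


def aggregate_replicates(
    values: Sequence[float],
    animals: Sequence[str],
) -> pd.Series:
    """Collapse technical replicates to one biological replicate per animal.

    Fields of view and eyes from the same animal are technical replicates;
    the biological-replicate value is their mean.  Animals with no values
    are dropped with a warning.
    """
    if len(values) != len(animals):
        raise ValueError("values and animals must have equal length")
    df = pd.DataFrame({"animal": list(animals), "value": list(values)})
    df = df.dropna(subset=["value"])
    dropped = set(animals) - set(df["animal"])
    if dropped:
        warnings.warn(f"animals with no values dropped: {sorted(dropped)}", stacklevel=2)
    return df.groupby("animal", sort=True)["value"].mean()
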