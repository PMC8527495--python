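"""Embryo segmentation and anterior–posterior coordinate frame.

A lateral-view blastoderm embryo is an ovoid; its long axis is the
anterior–posterior (AP) axis and the short axis dorsal–ventral (DV).  The
mask is segmented from the nuclear channel, the axis frame is fit from the
mask's second central moments, and every pixel is mapped to normalized
embryo coordinates: ``u`` runs 0 (anterior tip) to 1 (posterior tip) in
egg-length fractions, ``v`` is the signed DV offset divided by the total DV
extent.  The central band — the pixels with ``|v| <= dv_fraction / 2``,
default the central 10% of the DV axis — is the region from which the 1D
profile is computed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional

import numpy as np
from scipy import ndimage
from skimage.filters import gaussian, threshold_otsu
from skimage.measure import find_contours, label


class SegmentationError(ValueError):
    pass


class GeometryError(ValueError):
    pass


@dataclass(frozen=True)
class EmbryoGeometry:
    """Embryo mask plus its principal-axis coordinate frame.

    ``ap_unit`` / ``dv_unit`` are orthonormal (row, col) vectors;
    projections of mask pixels (relative to the centroid) onto them span
    ``[ap_min, ap_max]`` and ``[dv_min, dv_max]`` pixels.  ``anterior_sign``
    is +1 when the anterior tip lies at ``ap_min`` and -1 when at
    ``ap_max``.
    """

    mask: np.ndarray
    centroid: np.ndarray
    ap_unit: np.ndarray
    dv_unit: np.ndarray
    ap_min: float
    ap_max: float
    dv_min: float
    dv_max: float
    anterior_sign: int

    @property
    def ap_extent(self) -> float:
        return self.ap_max - self.ap_min

    @property
    def dv_extent(self) -> float:
        return self.dv_max - self.dv_min

    def to_dict(self) -> dict:
        return {
            "centroid": self.centroid.tolist(),
            "ap_unit": self.ap_unit.tolist(),
            "dv_unit": self.dv_unit.tolist(),
            "ap_extent": self.ap_extent,
            "dv_extent": self.dv_extent,
            "anterior_sign": self.anterior_sign,
        }


def smoothed_boundary_surface(
    image: np.ndarray, nuclear_channel: int
) -> tuple[np.ndarray, float]:
    """Smoothed nuclear channel and its Otsu level.

    The iso-contour of this surface at the returned level traces the
    embryo outline with sub-pixel precision; :func:`fit_axes` uses it to
    measure axis extents stably under rotation of the imaging frame.
    """
    nuc = np.asarray(image[nuclear_channel], dtype=float)
    if np.ptp(nuc) == 0:
        raise SegmentationError("segmentation failed: constant nuclear channel")
    smoothed = gaussian(nuc, sigma=2, preserve_range=True)
    return smoothed, float(threshold_otsu(smoothed))


def segment_embryo(image: np.ndarray, nuclear_channel: int) -> np.ndarray:
    """Segment the embryo from the nuclear channel.

    Light Gaussian smoothing, Otsu global threshold, keep the largest
    connected component, fill holes.  Raises :class:`SegmentationError`
    for constant images, empty masks, or masks hugging the image border
    (a sign the embryo was not fully in frame).
    """
    image = np.asarray(image)
    if image.ndim != 3 or nuclear_channel >= image.shape[0]:
        raise SegmentationError("nuclear channel missing")
    try:
        smoothed, thresh = smoothed_boundary_surface(image, nuclear_channel)
    except SegmentationError:
        raise
    except ValueError as exc:
        raise SegmentationError(f"segmentation failed: {exc}") from exc
    mask = smoothed > thresh
    if not mask.any():
        raise SegmentationError("segmentation failed: empty mask")
    labels = label(mask)
    largest = np.argmax(np.bincount(labels.ravel())[1:]) + 1
    mask = labels == largest
    mask = ndimage.binary_fill_holes(mask)
    border = np.concatenate([mask[0], mask[-1], mask[:, 0], mask[:, -1]])
    if border.mean() > 0.5:
        raise SegmentationError("segmentation failed: mask touches image border")
    return mask


def _principal_axes(mask: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Centroid and orthonormal principal axes from mask second moments."""
    coords = np.argwhere(mask).astype(float)
    centroid = coords.mean(axis=0)
    centered = coords - centroid
    cov = centered.T @ centered / len(coords)
    eigvals, eigvecs = np.linalg.eigh(cov)  # ascending
    if eigvals[0] <= 0 or eigvals[1] / eigvals[0] < 1.2:
        raise GeometryError("ambiguous axes: mask is nearly circular")
    ap = eigvecs[:, 1]
    # canonical orientation: AP unit points toward +col (ties: +row)
    if ap[1] < 0 or (ap[1] == 0 and ap[0] < 0):
        ap = -ap
    dv = np.array([-ap[1], ap[0]])
    return centroid, ap, dv


def fit_axes(
    mask: np.ndarray,
    anterior: Literal["left", "right", "auto"] = "left",
    target: Optional[np.ndarray] = None,
    boundary: Optional[tuple[np.ndarray, float]] = None,
) -> EmbryoGeometry:
    """Fit the AP/DV frame of a segmented embryo.

    ``anterior`` resolves the 180° ambiguity of the principal axis:
    ``left``/``right`` use the imaging convention (anterior at low/high
    column coordinate); ``auto`` orients the axis so that the strongest
    stripe signal in ``target`` lies in the posterior half — valid for
    wild-type-like patterns where the posterior-most stripe is strongest,
    but unreliable when posterior expression is strongly reduced.

    ``boundary`` is an optional ``(surface, level)`` pair (see
    :func:`smoothed_boundary_surface`); when given, the axis extents are
    measured on the sub-pixel iso-contour of the surface, which is stable
    to tip rasterization; otherwise extremes of the mask pixel centers are
    used.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise GeometryError("empty mask")
    centroid, ap, dv = _principal_axes(mask)
    coords = np.argwhere(mask).astype(float) - centroid
    p_ap = coords @ ap
    p_dv = coords @ dv
    if boundary is not None:
        surface, level = boundary
        contours = find_contours(np.asarray(surface, dtype=float), level)
        if contours:
            outline = max(contours, key=len) - centroid
            c_ap = outline @ ap
            c_dv = outline @ dv
            ap_min, ap_max = float(c_ap.min()), float(c_ap.max())
            dv_min, dv_max = float(c_dv.min()), float(c_dv.max())
        else:
            boundary = None
    if boundary is None:
        ap_min, ap_max = float(p_ap.min()), float(p_ap.max())
        dv_min, dv_max = float(p_dv.min()), float(p_dv.max())

    if anterior == "left":
        sign = 1  # ap_unit points toward +col, so low-col tip is at ap_min
    elif anterior == "right":
        sign = -1
    elif anterior == "auto":
        if target is None:
            raise GeometryError("auto anterior mode requires the target channel")
        vals = np.asarray(target, dtype=float)[mask]
        u_fwd = (p_ap - ap_min) / (ap_max - ap_min)
        nbins = 50
        idx = np.clip((u_fwd * nbins).astype(int), 0, nbins - 1)
        sums = np.bincount(idx, weights=vals, minlength=nbins)
        counts = np.maximum(np.bincount(idx, minlength=nbins), 1)
        prof = sums / counts
        sign = 1 if np.argmax(prof) >= nbins / 2 else -1
    else:
        raise GeometryError(f"unknown anterior policy {anterior!r}")

    return EmbryoGeometry(
        mask=mask,
        centroid=centroid,
        ap_unit=ap,
        dv_unit=dv,
        ap_min=ap_min,
        ap_max=ap_max,
        dv_min=dv_min,
        dv_max=dv_max,
        anterior_sign=sign,
    )


def to_embryo_coords(
    pixels: np.ndarray, geometry: EmbryoGeometry
) -> tuple[np.ndarray, np.ndarray]:
    """Map (row, col) pixels to normalized embryo coordinates (u, v).

    ``u`` is the AP fraction (0 anterior tip, 1 posterior tip); ``v`` the
    signed DV offset from the centroid divided by the total DV extent,
    approximately in [-0.5, 0.5].
    """
    pixels = np.atleast_2d(np.asarray(pixels, dtype=float))
    rel = pixels - geometry.centroid
    p_ap = rel @ geometry.ap_unit
    p_dv = rel @ geometry.dv_unit
    u = (p_ap - geometry.ap_min) / geometry.ap_extent
    if geometry.anterior_sign < 0:
        u = 1.0 - u  # exact flip symmetry
    v = p_dv / geometry.dv_extent
    return u, v


def extract_central_band(
    image: np.ndarray,
    geometry: EmbryoGeometry,
    dv_fraction: float = 0.10,
    channel: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Collect (u, intensity) samples from the central DV band.

    Returns the target-channel values of all in-mask pixels whose DV
    coordinate satisfies ``|v| <= dv_fraction / 2``, tagged with their AP
    fraction ``u``.
    """
    if not (0 < dv_fraction <= 1):
        raise GeometryError("dv_fraction must be in (0, 1]")
    image = np.asarray(image)
    pixels = np.argwhere(geometry.mask)
    u, v = to_embryo_coords(pixels, geometry)
    keep = np.abs(v) <= dv_fraction / 2
    if not keep.any():
        raise GeometryError("central band is empty")
    vals = np.asarray(image[channel], dtype=float)[pixels[keep, 0], pixels[keep, 1]]
    return u[keep], vals
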