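"""Segmentation of lipid-stained adipocytes in 3D volumes.

The classical (default) chain mirrors the structure of a commercial
general-analysis pipeline: intensity thresholding of the lipid channel,
morphological "circular open" to drop regions that cannot contain a sphere
of minimal adipocyte size, "separate objects" via watershed on the
Euclidean distance transform, and object filtering (minimum volume,
border-touching exclusion).  All distances are physical (µm) so the chain
is anisotropy-aware.

An optional trainable backend with the same thresholding contract lives in
:mod:`adipo3d.learning`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage import filters, morphology, segmentation as skseg

from .volumes import ImageVolume, LabelVolume, ParameterError, voxel_volume

logger = logging.getLogger(__name__)

__all__ = [
    "SegmentationConfig",
    "ThresholdError",
    "binarize",
    "circular_open",
    "separate_objects",
    "filter_objects",
    "segment",
    "zstack_average",
]


class ThresholdError(ParameterError):
    """Automatic thresholding failed (e.g. constant-intensity input)."""


@dataclass(frozen=True)
class SegmentationConfig:
    """Configuration of the segmentation chain.

    Attributes
    ----------
    backend : str
        ``"classical"`` (default) or ``"trainable"`` (requires a trained
        model passed to :func:`segment`).
    threshold_method : str
        ``"otsu"`` or ``"fixed"`` (then ``fixed_threshold`` is used).
    h_maxima : float
        Seed-suppression depth (µm) for the distance-transform watershed:
        local maxima shallower than this are merged, which prevents one
        cell from splitting over small distance-map ripples.
    open_radius : float
        Radius (µm) of the ellipsoidal structuring element of the circular
        open; regions that cannot accommodate a sphere of this radius are
        removed.  Default 10 µm, well under the smallest adipocyte radius.
    min_volume : float
        Objects smaller than this (µm³) are discarded.  Default 20,000 µm³
        sits below the smallest expected adipocyte (~40 µm diameter,
        ~33,500 µm³) and above segmentation debris.
    border_policy : str
        ``"exclude_touching"`` drops objects touching the grid boundary
        (clipped cells have biased volumes); ``"keep"`` retains them.
    crop_extent : tuple or None
        Optional ``(x, y, z)`` µm crop applied before segmentation.
    open_before_separation : bool
        If True (default) the circular open runs on the binary mask before
        object separation; if False each separated object is opened
        individually afterwards.
    depth_correction : str
        ``"exponential_fit"`` (default) estimates the depth attenuation of
        the foreground by a log-linear fit of per-slice foreground
        intensity vs depth and divides it out before thresholding, so a
        single global threshold cuts every cell at the same fraction of its
        local edge amplitude; ``"none"`` disables the correction.
    """

    backend: str = "classical"
    threshold_method: str = "otsu"
    fixed_threshold: float = 0.5
    h_maxima: float = 4.0
    open_radius: float = 10.0
    min_volume: float = 20_000.0
    border_policy: str = "exclude_touching"
    crop_extent: tuple[float, float, float] | None = None
    open_before_separation: bool = True
    depth_correction: str = "exponential_fit"

    def validate(self) -> None:
        if self.backend not in ("classical", "trainable"):
            raise ParameterError(f"unknown backend {self.backend!r}")
        if self.threshold_method not in ("otsu", "fixed"):
            raise ParameterError(f"unknown threshold_method {self.threshold_method!r}")
        if self.h_maxima < 0 or self.open_radius < 0 or self.min_volume < 0:
            raise ParameterError("h_maxima, open_radius and min_volume must be >= 0")
        if self.border_policy not in ("exclude_touching", "keep"):
            raise ParameterError(f"unknown border_policy {self.border_policy!r}")
        if self.depth_correction not in ("none", "exponential_fit"):
            raise ParameterError(f"unknown depth_correction {self.depth_correction!r}")


def _correct_depth_attenuation(channel: np.ndarray, dz: float) -> np.ndarray:
    """Divide out an exponential depth decay fitted to the foreground signal.

    A rough global Otsu split provides per-slice foreground means; a
    log-linear least-squares fit over slices containing foreground gives
    the decay rate, clamped to decay (rate <= 0) so noise cannot produce a
    spurious brightening with depth.
    """
    flat = channel.reshape(channel.shape[0], -1)
    try:
        rough = filters.threshold_otsu(channel)
    except ValueError:
        return channel
    fg = flat > rough
    counts = fg.sum(axis=1)
    valid = counts > 0
    if valid.sum() < 2:
        return channel
    means = np.where(valid, (flat * fg).sum(axis=1) / np.maximum(counts, 1), np.nan)
    z = np.arange(channel.shape[0], dtype=float) * dz
    slope, intercept = np.polyfit(z[valid], np.log(means[valid]), 1)
    if slope >= 0:
        return channel
    gain = np.exp(-(slope * z)).astype(channel.dtype)
    return channel * gain[:, None, None]


def binarize(
    channel: np.ndarray,
    config: SegmentationConfig = SegmentationConfig(),
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> np.ndarray:
    """Foreground mask of the lipid channel by intensity thresholding.

    Applies the configured depth correction, thresholds (Otsu or fixed),
    and fills enclosed holes so each cell is a solid blob.
    """
    config.validate()
    channel = np.asarray(channel)
    if channel.size == 0:
        raise ParameterError("empty channel")
    if config.depth_correction == "exponential_fit" and channel.ndim == 3:
        channel = _correct_depth_attenuation(channel, voxel_size[2])
    if config.threshold_method == "otsu":
        if np.ptp(channel) == 0:
            raise ThresholdError("constant-intensity input: Otsu threshold undefined")
        thr = filters.threshold_otsu(channel)
    else:
        thr = config.fixed_threshold
    mask = channel > thr
    return ndi.binary_fill_holes(mask)


def _ellipsoid_footprint(
    radius: float, voxel_size: tuple[float, float, float]
) -> np.ndarray:
    """Boolean ellipsoid with physical radius `radius` on the (z, y, x) grid."""
    dx, dy, dz = voxel_size
    rz, ry, rx = (int(round(radius / d)) for d in (dz, dy, dx))
    zz, yy, xx = np.ogrid[-rz : rz + 1, -ry : ry + 1, -rx : rx + 1]
    out = np.zeros((2 * rz + 1, 2 * ry + 1, 2 * rx + 1))
    for axis_grid, r in ((zz, rz), (yy, ry), (xx, rx)):
        if r > 0:
            out = out + (axis_grid / r) ** 2
    return out <= 1.0


def circular_open(
    mask: np.ndarray,
    radius: float,
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> np.ndarray:
    """Morphological opening with an ellipsoidal element of physical radius.

    Removes any region that cannot accommodate the ellipsoid (the digital
    analogue of a sphere of radius ``radius`` µm on an anisotropic grid).
    Anti-extensive and idempotent; radius 0 is the identity.
    """
    if radius < 0:
        raise ParameterError("radius must be >= 0")
    mask = np.asarray(mask, dtype=bool)
    fp = _ellipsoid_footprint(radius, voxel_size)
    if fp.size == 1:
        return mask.copy()
    return ndi.binary_opening(mask, structure=fp)


def separate_objects(
    mask: np.ndarray,
    voxel_size: tuple[float, float, float],
    config: SegmentationConfig = SegmentationConfig(),
) -> np.ndarray:
    """Split touching cells by watershed on the Euclidean distance transform.

    The distance map is computed with physical sampling so anisotropic
    voxels are handled correctly; watershed seeds are its h-maxima with
    suppression depth ``config.h_maxima`` (µm).  Every mask voxel receives
    a label (no watershed lines).
    """
    config.validate()
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return np.zeros(mask.shape, dtype=np.int32)
    dx, dy, dz = voxel_size
    dist = ndi.distance_transform_edt(mask, sampling=(dz, dy, dx))
    if config.h_maxima > 0:
        peaks = morphology.h_maxima(dist, config.h_maxima)
    else:
        peaks = morphology.local_maxima(dist)
    markers, n = ndi.label(peaks, structure=np.ones((3, 3, 3), dtype=bool))
    if n == 0:  # pathological: fall back to connected components
        markers, _ = ndi.label(mask)
    labels = skseg.watershed(-dist, markers=markers, mask=mask)
    return labels.astype(np.int32)


def _relabel_contiguous(labels: np.ndarray, keep: np.ndarray) -> np.ndarray:
    """Keep the given label ids and renumber them 1..k preserving order."""
    lut = np.zeros(labels.max() + 1, dtype=np.int32)
    lut[np.sort(keep)] = np.arange(1, len(keep) + 1, dtype=np.int32)
    return lut[labels]


def filter_objects(
    labels: np.ndarray,
    voxel_size: tuple[float, float, float],
    config: SegmentationConfig = SegmentationConfig(),
) -> np.ndarray:
    """Drop small and (optionally) border-touching objects; relabel from 1."""
    config.validate()
    labels = np.asarray(labels)
    if labels.max() == 0:
        return labels.astype(np.int32)
    counts = np.bincount(labels.ravel())
    vols = counts * voxel_volume(voxel_size)
    bad = vols < config.min_volume
    bad[0] = False
    if config.border_policy == "exclude_touching":
        border_ids = np.unique(
            np.concatenate(
                [
                    labels[0].ravel(), labels[-1].ravel(),
                    labels[:, 0].ravel(), labels[:, -1].ravel(),
                    labels[:, :, 0].ravel(), labels[:, :, -1].ravel(),
                ]
            )
        )
        bad[border_ids] = True
        bad[0] = False
    keep = np.flatnonzero(~bad & (counts > 0))
    keep = keep[keep > 0]
    return _relabel_contiguous(labels, keep)


def _open_per_object(labels: np.ndarray, radius: float, voxel_size) -> np.ndarray:
    """Apply the circular open to each labeled object independently."""
    out = np.zeros_like(labels, dtype=np.int32)
    fp = _ellipsoid_footprint(radius, voxel_size)
    pad = [s // 2 for s in fp.shape]
    objects = ndi.find_objects(labels)
    for lab, sl in enumerate(objects, start=1):
        if sl is None:
            continue
        sl_pad = tuple(
            slice(max(s.start - p, 0), min(s.stop + p, dim))
            for s, p, dim in zip(sl, pad, labels.shape)
        )
        sub = labels[sl_pad] == lab
        opened = ndi.binary_opening(sub, structure=fp) if fp.size > 1 else sub
        out[sl_pad][opened] = lab
    return out


def segment(
    image: ImageVolume,
    config: SegmentationConfig = SegmentationConfig(),
    model=None,
) -> tuple[LabelVolume, dict]:
    """Full segmentation chain: crop → binarize → open → separate → filter.

    Parameters
    ----------
    image
        Volume with a ``"lipid"`` channel.
    config
        See :class:`SegmentationConfig`.
    model
        Trained backend (required when ``config.backend == "trainable"``).

    Returns
    -------
    (labels, log)
        Final label volume and a run log with voxel/object counts entering
        and leaving each stage.
    """
    config.validate()
    if config.crop_extent is not None:
        from .io import crop_volume

        image = crop_volume(image, config.crop_extent, origin=(0.0, 0.0, 0.0))
    lipid = image.channel("lipid")
    log: dict = {"shape": tuple(image.shape), "voxel_size": tuple(image.voxel_size)}

    if config.backend == "trainable":
        if model is None:
            raise ParameterError(
                "backend='trainable' requires a trained model; train one with "
                "adipo3d.learning.train_backend or use backend='classical'"
            )
        mask = model.predict_mask(lipid)
    else:
        mask = binarize(lipid, config, image.voxel_size)
    log["mask_voxels"] = int(mask.sum())

    if config.open_before_separation and config.open_radius > 0:
        mask = circular_open(mask, config.open_radius, image.voxel_size)
        log["opened_voxels"] = int(mask.sum())

    labels = separate_objects(mask, image.voxel_size, config)
    log["separated_objects"] = int(labels.max())

    if not config.open_before_separation and config.open_radius > 0:
        labels = _open_per_object(labels, config.open_radius, image.voxel_size)
        log["opened_voxels"] = int((labels > 0).sum())

    labels = filter_objects(labels, image.voxel_size, config)
    log["final_objects"] = int(labels.max())
    log["final_voxels"] = int((labels > 0).sum())

    meta = dict(image.meta)
    meta["segmentation_log"] = log
    return LabelVolume(labels, image.voxel_size, meta=meta), log


def zstack_average(frames: np.ndarray, window: int) -> np.ndarray:
    """Sliding-window mean along the stack axis (axis 0).

    Output depth is ``depth - window + 1``; ``window=1`` is the identity.
    Used to prepare averaged training slices for the trainable backend.
    """
    frames = np.asarray(frames, dtype=float)
    if frames.ndim < 1:
        raise ParameterError("frames must be a stack")
    depth = frames.shape[0]
    if window < 1:
        raise ParameterError("window must be >= 1")
    if window > depth:
        raise ParameterError(f"window {window} exceeds stack depth {depth}")
    cum = np.cumsum(frames, axis=0, dtype=float)
    cum = np.concatenate([np.zeros_like(cum[:1]), cum], axis=0)
    return (cum[window:] - cum[:-window]) / window
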