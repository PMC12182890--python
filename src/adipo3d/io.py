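"""Volume and table I/O, cropping, configuration, provenance.

Volumes travel as OME-TIFF (multi-channel, axes CZYX, physical voxel size
in the OME pixel metadata); labels as 32-bit TIFF with the same metadata;
feature tables and distributions as CSV; manifests, summaries and
provenance as JSON.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .segmentation import SegmentationConfig
from .stats import BinSpec, StudyDesign, default_bin_specs
from .synthetic import GeneratorParams, NoiseParams, TissuePhantom
from .volumes import AdipoError, ImageVolume, LabelVolume, ParameterError

__all__ = [
    "SpacingError",
    "BoundsError",
    "read_volume",
    "write_volume",
    "read_labels",
    "write_labels",
    "crop_volume",
    "PipelineConfig",
    "config_hash",
    "write_study",
]


class SpacingError(AdipoError):
    """No voxel spacing available from metadata or override."""


class BoundsError(AdipoError, ValueError):
    """Requested crop exceeds the volume bounds."""


DEFAULT_CHANNELS = ("lipid", "ecm")


def _ome_metadata(voxel_size, channel_names) -> dict:
    dx, dy, dz = voxel_size
    return {
        "axes": "CZYX",
        "PhysicalSizeX": dx, "PhysicalSizeXUnit": "µm",
        "PhysicalSizeY": dy, "PhysicalSizeYUnit": "µm",
        "PhysicalSizeZ": dz, "PhysicalSizeZUnit": "µm",
        "Channel": {"Name": list(channel_names)},
    }


def write_volume(path, volume: ImageVolume) -> Path:
    """Write a multi-channel volume as OME-TIFF with voxel size metadata."""
    path = Path(path)
    tags = sorted(volume.channels)
    stack = np.stack([volume.channels[t] for t in tags], axis=0)
    tifffile.imwrite(
        path, stack, ome=True, metadata=_ome_metadata(volume.voxel_size, tags)
    )
    return path


def _spacing_from_ome(tf: tifffile.TiffFile):
    if not tf.ome_metadata:
        return None
    meta = tifffile.xml2dict(tf.ome_metadata)
    try:
        px = meta["OME"]["Image"]
        if isinstance(px, list):
            px = px[0]
        px = px["Pixels"]
        return (
            float(px["PhysicalSizeX"]),
            float(px["PhysicalSizeY"]),
            float(px["PhysicalSizeZ"]),
        )
    except (KeyError, TypeError, ValueError):
        return None


def _channel_names_from_ome(tf: tifffile.TiffFile, n: int):
    try:
        meta = tifffile.xml2dict(tf.ome_metadata)
        px = meta["OME"]["Image"]
        if isinstance(px, list):
            px = px[0]
        chans = px["Pixels"]["Channel"]
        if isinstance(chans, dict):
            chans = [chans]
        names = [c.get("Name") for c in chans]
        if len(names) == n and all(names):
            return names
    except (KeyError, TypeError, AttributeError):
        pass
    return None


def read_volume(path, spacing_override=None, channel_names=None) -> ImageVolume:
    """Read a TIFF/OME-TIFF as an :class:`ImageVolume`.

    Voxel spacing ``(dx, dy, dz)`` comes from OME metadata when present,
    else from ``spacing_override``; with neither a :class:`SpacingError`
    is raised.  3D files become a single ``"lipid"`` channel; 4D files are
    taken as (C, Z, Y, X).
    """
    path = Path(path)
    try:
        with tifffile.TiffFile(path) as tf:
            data = tf.asarray()
            spacing = _spacing_from_ome(tf)
            ome_names = _channel_names_from_ome(tf, data.shape[0]) if data.ndim == 4 else None
    except (tifffile.TiffFileError, OSError) as exc:
        raise AdipoError(f"cannot read TIFF {path}: {exc}") from exc
    if spacing is None:
        spacing = spacing_override
    if spacing is None:
        raise SpacingError(
            f"{path} carries no OME voxel-size metadata and no spacing_override was given"
        )
    if data.ndim == 3:
        data = data[None]
    if data.ndim != 4:
        raise AdipoError(f"expected a 3D or 4D (C,Z,Y,X) TIFF, got shape {data.shape}")
    names = channel_names or ome_names
    if names is None:
        names = list(DEFAULT_CHANNELS[: data.shape[0]])
        if len(names) < data.shape[0]:
            names += [f"ch{i}" for i in range(len(names), data.shape[0])]
    channels = {n: data[i] for i, n in enumerate(names)}
    return ImageVolume(channels, tuple(float(s) for s in spacing), meta={"path": str(path)})


def write_labels(path, labels: LabelVolume) -> Path:
    path = Path(path)
    tifffile.imwrite(
        path,
        labels.data.astype(np.int32),
        ome=True,
        metadata=_ome_metadata(labels.voxel_size, ["labels"]) | {"axes": "ZYX"},
    )
    return path


def read_labels(path, spacing_override=None) -> LabelVolume:
    path = Path(path)
    with tifffile.TiffFile(path) as tf:
        data = tf.asarray()
        spacing = _spacing_from_ome(tf) or spacing_override
    if spacing is None:
        raise SpacingError(f"{path}: no voxel-size metadata and no override")
    return LabelVolume(data.astype(np.int32), tuple(float(s) for s in spacing))


def crop_volume(volume: ImageVolume, extent, origin=(0.0, 0.0, 0.0)) -> ImageVolume:
    """Crop a physical box ``extent`` (x, y, z) µm starting at ``origin`` µm.

    Voxel alignment is by floor: the crop starts at voxel
    ``floor(origin/spacing)`` and spans ``floor(extent/spacing)`` voxels
    per axis.  An out-of-bounds box raises :class:`BoundsError`.
    """
    dx, dy, dz = volume.voxel_size
    nz, ny, nx = volume.shape
    spacing = np.array([dx, dy, dz])
    ext = np.asarray(extent, dtype=float)
    org = np.asarray(origin, dtype=float)
    if np.any(ext <= 0):
        raise ParameterError("crop extent must be positive")
    start = np.floor(org / spacing + 1e-9).astype(int)  # (x, y, z) voxel index
    size = np.floor(ext / spacing + 1e-9).astype(int)
    stop = start + size
    bounds = np.array([nx, ny, nz])
    if np.any(start < 0) or np.any(stop > bounds):
        raise BoundsError(
            f"crop box voxels [{start}..{stop}) (x,y,z) exceeds volume bounds {bounds}"
        )
    sl = (slice(start[2], stop[2]), slice(start[1], stop[1]), slice(start[0], stop[0]))
    channels = {t: ch[sl] for t, ch in volume.channels.items()}
    meta = dict(volume.meta)
    meta["crop"] = {"origin_um": list(map(float, org)), "extent_um": list(map(float, ext))}
    return ImageVolume(channels, volume.voxel_size, meta=meta)


# ---------------------------------------------------------------------------
# configuration

@dataclasses.dataclass
class PipelineConfig:
    """Everything one end-to-end run needs, loadable from YAML."""

    groups: dict[str, GeneratorParams]
    design: StudyDesign = dataclasses.field(default_factory=StudyDesign)
    segmentation: SegmentationConfig = dataclasses.field(default_factory=SegmentationConfig)
    bins: dict[str, BinSpec] = dataclasses.field(default_factory=default_bin_specs)
    seed: int = 0
    log_level: str = "INFO"

    def validate(self) -> None:
        self.design.validate()
        self.segmentation.validate()
        for g in self.design.groups:
            if g not in self.groups:
                raise ParameterError(f"config missing generator params for group {g!r}")
            self.groups[g].validate()

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        groups = {}
        for name, p in raw.get("groups", {}).items():
            p = dict(p)
            if "noise" in p:
                p["noise"] = NoiseParams(**p["noise"])
            for key in ("domain_size", "psf_sigma", "voxel_size"):
                if key in p:
                    p[key] = tuple(p[key])
            groups[name] = GeneratorParams(**p)
        design = StudyDesign(**raw["design"]) if "design" in raw else StudyDesign(
            groups=tuple(groups) or ("healthy", "obese")
        )
        seg = raw.get("segmentation", {})
        if "crop_extent" in seg and seg["crop_extent"] is not None:
            seg["crop_extent"] = tuple(seg["crop_extent"])
        segmentation = SegmentationConfig(**seg)
        bins = {
            name: BinSpec(name, tuple(edges))
            for name, edges in raw.get("bins", {}).items()
        } or default_bin_specs()
        return cls(
            groups=groups,
            design=design,
            segmentation=segmentation,
            bins=bins,
            seed=int(raw.get("seed", 0)),
            log_level=raw.get("log_level", "INFO"),
        )

    def to_dict(self) -> dict:
        return {
            "groups": {g: dataclasses.asdict(p) for g, p in self.groups.items()},
            "design": dataclasses.asdict(self.design),
            "segmentation": dataclasses.asdict(self.segmentation),
            "bins": {n: list(b.edges) for n, b in self.bins.items()},
            "seed": self.seed,
            "log_level": self.log_level,
        }

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(json.loads(json.dumps(self.to_dict())), fh, sort_keys=True)


def config_hash(config: PipelineConfig) -> str:
    """Stable sha256 over the canonical JSON form of a config."""
    blob = json.dumps(config.to_dict(), sort_keys=True, default=float).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_study(phantoms: dict[str, TissuePhantom], manifest: list[dict], out_dir) -> Path:
    """Write a generated study: per-sample volumes, labels, ground truth, manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for entry in manifest:
        sid = entry["sample_id"]
        phantom = phantoms[sid]
        img_path = out / f"{sid}_image.ome.tiff"
        lab_path = out / f"{sid}_labels.ome.tiff"
        gt_path = out / f"{sid}_cells.csv"
        write_volume(img_path, phantom.image)
        write_labels(lab_path, phantom.labels)
        pd.DataFrame(
            [
                {
                    "label_id": c.label_id,
                    "true_volume_um3": c.true_volume,
                    "true_radius_um": c.true_radius,
                    "true_centroid_x_um": c.true_centroid[0],
                    "true_centroid_y_um": c.true_centroid[1],
                    "true_centroid_z_um": c.true_centroid[2],
                }
                for c in phantom.cells
            ]
        ).to_csv(gt_path, index=False)
        entry.update(
            image=img_path.name, labels=lab_path.name, ground_truth=gt_path.name
        )
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return out / "manifest.json"
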