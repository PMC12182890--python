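"""Synthetic cleared-adipose-tissue phantoms with exact ground truth.

The generator emulates the statistical structure a light-sheet morphometry
pipeline has to cope with: densely packed convex adipocytes (lipid channel),
a thin extracellular-matrix shell between cells (ECM channel), anisotropic
optical blur, exponential signal decay with imaging depth, and
Poisson–Gaussian camera noise.  Cells are spheres so that every ground-truth
quantity (volume, radius, centroid, sphericity) is analytic.

All randomness is driven by ``GeneratorParams.seed``; the three stochastic
stages (volume sampling, packing, noise) draw from independent child
streams of that seed, so each stage is individually reproducible.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from scipy.special import ndtri

from .volumes import ImageVolume, LabelVolume, ParameterError

logger = logging.getLogger(__name__)

__all__ = [
    "NoiseParams",
    "GeneratorParams",
    "GroundTruthCell",
    "TissuePhantom",
    "PackingError",
    "sample_true_volumes",
    "pack_adipocytes",
    "render_tissue",
    "generate_study",
]

#: Maximum total sphere volume / domain volume accepted by the packer.
#: Random sequential addition with clearance becomes infeasible well below
#: close packing; 55% is a generous ceiling for polydisperse spheres
#: inserted densest-first.
MAX_PACKING_FRACTION = 0.55


class PackingError(ParameterError):
    """Sphere packing could not be completed within the attempt budget."""


@dataclass(frozen=True)
class NoiseParams:
    """Camera noise model: Poisson photon noise plus Gaussian read noise.

    ``photon_scale`` is the expected photon count at unit intensity
    (0 disables shot noise); ``read_sigma`` is the read-noise standard
    deviation in intensity units (0 disables it).
    """

    photon_scale: float = 200.0
    read_sigma: float = 0.01

    def validate(self) -> None:
        if self.photon_scale < 0 or self.read_sigma < 0:
            raise ParameterError("noise parameters must be non-negative")


@dataclass(frozen=True)
class GeneratorParams:
    """Parameters of one phantom.

    Defaults reproduce the imaging geometry of the study this package
    models: 1.62 µm lateral pixels, 4 µm light-sheet step, usable depth
    ~400 µm, 450 cells per sample with a mean volume calibrated to the
    healthy-group mean.

    Attributes
    ----------
    n_cells : int
        Number of adipocytes per phantom.
    domain_size : tuple
        Physical extent ``(x, y, z)`` in µm.
    volume_mean, volume_cv : float
        Mean and coefficient of variation of the true volume distribution
        (µm³; cv dimensionless).
    volume_family : str
        ``"lognormal"`` draws i.i.d.; ``"quantile_matched_lognormal"``
        places cells at evenly spaced lognormal quantiles and rescales so
        the sample mean equals ``volume_mean`` exactly.
    ecm_gap : float
        Minimum surface-to-surface clearance between cells, which the ECM
        shell fills (µm).
    boundary_margin : float
        Extra clearance between every sphere surface and the domain wall
        (µm) so that optical blur cannot push a complete cell's footprint
        onto the grid boundary.
    psf_sigma : tuple
        Gaussian blur sigmas ``(σx, σy, σz)`` in µm.
    attenuation_length : float
        Depth decay constant L in µm; intensity is scaled by exp(-z/L).
        ``inf`` disables attenuation.
    noise : NoiseParams
    voxel_size : tuple
        ``(dx, dy, dz)`` in µm.
    seed : int
    """

    n_cells: int = 450
    domain_size: tuple[float, float, float] = (1250.0, 1250.0, 320.0)
    volume_mean: float = 248_754.0
    volume_cv: float = 0.4
    volume_family: str = "quantile_matched_lognormal"
    ecm_gap: float = 4.0
    boundary_margin: float = 10.0
    psf_sigma: tuple[float, float, float] = (2.0, 2.0, 4.0)
    attenuation_length: float = 400.0
    noise: NoiseParams = field(default_factory=NoiseParams)
    voxel_size: tuple[float, float, float] = (1.62, 1.62, 4.0)
    seed: int = 0

    def validate(self) -> None:
        if self.n_cells < 1:
            raise ParameterError("n_cells must be >= 1")
        if any(v <= 0 for v in self.domain_size):
            raise ParameterError("domain_size extents must be positive")
        if self.volume_mean <= 0:
            raise ParameterError("volume_mean must be positive")
        if self.volume_cv < 0:
            raise ParameterError("volume_cv must be >= 0")
        if self.volume_family not in ("lognormal", "quantile_matched_lognormal"):
            raise ParameterError(f"unknown volume_family {self.volume_family!r}")
        if self.ecm_gap < 0 or self.boundary_margin < 0:
            raise ParameterError("ecm_gap and boundary_margin must be >= 0")
        if any(s < 0 for s in self.psf_sigma):
            raise ParameterError("psf_sigma must be >= 0")
        if self.attenuation_length <= 0:
            raise ParameterError("attenuation_length must be positive (use inf to disable)")
        if any(v <= 0 for v in self.voxel_size):
            raise ParameterError("voxel_size must be positive")
        self.noise.validate()

    def replace(self, **kwargs) -> "GeneratorParams":
        return dataclasses.replace(self, **kwargs)

    def rng(self, stream: int) -> np.random.Generator:
        """Child generator for one stochastic stage (0=volumes, 1=packing, 2=noise)."""
        return np.random.default_rng(np.random.SeedSequence((int(self.seed), stream)))


@dataclass(frozen=True)
class GroundTruthCell:
    """True geometry of one simulated adipocyte (spherical)."""

    label_id: int
    true_volume: float  # µm³
    true_centroid: tuple[float, float, float]  # (x, y, z) µm
    true_radius: float  # µm


@dataclass
class TissuePhantom:
    """A rendered phantom: image, ground-truth labels and cell list."""

    image: ImageVolume
    labels: LabelVolume
    cells: list[GroundTruthCell]
    params: GeneratorParams

    def __post_init__(self) -> None:
        if not self.labels.matches(self.image):
            raise ParameterError("phantom image and labels must share grid and spacing")
        grid_ids = set(int(i) for i in self.labels.ids())
        cell_ids = set(c.label_id for c in self.cells)
        if not grid_ids <= cell_ids:
            raise ParameterError(f"labels present in grid but not in cells: {grid_ids - cell_ids}")

    @property
    def true_volumes(self) -> np.ndarray:
        return np.array([c.true_volume for c in self.cells])


def _lognormal_params(mean: float, cv: float) -> tuple[float, float]:
    """(mu, sigma) of the underlying normal for a lognormal with given mean/cv."""
    sigma2 = np.log1p(cv * cv)
    mu = np.log(mean) - sigma2 / 2.0
    return mu, float(np.sqrt(sigma2))


def sample_true_volumes(params: GeneratorParams) -> np.ndarray:
    """Draw the true per-cell volumes (µm³) for one phantom.

    With ``volume_family="quantile_matched_lognormal"`` the cells sit at the
    midpoint quantiles ``(i + 0.5)/n`` of the lognormal and are rescaled so
    the sample mean equals ``volume_mean`` to floating precision — the
    calibration mode used to pin a cohort to a target mean.  Plain
    ``"lognormal"`` draws i.i.d. from the same distribution.
    """
    params.validate()
    n = params.n_cells
    if params.volume_cv == 0:
        return np.full(n, float(params.volume_mean))
    mu, sigma = _lognormal_params(params.volume_mean, params.volume_cv)
    if params.volume_family == "quantile_matched_lognormal":
        q = (np.arange(n) + 0.5) / n
        v = np.exp(mu + sigma * ndtri(q))
        v *= params.volume_mean / v.mean()
        return v
    rng = params.rng(0)
    return rng.lognormal(mu, sigma, size=n)


def _radius_from_volume(v: np.ndarray | float) -> np.ndarray | float:
    return (3.0 * np.asarray(v) / (4.0 * np.pi)) ** (1.0 / 3.0)


def pack_adipocytes(
    volumes: np.ndarray | list[float], params: GeneratorParams
) -> list[GroundTruthCell]:
    """Place non-overlapping spheres in the domain by random sequential addition.

    Spheres are inserted densest-first with surface-to-surface clearance
    ``ecm_gap`` between cells and ``boundary_margin`` to the domain walls;
    every sphere lies fully inside the domain.  Deterministic given
    ``params.seed``.

    Raises
    ------
    PackingError
        If the requested packing fraction exceeds the feasibility ceiling or
        a sphere cannot be placed within the attempt budget.
    """
    params.validate()
    volumes = np.asarray(volumes, dtype=float)
    if volumes.ndim != 1 or volumes.size == 0 or np.any(volumes <= 0):
        raise ParameterError("volumes must be a non-empty 1D array of positive values")
    ext = np.asarray(params.domain_size, dtype=float)  # (x, y, z)
    domain_vol = float(np.prod(ext))
    frac = volumes.sum() / domain_vol
    if frac > MAX_PACKING_FRACTION:
        raise PackingError(
            f"requested packing fraction {frac:.3f} exceeds the feasible "
            f"ceiling {MAX_PACKING_FRACTION:.2f} for random sequential addition"
        )

    order = np.argsort(volumes)[::-1]  # densest-first = largest radius first
    radii = np.asarray(_radius_from_volume(volumes))
    rng = params.rng(1)

    placed_centers = np.empty((len(volumes), 3))
    placed_radii = np.empty(len(volumes))
    n_placed = 0
    max_attempts_per_cell = 20_000

    for idx in order:
        r = radii[idx]
        lo = r + params.boundary_margin
        hi = ext - (r + params.boundary_margin)
        if np.any(hi < lo):
            raise PackingError(
                f"sphere of radius {r:.1f} µm (+margin) does not fit the domain {tuple(ext)}"
            )
        for _ in range(max_attempts_per_cell):
            c = rng.uniform(lo, hi)
            if n_placed:
                d2 = np.sum((placed_centers[:n_placed] - c) ** 2, axis=1)
                min_sep = placed_radii[:n_placed] + r + params.ecm_gap
                if np.any(d2 < min_sep**2):
                    continue
            placed_centers[n_placed] = c
            placed_radii[n_placed] = r
            n_placed += 1
            break
        else:
            achieved_frac = (
                (4.0 / 3.0) * np.pi * np.sum(placed_radii[:n_placed] ** 3) / domain_vol
            )
            raise PackingError(
                f"failed to place sphere {n_placed + 1}/{len(volumes)} "
                f"(r={r:.1f} µm) after {max_attempts_per_cell} attempts; "
                f"achieved packing fraction {achieved_frac:.3f}"
            )

    cells = [
        GroundTruthCell(
            label_id=i + 1,
            true_volume=float(volumes[order[i]]),
            true_centroid=tuple(float(v) for v in placed_centers[i]),
            true_radius=float(placed_radii[i]),
        )
        for i in range(n_placed)
    ]
    return cells


def _rasterize_cells(
    cells: list[GroundTruthCell],
    shape: tuple[int, int, int],
    voxel_size: tuple[float, float, float],
) -> np.ndarray:
    """Label grid with each sphere stamped into its bounding box.

    A voxel belongs to a cell when its center lies inside the true sphere.
    Cells never overlap by construction, so stamp order is irrelevant.
    """
    dx, dy, dz = voxel_size
    nz, ny, nx = shape
    labels = np.zeros(shape, dtype=np.int32)
    spacing = np.array([dz, dy, dx])
    for cell in cells:
        cx, cy, cz = cell.true_centroid
        center = np.array([cz, cy, cx])  # grid order
        r = cell.true_radius
        lo = np.maximum(np.floor((center - r) / spacing).astype(int), 0)
        hi = np.minimum(np.ceil((center + r) / spacing).astype(int) + 1, [nz, ny, nx])
        if np.any(hi <= lo):
            continue
        zz, yy, xx = np.ogrid[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]]
        d2 = (
            (zz * dz - cz) ** 2
            + (yy * dy - cy) ** 2
            + (xx * dx - cx) ** 2
        )
        box = labels[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]]
        box[d2 <= r * r] = cell.label_id
    return labels


def render_tissue(cells: list[GroundTruthCell], params: GeneratorParams) -> TissuePhantom:
    """Render packed cells into a two-channel image volume plus ground truth.

    Optical model: binary occupancy (lipid inside each sphere, ECM in the
    ≤ ``ecm_gap`` shell around cells) → anisotropic Gaussian blur
    (``psf_sigma``) → depth attenuation ``exp(-z/L)`` → Poisson photon noise
    and Gaussian read noise.  Setting blur, attenuation (``inf``) and noise
    to zero yields the exact binary rasterization.
    """
    params.validate()
    dx, dy, dz = params.voxel_size
    ex, ey, ez = params.domain_size
    shape = (int(ez // dz), int(ey // dy), int(ex // dx))
    if min(shape) < 1:
        raise ParameterError("voxel_size coarser than the domain extent")
    if cells:
        r_min = min(c.true_radius for c in cells)
        if r_min < max(params.voxel_size):
            logger.warning(
                "smallest cell radius %.2f µm is below the coarsest voxel "
                "dimension %.2f µm; rendering will be unresolved",
                r_min,
                max(params.voxel_size),
            )

    labels = _rasterize_cells(cells, shape, params.voxel_size)
    lipid = (labels > 0).astype(np.float32)

    # ECM shell: voxels within ecm_gap of a true sphere surface (analytic
    # distance, stamped per cell), outside every cell
    ecm = np.zeros_like(lipid)
    if params.ecm_gap > 0:
        nz, ny, nx = shape
        spacing = np.array([dz, dy, dx])
        for cell in cells:
            cx, cy, cz = cell.true_centroid
            center = np.array([cz, cy, cx])
            r_out = cell.true_radius + params.ecm_gap
            lo = np.maximum(np.floor((center - r_out) / spacing).astype(int), 0)
            hi = np.minimum(
                np.ceil((center + r_out) / spacing).astype(int) + 1, [nz, ny, nx]
            )
            if np.any(hi <= lo):
                continue
            zz, yy, xx = np.ogrid[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]]
            d2 = (zz * dz - cz) ** 2 + (yy * dy - cy) ** 2 + (xx * dx - cx) ** 2
            box = ecm[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]]
            box[(d2 > cell.true_radius**2) & (d2 <= r_out**2)] = 1.0
        ecm[labels > 0] = 0.0

    sx, sy, sz = params.psf_sigma
    sigma_vox = (sz / dz, sy / dy, sx / dx)
    channels = {"lipid": lipid, "ecm": ecm}
    for tag, ch in channels.items():
        if any(s > 0 for s in sigma_vox):
            ch = ndi.gaussian_filter(ch, sigma=sigma_vox)
        if np.isfinite(params.attenuation_length):
            z_phys = np.arange(shape[0], dtype=np.float32) * dz
            decay = np.exp(-z_phys / params.attenuation_length).astype(np.float32)
            ch = ch * decay[:, None, None]
        channels[tag] = ch

    rng = params.rng(2)
    for tag, ch in channels.items():
        if params.noise.photon_scale > 0:
            lam = np.clip(ch, 0, None) * params.noise.photon_scale
            ch = rng.poisson(lam).astype(np.float32) / params.noise.photon_scale
        if params.noise.read_sigma > 0:
            ch = ch + rng.normal(0.0, params.noise.read_sigma, size=ch.shape).astype(np.float32)
        channels[tag] = ch.astype(np.float32)

    image = ImageVolume(
        channels=channels,
        voxel_size=params.voxel_size,
        meta={"seed": params.seed, "generator": "adipo3d.synthetic"},
    )
    label_vol = LabelVolume(labels, params.voxel_size, meta={"seed": params.seed})
    return TissuePhantom(image=image, labels=label_vol, cells=list(cells), params=params)


def generate_phantom(params: GeneratorParams) -> TissuePhantom:
    """Convenience: sample volumes, pack, and render one phantom."""
    volumes = sample_true_volumes(params)
    cells = pack_adipocytes(volumes, params)
    return render_tissue(cells, params)


def derive_sample_seed(group_seed: int, sample_index: int) -> int:
    """Stable per-sample seed below 2**31 derived from a group seed."""
    ss = np.random.SeedSequence((int(group_seed), int(sample_index), 0xA21))
    return int(ss.generate_state(1)[0] % (2**31))


def generate_study(design, params_per_group: dict, out_dir=None):
    """Generate one phantom per sample of a group × sample study design.

    Parameters
    ----------
    design : StudyDesign
        Groups, samples per group and cells per sample.
    params_per_group
        Mapping group label → :class:`GeneratorParams`; each sample gets a
        sample-specific seed derived from its group's seed.
    out_dir : path-like, optional
        When given, phantoms, ground truth and a ``manifest.json`` are
        written there (see :mod:`adipo3d.io`).

    Returns
    -------
    (phantoms, manifest)
        ``phantoms`` maps sample id → :class:`TissuePhantom`; ``manifest``
        is a list of per-sample records (group, sample id, seed, paths).
    """
    from .stats import StudyDesign  # local import to avoid cycle at module load

    if not isinstance(design, StudyDesign):
        design = StudyDesign(**design) if isinstance(design, dict) else design
    design.validate()
    missing = [g for g in design.groups if g not in params_per_group]
    if missing:
        raise ParameterError(f"missing GeneratorParams for groups: {missing}")

    phantoms: dict[str, TissuePhantom] = {}
    manifest: list[dict] = []
    for group in design.groups:
        base = params_per_group[group]
        for s in range(design.samples_per_group):
            sample_id = f"{group}_s{s + 1}"
            if sample_id in phantoms:
                raise ParameterError(f"duplicate sample id {sample_id!r}")
            seed = derive_sample_seed(base.seed, s)
            p = base.replace(seed=seed, n_cells=design.cells_per_sample)
            phantom = generate_phantom(p)
            phantoms[sample_id] = phantom
            entry = {"group": group, "sample_id": sample_id, "seed": seed,
                     "n_cells": len(phantom.cells)}
            manifest.append(entry)

    if out_dir is not None:
        from . import io as _io

        _io.write_study(phantoms, manifest, out_dir)
    return phantoms, manifest
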