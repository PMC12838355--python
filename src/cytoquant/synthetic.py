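"""Synthetic confocal phantoms of single sorted immune cells.

Two-channel (DAPI + marker) 3D stacks with known ground-truth masks, built
to exercise the projection/segmentation/quantification chain: a cell body
containing a nucleus whose shape mimics the sorted myeloid morphologies
(round, kidney-shaped monocyte, multilobed granulocyte), a marker channel
distributed between nucleus and cytoplasm with a configurable
nuclear:cytoplasmic ratio, photon-like noise, and Gaussian optical blur.

The default z-profile is ``"slab"``: cells settle and flatten on adhesion
slides, and the imaged z-range (default 31 x 0.19 µm ≈ 5.7 µm) lies inside
the cell body, so within its footprint the cell spans every optical
section.  This renders the noiseless z-sum projection exactly three-level
(background / cytoplasm / nucleus), which is the regime in which a single
global Otsu threshold can recover the cell footprint exactly.  A true
ellipsoidal z-profile is available via ``z_profile="ellipsoid"``; it
produces rim columns thinner than one section and is documented as harder
to segment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterator, Literal, Mapping

import numpy as np
from scipy.ndimage import gaussian_filter

from .errors import DimensionError, ValidationError
from .stack import AcquisitionGeometry, ImageStack

NucleusShape = Literal["round", "kidney", "multilobed"]


@dataclass(frozen=True)
class CellGeometry:
    """Shape parameters of one synthetic cell.

    Parameters
    ----------
    cell_radii : (float, float, float)
        Semi-axes of the cell envelope in µm, ``(rx, ry, rz)``.
    nucleus_shape : {"round", "kidney", "multilobed"}
        Morphological class: round, kidney-shaped (monocyte-like, an
        ellipse minus an offset elliptical bite) or multilobed
        (granulocyte-like, a ring of ``n_lobes`` discs).
    n_lobes : int
        Number of nuclear lobes for the multilobed shape, in [2, 5].
    nucleus_scale : float
        Target nucleus volume as a fraction of cell volume, in (0, 1).
        Exact for the round shape; approximate (within a few percent) for
        kidney and multilobed shapes.
    center_jitter : float
        Half-width (µm) of the uniform jitter applied to the cell centre.
    z_profile : {"slab", "ellipsoid"}
        Axial model of the cell body (see module docstring).
    """

    cell_radii: tuple[float, float, float] = (6.0, 6.0, 6.0)
    nucleus_shape: NucleusShape = "round"
    n_lobes: int = 3
    nucleus_scale: float = 0.30
    center_jitter: float = 0.3
    z_profile: Literal["slab", "ellipsoid"] = "slab"

    def __post_init__(self) -> None:
        if any(r <= 0 for r in self.cell_radii):
            raise ValidationError("cell radii must be positive")
        if self.nucleus_shape not in ("round", "kidney", "multilobed"):
            raise ValidationError(f"unknown nucleus shape {self.nucleus_shape!r}")
        if self.nucleus_shape == "multilobed" and not 2 <= self.n_lobes <= 5:
            raise ValidationError("n_lobes must be in [2, 5]")
        if not 0 < self.nucleus_scale < 1:
            raise ValidationError("nucleus_scale must be in (0, 1)")
        if self.center_jitter < 0:
            raise ValidationError("center_jitter must be >= 0")


def granulocyte_geometry(**overrides) -> CellGeometry:
    """Granulocyte preset: multilobed (default 3-lobe) nucleus."""
    return CellGeometry(nucleus_shape="multilobed", n_lobes=3, **overrides)


def monocyte_geometry(**overrides) -> CellGeometry:
    """Monocyte preset: kidney-shaped nucleus."""
    return CellGeometry(nucleus_shape="kidney", **overrides)


@dataclass(frozen=True)
class IntensityModel:
    """Mean intensities, noise and blur for one rendered stack.

    ``mu_nuc``/``mu_cyt`` are the marker-channel means inside nucleus and
    cytoplasm (arbitrary detector units); ``mu_dapi`` the nuclear-stain
    mean inside the nucleus; ``background`` the off-structure mean for both
    channels.  Noise is applied per voxel before optical blur.

    The default nuclear:cytoplasmic marker ratio is 2 (120/60).  With a
    single global Otsu threshold, substantially higher ratios make the
    nucleus-cytoplasm contrast exceed the cell-background contrast and the
    threshold jumps inside the cell; see docs/methods.md.
    """

    mu_nuc: float = 120.0
    mu_cyt: float = 60.0
    mu_dapi: float = 150.0
    background: float = 5.0
    noise_model: Literal["gaussian", "poisson"] = "gaussian"
    noise_sigma: float = 6.0
    poisson_scale: float = 1.0
    psf_sigma: float = 0.10

    def __post_init__(self) -> None:
        if min(self.mu_nuc, self.mu_cyt, self.mu_dapi, self.background) < 0:
            raise ValidationError("intensity means must be >= 0")
        if self.background >= min(self.mu_dapi, max(self.mu_nuc, self.mu_cyt)):
            raise ValidationError(
                "background must be below the stain means "
                "(background < min(mu_dapi, max(mu_nuc, mu_cyt)))"
            )
        if self.noise_model not in ("gaussian", "poisson"):
            raise ValidationError(f"unknown noise model {self.noise_model!r}")
        if self.noise_sigma < 0 or self.psf_sigma < 0:
            raise ValidationError("noise_sigma and psf_sigma must be >= 0")
        if self.poisson_scale <= 0:
            raise ValidationError("poisson_scale must be > 0")


@dataclass
class SyntheticTruth:
    """Ground truth attached to one generated stack."""

    cell_mask_3d: np.ndarray
    nucleus_mask_3d: np.ndarray
    geometry: CellGeometry
    intensity_model: IntensityModel
    seed: int

    def __post_init__(self) -> None:
        if self.cell_mask_3d.shape != self.nucleus_mask_3d.shape:
            raise DimensionError("truth masks must share one shape")
        if np.any(self.nucleus_mask_3d & ~self.cell_mask_3d):
            raise ValidationError("nucleus mask must lie inside the cell mask")

    @property
    def cell_footprint(self) -> np.ndarray:
        """2D (y, x) projection of the cell mask (any voxel along z)."""
        return self.cell_mask_3d.any(axis=0)

    @property
    def nucleus_footprint(self) -> np.ndarray:
        return self.nucleus_mask_3d.any(axis=0)


def _nucleus_footprint_2d(
    yy: np.ndarray,
    xx: np.ndarray,
    geometry: CellGeometry,
    rng: np.random.Generator,
    psf_sigma: float,
) -> np.ndarray:
    """Render the 2D nucleus cross-section inside the (rotated, centred)
    cell coordinate frame ``(yy, xx)`` in µm."""
    rx, ry, _ = geometry.cell_radii
    rmin = min(rx, ry)
    scale = geometry.nucleus_scale

    if geometry.nucleus_shape == "round":
        a, b = rx * math.sqrt(scale), ry * math.sqrt(scale)
        extent = max(a, b)
        offset = _nucleus_offset(rng, rmin, extent, psf_sigma)
        oy, ox = offset
        return ((yy - oy) / b) ** 2 + ((xx - ox) / a) ** 2 <= 1.0

    if geometry.nucleus_shape == "kidney":
        # base ellipse inflated so that area after the bite ~ scale
        a = rx * math.sqrt(scale * 1.45)
        b = ry * math.sqrt(scale * 1.45)
        extent = max(a, b)
        offset = _nucleus_offset(rng, rmin, extent, psf_sigma)
        oy, ox = offset
        base = ((yy - oy) / b) ** 2 + ((xx - ox) / a) ** 2 <= 1.0
        phi = rng.uniform(0.0, 2.0 * math.pi)
        # bite: offset ellipse removing ~30% of the base area
        ba, bb = 0.75 * a, 0.75 * b
        by = oy + 0.95 * b * math.sin(phi)
        bx = ox + 0.95 * a * math.cos(phi)
        bite = ((yy - by) / bb) ** 2 + ((xx - bx) / ba) ** 2 <= 1.0
        return base & ~bite

    # multilobed: ring of n_lobes discs; lobes may be disjoint (the thin
    # chromatin bridges of a real granulocyte are below our resolution)
    k = geometry.n_lobes
    r_lobe = math.sqrt(scale * rx * ry / k) * 1.05
    ring = min(1.5 * r_lobe, 0.92 * rmin - r_lobe)
    extent = ring + r_lobe
    oy, ox = _nucleus_offset(rng, rmin, extent, psf_sigma)
    phase = rng.uniform(0.0, 2.0 * math.pi)
    mask = np.zeros(yy.shape, dtype=bool)
    for i in range(k):
        ang = phase + 2.0 * math.pi * i / k
        cy = oy + ring * math.sin(ang)
        cx = ox + ring * math.cos(ang)
        mask |= (yy - cy) ** 2 + (xx - cx) ** 2 <= r_lobe**2
    return mask


def _nucleus_offset(
    rng: np.random.Generator, rmin: float, extent: float, psf_sigma: float
) -> tuple[float, float]:
    """Uniform nucleus-centre offset within an interior margin chosen so
    that optical blur cannot push nuclear signal outside the cell."""
    margin = 0.92 * rmin - extent - 3.0 * psf_sigma
    if margin <= 0:
        return (0.0, 0.0)
    r = margin * math.sqrt(rng.uniform())
    phi = rng.uniform(0.0, 2.0 * math.pi)
    return (r * math.sin(phi), r * math.cos(phi))


def generate_cell_stack(
    geometry: CellGeometry,
    intensity: IntensityModel,
    acq: AcquisitionGeometry | None = None,
    seed: int = 0,
    stack_id: str = "",
) -> tuple[ImageStack, SyntheticTruth]:
    """Render one two-channel stack (channel 0 = DAPI, channel 1 = marker).

    The expected marker intensity is ``mu_nuc`` inside the nucleus,
    ``mu_cyt`` in the cytoplasm and ``background`` outside the cell; the
    DAPI channel is ``mu_dapi`` inside the nucleus and ``background``
    elsewhere.  Per-voxel noise is applied first, then Gaussian blur of
    width ``psf_sigma`` (µm, isotropic in physical units).  Identical
    ``(parameters, seed)`` give bit-identical output.

    Returns
    -------
    (ImageStack, SyntheticTruth)
    """
    if acq is None:
        acq = AcquisitionGeometry()
    rng = np.random.default_rng(seed)
    nz, ny, nx = acq.shape_zyx
    rx, ry, rz = geometry.cell_radii

    fy, fx = acq.field_um
    cy0, cx0 = fy / 2.0, fx / 2.0
    j = geometry.center_jitter
    cy = cy0 + rng.uniform(-j, j)
    cx = cx0 + rng.uniform(-j, j)
    rmax = max(rx, ry) + j
    if 2 * rmax > min(fy, fx):
        raise DimensionError(
            f"cell (max lateral extent {2 * rmax:.2f} µm with jitter) does not "
            f"fit in the field ({fy:.2f} x {fx:.2f} µm)"
        )

    theta = rng.uniform(0.0, math.pi)
    y_um = np.arange(ny, dtype=np.float64) * acq.dy
    x_um = np.arange(nx, dtype=np.float64) * acq.dx
    ygrid, xgrid = np.meshgrid(y_um - cy, x_um - cx, indexing="ij")
    ct, st = math.cos(theta), math.sin(theta)
    yy = ct * ygrid - st * xgrid
    xx = st * ygrid + ct * xgrid

    cell2d = (yy / ry) ** 2 + (xx / rx) ** 2 <= 1.0
    nuc2d = _nucleus_footprint_2d(yy, xx, geometry, rng, intensity.psf_sigma)
    nuc2d &= cell2d

    z_um = np.arange(nz, dtype=np.float64) * acq.dz
    cz = acq.depth_um / 2.0
    if geometry.z_profile == "slab":
        zwin = np.abs(z_um - cz) <= rz
        cell3d = zwin[:, None, None] & cell2d[None, :, :]
        nuc3d = zwin[:, None, None] & nuc2d[None, :, :]
    else:
        zr = (z_um - cz) / rz
        lat = (yy / ry) ** 2 + (xx / rx) ** 2
        cell3d = zr[:, None, None] ** 2 + lat[None, :, :] <= 1.0
        # nucleus: same z window scaled by sqrt(nucleus area fraction)
        nscale = math.sqrt(geometry.nucleus_scale)
        nuc3d = (zr[:, None, None] / nscale) ** 2 + (lat[None, :, :]) <= 1.0
        nuc3d &= nuc2d[None, :, :]
        nuc3d &= cell3d

    bg = intensity.background
    dapi = np.full((nz, ny, nx), bg, dtype=np.float32)
    marker = np.full((nz, ny, nx), bg, dtype=np.float32)
    if geometry.z_profile == "slab":
        # per-slice structure is a single 2D plane: paint once, broadcast
        plane_m = np.full((ny, nx), bg, dtype=np.float32)
        plane_m[cell2d] = intensity.mu_cyt
        plane_m[nuc2d] = intensity.mu_nuc
        plane_d = np.full((ny, nx), bg, dtype=np.float32)
        plane_d[nuc2d] = intensity.mu_dapi
        marker[zwin] = plane_m
        dapi[zwin] = plane_d
    else:
        marker[cell3d] = intensity.mu_cyt
        marker[nuc3d] = intensity.mu_nuc
        dapi[nuc3d] = intensity.mu_dapi

    # photon-like noise first (see docs/methods.md on the ordering), then blur
    if intensity.noise_model == "gaussian":
        if intensity.noise_sigma > 0:
            shape = (nz, ny, nx)
            for arr in (dapi, marker):
                noise = rng.standard_normal(shape, dtype=np.float32)
                noise *= intensity.noise_sigma
                arr += noise
                np.clip(arr, 0.0, None, out=arr)
    else:
        s = intensity.poisson_scale
        dapi = (rng.poisson(dapi * s) / s).astype(np.float32)
        marker = (rng.poisson(marker * s) / s).astype(np.float32)

    if intensity.psf_sigma > 0:
        sig = (
            intensity.psf_sigma / acq.dz,
            intensity.psf_sigma / acq.dy,
            intensity.psf_sigma / acq.dx,
        )
        dapi = gaussian_filter(dapi, sig)
        marker = gaussian_filter(marker, sig)

    voxels = np.stack([dapi, marker], axis=-1)
    stack = ImageStack(
        voxels=voxels,
        geometry=acq,
        channel_names=("dapi", "marker"),
        stack_id=stack_id,
    )
    truth = SyntheticTruth(
        cell_mask_3d=cell3d,
        nucleus_mask_3d=nuc3d,
        geometry=geometry,
        intensity_model=intensity,
        seed=seed,
    )
    return stack, truth


# ---------------------------------------------------------------------------
# cohort generation


@dataclass(frozen=True)
class CohortDesign:
    """Factorial design of a two-age-group imaging cohort.

    ``groups x n_donors_per_group x cell_types x markers x
    cells_per_donor_per_marker`` stacks are generated, each with a per-cell
    seed derived deterministically from ``seed``.  ``intensities`` maps
    ``(group, marker)`` to an :class:`IntensityModel` so that group- or
    marker-specific effects (e.g. a nuclear-to-cytoplasmic translocation in
    one age group) can be planted; ``geometries`` maps cell type to a
    :class:`CellGeometry`.
    """

    groups: tuple[str, ...] = ("junior", "senior")
    n_donors_per_group: int = 8
    cell_types: tuple[str, ...] = ("MO",)
    markers: tuple[str, ...] = ("HMGB1",)
    cells_per_donor_per_marker: int = 30
    intensities: Mapping[tuple[str, str], IntensityModel] = field(
        default_factory=dict
    )
    geometries: Mapping[str, CellGeometry] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.groups) < 1 or self.n_donors_per_group < 1:
            raise ValidationError("need >= 1 group and >= 1 donor per group")
        if (
            len(self.cell_types) < 1
            or len(self.markers) < 1
            or self.cells_per_donor_per_marker < 1
        ):
            raise ValidationError("counts must be >= 1")

    @classmethod
    def uniform(
        cls,
        intensity: IntensityModel | None = None,
        geometry: CellGeometry | None = None,
        **kwargs,
    ) -> "CohortDesign":
        """Design with identical parameters in every stratum (null cohort)."""
        design = cls(**kwargs)
        intensity = intensity if intensity is not None else IntensityModel()
        intensities = {
            (g, m): intensity for g in design.groups for m in design.markers
        }
        geometries = {
            t: (geometry if geometry is not None else _default_geometry(t))
            for t in design.cell_types
        }
        return replace(design, intensities=intensities, geometries=geometries)

    def with_translocation(
        self, group: str, marker: str, factor: float
    ) -> "CohortDesign":
        """Plant a cytoplasmic-shift effect: multiply ``mu_cyt`` by
        ``factor`` for one (group, marker) stratum."""
        base = self.intensity_for(group, marker)
        planted = replace(base, mu_cyt=base.mu_cyt * factor)
        intensities = dict(self.intensities)
        intensities[(group, marker)] = planted
        return replace(self, intensities=intensities)

    def intensity_for(self, group: str, marker: str) -> IntensityModel:
        if (group, marker) in self.intensities:
            return self.intensities[(group, marker)]
        return IntensityModel()

    def geometry_for(self, cell_type: str) -> CellGeometry:
        if cell_type in self.geometries:
            return self.geometries[cell_type]
        return _default_geometry(cell_type)

    @property
    def total_cells(self) -> int:
        return (
            len(self.groups)
            * self.n_donors_per_group
            * len(self.cell_types)
            * len(self.markers)
            * self.cells_per_donor_per_marker
        )


def _default_geometry(cell_type: str) -> CellGeometry:
    if cell_type.upper().startswith("GR"):
        return granulocyte_geometry()
    if cell_type.upper().startswith("MO"):
        return monocyte_geometry()
    return CellGeometry()


@dataclass
class CohortItem:
    """One generated cohort member: stack, ground truth and labels."""

    stack: ImageStack
    truth: SyntheticTruth
    labels: dict


def generate_cohort(
    design: CohortDesign, acq: AcquisitionGeometry | None = None
) -> Iterator[CohortItem]:
    """Yield every stack of ``design`` in a fixed label order.

    Iteration order is groups, donors, cell types, markers, cells (outer to
    inner).  Per-cell seeds are drawn from ``default_rng(design.seed)`` in
    that order, so the full cohort is reproducible bit-exactly from the
    master seed, and any prefix of the iteration is stable under extension
    of the inner loops.
    """
    if acq is None:
        acq = AcquisitionGeometry()
    master = np.random.default_rng(design.seed)
    idx = 0
    for group in design.groups:
        for d in range(design.n_donors_per_group):
            donor = f"{group}_d{d + 1}"
            for cell_type in design.cell_types:
                for marker in design.markers:
                    intensity = design.intensity_for(group, marker)
                    geometry = design.geometry_for(cell_type)
                    for c in range(design.cells_per_donor_per_marker):
                        cell_seed = int(master.integers(0, 2**31))
                        cell_id = (
                            f"{donor}_{cell_type}_{marker}_c{c + 1:03d}"
                        )
                        stack, truth = generate_cell_stack(
                            geometry,
                            intensity,
                            acq,
                            seed=cell_seed,
                            stack_id=cell_id,
                        )
                        yield CohortItem(
                            stack=stack,
                            truth=truth,
                            labels={
                                "cell_id": cell_id,
                                "donor": donor,
                                "group": group,
                                "cell_type": cell_type,
                                "marker": marker,
                                "seed": cell_seed,
                                "index": idx,
                            },
                        )
                        idx += 1
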