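"""Reduction of 3D stacks to 2D maps and cell/compartment segmentation.

The chain mirrors a standard single-cell confocal quantification recipe:
sum the voxel intensities along the optical axis, rescale the projection to
the full 8-bit range, take a global Otsu threshold to separate the cell
from background, keep the largest connected object as the cell of
interest, and split it into nuclear and cytoplasmic compartments using the
nuclear-stain (DAPI) channel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, NamedTuple

import numpy as np
from skimage import measure

from .errors import DimensionError, SegmentationWarning, ValidationError
from .stack import ImageStack


def sum_project(stack: ImageStack, channel: str) -> np.ndarray:
    """Z-sum projection of one channel: ``out[y, x] = sum_z voxels[z, y, x]``.

    No normalisation is applied; integer-valued inputs give exact integer
    sums (float64 accumulation).
    """
    return stack.channel(channel).astype(np.float64).sum(axis=0)


def rescale_8bit(proj: np.ndarray) -> np.ndarray:
    """Linearly rescale a projection to the full 8-bit range.

    ``out = round(255 * (v - min) / (max - min))`` with half-up rounding
    (fixed for cross-platform reproducibility).  A constant input maps to
    the all-zero image, preserving the "non-zero pixel" semantics of the
    downstream pixel count N.
    """
    proj = np.asarray(proj, dtype=np.float64)
    lo = proj.min()
    hi = proj.max()
    if hi == lo:
        return np.zeros(proj.shape, dtype=np.uint8)
    scaled = 255.0 * (proj - lo) / (hi - lo)
    return np.floor(scaled + 0.5).astype(np.uint8)


class OtsuResult(NamedTuple):
    """Otsu threshold plus a degeneracy flag.

    ``threshold`` is the smallest value of t maximising the between-class
    variance of the classes ``{v <= t}`` / ``{v > t}``; the foreground is
    ``img > threshold``.  For a constant (single-class) image
    ``threshold`` equals that constant value — so the foreground is empty —
    and ``single_class`` is True.
    """

    threshold: int
    single_class: bool


def otsu_threshold(values: np.ndarray) -> OtsuResult:
    """Global Otsu threshold of 8-bit values (image or masked pixel set).

    The between-class variance is compared in exact integer arithmetic
    (cross-multiplied rationals), so the smallest-maximiser tie-break is
    bit-exact and platform independent.
    """
    values = np.asarray(values)
    if values.size == 0:
        raise ValidationError("cannot threshold an empty pixel set")
    hist = np.bincount(values.ravel().astype(np.int64), minlength=256)
    nonzero = np.flatnonzero(hist)
    if nonzero.size == 1:
        return OtsuResult(threshold=int(nonzero[0]), single_class=True)

    total = int(hist.sum())
    weighted_total = int((np.arange(256) * hist).sum())
    # between-class variance at t:  (A*w0 - W*s0)^2 / (W^2 * w0 * (W - w0));
    # the W^2 factor is common to all t and dropped.
    best_t = 0
    best_num = -1  # numerator of best fraction
    best_den = 1
    w0 = 0
    s0 = 0
    for t in range(256):
        w0 += int(hist[t])
        s0 += t * int(hist[t])
        if w0 == 0 or w0 == total:
            continue
        num = (weighted_total * w0 - total * s0) ** 2
        den = w0 * (total - w0)
        # strict improvement only: ties resolve to the smallest t
        if num * best_den > best_num * den:
            best_t, best_num, best_den = t, num, den
    return OtsuResult(threshold=best_t, single_class=False)


def largest_component(mask: np.ndarray, connectivity: int = 2) -> np.ndarray:
    """Largest connected foreground object of a binary mask.

    Connectivity is 8-neighbour by default (``connectivity=2`` in 2D);
    pass 1 for 4-neighbour.  Ties in component size are broken by the
    component whose first pixel comes earliest in raster order.  An
    all-background mask is returned unchanged with a
    :class:`SegmentationWarning`.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        warnings.warn(
            "no foreground object in mask", SegmentationWarning, stacklevel=2
        )
        return mask.copy()
    labels = measure.label(mask, connectivity=connectivity)
    sizes = np.bincount(labels.ravel())
    sizes[0] = 0
    best = sizes.max()
    candidates = np.flatnonzero(sizes == best)
    if candidates.size == 1:
        winner = candidates[0]
    else:
        flat = labels.ravel()
        winner = min(
            candidates, key=lambda lab: int(np.argmax(flat == lab))
        )
    return labels == winner


def nucleus_mask(
    dapi8: np.ndarray, cell: np.ndarray
) -> tuple[np.ndarray, bool]:
    """Nuclear mask from the 8-bit DAPI projection, restricted to the cell.

    Otsu is computed on the DAPI pixels inside the cell mask only; the
    nuclear mask keeps every resulting component (lobed nuclei may be
    non-contiguous).  If the in-cell DAPI is single-class the nucleus is
    returned empty — the cell is then treated as all cytoplasm — and the
    flag is True.

    Returns
    -------
    (mask, single_class_flag)
    """
    dapi8 = np.asarray(dapi8)
    cell = np.asarray(cell, dtype=bool)
    if dapi8.shape != cell.shape:
        raise DimensionError("DAPI image and cell mask shapes differ")
    if not cell.any():
        raise ValidationError("cell mask has no foreground pixel")
    res = otsu_threshold(dapi8[cell])
    if res.single_class:
        warnings.warn(
            "single-class DAPI inside cell: empty nucleus, cell treated "
            "as all-cytoplasm",
            SegmentationWarning,
            stacklevel=2,
        )
        return np.zeros_like(cell), True
    return (dapi8 > res.threshold) & cell, False


@dataclass
class CompartmentSet:
    """Disjoint nuclear/cytoplasmic partition of a cell mask.

    Invariant (exact, pixelwise): ``nucleus & cytoplasm`` is empty and
    ``nucleus | cytoplasm == cell``.
    """

    cell: np.ndarray
    nucleus: np.ndarray
    cytoplasm: np.ndarray

    def __post_init__(self) -> None:
        if not (
            self.cell.shape == self.nucleus.shape == self.cytoplasm.shape
        ):
            raise DimensionError("compartment masks must share one shape")
        if np.any(self.nucleus & self.cytoplasm):
            raise ValidationError("nucleus and cytoplasm overlap")
        if not np.array_equal(self.nucleus | self.cytoplasm, self.cell):
            raise ValidationError("nucleus and cytoplasm do not tile the cell")


def compartments(cell: np.ndarray, nucleus: np.ndarray) -> CompartmentSet:
    """Split the cell mask into nuclear and cytoplasmic compartments.

    The nucleus is intersected with the cell first, then
    ``cytoplasm = cell & ~nucleus``; the partition invariant holds exactly
    by construction.
    """
    cell = np.asarray(cell, dtype=bool)
    nucleus = np.asarray(nucleus, dtype=bool)
    if cell.shape != nucleus.shape:
        raise DimensionError("cell and nucleus mask shapes differ")
    nuc = nucleus & cell
    return CompartmentSet(cell=cell, nucleus=nuc, cytoplasm=cell & ~nuc)


CellMaskChannel = Literal["marker", "nuclear", "union"]


@dataclass(frozen=True)
class SegmentationConfig:
    """Options of the segmentation chain.

    ``cell_mask_channel`` selects which projection the cell-level Otsu is
    computed on: the marker channel being quantified (default), the nuclear
    stain, or the union of both foregrounds.
    """

    nuclear_channel: str = "dapi"
    marker_channel: str = "marker"
    cell_mask_channel: CellMaskChannel = "marker"
    connectivity: int = 2


@dataclass
class SegmentationResult:
    """Outputs and QC flags of :func:`segment_cell`."""

    compartments: CompartmentSet
    marker8: np.ndarray
    dapi8: np.ndarray
    cell_threshold: int
    flags: list = field(default_factory=list)


def segment_cell(
    stack: ImageStack, config: SegmentationConfig | None = None
) -> SegmentationResult:
    """Full chain: project, rescale, Otsu, largest component, compartments.

    Degenerate inputs (constant projections, empty foreground) do not
    raise; they set QC flags (``otsu_single_class_cell``,
    ``empty_cell_mask``, ``otsu_single_class_nucleus``) and yield empty
    compartments where nothing can be segmented.
    """
    if config is None:
        config = SegmentationConfig()
    marker8 = rescale_8bit(sum_project(stack, config.marker_channel))
    dapi8 = rescale_8bit(sum_project(stack, config.nuclear_channel))

    flags: list[str] = []

    def _foreground(img8: np.ndarray, tag: str) -> tuple[np.ndarray, int]:
        res = otsu_threshold(img8)
        if res.single_class:
            flags.append(f"otsu_single_class_{tag}")
        return img8 > res.threshold, res.threshold

    if config.cell_mask_channel == "marker":
        fg, thr = _foreground(marker8, "cell")
    elif config.cell_mask_channel == "nuclear":
        fg, thr = _foreground(dapi8, "cell")
    else:
        fg_m, thr = _foreground(marker8, "cell")
        fg_d, _ = _foreground(dapi8, "cell_dapi")
        fg = fg_m | fg_d

    if fg.any():
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", SegmentationWarning)
            cell = largest_component(fg, connectivity=config.connectivity)
    else:
        flags.append("empty_cell_mask")
        cell = fg

    if cell.any():
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", SegmentationWarning)
            nuc, single = nucleus_mask(dapi8, cell)
        if single:
            flags.append("otsu_single_class_nucleus")
    else:
        nuc = np.zeros_like(cell)

    return SegmentationResult(
        compartments=compartments(cell, nuc),
        marker8=marker8,
        dapi8=dapi8,
        cell_threshold=thr,
        flags=flags,
    )
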