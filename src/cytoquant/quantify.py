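"""Per-compartment intensity metrics: histogram H(k), N, S, MFI, HWHM.

For each compartment of the 8-bit marker projection the pixel-value
histogram ``H(k) = #{(y, x) | I(y, x) = k}`` is built over ``k in
[1, 255]`` (value-0 pixels carry no detectable fluorescence and are
excluded).  From it come

* ``N`` — the number of non-zero pixels,
* ``S`` — the integrated intensity (sum of pixel values),
* ``MFI = S / N`` — the mean pixel intensity, an image-based analog of
  flow cytometry's mean fluorescence intensity,
* ``HWHM`` — the half-width at half-maximum of the histogram, a measure
  of fluorophore dispersion within the compartment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, NamedTuple

import numpy as np

from .errors import DimensionError, ValidationError
from .segmentation import (
    CompartmentSet,
    SegmentationConfig,
    SegmentationResult,
    segment_cell,
)
from .stack import ImageStack

#: histogram domain: intensities 1..255 (index i holds H(i + 1))
HIST_KS = np.arange(1, 256)


def histogram(img8: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Pixel-value histogram of masked pixels over k = 1..255.

    Returns an integer array of length 255; ``out[i]`` counts masked
    pixels with value exactly ``i + 1``.  Zero-valued pixels are excluded
    by the domain.
    """
    img8 = np.asarray(img8)
    mask = np.asarray(mask, dtype=bool)
    if img8.shape != mask.shape:
        raise DimensionError("image and mask shapes differ")
    return np.bincount(img8[mask].ravel().astype(np.int64), minlength=256)[1:]


def metrics_ns(
    img8: np.ndarray, mask: np.ndarray
) -> tuple[int, int, float]:
    """Non-zero pixel count N, integrated intensity S and MFI = S/N.

    Zero-valued pixels contribute nothing to either N or S, so S over all
    masked pixels equals S over non-zero ones.  ``N == 0`` yields a
    missing (NaN) MFI, never 0.
    """
    img8 = np.asarray(img8)
    mask = np.asarray(mask, dtype=bool)
    if img8.shape != mask.shape:
        raise DimensionError("image and mask shapes differ")
    vals = img8[mask].astype(np.int64)
    n = int(np.count_nonzero(vals))
    s = int(vals.sum())
    mfi = s / n if n > 0 else math.nan
    return n, s, mfi


class HwhmResult(NamedTuple):
    """HWHM value plus a flag set when a half-max crossing had to be
    clamped to the edge of the intensity domain."""

    value: float
    truncated: bool


HwhmMode = Literal["half_fwhm", "one_sided"]


def hwhm(counts: np.ndarray, mode: HwhmMode = "half_fwhm") -> HwhmResult:
    """Half-width at half-maximum of an intensity histogram.

    The mode bin ``k*`` is the smallest k maximising ``H(k)``; the
    half-max level is ``H(k*) / 2``.  Scanning left and right from the
    mode, the first bin strictly below the level marks a crossing, located
    to sub-bin precision by linear interpolation between that bin and its
    inner neighbour (a plateau exactly at half-max therefore resolves to
    its outermost edge).  The default returns half the full width between
    the two crossings; ``mode="one_sided"`` returns the mode-to-right-
    crossing distance.  A side that never drops below the level within
    [1, 255] is clamped to the domain edge and flagged ``truncated``.

    A histogram with all mass in a single bin has zero dispersion by
    convention: HWHM = 0 exactly.
    """
    counts = np.asarray(counts, dtype=np.float64)
    if counts.shape != (255,):
        raise DimensionError("expected a length-255 histogram over k=1..255")
    if counts.sum() <= 0:
        raise ValidationError("histogram has no mass")
    if np.count_nonzero(counts) == 1:
        return HwhmResult(0.0, False)

    i_mode = int(np.argmax(counts))  # smallest maximiser (argmax convention)
    level = counts[i_mode] / 2.0

    def _cross(direction: int) -> tuple[float, bool]:
        i = i_mode
        while True:
            j = i + direction
            if j < 0 or j > 254:
                return float(HIST_KS[i]), True  # clamped to domain edge
            if counts[j] < level:
                inner, outer = counts[j - direction], counts[j]
                frac = (inner - level) / (inner - outer)
                return float(HIST_KS[j - direction]) + direction * frac, False
            i = j

    right, trunc_r = _cross(+1)
    if mode == "one_sided":
        return HwhmResult(right - float(HIST_KS[i_mode]), trunc_r)
    left, trunc_l = _cross(-1)
    return HwhmResult((right - left) / 2.0, trunc_r or trunc_l)


@dataclass
class CompartmentMetrics:
    """N, S, MFI and HWHM for one compartment of one cell.

    ``N == 0`` leaves MFI and HWHM as NaN (explicit missing values).
    ``low_quality`` marks compartments with fewer non-zero pixels than the
    configured minimum.
    """

    n: int
    s: int
    mfi: float
    hwhm: float
    hwhm_truncated: bool = False
    low_quality: bool = False


def compartment_metrics(
    img8: np.ndarray,
    mask: np.ndarray,
    hwhm_mode: HwhmMode = "half_fwhm",
    min_pixels: int = 10,
) -> CompartmentMetrics:
    """All metrics of one compartment from the 8-bit image and its mask."""
    n, s, mfi = metrics_ns(img8, mask)
    if n == 0:
        return CompartmentMetrics(
            n=0, s=0, mfi=math.nan, hwhm=math.nan, low_quality=True
        )
    res = hwhm(histogram(img8, mask), mode=hwhm_mode)
    return CompartmentMetrics(
        n=n,
        s=s,
        mfi=mfi,
        hwhm=res.value,
        hwhm_truncated=res.truncated,
        low_quality=n < min_pixels,
    )


@dataclass(frozen=True)
class QuantConfig:
    """Configuration of the per-cell quantification chain."""

    segmentation: SegmentationConfig = SegmentationConfig()
    hwhm_mode: HwhmMode = "half_fwhm"
    min_pixels: int = 10


@dataclass
class QuantRecord:
    """Per-cell, per-marker quantification with cohort labels and QC."""

    cell_id: str
    donor: str = ""
    group: str = ""
    cell_type: str = ""
    marker: str = ""
    nuclear: CompartmentMetrics | None = None
    cytoplasmic: CompartmentMetrics | None = None
    qc_flags: list = field(default_factory=list)


def quantify_cell(
    stack: ImageStack,
    config: QuantConfig | None = None,
    labels: dict | None = None,
    compartment_set: CompartmentSet | None = None,
) -> QuantRecord:
    """Quantify one stack end to end.

    Runs projection, rescale, segmentation and per-compartment metrics for
    the marker channel; deterministic for fixed input and config.
    Segmentation degeneracies propagate into ``qc_flags``.

    ``compartment_set`` bypasses Otsu segmentation with externally supplied
    masks (e.g. synthetic ground truth) — a validation path that isolates
    the quantification stage from segmentation error.
    """
    if config is None:
        config = QuantConfig()
    labels = labels or {}
    flags: list[str] = []
    if compartment_set is None:
        seg: SegmentationResult = segment_cell(stack, config.segmentation)
        comp = seg.compartments
        marker8 = seg.marker8
        flags.extend(seg.flags)
    else:
        from .segmentation import rescale_8bit, sum_project

        comp = compartment_set
        marker8 = rescale_8bit(
            sum_project(stack, config.segmentation.marker_channel)
        )

    nuc = compartment_metrics(
        marker8, comp.nucleus, config.hwhm_mode, config.min_pixels
    )
    cyt = compartment_metrics(
        marker8, comp.cytoplasm, config.hwhm_mode, config.min_pixels
    )
    if nuc.low_quality:
        flags.append("low_n_nuclear")
    if cyt.low_quality:
        flags.append("low_n_cytoplasmic")
    if nuc.hwhm_truncated or cyt.hwhm_truncated:
        flags.append("hwhm_truncated")

    return QuantRecord(
        cell_id=str(labels.get("cell_id", stack.stack_id or "cell")),
        donor=str(labels.get("donor", "")),
        group=str(labels.get("group", "")),
        cell_type=str(labels.get("cell_type", "")),
        marker=str(labels.get("marker", "")),
        nuclear=nuc,
        cytoplasmic=cyt,
        qc_flags=flags,
    )


def records_to_frame(records) -> "pandas.DataFrame":  # noqa: F821
    """Flatten QuantRecords into one tidy row per cell.

    Columns: labels, then ``nuc_``/``cyt_``-prefixed N, S, MFI, HWHM and
    QC fields.  Missing metrics stay NaN, never 0.
    """
    import pandas as pd

    rows = []
    for r in records:
        row = {
            "cell_id": r.cell_id,
            "donor": r.donor,
            "group": r.group,
            "cell_type": r.cell_type,
            "marker": r.marker,
        }
        for prefix, m in (("nuc", r.nuclear), ("cyt", r.cytoplasmic)):
            if m is None:
                m = CompartmentMetrics(
                    n=0, s=0, mfi=math.nan, hwhm=math.nan, low_quality=True
                )
            row[f"{prefix}_n"] = m.n
            row[f"{prefix}_s"] = m.s
            row[f"{prefix}_mfi"] = m.mfi
            row[f"{prefix}_hwhm"] = m.hwhm
            row[f"{prefix}_hwhm_truncated"] = m.hwhm_truncated
            row[f"{prefix}_low_quality"] = m.low_quality
        row["qc_flags"] = ";".join(r.qc_flags)
        rows.append(row)
    return pd.DataFrame(rows)
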