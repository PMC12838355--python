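"""Independent brute-force oracles used by the tests.

These deliberately avoid the package's own formulations: exact rational
arithmetic and per-candidate scans instead of cumulative recursions,
flood fill instead of library labelling, full enumeration instead of
closed-form test distributions.
"""

from __future__ import annotations

from fractions import Fraction
from itertools import combinations

import numpy as np


def otsu_brute_force(img: np.ndarray) -> int:
    """Exhaustive Otsu: for every t in [0, 255] compute the between-class
    variance of {v <= t} vs {v > t} in exact rational arithmetic and
    return the smallest maximiser."""
    hist = np.bincount(np.asarray(img).ravel().astype(int), minlength=256)
    total = int(hist.sum())
    best_t, best_v = 0, Fraction(-1)
    for t in range(256):
        w0 = int(hist[: t + 1].sum())
        w1 = total - w0
        if w0 == 0 or w1 == 0:
            continue
        mu0 = Fraction(int((np.arange(t + 1) * hist[: t + 1]).sum()), w0)
        mu1 = Fraction(
            int((np.arange(t + 1, 256) * hist[t + 1 :]).sum()), w1
        )
        v = Fraction(w0, total) * Fraction(w1, total) * (mu0 - mu1) ** 2
        if v > best_v:
            best_t, best_v = t, v
    return best_t


def largest_component_flood(mask: np.ndarray, connectivity: int = 2):
    """Flood-fill connected components; returns (largest-component mask,
    list of component sizes).  Tie broken by earliest raster-order seed."""
    mask = np.asarray(mask, dtype=bool)
    ny, nx = mask.shape
    seen = np.zeros_like(mask)
    if connectivity == 2:
        neigh = [(-1, -1), (-1, 0), (-1, 1), (0, -1),
                 (0, 1), (1, -1), (1, 0), (1, 1)]
    else:
        neigh = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    best, best_size, sizes = None, 0, []
    for y0 in range(ny):
        for x0 in range(nx):
            if not mask[y0, x0] or seen[y0, x0]:
                continue
            comp = np.zeros_like(mask)
            stackq = [(y0, x0)]
            seen[y0, x0] = comp[y0, x0] = True
            while stackq:
                y, x = stackq.pop()
                for dy, dx in neigh:
                    yy, xx = y + dy, x + dx
                    if (
                        0 <= yy < ny and 0 <= xx < nx
                        and mask[yy, xx] and not seen[yy, xx]
                    ):
                        seen[yy, xx] = comp[yy, xx] = True
                        stackq.append((yy, xx))
            size = int(comp.sum())
            sizes.append(size)
            if size > best_size:  # first (raster-earliest) wins ties
                best, best_size = comp, size
    return best, sizes


def mannwhitney_permutation_p(x, y) -> float:
    """Two-sided Mann–Whitney p by full enumeration of group assignments
    (tie-free data assumed; n1 + n2 choose n1 splits)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    n1, n2 = x.size, y.size
    m = n1 * n2 / 2.0
    u_obs = float((x[:, None] > y[None, :]).sum())
    count = 0
    total = 0
    for ix in combinations(range(n1 + n2), n1):
        xs = pooled[list(ix)]
        ys = np.delete(pooled, list(ix))
        u = float((xs[:, None] > ys[None, :]).sum())
        if abs(u - m) >= abs(u_obs - m) - 1e-12:
            count += 1
        total += 1
    return count / total


def gaussian_hwhm(sigma: float) -> float:
    """Closed-form half width at half maximum of a Gaussian."""
    return sigma * np.sqrt(2.0 * np.log(2.0))


def noiseless_mfi_ratio(intensity, n_slices: int) -> float:
    """Closed-form nuclear:cytoplasmic 8-bit MFI ratio of a noiseless,
    blur-free slab phantom.

    All projection columns take one of three exact values (background,
    cytoplasm, nucleus); after full-range rescale with half-up rounding
    the nucleus maps to 255 and the cytoplasm to
    round(255 (cyt - bg) / (nuc - bg))."""
    bg = intensity.background * n_slices
    cyt = intensity.mu_cyt * n_slices
    nuc = intensity.mu_nuc * n_slices
    cyt8 = np.floor(255.0 * (cyt - bg) / (nuc - bg) + 0.5)
    return 255.0 / cyt8
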