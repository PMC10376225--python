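"""Per-slice preprocessing: skull stripping, edge-preserving denoising,
and brain-restricted contrast enhancement.

The stage order is fixed: skull_strip -> anisotropic_diffusion ->
hist_equalize.  Skull stripping is the classic morphological recipe (Otsu
binarization, erosion to detach brain tissue from the bright skull/scalp
rim, largest connected component, dilation, hole filling).  Denoising is
the Perona-Malik explicit scheme with exponential conductance.  Contrast
enhancement is CDF-based histogram equalization computed from, and applied
to, brain-mask pixels only — background zeros would otherwise dominate the
CDF.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.morphology import disk

from .mri_io import Slice

__all__ = [
    "PreprocessConfig",
    "PreprocessResult",
    "otsu_threshold",
    "skull_strip",
    "anisotropic_diffusion",
    "hist_equalize",
    "preprocess_slice",
]


@dataclass
class PreprocessConfig:
    """Knobs for the preprocessing stage.

    morph_radius: disk radius (px) of the structuring element used in the
        skull-strip erosion/dilation.
    diffusion_iters, kappa, lam: Perona-Malik iteration count, conductance
        scale (intensity units on an 8-bit scale) and explicit step weight;
        lam must satisfy the 2D stability bound 0 < lam <= 0.25.
    histeq_bins: histogram bin count for equalization.
    """

    morph_radius: int = 3
    diffusion_iters: int = 10
    kappa: float = 30.0
    lam: float = 0.14
    histeq_bins: int = 256

    def __post_init__(self) -> None:
        if self.morph_radius < 1:
            raise ValueError("morph_radius must be >= 1")
        if not (0 < self.lam <= 0.25):
            raise ValueError(f"lam={self.lam} outside the stability bound (0, 0.25]")
        if self.kappa <= 0:
            raise ValueError("kappa must be > 0")
        if self.histeq_bins < 2:
            raise ValueError("histeq_bins must be >= 2")
        if self.diffusion_iters < 0:
            raise ValueError("diffusion_iters must be >= 0")


@dataclass
class PreprocessResult:
    """clean: equalized (display-contrast) slice; smooth: the diffused
    slice before equalization, on the original intensity scale."""

    clean: Slice
    brain_mask: np.ndarray
    smooth: Slice | None = None
    empty: bool = False  # warning flag: no brain foreground found


def otsu_threshold(sl: Slice | np.ndarray) -> tuple[float, np.ndarray]:
    """Otsu's threshold over the exact value histogram.

    Returns ``(threshold, mask)`` where the threshold maximizes the
    between-class variance over candidate cuts between consecutive distinct
    values and ``mask = data > threshold``.  Ties pick the lowest cut.
    Raises ``ValueError`` on a constant image (no threshold exists).
    """
    data = sl.data if isinstance(sl, Slice) else np.asarray(sl, dtype=np.float64)
    values, counts = np.unique(data, return_counts=True)
    if values.size < 2:
        raise ValueError("degenerate input: constant image has no Otsu threshold")
    counts = counts.astype(np.float64)
    total = counts.sum()
    w0 = np.cumsum(counts)[:-1]          # pixels at or below candidate cut
    w1 = total - w0
    cum = np.cumsum(counts * values)
    mu0 = cum[:-1] / w0
    mu1 = (cum[-1] - cum[:-1]) / w1
    sigma_b = w0 * w1 * (mu0 - mu1) ** 2
    k = int(np.argmax(sigma_b))          # argmax takes the first maximum
    thr = 0.5 * (values[k] + values[k + 1])
    return float(thr), data > thr


def skull_strip(
    sl: Slice, cfg: PreprocessConfig | None = None
) -> tuple[Slice, np.ndarray, bool]:
    """Strip skull/scalp, returning (brain slice, brain mask, empty flag).

    Otsu binarize -> erode (disk of ``morph_radius``, detaching brain
    tissue from the bright rim) -> keep largest connected component ->
    dilate back -> fill interior holes.  Outside-mask pixels are zeroed.
    Slices with no usable foreground (volume extremes) return an empty
    mask with the warning flag set instead of raising.
    """
    cfg = cfg or PreprocessConfig()
    data = sl.data
    empty_mask = np.zeros(data.shape, dtype=bool)
    try:
        _, fg = otsu_threshold(sl)
    except ValueError:
        return Slice(np.zeros_like(data), sl.spacing, sl.index), empty_mask, True
    if not fg.any():
        return Slice(np.zeros_like(data), sl.spacing, sl.index), empty_mask, True

    selem = disk(cfg.morph_radius)
    core = ndimage.binary_erosion(fg, structure=selem, border_value=0)
    if not core.any():
        # foreground thinner than the structuring element everywhere
        return Slice(np.zeros_like(data), sl.spacing, sl.index), empty_mask, True
    labels, n = ndimage.label(core)
    if n > 1:
        sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=range(1, n + 1))
        core = labels == (1 + int(np.argmax(sizes)))
    mask = ndimage.binary_dilation(core, structure=selem)
    mask = ndimage.binary_fill_holes(mask)
    brain = np.where(mask, data, 0.0)
    return Slice(brain, sl.spacing, sl.index), mask, False


def anisotropic_diffusion(sl: Slice, cfg: PreprocessConfig | None = None) -> Slice:
    """Perona-Malik edge-preserving smoothing (explicit scheme).

    4-neighbour fluxes with exponential conductance
    ``c(g) = exp(-(g/kappa)^2)``, update ``I <- I + lam * sum(c * dI)``,
    replicated (Neumann) boundaries.  Constant images are fixed points and
    the discrete max principle holds for ``lam <= 0.25``.
    """
    cfg = cfg or PreprocessConfig()
    img = sl.data.copy()
    for _ in range(cfg.diffusion_iters):
        padded = np.pad(img, 1, mode="edge")
        d_n = padded[:-2, 1:-1] - img
        d_s = padded[2:, 1:-1] - img
        d_w = padded[1:-1, :-2] - img
        d_e = padded[1:-1, 2:] - img
        flux = sum(np.exp(-((d / cfg.kappa) ** 2)) * d for d in (d_n, d_s, d_w, d_e))
        img += cfg.lam * flux
    return Slice(img, sl.spacing, sl.index)


def hist_equalize(
    sl: Slice, mask: np.ndarray, cfg: PreprocessConfig | None = None
) -> Slice:
    """Global CDF equalization restricted to the mask.

    The CDF is estimated from in-mask pixels on ``histeq_bins`` bins and
    in-mask intensities are remapped onto [0, 255]; out-of-mask pixels pass
    through bit-identically.  The mapping is monotone non-decreasing.
    Raises ``ValueError`` on an empty mask.
    """
    cfg = cfg or PreprocessConfig()
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("degenerate input: empty mask")
    data = sl.data
    pix = data[mask]
    lo, hi = float(pix.min()), float(pix.max())
    out = data.copy()
    if hi == lo:
        # constant region: nothing to redistribute
        return Slice(out, sl.spacing, sl.index)
    edges = np.linspace(lo, hi, cfg.histeq_bins + 1)
    hist, _ = np.histogram(pix, bins=edges)
    cdf = np.cumsum(hist).astype(np.float64)
    cdf /= cdf[-1]
    # normalize away the mass of the first occupied bin so the lowest level
    # maps to 0 and the highest to 255 (classic display-range equalization)
    cdf_min = cdf[np.flatnonzero(hist)[0]]
    if cdf_min < 1.0:
        cdf = (cdf - cdf_min) / (1.0 - cdf_min)
        cdf = np.clip(cdf, 0.0, 1.0)
    # map each pixel through the CDF of its bin (monotone by construction)
    idx = np.clip(np.digitize(pix, edges[1:-1]), 0, cfg.histeq_bins - 1)
    out[mask] = cdf[idx] * 255.0
    return Slice(out, sl.spacing, sl.index)


def preprocess_slice(
    sl: Slice, cfg: PreprocessConfig | None = None
) -> PreprocessResult:
    """skull_strip -> anisotropic_diffusion -> hist_equalize, in order.

    Slices with no brain foreground come back untouched (zeros) with the
    ``empty`` flag set so volume processing never aborts.
    """
    cfg = cfg or PreprocessConfig()
    brain, mask, empty = skull_strip(sl, cfg)
    if empty:
        return PreprocessResult(clean=brain, brain_mask=mask, smooth=brain, empty=True)
    smooth = anisotropic_diffusion(brain, cfg)
    clean = hist_equalize(smooth, mask, cfg)
    return PreprocessResult(clean=clean, brain_mask=mask, smooth=smooth, empty=False)
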