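"""Similarity measures for registration, outlier rejection and evaluation.

All measures accept an optional binary mask and evaluate strictly inside
it: voxels outside the mask never influence the score.  NCC and LNCC live
in [-1, 1]; SSIM in [-1, 1]; NMI >= 0; PSNR is finite unless the images
are identical (then +inf, flagged).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.metrics import structural_similarity

__all__ = ["SimilarityScore", "ncc", "lncc", "mutual_information",
           "normalized_mutual_information", "psnr", "ssim",
           "evaluate_similarity", "METRICS"]

METRICS = ("NCC", "LNCC", "SSIM", "PSNR", "NMI", "MI")


@dataclass(frozen=True)
class SimilarityScore:
    metric: str
    value: float
    n_voxels: int


def _masked(a, b, mask):
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("arrays must have the same shape")
    if mask is None:
        return a.ravel(), b.ravel()
    m = np.asarray(mask, dtype=bool)
    if m.shape != a.shape:
        raise ValueError("mask shape mismatch")
    return a[m], b[m]


def ncc(a, b, mask=None, on_zero_variance: str = "raise") -> float:
    """Pearson correlation of the masked intensities (symmetric in a, b).

    ``on_zero_variance`` controls the degenerate case: ``"raise"`` (the
    default) or ``"zero"`` (return 0.0, used inside registration where a
    flat candidate projection should score as uninformative, not fail).
    """
    x, y = _masked(a, b, mask)
    if x.size < 2:
        raise ValueError("need at least 2 masked voxels")
    xc = x - x.mean()
    yc = y - y.mean()
    nx = np.linalg.norm(xc)
    ny = np.linalg.norm(yc)
    if nx < 1e-12 or ny < 1e-12:
        if on_zero_variance == "zero":
            return 0.0
        raise ValueError("zero variance in NCC input")
    return float(np.clip(xc @ yc / (nx * ny), -1.0, 1.0))


def lncc(a, b, mask=None, radius: int = 2) -> float:
    """Localized NCC: mean over masked voxels of the Pearson coefficient
    computed in cubic windows of half-width ``radius``.

    Window statistics are mask-weighted, confining the measure to the
    masked region; zero-variance windows are skipped.
    """
    if radius < 1:
        raise ValueError("radius must be >= 1")
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("arrays must have the same shape")
    m = np.ones(a.shape) if mask is None else np.asarray(mask, dtype=float)
    size = 2 * radius + 1

    def box(x):
        return ndimage.uniform_filter(x, size=size, mode="constant") * size ** a.ndim

    n = box(m)
    sa, sb = box(a * m), box(b * m)
    saa, sbb, sab = box(a * a * m), box(b * b * m), box(a * b * m)
    with np.errstate(invalid="ignore", divide="ignore"):
        mu_a, mu_b = sa / n, sb / n
        va = saa / n - mu_a ** 2
        vb = sbb / n - mu_b ** 2
        cab = sab / n - mu_a * mu_b
        cc = cab / np.sqrt(va * vb)
    valid = (m > 0.5) & (n >= 2) & (va > 1e-12) & (vb > 1e-12)
    if not valid.any():
        raise ValueError("no valid LNCC windows")
    return float(np.clip(np.mean(np.clip(cc[valid], -1.0, 1.0)), -1.0, 1.0))


def _hist_entropies(a, b, mask, bins):
    x, y = _masked(a, b, mask)
    h, _, _ = np.histogram2d(x, y, bins=bins)
    p = h / h.sum()
    px = p.sum(axis=1)
    py = p.sum(axis=0)

    def H(q):
        q = q[q > 0]
        return -np.sum(q * np.log(q))

    return H(px), H(py), H(p.ravel()), x.size


def mutual_information(a, b, mask=None, bins: int = 32) -> float:
    hx, hy, hxy, _ = _hist_entropies(a, b, mask, bins)
    return float(hx + hy - hxy)


def normalized_mutual_information(a, b, mask=None, bins: int = 32) -> float:
    """Studholme NMI, (H(a) + H(b)) / H(a, b); >= 1 for any pair."""
    hx, hy, hxy, _ = _hist_entropies(a, b, mask, bins)
    if hxy < 1e-12:
        return 2.0  # both images constant: perfectly redundant
    return float((hx + hy) / hxy)


def psnr(a, ref, mask=None) -> float:
    """Peak signal-to-noise ratio in dB with peak = max of the reference
    inside the mask.  Identical inputs give +inf."""
    x, r = _masked(a, ref, mask)
    mse = float(np.mean((x - r) ** 2))
    if mse == 0.0:
        return float("inf")
    peak = float(np.max(np.abs(r)))
    if peak <= 0:
        raise ValueError("reference peak is not positive")
    return float(10.0 * np.log10(peak ** 2 / mse))


def ssim(a, b, mask=None, win_size: int = 7) -> float:
    """Mean structural similarity over the mask, after linearly rescaling
    both images to [0, 1] over the masked intensity range."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    m = np.ones(a.shape, dtype=bool) if mask is None else np.asarray(mask, bool)

    def rescale(x):
        lo, hi = x[m].min(), x[m].max()
        if hi - lo < 1e-12:
            return np.zeros_like(x)
        return (x - lo) / (hi - lo)

    ra, rb = rescale(a), rescale(b)
    if np.array_equal(ra[m], rb[m]):
        return 1.0
    # windows near the mask boundary must not see outside intensities:
    # pin them to a constant so the score depends on masked voxels only
    ra = np.where(m, ra, 0.0)
    rb = np.where(m, rb, 0.0)
    _, smap = structural_similarity(ra, rb, win_size=win_size, data_range=1.0,
                                    full=True)
    return float(np.mean(smap[m]))


def evaluate_similarity(a, b, mask=None, metric: str = "NCC",
                        **kwargs) -> SimilarityScore:
    """Score two arrays under a named metric restricted to the mask.

    PSNR treats the *second* argument as the reference; all other metrics
    are symmetric.
    """
    name = metric.upper()
    n = int(np.sum(mask)) if mask is not None else int(np.asarray(a).size)
    if name == "NCC":
        v = ncc(a, b, mask, **kwargs)
    elif name == "LNCC":
        v = lncc(a, b, mask, **kwargs)
    elif name == "SSIM":
        v = ssim(a, b, mask, **kwargs)
    elif name == "PSNR":
        v = psnr(a, b, mask, **kwargs)
    elif name == "NMI":
        v = normalized_mutual_information(a, b, mask, **kwargs)
    elif name == "MI":
        v = mutual_information(a, b, mask, **kwargs)
    else:
        raise ValueError(f"unknown metric {metric!r}; choose from {METRICS}")
    return SimilarityScore(name, v, n)
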