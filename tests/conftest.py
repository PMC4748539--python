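import numpy as np
import pytest

from slicequant.segmentation import SegmentationParams
from slicequant.simulate import FieldSpec


@pytest.fixture
def params():
    return SegmentationParams()


@pytest.fixture
def small_spec():
    """A compact field spec used throughout: fast but honors every
    generator guarantee (separation, margins, noise)."""
    return FieldSpec(width=160, height=160, n_nuclei=24, seed=11)


# ---------------------------------------------------------------------------
# independent oracles (deliberately naive implementations)
# ---------------------------------------------------------------------------


def iterative_reconstruction_erosion(seed, mask, max_iter=100_000):
    """Morphological reconstruction by erosion via fixed-point iteration:
    repeatedly take the pointwise max of the mask image and the 8-connected
    grayscale erosion of the current estimate until nothing changes."""
    import scipy.ndimage as ndi

    out = np.asarray(seed, dtype=float).copy()
    mask = np.asarray(mask, dtype=float)
    footprint = np.ones((3, 3), dtype=bool)
    for _ in range(max_iter):
        nxt = np.maximum(mask, ndi.grey_erosion(out, footprint=footprint))
        if np.array_equal(nxt, out):
            return out
        out = nxt
    raise RuntimeError("reconstruction oracle did not converge")


def bfs_component_count(mask, min_px):
    """Count 8-connected components with at least ``min_px`` pixels by
    plain breadth-first search over a boolean mask."""
    mask = np.asarray(mask, dtype=bool)
    seen = np.zeros_like(mask)
    h, w = mask.shape
    count = 0
    for r0 in range(h):
        for c0 in range(w):
            if not mask[r0, c0] or seen[r0, c0]:
                continue
            size = 0
            stack = [(r0, c0)]
            seen[r0, c0] = True
            while stack:
                r, c = stack.pop()
                size += 1
                for dr in (-1, 0, 1):
                    for dc in (-1, 0, 1):
                        rr, cc = r + dr, c + dc
                        if 0 <= rr < h and 0 <= cc < w and mask[rr, cc] and not seen[rr, cc]:
                            seen[rr, cc] = True
                            stack.append((rr, cc))
            if size >= min_px:
                count += 1
    return count


def exhaustive_otsu(raster, nbins=256):
    """Exhaustive between-class-variance maximizer over all candidate cut
    levels of an ``nbins``-bin histogram; tied maximizers are averaged."""
    arr = np.asarray(raster, dtype=float).ravel()
    lo, hi = arr.min(), arr.max()
    assert lo < hi, "oracle needs a non-degenerate raster"
    counts, edges = np.histogram(arr, bins=nbins, range=(lo, hi))
    centers = (edges[:-1] + edges[1:]) / 2.0
    best_var = -1.0
    best_levels = []
    for t in range(nbins - 1):  # cut after bin t; top-bin cut leaves a class empty
        n0 = counts[: t + 1].sum()
        n1 = counts[t + 1 :].sum()
        if n0 == 0 or n1 == 0:
            var = 0.0
        else:
            mu0 = (counts[: t + 1] * centers[: t + 1]).sum() / n0
            mu1 = (counts[t + 1 :] * centers[t + 1 :]).sum() / n1
            var = n0 * n1 * (mu0 - mu1) ** 2
        if var > best_var + 1e-9 * max(best_var, 1.0):
            best_var = var
            best_levels = [t]
        elif abs(var - best_var) <= 1e-9 * max(best_var, 1.0):
            best_levels.append(t)
    level = float(np.mean(best_levels))
    width = (hi - lo) / nbins
    return lo + (level + 1.0) * width
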