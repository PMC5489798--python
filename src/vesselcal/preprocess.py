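"""Image loading, binarization by intensity threshold, and thinning.

Images are plain 2-D numpy arrays in (row, col) convention, origin top-left,
0-based.  Grayscale intensities live either in [0, 255] (integer input) or
[0, 1] (float input); binary images are uint8 arrays of {0, 1}.
"""

from __future__ import annotations

from typing import Literal, Union

import imageio.v3 as iio
import numpy as np
from skimage.filters import threshold_otsu
from skimage.morphology import skeletonize as _zhang_suen

__all__ = ["load_image", "to_gray", "binarize", "skeletonize"]

ChannelPolicy = Literal["green", "luminance", "red", "blue"]
# ITU-R BT.601 luma weights
_LUMA = np.array([0.299, 0.587, 0.114])
_CHANNEL_INDEX = {"red": 0, "green": 1, "blue": 2}


def load_image(path, channel_policy: ChannelPolicy = "green") -> np.ndarray:
    """Load a PNG/TIFF/JPEG/PPM file and reduce it to a grayscale grid.

    Fundus photographs carry the highest vessel contrast in the green plane,
    hence the default ``channel_policy="green"``; ``"luminance"`` applies the
    BT.601 weighted sum instead.  Single-channel files pass through unchanged.
    """
    try:
        arr = np.asarray(iio.imread(path))
    except FileNotFoundError:
        raise
    except Exception as exc:  # corrupt / undecodable
        raise IOError(f"cannot read image file {path!r}: {exc}") from exc
    return to_gray(arr, channel_policy)


def to_gray(arr: np.ndarray, channel_policy: ChannelPolicy = "green") -> np.ndarray:
    """Reduce a decoded array to 2-D grayscale under ``channel_policy``."""
    arr = np.asarray(arr)
    if arr.ndim == 2:
        return arr
    if arr.ndim == 3 and arr.shape[2] in (3, 4):
        rgb = arr[..., :3]
        if channel_policy == "luminance":
            out = rgb.astype(float) @ _LUMA
            if np.issubdtype(arr.dtype, np.integer):
                out = np.rint(out).astype(arr.dtype)
            return out
        try:
            return rgb[..., _CHANNEL_INDEX[channel_policy]]
        except KeyError:
            raise ValueError(f"unknown channel policy {channel_policy!r}") from None
    raise ValueError(
        f"unsupported image layout with shape {arr.shape}; expected 2-D or "
        "3-D with 3 or 4 channels"
    )


def _intensity_range(image: np.ndarray) -> tuple[float, float]:
    """Declared intensity range: [0,1] for unit-scaled floats, else [0,255]."""
    if np.issubdtype(image.dtype, np.floating) and image.size and image.max() <= 1.0:
        return 0.0, 1.0
    return 0.0, 255.0


def binarize(
    image: np.ndarray,
    threshold: Union[float, Literal["auto"]] = "auto",
    polarity: Literal["bright_vessels", "dark_vessels"] = "bright_vessels",
) -> np.ndarray:
    """Threshold a grayscale image to a {0, 1} vessel map.

    With ``polarity="bright_vessels"`` a pixel maps to 1 iff its intensity
    strictly exceeds the threshold S (hand-labeled vessel maps are white on
    black); ``"dark_vessels"`` inverts the comparison for raw fundus photos.
    Pixels exactly equal to S map to background in both polarities — the
    strict inequalities leave the tie unassigned, and background is the
    conservative choice.  ``threshold="auto"`` selects S by Otsu's criterion
    on the grayscale histogram.
    """
    image = np.asarray(image)
    if image.ndim != 2:
        raise ValueError("binarize expects a 2-D grayscale image")
    if threshold == "auto":
        if np.ptp(image) == 0:
            # degenerate constant image: nothing exceeds any threshold
            return np.zeros(image.shape, dtype=np.uint8)
        s = float(threshold_otsu(image))
    else:
        s = float(threshold)
        lo, hi = _intensity_range(image)
        if not lo <= s <= hi:
            raise ValueError(
                f"threshold {s} outside the image intensity range [{lo}, {hi}]"
            )
    if polarity == "bright_vessels":
        out = image > s
    elif polarity == "dark_vessels":
        out = image < s
    else:
        raise ValueError(f"unknown polarity {polarity!r}")
    return out.astype(np.uint8)


def skeletonize(mask: np.ndarray) -> np.ndarray:
    """Thin a binary vessel map to a 1-pixel-wide centerline skeleton.

    Uses Zhang–Suen two-subiteration parallel thinning (8-connectivity),
    which iteratively erodes outer pixel layers until no further layer can
    be removed, followed by a topology-preserving cleanup of the residual
    2×2 blocks the parallel scheme can leave at X-shaped junctions.  The
    result is a subset of the foreground, contains no full 2×2 foreground
    block, and preserves the number of 8-connected components.
    """
    mask = np.asarray(mask)
    uniq = np.unique(mask)
    if not np.all(np.isin(uniq, (0, 1))):
        raise ValueError("skeletonize expects a binary {0,1} image")
    sk = _zhang_suen(mask.astype(bool), method="zhang")
    return _prune_2x2_blocks(sk).astype(np.uint8)


_EIGHT_RING = [(-1, -1), (-1, 0), (-1, 1), (0, 1),
               (1, 1), (1, 0), (1, -1), (0, -1)]


def _is_simple(sk: np.ndarray, r: int, c: int) -> bool:
    """True when deleting (r, c) keeps its foreground neighbors connected.

    The neighbors' mutual 8-adjacency is evaluated directly (not the ring
    crossing number, which is conservative at diagonal contacts).
    """
    h, w = sk.shape
    nbrs = [(r + dr, c + dc) for dr, dc in _EIGHT_RING
            if 0 <= r + dr < h and 0 <= c + dc < w and sk[r + dr, c + dc]]
    if len(nbrs) < 2:
        return False
    # union-find over <= 8 nodes
    parent = {p: p for p in nbrs}

    def find(p):
        while parent[p] != p:
            parent[p] = parent[parent[p]]
            p = parent[p]
        return p

    for i, p in enumerate(nbrs):
        for q in nbrs[i + 1:]:
            if max(abs(p[0] - q[0]), abs(p[1] - q[1])) == 1:
                parent[find(p)] = find(q)
    return len({find(p) for p in nbrs}) == 1


def _prune_2x2_blocks(sk: np.ndarray) -> np.ndarray:
    """Delete simple pixels until no full 2×2 foreground block remains."""
    sk = sk.copy()
    while True:
        blocks = np.argwhere(sk[:-1, :-1] & sk[1:, :-1]
                             & sk[:-1, 1:] & sk[1:, 1:])
        if len(blocks) == 0:
            return sk
        deleted = False
        for r0, c0 in blocks:
            for r, c in ((r0, c0), (r0, c0 + 1), (r0 + 1, c0), (r0 + 1, c0 + 1)):
                if sk[r, c] and _is_simple(sk, r, c):
                    sk[r, c] = False
                    deleted = True
                    break
            if deleted:
                break
        if not deleted:       # no safely removable pixel; give up cleanly
            return sk
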