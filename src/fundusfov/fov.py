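"""Device field-of-view simulation on fundus images.

The restricted field of view (FOV) of a smartphone ophthalmoscope adapter is
simulated on a full fundus photograph in four steps:

1. fit a circle to the retina/background boundary (Canny edges on the green
   channel + circular Hough transform);
2. locate the optic disc — the brightest compact region inside the boundary
   — by high-quantile thresholding and morphological filtering;
3. build a circular mask centred on the disc with radius
   ``fov_fraction x boundary_radius`` (devices frame the optic nerve head);
4. mask and crop to the mask's square bounding box.

Device FOV fractions, measured as a fraction of the fundus-image boundary
radius: iExaminer 0.32, D-Eye 0.40, Peek Retina 0.45, iNview 0.94.

A separate :func:`preprocess_for_classifier` implements the fixed-input-size
preparation for the classifier: symmetric crop to a square, then bilinear
anti-aliased down-sampling to 227x227x3.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import feature, morphology, transform
from skimage.util import img_as_ubyte

__all__ = [
    "BoundaryCircle",
    "OpticDisc",
    "DeviceProfile",
    "MaskSpec",
    "BoundaryNotFound",
    "DiscNotFound",
    "DEVICE_PROFILES",
    "fit_boundary_circle",
    "detect_optic_disc",
    "make_device_mask",
    "apply_mask_and_crop",
    "preprocess_for_classifier",
]


class BoundaryNotFound(RuntimeError):
    """No circle scored above the acceptance floor."""


class DiscNotFound(RuntimeError):
    """No sufficiently large bright component inside the boundary."""


@dataclass(frozen=True)
class BoundaryCircle:
    center: tuple[float, float]  # (x, y)
    radius: float
    score: float  # normalised Hough accumulator peak in [0, 1]


@dataclass(frozen=True)
class OpticDisc:
    center: tuple[float, float]  # centroid (x, y)
    area: float  # px^2


@dataclass(frozen=True)
class DeviceProfile:
    name: str
    fov_fraction: float

    def __post_init__(self):
        if not 0.0 < self.fov_fraction <= 1.0:
            raise ValueError("fov_fraction must be in (0, 1]")


#: FOV radius as a fraction of the fundus-image boundary radius, per device.
DEVICE_PROFILES: dict[str, DeviceProfile] = {
    "iexaminer": DeviceProfile("iexaminer", 0.32),
    "deye": DeviceProfile("deye", 0.40),
    "peek": DeviceProfile("peek", 0.45),
    "inview": DeviceProfile("inview", 0.94),
}


@dataclass(frozen=True)
class MaskSpec:
    center: tuple[float, float]  # disc centre (x, y)
    radius: float  # exact: fov_fraction * boundary radius


def _to_gray(image: np.ndarray) -> np.ndarray:
    """Float grayscale in [0, 1] (mean over channels for RGB)."""
    img = np.asarray(image)
    if img.ndim == 3:
        img = img.mean(axis=2)
    if img.dtype == np.uint8:
        img = img / 255.0
    return img.astype(np.float64)


def _green_channel(image: np.ndarray) -> np.ndarray:
    img = np.asarray(image)
    if img.ndim == 3:
        img = img[..., 1]
    if img.dtype == np.uint8:
        img = img / 255.0
    return img.astype(np.float64)


def fit_boundary_circle(image: np.ndarray,
                        radius_range: tuple[float, float] | None = None,
                        score_floor: float = 0.25) -> BoundaryCircle:
    """Fit the retina boundary circle via Canny + circular Hough transform.

    The green channel carries the strongest retina/background contrast in
    fundus photographs, so edges are taken there.  The search covers radii
    in ``radius_range`` (default ``[0.25, 0.6] x min(H, W)``) with a coarse
    pass (step 2 px) refined to 1 px around the best candidate.  Ties are
    broken by larger accumulator score, then larger radius.

    Raises
    ------
    BoundaryNotFound
        If no edges exist or no circle reaches ``score_floor``.
    """
    g = _green_channel(image)
    if g.size == 0:
        raise BoundaryNotFound("empty image")
    edges = feature.canny(g, sigma=2.0)
    if not edges.any():
        raise BoundaryNotFound("no edges detected")
    m = min(g.shape)
    if radius_range is None:
        radius_range = (0.25 * m, 0.6 * m)
    lo, hi = (int(np.floor(radius_range[0])), int(np.ceil(radius_range[1])))
    lo = max(lo, 3)

    def _best(radii: np.ndarray):
        h = transform.hough_circle(edges, radii)
        accums, cxs, cys, rads = transform.hough_circle_peaks(
            h, radii, total_num_peaks=5)
        if len(accums) == 0:
            return None
        order = np.lexsort((rads, accums))  # ascending; take last: score then radius
        i = order[-1]
        return float(accums[i]), float(cxs[i]), float(cys[i]), float(rads[i])

    coarse = _best(np.arange(lo, hi + 1, 2))
    if coarse is None:
        raise BoundaryNotFound("no circle candidates")
    _, _, _, r0 = coarse
    fine = _best(np.arange(max(lo, int(r0) - 2), min(hi, int(r0) + 2) + 1))
    score, cx, cy, r = fine if fine is not None else coarse
    if score < score_floor:
        raise BoundaryNotFound(f"best circle score {score:.3f} < floor {score_floor}")
    return BoundaryCircle(center=(cx, cy), radius=r, score=score)


def detect_optic_disc(image: np.ndarray, boundary: BoundaryCircle,
                      quantile: float = 0.99,
                      min_area: float = 20.0,
                      max_area_fraction: float = 0.2,
                      smooth_sigma: float = 2.0) -> OpticDisc:
    """Locate the optic disc as the brightest compact region in the retina.

    The grayscale image is Gaussian-smoothed (``smooth_sigma``) so pixel
    noise cannot fragment the bright plateau; pixels strictly above the
    ``quantile`` intensity quantile inside the boundary circle are kept,
    cleaned by morphological opening then closing (disk structuring element
    scaled with the boundary radius), and the largest connected component's
    centroid and area are returned.

    Raises
    ------
    DiscNotFound
        If nothing survives thresholding, the largest component is smaller
        than ``min_area`` px^2, or it covers more than ``max_area_fraction``
        of the boundary circle (no compact bright region).
    """
    g = _to_gray(image)
    if smooth_sigma > 0:
        g = ndimage.gaussian_filter(g, smooth_sigma)
    h, w = g.shape
    yy, xx = np.mgrid[0:h, 0:w]
    cx, cy = boundary.center
    inside = (xx - cx) ** 2 + (yy - cy) ** 2 < boundary.radius ** 2
    if not inside.any():
        raise DiscNotFound("boundary circle does not intersect the image")
    thr = np.quantile(g[inside], quantile)
    bright = inside & (g > thr)  # strict: a constant region selects nothing
    se_r = max(1, int(round(3 * boundary.radius / 300.0)))
    se = morphology.disk(se_r)
    bright = morphology.closing(morphology.opening(bright, se), se)
    if not bright.any():
        raise DiscNotFound("no pixels above the intensity threshold")
    labels, n = ndimage.label(bright)
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    best = int(np.argmax(sizes)) + 1
    area = float(sizes[best - 1])
    if area < min_area:
        raise DiscNotFound(f"largest bright component {area:.0f} px^2 < {min_area}")
    if area > max_area_fraction * np.pi * boundary.radius ** 2:
        raise DiscNotFound("bright region is not compact")
    cy_c, cx_c = ndimage.center_of_mass(bright, labels, best)
    return OpticDisc(center=(float(cx_c), float(cy_c)), area=area)


def make_device_mask(boundary: BoundaryCircle, disc: OpticDisc,
                     device: DeviceProfile) -> MaskSpec:
    """Circular FOV mask: centred on the optic disc, radius
    ``device.fov_fraction x boundary.radius`` (exact; rounded only at
    rasterization)."""
    return MaskSpec(center=disc.center,
                    radius=device.fov_fraction * boundary.radius)


def apply_mask_and_crop(image: np.ndarray, mask: MaskSpec) -> np.ndarray:
    """Apply the circular mask and crop to its square bounding box.

    The output is a ``(2r+1) x (2r+1)`` square (r = mask radius rounded to
    the nearest pixel) centred on the mask centre; pixels farther than
    ``r + 0.5`` from the centre are zero, and regions falling outside the
    source frame are zero-padded, so the output is always square.
    """
    img = np.asarray(image)
    if mask.radius <= 0:
        raise ValueError("mask radius must be positive")
    h, w = img.shape[:2]
    mx, my = mask.center
    if not (0 <= mx < w and 0 <= my < h):
        raise ValueError("mask center lies outside the image")
    r = int(round(mask.radius))
    cx, cy = int(round(mx)), int(round(my))
    side = 2 * r + 1
    shape = (side, side) + img.shape[2:]
    out = np.zeros(shape, dtype=img.dtype)
    # overlap of the square window with the source frame
    x0, x1 = cx - r, cx + r + 1
    y0, y1 = cy - r, cy + r + 1
    sx0, sy0 = max(x0, 0), max(y0, 0)
    sx1, sy1 = min(x1, w), min(y1, h)
    out[sy0 - y0:sy1 - y0, sx0 - x0:sx1 - x0] = img[sy0:sy1, sx0:sx1]
    yy, xx = np.mgrid[0:side, 0:side]
    keep = (xx - r) ** 2 + (yy - r) ** 2 < (r + 0.5) ** 2
    out[~keep] = 0
    return out


def preprocess_for_classifier(image: np.ndarray, side: int = 227) -> np.ndarray:
    """Square-crop and down-sample an image to the classifier input size.

    Landscape inputs are cropped symmetrically from the left and right to a
    square (the extra pixel of an odd margin is removed from the right);
    portrait inputs are cropped top/bottom (extra pixel from the bottom).
    The square is then resized to ``side x side x 3`` with bilinear
    anti-aliased interpolation.  An input already at the target size is
    returned unchanged, making the operation idempotent.
    """
    img = np.asarray(image)
    if img.ndim == 2:
        img = np.stack([img] * 3, axis=-1)
    h, w = img.shape[:2]
    if (h, w) == (side, side):
        return img
    if w > h:
        left = (w - h) // 2
        img = img[:, left:left + h]
    elif h > w:
        top = (h - w) // 2
        img = img[top:top + w, :]
    resized = transform.resize(img, (side, side), order=1, anti_aliasing=True,
                               preserve_range=False)
    return img_as_ubyte(np.clip(resized, 0.0, 1.0))
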