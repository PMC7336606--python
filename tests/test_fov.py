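import numpy as np
import pytest
from skimage import feature

from fundusfov.fov import (DEVICE_PROFILES, BoundaryCircle, BoundaryNotFound,
                           DeviceProfile, DiscNotFound, MaskSpec,
                           apply_mask_and_crop, detect_optic_disc,
                           fit_boundary_circle, make_device_mask,
                           preprocess_for_classifier)
from fundusfov.phantom import PhantomConfig, generate_phantom


def brute_force_circle(image, center_hint, radius_hint, window=4):
    """Oracle: grid search over (cx, cy, r) maximising the fraction of the
    circle's perimeter covered by Canny edge pixels of the same image."""
    g = image[..., 1] / 255.0
    edges = feature.canny(g, sigma=2.0)
    ey, ex = np.nonzero(edges)
    best, best_cov = None, -1.0
    cx0, cy0 = center_hint
    theta = np.linspace(0, 2 * np.pi, 360, endpoint=False)
    for cx in range(int(cx0) - window, int(cx0) + window + 1):
        for cy in range(int(cy0) - window, int(cy0) + window + 1):
            for r in range(int(radius_hint) - window, int(radius_hint) + window + 1):
                px = cx + r * np.cos(theta)
                py = cy + r * np.sin(theta)
                ok = (px >= 0) & (px < image.shape[1]) & (py >= 0) & (py < image.shape[0])
                if not ok.any():
                    continue
                d2 = (ex[None, :] - px[ok, None]) ** 2 + (ey[None, :] - py[ok, None]) ** 2
                cov = (d2.min(axis=1) <= 2.0).mean()
                if cov > best_cov:
                    best_cov, best = cov, (cx, cy, r)
    return best


def test_boundary_fit_matches_brute_force_oracle():
    cfg = PhantomConfig(image_width=200, image_height=200,
                        boundary_center=(100.0, 100.0), boundary_radius=80.0,
                        disc_offset=(36.0, -8.0), disc_radius=9.0,
                        noise_sd=0.0)
    img, truth = generate_phantom(cfg, 0, seed=3)
    fit = fit_boundary_circle(img)
    oracle = brute_force_circle(img, truth.boundary_center,
                                truth.boundary_radius)
    assert abs(fit.center[0] - oracle[0]) <= 2
    assert abs(fit.center[1] - oracle[1]) <= 2
    assert abs(fit.radius - oracle[2]) <= 2
    # and the oracle itself recovers the generator truth
    assert abs(fit.center[0] - truth.boundary_center[0]) <= 2
    assert abs(fit.center[1] - truth.boundary_center[1]) <= 2
    assert abs(fit.radius - truth.boundary_radius) <= 2


def test_all_black_image_raises():
    with pytest.raises(BoundaryNotFound):
        fit_boundary_circle(np.zeros((120, 120, 3), dtype=np.uint8))


def test_truncated_boundary_recovered():
    """A boundary circle overhanging the left image edge is still fitted
    from the visible arc (radius within 3 px)."""
    h, w, r_true = 200, 200, 80
    yy, xx = np.mgrid[0:h, 0:w]
    cx, cy = 30.0, 100.0  # circle sticks out of the left edge
    img = np.zeros((h, w, 3), dtype=np.uint8)
    inside = (xx - cx) ** 2 + (yy - cy) ** 2 < r_true ** 2
    img[inside] = (110, 60, 25)
    fit = fit_boundary_circle(img)
    assert abs(fit.radius - r_true) <= 3
    assert abs(fit.center[1] - cy) <= 3


def test_disc_detection_close_to_smoothed_argmax(dr_phantom):
    from scipy import ndimage
    img, truth = dr_phantom
    boundary = BoundaryCircle(center=truth.boundary_center,
                              radius=truth.boundary_radius, score=1.0)
    disc = detect_optic_disc(img, boundary)
    # independent oracle: argmax of the Gaussian-smoothed intensity
    g = ndimage.gaussian_filter(img.mean(axis=2), 3.0)
    yy, xx = np.mgrid[0:g.shape[0], 0:g.shape[1]]
    bx, by = boundary.center
    g[(xx - bx) ** 2 + (yy - by) ** 2 >= boundary.radius ** 2] = 0
    iy, ix = np.unravel_index(np.argmax(g), g.shape)
    assert np.hypot(disc.center[0] - ix, disc.center[1] - iy) <= 3
    assert np.hypot(disc.center[0] - truth.disc_center[0],
                    disc.center[1] - truth.disc_center[1]) <= 3


def test_uniform_retina_has_no_disc():
    h = w = 160
    yy, xx = np.mgrid[0:h, 0:w]
    img = np.zeros((h, w, 3), dtype=np.uint8)
    inside = (xx - 80) ** 2 + (yy - 80) ** 2 < 70 ** 2
    img[inside] = (115, 63, 25)
    boundary = BoundaryCircle(center=(80.0, 80.0), radius=70.0, score=1.0)
    with pytest.raises(DiscNotFound):
        detect_optic_disc(img, boundary)


def test_largest_bright_component_wins():
    h = w = 240
    img = np.full((h, w, 3), 60, dtype=np.uint8)
    img[40:60, 40:60] = 230   # 400 px^2
    img[180:188, 180:188] = 230  # 64 px^2
    boundary = BoundaryCircle(center=(120.0, 120.0), radius=115.0, score=1.0)
    disc = detect_optic_disc(img, boundary)
    assert disc.center == pytest.approx((49.5, 49.5), abs=1.0)
    assert disc.area == pytest.approx(400, rel=0.15)


@pytest.mark.parametrize("name,frac,radius,expected", [
    ("iexaminer", 0.32, 100.0, 32.0),
    ("inview", 0.94, 500.0, 470.0),
])
def test_device_mask_radius(name, frac, radius, expected):
    boundary = BoundaryCircle(center=(0.0, 0.0), radius=radius, score=1.0)
    disc_center = (10.0, 5.0)
    from fundusfov.fov import OpticDisc
    disc = OpticDisc(center=disc_center, area=300.0)
    profile = DEVICE_PROFILES[name]
    assert profile.fov_fraction == frac
    mask = make_device_mask(boundary, disc, profile)
    assert mask.radius == expected
    assert mask.center == disc_center


def test_full_fov_mask_is_identity_radius():
    from fundusfov.fov import OpticDisc
    boundary = BoundaryCircle(center=(0.0, 0.0), radius=97.0, score=1.0)
    disc = OpticDisc(center=(5.0, 5.0), area=100.0)
    mask = make_device_mask(boundary, disc, DeviceProfile("full", 1.0))
    assert mask.radius == boundary.radius


def test_mask_linearity():
    from fundusfov.fov import OpticDisc
    boundary = BoundaryCircle(center=(0.0, 0.0), radius=123.0, score=1.0)
    disc = OpticDisc(center=(3.0, 4.0), area=50.0)
    fracs = np.linspace(0.1, 1.0, 10)
    radii = [make_device_mask(boundary, disc, DeviceProfile("d", f)).radius
             for f in fracs]
    assert np.allclose(radii, fracs * boundary.radius)


def test_mask_and_crop_geometry(dr_phantom):
    img, _ = dr_phantom
    mask = MaskSpec(center=(110.0, 110.0), radius=32.0)
    out = apply_mask_and_crop(img, mask)
    assert out.shape == (65, 65, 3)
    r = 32
    yy, xx = np.mgrid[0:65, 0:65]
    outside = (xx - r) ** 2 + (yy - r) ** 2 >= (r + 0.5) ** 2
    assert (out[outside] == 0).all()


def test_mask_overhanging_edge_is_padded(dr_phantom):
    img, _ = dr_phantom
    w = img.shape[1]
    mask = MaskSpec(center=(w - 5.0, 110.0), radius=40.0)
    out = apply_mask_and_crop(img, mask)
    assert out.shape == (81, 81, 3)
    # the overhang beyond the right edge of the source is zero
    assert (out[:, -30:] == 0).all()


def test_mask_center_outside_rejected(dr_phantom):
    img, _ = dr_phantom
    with pytest.raises(ValueError):
        apply_mask_and_crop(img, MaskSpec(center=(500.0, 10.0), radius=20.0))


def test_lesion_retention_monotone_in_fov(default_config):
    """Fraction of truth lesions inside a disc-centred mask is
    non-decreasing in the FOV fraction, reaching 1 once the mask covers the
    whole boundary circle."""
    _, truth = generate_phantom(default_config, 4, seed=21)
    dx, dy = truth.disc_center
    dists = np.array([np.hypot(l.x - dx, l.y - dy) for l in truth.lesions])
    fracs = [0.32, 0.40, 0.45, 0.94, 1.0, 1.5]
    retention = [(dists < f * truth.boundary_radius).mean() for f in fracs]
    assert all(a <= b + 1e-12 for a, b in zip(retention, retention[1:]))
    # mask covering the full boundary from the disc centre keeps everything
    cover = (np.hypot(dx - truth.boundary_center[0],
                      dy - truth.boundary_center[1])
             + truth.boundary_radius) / truth.boundary_radius
    assert (dists < cover * truth.boundary_radius).mean() == 1.0


def test_preprocess_shapes_and_idempotence(dr_phantom):
    img, _ = dr_phantom
    rect = np.zeros((400, 500, 3), dtype=np.uint8)
    rect[:, :, 0] = np.linspace(0, 255, 500, dtype=np.uint8)[None, :]
    out = preprocess_for_classifier(rect)
    assert out.shape == (227, 227, 3)
    sq = preprocess_for_classifier(np.full((300, 300, 3), 90, dtype=np.uint8))
    assert sq.shape == (227, 227, 3)
    small = preprocess_for_classifier(img)
    assert small.shape == (227, 227, 3)
    assert np.array_equal(preprocess_for_classifier(small), small)


def test_preprocess_portrait_crops_top_bottom():
    img = np.zeros((500, 400, 3), dtype=np.uint8)
    img[50:450] = 200  # content in the middle band
    out = preprocess_for_classifier(img)
    assert out.shape == (227, 227, 3)
    assert out.mean() > 100  # the kept square is mostly content


def test_device_profile_validation():
    with pytest.raises(ValueError):
        DeviceProfile("bad", 0.0)
    with pytest.raises(ValueError):
        DeviceProfile("bad", 1.5)
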