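"""Synthetic fundus phantoms with exact ground truth.

A phantom emulates the handful of properties of a real fundus photograph that
the FOV-simulation pipeline exploits: a bright roughly-circular retina on a
dark background, a single brightest compact region (the optic disc) offset
from the image centre, a darker vessel tree radiating from the disc, and —
for diseased eyes — small dark dots (microaneurysm-like) and bright blobs
(exudate-like) placed preferentially away from the disc.  Nothing else about
retinal texture is modelled: the generator's purpose is to make every
downstream stage testable against known truth, not photorealism.

Intensity model (before noise): background ~0.02, retinal base ~0.45 with a
mild illumination ramp, vessels darker, bright lesions ~0.75, optic disc
~0.95 and strictly the image maximum.  Pixel coordinates are 0-based,
x rightwards, y downwards; circle membership is strict Euclidean
distance < radius.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from PIL import Image

__all__ = [
    "PhantomConfig",
    "PhantomTruth",
    "Lesion",
    "generate_phantom",
    "generate_cohort",
    "save_cohort",
]

#: Chromatic tint applied to the scalar intensity field to produce the
#: reddish-orange cast of fundus photographs (per-channel gain on RGB).
_TINT = np.array([1.0, 0.55, 0.22])


@dataclass(frozen=True)
class PhantomConfig:
    """Geometry and intensity parameters of a synthetic fundus image.

    Defaults describe a 220x220 px image with a centred retina disc of
    radius 97 px, an optic disc offset to the right of centre, and lesions
    constrained to lie at least ``lesion_eccentricity_min`` boundary radii
    from the disc centre (DR lesions cluster away from the optic disc).
    """

    image_width: int = 220
    image_height: int = 220
    boundary_center: tuple[float, float] = (110.0, 110.0)
    boundary_radius: float = 97.0
    disc_offset: tuple[float, float] = (44.0, -10.0)
    disc_radius: float = 11.0
    disc_brightness: float = 0.95
    n_vessels: int = 7
    lesion_count_range: tuple[int, int] = (2, 8)
    lesion_eccentricity_min: float = 0.4
    noise_sd: float = 0.01
    illumination_gradient: float = 0.05

    def validate(self) -> None:
        cx, cy = self.boundary_center
        r = self.boundary_radius
        if r <= 0:
            raise ValueError("boundary_radius must be positive")
        if not (cx - r >= 0 and cx + r <= self.image_width
                and cy - r >= 0 and cy + r <= self.image_height):
            raise ValueError("boundary circle must fit inside the image")
        dx, dy = self.disc_offset
        if np.hypot(dx, dy) + self.disc_radius > r:
            raise ValueError("optic disc must lie inside the boundary circle")
        if not 0.0 <= self.lesion_eccentricity_min < 1.0:
            raise ValueError("lesion_eccentricity_min must be in [0, 1)")
        if not 0.0 < self.disc_brightness <= 1.0:
            raise ValueError("disc_brightness must be in (0, 1]")
        lo, hi = self.lesion_count_range
        if lo < 0 or hi < lo:
            raise ValueError("lesion_count_range must be 0 <= min <= max")

    @property
    def disc_center(self) -> tuple[float, float]:
        return (self.boundary_center[0] + self.disc_offset[0],
                self.boundary_center[1] + self.disc_offset[1])


@dataclass(frozen=True)
class Lesion:
    x: float
    y: float
    kind: str  # "dark_dot" | "bright_blob"


@dataclass
class PhantomTruth:
    """Ground truth for one rendered phantom."""

    boundary_center: tuple[float, float]
    boundary_radius: float
    disc_center: tuple[float, float]
    disc_radius: float
    lesions: list[Lesion] = field(default_factory=list)
    grade: int = 0

    @property
    def dr_label(self) -> int:
        """Binary DR label: 1 for any grade above 0."""
        return int(self.grade > 0)

    def to_record(self, file: str | None = None) -> dict:
        rec = {
            "boundary": {"cx": self.boundary_center[0],
                         "cy": self.boundary_center[1],
                         "r": self.boundary_radius},
            "disc": {"cx": self.disc_center[0], "cy": self.disc_center[1],
                     "r": self.disc_radius},
            "lesions": [asdict(l) for l in self.lesions],
            "grade": self.grade,
        }
        if file is not None:
            rec = {"file": file, **rec}
        return rec


def _lesion_count(config: PhantomConfig, grade: int,
                  rng: np.random.Generator) -> int:
    """Number of lesions for a grade: 0 for grade 0, otherwise a draw from
    the configured range whose lower bound rises with severity (grades 3-4
    always get at least one lesion; grades 1-2 get at least one as well so
    the binary label is renderable)."""
    if grade == 0:
        return 0
    lo, hi = config.lesion_count_range
    lo = max(1, lo)
    hi = max(lo, hi)
    # shift the admissible window upwards with severity
    span = hi - lo
    lo_g = lo + int(round(span * (grade - 1) / 4))
    return int(rng.integers(lo_g, hi + 1))


def _sample_lesion_positions(config: PhantomConfig, n: int,
                             rng: np.random.Generator) -> list[tuple[float, float]]:
    """Rejection-sample lesion centres: inside 0.92x the boundary circle and
    at least lesion_eccentricity_min * boundary_radius from the disc centre."""
    bx, by = config.boundary_center
    dx, dy = config.disc_center
    r = config.boundary_radius
    min_d = config.lesion_eccentricity_min * r
    out: list[tuple[float, float]] = []
    while len(out) < n:
        u = rng.uniform(-1.0, 1.0, size=2)
        x, y = bx + u[0] * r * 0.92, by + u[1] * r * 0.92
        if np.hypot(x - bx, y - by) >= r * 0.92:
            continue
        if np.hypot(x - dx, y - dy) < min_d:
            continue
        out.append((float(x), float(y)))
    return out


def _render(config: PhantomConfig, truth: PhantomTruth,
            rng: np.random.Generator) -> np.ndarray:
    """Rasterize a phantom as float RGB in [0, 1]."""
    h, w = config.image_height, config.image_width
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    bx, by = config.boundary_center
    r = config.boundary_radius
    d2 = (xx - bx) ** 2 + (yy - by) ** 2
    inside = d2 < r ** 2  # strict membership

    base = np.full((h, w), 0.02)
    # illumination ramp across the retina, normalised by the radius
    ramp = 1.0 + config.illumination_gradient * (xx - bx) / r
    base[inside] = (0.45 * ramp)[inside]

    # vessel tree: seeded random walks from the disc centre, drawn darker
    dcx, dcy = config.disc_center
    for _ in range(config.n_vessels):
        ang = rng.uniform(0, 2 * np.pi)
        x, y = dcx, dcy
        width = rng.uniform(1.0, 2.0)
        for _ in range(int(2.2 * r)):
            ang += rng.normal(0.0, 0.12)
            x += np.cos(ang)
            y += np.sin(ang)
            if (x - bx) ** 2 + (y - by) ** 2 >= (0.97 * r) ** 2:
                break
            ix, iy = int(round(x)), int(round(y))
            half = int(np.ceil(width))
            y0, y1 = max(0, iy - half), min(h, iy + half + 1)
            x0, x1 = max(0, ix - half), min(w, ix + half + 1)
            patch = base[y0:y1, x0:x1]
            base[y0:y1, x0:x1] = np.minimum(patch, 0.25)

    # lesions
    for les in truth.lesions:
        if les.kind == "dark_dot":
            rad, val = rng.uniform(2.0, 3.2), 0.12
            dd2 = (xx - les.x) ** 2 + (yy - les.y) ** 2
            sel = dd2 < rad ** 2
            base[sel] = val
        else:  # bright_blob: smooth gaussian bump capped below the disc
            rad = rng.uniform(3.0, 5.0)
            dd2 = (xx - les.x) ** 2 + (yy - les.y) ** 2
            bump = 0.75 * np.exp(-dd2 / (2 * (rad / 1.5) ** 2))
            base = np.maximum(base, np.where(inside, bump, base))

    # optic disc: brightest compact region, plateau core with gaussian skirt
    dd2 = (xx - dcx) ** 2 + (yy - dcy) ** 2
    disc_core = dd2 < config.disc_radius ** 2
    skirt = config.disc_brightness * np.exp(-dd2 / (2 * (config.disc_radius / 1.2) ** 2))
    base = np.maximum(base, np.where(inside, np.minimum(skirt, config.disc_brightness), base))
    base[disc_core & inside] = config.disc_brightness

    if config.noise_sd > 0:
        base = base + rng.normal(0.0, config.noise_sd, size=base.shape)
    # noise must not beat the disc plateau: clip non-disc pixels just below it
    base = np.clip(base, 0.0, config.disc_brightness)

    rgb = base[..., None] * _TINT[None, None, :]
    return np.clip(rgb, 0.0, 1.0)


def generate_phantom(config: PhantomConfig, grade: int,
                     seed: int) -> tuple[np.ndarray, PhantomTruth]:
    """Render one phantom.

    Parameters
    ----------
    config : PhantomConfig
        Geometry/intensity parameters; validated before rendering.
    grade : int
        DR severity grade 0-4 (0 = no DR; lesions appear for grade >= 1).
    seed : int
        Seed for all randomness; identical (config, grade, seed) gives
        bitwise-identical images.

    Returns
    -------
    (image, truth)
        ``image`` is a uint8 RGB array of shape (H, W, 3); ``truth``
        describes the rendered geometry exactly.
    """
    config.validate()
    if grade not in (0, 1, 2, 3, 4):
        raise ValueError(f"grade must be an integer 0-4, got {grade!r}")
    rng = np.random.default_rng(seed)
    n_lesions = _lesion_count(config, grade, rng)
    positions = _sample_lesion_positions(config, n_lesions, rng)
    kinds = rng.choice(["dark_dot", "bright_blob"], size=n_lesions)
    lesions = [Lesion(x, y, str(k)) for (x, y), k in zip(positions, kinds)]
    truth = PhantomTruth(
        boundary_center=config.boundary_center,
        boundary_radius=config.boundary_radius,
        disc_center=config.disc_center,
        disc_radius=config.disc_radius,
        lesions=lesions,
        grade=grade,
    )
    img = _render(config, truth, rng)
    return (img * 255.0 + 0.5).astype(np.uint8), truth


def generate_cohort(config: PhantomConfig, grade_counts,
                    seed: int) -> list[tuple[np.ndarray, PhantomTruth]]:
    """Render a cohort with exact per-grade counts.

    ``grade_counts`` is a 5-vector (counts for grades 0..4).  Per-image seeds
    are derived deterministically from the cohort seed via a SeedSequence
    spawn, so cohorts are reproducible and images independent.
    """
    counts = [int(c) for c in grade_counts]
    if len(counts) != 5 or any(c < 0 for c in counts):
        raise ValueError("grade_counts must be 5 non-negative counts")
    grades = [g for g, c in enumerate(counts) for _ in range(c)]
    seeds = np.random.SeedSequence(seed).generate_state(max(len(grades), 1))
    out = []
    for i, g in enumerate(grades):
        out.append(generate_phantom(config, g, int(seeds[i] % (2 ** 31))))
    return out


def save_cohort(cohort, out_dir: str | Path, prefix: str = "phantom") -> Path:
    """Write a cohort as 8-bit RGB PNGs plus a JSON truth manifest.

    Returns the path of the truth file (``truth.json`` in ``out_dir``).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    records = []
    for i, (img, truth) in enumerate(cohort):
        name = f"{prefix}_{i:05d}.png"
        Image.fromarray(img, mode="RGB").save(out_dir / name)
        records.append(truth.to_record(file=name))
    truth_path = out_dir / "truth.json"
    truth_path.write_text(json.dumps(records, indent=1))
    return truth_path
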