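"""Synthetic EM-like sarcomere scenes with exact paired ground truth.

Real training data for the segmenters are micrographs of ultrathin muscle
sections with a repeating band pattern (A band, I band, Z disks/mitochondria,
SR, and intermyofibrillar "near-SR" cytosol) and dark, roughly circular
glycogen granules of 15–40 nm whose density depends on the region.  This
module emulates those features — banded background intensities, region-
dependent granule coverage, Gaussian granule diameters — at a level of
realism sufficient to train and test the pipeline, with bit-exact ground
truth masks.  Photorealistic EM texture is an explicit non-goal.

The band period is compressed relative to a real sarcomere (~2 µm) so that a
small fixture crop shows several full periods.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .io_core import EMImage, SegMask
from .regions import REGION_NAMES, pixel_fraction

#: Background gray level per locations label (A darker than I; Z/mito darkest).
REGION_INTENSITY = {0: 100, 1: 140, 2: 190, 3: 70, 4: 115, 5: 165}
GRANULE_INTENSITY = 35


@dataclass
class SceneConfig:
    """Parameters of one synthetic scene.

    ``band_fractions`` gives the fractional widths of the A band, I band, and
    Z/mito stripe within one period; the remainder is split evenly between two
    SR and two near-SR stripes flanking the A band.  ``region_granule_vf``
    maps a locations label (1–5) to the target areal granule fraction in that
    region.
    """

    size_px: int = 256
    pixel_nm: float = 0.8
    sarcomere_period_nm: float = 120.0
    band_fractions: tuple[float, float, float] = (0.40, 0.28, 0.06)
    region_granule_vf: dict[int, float] = field(
        default_factory=lambda: {1: 0.005, 2: 0.02, 3: 0.002, 4: 0.01, 5: 0.04}
    )
    diameter_mean_nm: float = 25.0
    diameter_sd_nm: float = 5.0
    min_diameter_nm: float = 5.0
    noise_sd: float = 8.0
    rotation_deg: float = 0.0
    seed: int = 0

    def __post_init__(self):
        fa, fi, fz = self.band_fractions
        if min(fa, fi, fz) <= 0 or fa + fi + fz > 1:
            raise ValueError("band fractions must be positive and sum to <= 1")
        for lab, f in self.region_granule_vf.items():
            if lab not in REGION_NAMES:
                raise ValueError(f"unknown region label {lab}")
            if not 0 <= f <= 0.5:
                raise ValueError(f"areal fraction {f} for label {lab} outside [0, 0.5]")
        if self.diameter_sd_nm < 0:
            raise ValueError("diameter_sd_nm must be >= 0")


def _locations_labels(cfg: SceneConfig) -> np.ndarray:
    """Analytic band layout: stripes perpendicular to the (rotated) fiber axis.

    One period is ordered A | SR | near-SR | I/2 | Z | I/2 | near-SR | SR.
    """
    fa, fi, fz = cfg.band_fractions
    rem = 1.0 - fa - fi - fz
    fsr = rem / 4.0
    fnsr = rem / 4.0
    # cumulative boundaries of the 8 stripes within one unit period
    widths = [fa, fsr, fnsr, fi / 2, fz, fi / 2, fnsr, fsr]
    labels_seq = [1, 4, 5, 2, 3, 2, 5, 4]
    bounds = np.cumsum(widths)

    period_px = cfg.sarcomere_period_nm / cfg.pixel_nm
    theta = np.deg2rad(cfg.rotation_deg)
    rr, cc = np.mgrid[0 : cfg.size_px, 0 : cfg.size_px]
    axial = (np.cos(theta) * cc + np.sin(theta) * rr) / period_px
    phase = np.mod(axial, 1.0)

    out = np.empty((cfg.size_px, cfg.size_px), dtype=np.uint8)
    lo = 0.0
    for hi, lab in zip(bounds, labels_seq):
        out[(phase >= lo) & (phase < hi)] = lab
        lo = hi
    out[phase >= bounds[-1]] = labels_seq[-1]  # guard against rounding
    return out


def _truncnorm(mean: float, sd: float, lower: float):
    if sd == 0:
        return None
    a = (lower - mean) / sd
    return stats.truncnorm(a, np.inf, loc=mean, scale=sd)


def _paint_disk(mask: np.ndarray, cy: float, cx: float, radius_px: float) -> None:
    h, w = mask.shape
    r0 = max(int(np.floor(cy - radius_px)) - 1, 0)
    r1 = min(int(np.ceil(cy + radius_px)) + 2, h)
    c0 = max(int(np.floor(cx - radius_px)) - 1, 0)
    c1 = min(int(np.ceil(cx + radius_px)) + 2, w)
    if r0 >= r1 or c0 >= c1:
        return
    yy, xx = np.ogrid[r0:r1, c0:c1]
    inside = (yy + 0.5 - cy) ** 2 + (xx + 0.5 - cx) ** 2 <= radius_px**2
    mask[r0:r1, c0:c1][inside] = 1


def generate_scene(cfg: SceneConfig) -> tuple[EMImage, SegMask, SegMask]:
    """Generate one co-registered (image, locations mask, granules mask) triple.

    Granule centers are uniform within their region, overlap allowed; disks are
    added until the region's measured areal coverage reaches its target.  The
    same seed always yields a bit-identical triple.
    """
    rng = np.random.default_rng(cfg.seed)
    loc = _locations_labels(cfg)
    gran = np.zeros_like(loc)

    dist = _truncnorm(cfg.diameter_mean_nm, cfg.diameter_sd_nm, cfg.min_diameter_nm)
    # a sub-pixel disk still consumes an attempt, so floor the area at 1 px
    mean_disk_px = max(np.pi * (cfg.diameter_mean_nm / 2 / cfg.pixel_nm) ** 2, 1.0)

    for lab in sorted(cfg.region_granule_vf):
        target = cfg.region_granule_vf[lab]
        if target == 0:
            continue
        region = loc == lab
        n_region = int(region.sum())
        if n_region == 0:
            continue
        rows, cols = np.nonzero(region)
        max_attempts = int(20 * target * n_region / mean_disk_px) + 200
        attempts = 0
        # place disks in batches sized from the Boolean-coverage deficit, so
        # the O(region) coverage measurement runs only a handful of times
        while True:
            coverage = gran[region].sum() / n_region
            if coverage >= target:
                break
            if attempts >= max_attempts:
                raise RuntimeError(
                    f"areal fraction {target} unreachable for region {lab} "
                    f"within {max_attempts} placement attempts"
                )
            deficit = -np.log1p(-(target - coverage))
            batch = max(1, int(0.8 * deficit * n_region / mean_disk_px))
            batch = min(batch, max_attempts - attempts)
            for _ in range(batch):
                k = rng.integers(len(rows))
                cy = rows[k] + rng.random()
                cx = cols[k] + rng.random()
                if dist is None:
                    d_nm = cfg.diameter_mean_nm
                else:
                    d_nm = float(dist.ppf(rng.random()))
                _paint_disk(gran, cy, cx, d_nm / 2 / cfg.pixel_nm)
            attempts += batch

    background = np.empty(loc.shape, dtype=np.float64)
    for lab, level in REGION_INTENSITY.items():
        background[loc == lab] = level
    background[gran == 1] = GRANULE_INTENSITY
    noisy = background + rng.normal(0.0, cfg.noise_sd, size=loc.shape)
    pixels = np.clip(np.rint(noisy), 0, 255).astype(np.uint8)

    image = EMImage(pixels, cfg.pixel_nm, source_id=f"scene-{cfg.seed}")
    return (
        image,
        SegMask(loc, cfg.pixel_nm, "locations"),
        SegMask(gran, cfg.pixel_nm, "granules"),
    )


def scene_truth_pf(locations: SegMask, granules: SegMask) -> dict[str, float]:
    """Ground-truth pixel fractions per region (shared oracle with the pipeline)."""
    return pixel_fraction(locations, granules).pf


def isolated_granule_mask(
    n: int,
    diameter_mean_nm: float = 25.0,
    diameter_sd_nm: float = 5.0,
    pixel_nm: float = 0.8,
    min_diameter_nm: float = 5.0,
    seed: int = 0,
) -> tuple[SegMask, np.ndarray]:
    """A granules mask of ``n`` guaranteed non-touching disks on a jittered grid.

    Returns the mask and the array of true (continuous) diameters in nm; used
    to validate morphometric diameter recovery without merged silhouettes.
    """
    rng = np.random.default_rng(seed)
    dist = _truncnorm(diameter_mean_nm, diameter_sd_nm, min_diameter_nm)
    cell_px = int(np.ceil((diameter_mean_nm + 5 * diameter_sd_nm) / pixel_nm)) + 6
    side = int(np.ceil(np.sqrt(n)))
    mask = np.zeros((side * cell_px, side * cell_px), dtype=np.uint8)
    diameters = np.empty(n)
    for i in range(n):
        gy, gx = divmod(i, side)
        d_nm = diameter_mean_nm if dist is None else float(dist.ppf(rng.random()))
        diameters[i] = d_nm
        jitter = cell_px / 2 - d_nm / 2 / pixel_nm - 2
        jy = rng.uniform(-1, 1) * max(jitter, 0)
        jx = rng.uniform(-1, 1) * max(jitter, 0)
        _paint_disk(mask, gy * cell_px + cell_px / 2 + jy, gx * cell_px + cell_px / 2 + jx, d_nm / 2 / pixel_nm)
    return SegMask(mask, pixel_nm, "granules"), diameters
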