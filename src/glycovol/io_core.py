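"""Image and label-mask I/O, standardization, and sample metadata.

EM micrographs arrive as square 8-bit grayscale rasters digitized anywhere in
the 0.4–1.4 nm/pixel range; the pipeline standardizes every image to
1,024 × 1,024 pixels at a nominal 0.8 nm pitch before segmentation.  Label
masks are single-channel 8-bit PNGs: the *locations* scheme uses labels 0–5
(0 unclassified, 1 A band, 2 I band, 3 mitochondria/Z disk, 4 SR, 5 near-SR
intermyofibrillar cytosol) and the *granules* scheme uses 0/1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
from skimage.transform import resize

STANDARD_SIZE = 1024
STANDARD_PIXEL_NM = 0.8
SUPPORTED_PIXEL_NM = (0.4, 1.4)

#: Permitted label sets per mask scheme.
SCHEME_LABELS = {
    "locations": frozenset(range(6)),
    "granules": frozenset((0, 1)),
}


class MaskValidationError(ValueError):
    """Raised when a mask holds labels outside its scheme's permitted set."""


@dataclass
class EMImage:
    """A 2-D 8-bit grayscale electron micrograph with physical pixel pitch."""

    pixels: np.ndarray
    pixel_nm: float
    source_id: str = ""

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError(f"expected a 2-D raster, got ndim={self.pixels.ndim}")
        if min(self.pixels.shape) < 64:
            raise ValueError(f"image sides must be >= 64 px, got {self.pixels.shape}")
        if not self.pixel_nm > 0:
            raise ValueError(f"pixel_nm must be positive, got {self.pixel_nm}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class SegMask:
    """An integer label raster paired with an :class:`EMImage`.

    ``scheme`` is ``"locations"`` (labels 0–5) or ``"granules"`` (labels 0/1).
    """

    labels: np.ndarray
    pixel_nm: float
    scheme: str

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError(f"expected a 2-D raster, got ndim={self.labels.ndim}")
        if self.scheme not in SCHEME_LABELS:
            raise ValueError(f"unknown scheme {self.scheme!r}")
        validate_labels(self.labels, self.scheme)

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape


def validate_labels(labels: np.ndarray, scheme: str) -> None:
    allowed = SCHEME_LABELS[scheme]
    present = set(np.unique(labels).tolist())
    bad = sorted(present - allowed)
    if bad:
        raise MaskValidationError(
            f"labels {bad} are not permitted in scheme {scheme!r} (allowed: {sorted(allowed)})"
        )


@dataclass
class SampleMeta:
    """Per-subject metadata: diagnosis and clinical index on a 0–10 scale."""

    subject_id: str
    diagnosis: str
    clinical_index: float
    image_ids: list[str] = field(default_factory=list)

    def __post_init__(self):
        if self.diagnosis not in ("MHN", "MHS"):
            raise ValueError(f"diagnosis must be MHN or MHS, got {self.diagnosis!r}")
        if not 0.0 <= self.clinical_index <= 10.0:
            raise ValueError(f"clinical_index must lie in [0, 10], got {self.clinical_index}")


def _read_gray8(path: str | Path) -> np.ndarray:
    arr = iio.imread(Path(path))
    if arr.ndim == 3:
        # reject true color; tolerate a redundant single channel
        if arr.shape[2] == 1:
            arr = arr[:, :, 0]
        else:
            raise ValueError(f"{path}: expected a single-channel raster, got shape {arr.shape}")
    if arr.dtype != np.uint8:
        raise ValueError(f"{path}: expected 8-bit data, got {arr.dtype}")
    return arr


def read_image(path: str | Path, pixel_nm: float, source_id: str | None = None) -> EMImage:
    """Read an 8-bit grayscale PNG as an :class:`EMImage`."""
    arr = _read_gray8(path)
    return EMImage(arr, pixel_nm=pixel_nm, source_id=source_id or Path(path).stem)


def write_image(image: EMImage, path: str | Path) -> None:
    iio.imwrite(Path(path), image.pixels.astype(np.uint8), extension=".png")


def read_mask(path: str | Path, scheme: str, pixel_nm: float = STANDARD_PIXEL_NM) -> SegMask:
    """Read a single-channel 8-bit PNG as a validated :class:`SegMask`.

    Raises :class:`MaskValidationError` naming the offending labels when the
    file holds values outside the scheme's permitted set.
    """
    arr = _read_gray8(path)
    return SegMask(arr, pixel_nm=pixel_nm, scheme=scheme)


def write_mask(mask: SegMask, path: str | Path) -> None:
    """Write a mask as a single-channel 8-bit PNG; inverse of :func:`read_mask`."""
    iio.imwrite(Path(path), mask.labels.astype(np.uint8), extension=".png")


def recast_standard(image: EMImage) -> EMImage:
    """Recast a square micrograph to 1,024 × 1,024 pixels at 0.8 nm nominal pitch.

    Grayscale intensities are resampled bilinearly (with anti-alias low-pass
    filtering when downsampling); the true post-recast pixel pitch is stored so
    that area computations never assume the nominal 0.8 nm exactly.
    """
    h, w = image.shape
    if h != w:
        raise ValueError(f"recast_standard requires a square input, got {image.shape}")
    lo, hi = SUPPORTED_PIXEL_NM
    if not lo <= image.pixel_nm <= hi:
        raise ValueError(f"pixel_nm {image.pixel_nm} outside supported range [{lo}, {hi}]")
    if h == STANDARD_SIZE:
        return EMImage(image.pixels.copy(), image.pixel_nm, image.source_id)
    out = resize(
        image.pixels.astype(np.float64),
        (STANDARD_SIZE, STANDARD_SIZE),
        order=1,
        anti_aliasing=h > STANDARD_SIZE,
        preserve_range=True,
    )
    new_pixel_nm = image.pixel_nm * h / STANDARD_SIZE
    return EMImage(np.clip(np.rint(out), 0, 255).astype(np.uint8), new_pixel_nm, image.source_id)


def recast_mask_nearest(mask: SegMask, size: int = STANDARD_SIZE) -> SegMask:
    """Nearest-neighbor mask resampling: never enlarges the label set."""
    h, w = mask.shape
    if h == size and w == size:
        return SegMask(mask.labels.copy(), mask.pixel_nm, mask.scheme)
    rows = (np.arange(size) + 0.5) * h / size
    cols = (np.arange(size) + 0.5) * w / size
    ri = np.clip(rows.astype(int), 0, h - 1)
    ci = np.clip(cols.astype(int), 0, w - 1)
    out = mask.labels[np.ix_(ri, ci)]
    return SegMask(out, mask.pixel_nm * h / size, mask.scheme)


def load_config(path: str | Path) -> dict:
    """Load a key-value YAML config (pixel pitch, slice thickness, palette...)."""
    import yaml

    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: expected a mapping of keys to values")
    return cfg


def read_sample_meta(path: str | Path) -> list[SampleMeta]:
    """Read per-subject metadata from CSV.

    Expected columns: ``subject_id, diagnosis, clinical_index, image_ids``
    where ``image_ids`` is a ``;``-separated list (may be empty).
    """
    df = pd.read_csv(path, dtype={"subject_id": str})
    metas = []
    for _, row in df.iterrows():
        ids = []
        if "image_ids" in df.columns and isinstance(row.get("image_ids"), str):
            ids = [s for s in row["image_ids"].split(";") if s]
        metas.append(
            SampleMeta(
                subject_id=str(row["subject_id"]),
                diagnosis=str(row["diagnosis"]),
                clinical_index=float(row["clinical_index"]),
                image_ids=ids,
            )
        )
    return metas


def write_sample_meta(metas: list[SampleMeta], path: str | Path) -> None:
    pd.DataFrame(
        {
            "subject_id": [m.subject_id for m in metas],
            "diagnosis": [m.diagnosis for m in metas],
            "clinical_index": [m.clinical_index for m in metas],
            "image_ids": [";".join(m.image_ids) for m in metas],
        }
    ).to_csv(path, index=False)
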