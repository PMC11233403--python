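"""Per-region pixel counts, pixel fractions, and sampled areas/volumes.

Combining the Locations mask (cell regions) with the Granules mask (granule
pixels) yields, for each region R, the total pixel count N_R, the granule
pixel count n_R, and the pixel fraction

    pf_R = n_R / N_R .

Pixels the Locations mask leaves unclassified (label 0) are excluded from
every region and from the whole-cell denominator; the whole-cell fraction
pools labels 1–5.  Sampled volume per region is N_R × pixel_nm² × slice
thickness, converted to µm³.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_core import SegMask

#: Region labels (Locations scheme) and their names; label 0 is "unclassified".
REGION_NAMES = {1: "A band", 2: "I band", 3: "mito/Z", 4: "SR", 5: "near-SR"}
WHOLE = "whole"

DEFAULT_SLICE_THICKNESS_NM = 60.0  # ultrathin sections are cut at 50-70 nm


@dataclass
class RegionQuant:
    """Per-region granule pixel statistics for one image.

    ``pf[region]`` is NaN when the region has no pixels (N_R = 0); the
    whole-cell entry is NaN when every pixel is unclassified.
    """

    N: dict[str, int]
    n: dict[str, int]
    pf: dict[str, float]
    image_id: str = ""
    pixel_nm: float = 0.8
    slice_thickness_nm: float = DEFAULT_SLICE_THICKNESS_NM

    def area_um2(self, region: str) -> float:
        return self.N[region] * self.pixel_nm**2 * 1e-6

    def volume_um3(self, region: str) -> float:
        if self.slice_thickness_nm is None or not self.slice_thickness_nm > 0:
            raise ValueError("slice_thickness_nm must be set and positive")
        return self.N[region] * self.pixel_nm**2 * self.slice_thickness_nm * 1e-9

    def to_frame(self, subject: str = "") -> pd.DataFrame:
        rows = []
        for region in list(REGION_NAMES.values()) + [WHOLE]:
            rows.append(
                {
                    "image_id": self.image_id,
                    "subject": subject,
                    "region": region,
                    "N_R": self.N[region],
                    "n_R": self.n[region],
                    "pf_R": self.pf[region],
                    "area_um2": self.area_um2(region),
                    "volume_um3": self.volume_um3(region),
                }
            )
        return pd.DataFrame(rows)


def pixel_fraction(
    locations: SegMask,
    granules: SegMask,
    slice_thickness_nm: float = DEFAULT_SLICE_THICKNESS_NM,
    image_id: str = "",
) -> RegionQuant:
    """Count granule pixels per cell region and form pixel fractions.

    A granule pixel is attributed to the region of its own Locations label, so
    granules straddling a region boundary are split between regions.  Granule
    pixels falling on unclassified (label 0) pixels are not counted anywhere.
    """
    if locations.shape != granules.shape:
        raise ValueError(f"shape mismatch: locations {locations.shape} vs granules {granules.shape}")
    if locations.scheme != "locations" or granules.scheme != "granules":
        raise ValueError("expected (locations, granules) masks in that order")
    if locations.pixel_nm != granules.pixel_nm:
        raise ValueError("masks must share pixel_nm")

    loc = locations.labels.ravel()
    gran = granules.labels.ravel().astype(bool)
    N_by_label = np.bincount(loc, minlength=6)
    n_by_label = np.bincount(loc, weights=gran, minlength=6).astype(np.int64)

    N = {name: int(N_by_label[lab]) for lab, name in REGION_NAMES.items()}
    n = {name: int(n_by_label[lab]) for lab, name in REGION_NAMES.items()}
    N[WHOLE] = int(N_by_label[1:6].sum())
    n[WHOLE] = int(n_by_label[1:6].sum())
    pf = {r: (n[r] / N[r]) if N[r] > 0 else math.nan for r in N}

    return RegionQuant(
        N=N,
        n=n,
        pf=pf,
        image_id=image_id,
        pixel_nm=locations.pixel_nm,
        slice_thickness_nm=slice_thickness_nm,
    )


def region_volume(quant: RegionQuant) -> dict[str, float]:
    """Sampled tissue volume per region in µm³ (area × slice thickness)."""
    return {r: quant.volume_um3(r) for r in quant.N}


def aggregate_by_subject(
    quants: list[RegionQuant], image_to_subject: dict[str, str]
) -> pd.DataFrame:
    """Unweighted per-subject means of pf_R (and counts) over a subject's images.

    ``image_to_subject`` maps every image_id to exactly one subject; an image
    without a subject is an error.
    """
    rows = []
    for q in quants:
        if q.image_id not in image_to_subject:
            raise KeyError(f"image {q.image_id!r} has no subject in the metadata")
        subject = image_to_subject[q.image_id]
        for region in q.pf:
            rows.append({"subject": subject, "region": region, "pf_R": q.pf[region]})
    df = pd.DataFrame(rows)
    return df.groupby(["subject", "region"], as_index=False)["pf_R"].mean()
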