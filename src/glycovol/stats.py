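"""Hierarchical (cluster-corrected) group comparison and clinical correlation.

Image-level measurements (e.g. granule volume fraction vf) are clustered
within subjects: images from the same biopsy are correlated, so a naive
two-sample t-test over images is anticonservative.  The correction follows
the standard design-effect route: estimate the intraclass correlation
coefficient (ICC) from a one-way ANOVA over clusters, inflate the naive
standard error of the group difference by √(1 + (m̄ − 1)·ICC) with m̄ the
mean cluster size, and refer the corrected t statistic to a conservative
t distribution with (number of clusters − 2) degrees of freedom.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps


@dataclass
class ClusteredSample:
    """Image-level values with their subject (cluster) ids."""

    values: np.ndarray
    cluster_ids: np.ndarray
    group: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.cluster_ids = np.asarray(self.cluster_ids)
        if self.values.shape != self.cluster_ids.shape:
            raise ValueError("values and cluster_ids must align")

    @property
    def n_clusters(self) -> int:
        return len(np.unique(self.cluster_ids))


@dataclass
class HierarchicalResult:
    mean_a: float
    mean_b: float
    difference: float
    icc: float
    mean_cluster_size: float
    design_effect: float
    naive_se: float
    corrected_se: float
    t_statistic: float
    df: float
    p_value: float
    naive_p_value: float


def icc_oneway(sample: ClusteredSample) -> float:
    """One-way ANOVA intraclass correlation, floored at 0.

    ICC = (MSB − MSW) / (MSB + (m̄ − 1)·MSW) with m̄ the arithmetic mean
    cluster size.  Requires ≥ 2 clusters; returns NaN when total variance
    is zero (ICC undefined).
    """
    groups = [sample.values[sample.cluster_ids == c] for c in np.unique(sample.cluster_ids)]
    k = len(groups)
    if k < 2:
        raise ValueError("ICC requires at least 2 clusters")
    n_total = sum(len(g) for g in groups)
    if n_total < 2:
        raise ValueError("ICC requires at least 2 observations")
    if np.ptp(sample.values) == 0:
        return math.nan
    m_bar = n_total / k
    grand = sample.values.mean()
    ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    msb = ssb / (k - 1)
    msw = ssw / (n_total - k) if n_total > k else 0.0
    denom = msb + (m_bar - 1) * msw
    if denom == 0:
        return math.nan
    return max(0.0, (msb - msw) / denom)


def _pooled_icc(a: ClusteredSample, b: ClusteredSample) -> float:
    """ICC of within-group clustering: group-centered values, pooled ANOVA.

    Centering by the two group means removes one between-cluster degree of
    freedom per group, so the between mean square uses (k − 2) df.
    """
    groups = []
    for tag, s in (("A", a), ("B", b)):
        centered = s.values - s.values.mean()
        for c in np.unique(s.cluster_ids):
            groups.append(centered[s.cluster_ids == c])
    k = len(groups)
    if k <= 2:
        return math.nan
    n_total = sum(len(g) for g in groups)
    all_values = np.concatenate(groups)
    if np.ptp(all_values) == 0:
        return math.nan
    m_bar = n_total / k
    ssb = sum(len(g) * g.mean() ** 2 for g in groups)  # grand mean is 0 by centering
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    msb = ssb / (k - 2)
    msw = ssw / (n_total - k) if n_total > k else 0.0
    denom = msb + (m_bar - 1) * msw
    if denom == 0:
        return math.nan
    return max(0.0, (msb - msw) / denom)


def clustered_difference_test(a: ClusteredSample, b: ClusteredSample) -> HierarchicalResult:
    """Design-effect-corrected comparison of equal-weighted image means.

    With ICC = 0 or one image per cluster the design effect is 1 and the
    result coincides with the ordinary pooled two-sample t-test.
    """
    if len(a.values) == 0 or len(b.values) == 0:
        raise ValueError("both groups must be non-empty")
    na, nb = len(a.values), len(b.values)
    k = a.n_clusters + b.n_clusters
    m_bar = (na + nb) / k
    icc = _pooled_icc(a, b) if k > 2 else icc_oneway(ClusteredSample(
        np.concatenate([a.values, b.values]),
        np.concatenate([a.cluster_ids.astype(str), b.cluster_ids.astype(str)]),
    ))
    if math.isnan(icc):
        raise ValueError("degenerate (zero-variance) data: ICC undefined")

    diff = a.values.mean() - b.values.mean()
    sp2 = (
        ((a.values - a.values.mean()) ** 2).sum() + ((b.values - b.values.mean()) ** 2).sum()
    ) / (na + nb - 2)
    naive_se = math.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    if naive_se == 0:
        raise ValueError("degenerate variance: naive SE is zero")
    deff = 1.0 + (m_bar - 1.0) * icc
    corrected_se = naive_se * math.sqrt(deff)
    df = max(k - 2, 1)
    t = diff / corrected_se
    p = 2.0 * sps.t.sf(abs(t), df)
    naive_t = diff / naive_se
    naive_p = 2.0 * sps.t.sf(abs(naive_t), na + nb - 2)
    return HierarchicalResult(
        mean_a=float(a.values.mean()),
        mean_b=float(b.values.mean()),
        difference=float(diff),
        icc=float(icc),
        mean_cluster_size=float(m_bar),
        design_effect=float(deff),
        naive_se=float(naive_se),
        corrected_se=float(corrected_se),
        t_statistic=float(t),
        df=float(df),
        p_value=float(p),
        naive_p_value=float(naive_p),
    )


def index_correlation(values, clinical_index) -> tuple[float, float]:
    """Pearson correlation of image-level values with the subject clinical index.

    Images are equal-weighted: each image contributes one (value, index) pair,
    the index being that of the image's subject.
    """
    values = np.asarray(values, dtype=float)
    clinical_index = np.asarray(clinical_index, dtype=float)
    if values.shape != clinical_index.shape:
        raise ValueError("values and clinical_index must align")
    if len(values) < 3:
        raise ValueError("correlation requires n >= 3")
    if np.ptp(values) == 0 or np.ptp(clinical_index) == 0:
        raise ValueError("constant input: correlation undefined")
    r, p = sps.pearsonr(values, clinical_index)
    return float(r), float(p)
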