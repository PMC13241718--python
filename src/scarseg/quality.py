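"""Per-slice image-quality and heterogeneity metrics, and cluster-structure
analysis of a test cohort.

SNR and CNR are measured between scar and healthy myocardium (myocardium
minus scar); entropy, dynamic range, and the intensity coefficient of
variation are computed over the whole slice after min–max rescaling to
8-bit.  Cohort heterogeneity is summarized by k-means clustering of the
standardized quality vectors with silhouette-based selection of k, and a
rank-sum comparison of any per-slice metric between the two clusters.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .core import SliceRecord, ValidationError

__all__ = ["QualityVector", "quality_metrics", "cluster_quality", "compare_groups"]


@dataclass
class QualityVector:
    snr: Optional[float]
    cnr: Optional[float]
    entropy_bits: float
    dynamic_range: float
    intensity_cov_pct: float
    scar_pixels: int

    def as_array(self) -> np.ndarray:
        vals = [self.snr, self.cnr, self.entropy_bits, self.dynamic_range,
                self.intensity_cov_pct, self.scar_pixels]
        return np.array([np.nan if v is None else float(v) for v in vals])


def _to_8bit(img: np.ndarray) -> np.ndarray:
    lo, hi = float(img.min()), float(img.max())
    if hi == lo:
        return np.zeros(img.shape, dtype=np.uint8)
    return np.round((img - lo) / (hi - lo) * 255.0).astype(np.uint8)


def quality_metrics(rec: SliceRecord, snr_numerator: str = "scar") -> QualityVector:
    """Quality vector for one slice.

    SNR = mean(signal) / SD(healthy myocardium); the signal region is scar
    by default (``snr_numerator="myo"`` uses healthy myocardium instead —
    both conventions occur in the literature).  CNR = |mean(scar) −
    mean(healthy myo)| / SD(healthy myo).  Entropy is Shannon entropy
    (base 2) of the 256-bin histogram of the 8-bit image.
    """
    img = np.asarray(rec.image, dtype=float)
    img8 = _to_8bit(img)
    hist = np.bincount(img8.ravel(), minlength=256).astype(float)
    probs = hist / hist.sum()
    nz = probs > 0
    entropy = float(-(probs[nz] * np.log2(probs[nz])).sum())
    dyn = float(int(img8.max()) - int(img8.min()))
    mean = float(img.mean())
    cov = 100.0 * float(img.std()) / mean if mean != 0 else 0.0

    snr = cnr = None
    scar_px = 0
    if rec.scar_mask is not None:
        scar_px = int(rec.scar_mask.sum())
    if rec.myo_mask is not None and rec.scar_mask is not None:
        healthy = rec.myo_mask & ~rec.scar_mask
        if healthy.any() and rec.scar_mask.any():
            sd_h = float(img[healthy].std())
            if sd_h > 0:
                mu_scar = float(img[rec.scar_mask].mean())
                mu_h = float(img[healthy].mean())
                num = mu_scar if snr_numerator == "scar" else mu_h
                snr = num / sd_h
                cnr = abs(mu_scar - mu_h) / sd_h
    return QualityVector(snr, cnr, entropy, dyn, cov, scar_px)


def cluster_quality(
    vectors: Sequence[QualityVector],
    k_candidates: Sequence[int] = (2, 3, 4),
    seed: int = 0,
    n_restarts: int = 20,
) -> Tuple[int, np.ndarray, Dict[int, float]]:
    """K-means over standardized quality vectors for each candidate k;
    returns (best k by mean silhouette, labels at best k, silhouette per k)."""
    if len(vectors) < 3:
        raise ValidationError("cluster_quality needs at least 3 slices")
    X = np.stack([v.as_array() for v in vectors])
    X = X[:, ~np.all(np.isnan(X), axis=0)]
    # impute the rare missing SNR/CNR with the column mean
    col_means = np.nanmean(X, axis=0)
    nan_r, nan_c = np.where(np.isnan(X))
    X[nan_r, nan_c] = col_means[nan_c]
    sd = X.std(axis=0)
    if np.all(sd == 0):
        raise ValidationError("all quality vectors identical; silhouette undefined")
    sd[sd == 0] = 1.0
    Xs = (X - X.mean(axis=0)) / sd

    scores: Dict[int, float] = {}
    labels_by_k: Dict[int, np.ndarray] = {}
    for k in k_candidates:
        if k < 2 or k >= len(vectors):
            continue
        km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
        labels = km.fit_predict(Xs)
        if len(np.unique(labels)) < 2:
            continue
        scores[k] = float(silhouette_score(Xs, labels))
        labels_by_k[k] = labels
    if not scores:
        raise ValidationError("no valid k produced a clustering")
    best_k = max(scores, key=scores.get)
    return best_k, labels_by_k[best_k], scores


def compare_groups(metric: Sequence[float], labels: Sequence[int]) -> Tuple[float, float]:
    """Two-sided Mann–Whitney rank-sum comparison of a per-slice metric
    between two clusters; returns (U statistic, p-value)."""
    metric = np.asarray(metric, dtype=float)
    labels = np.asarray(labels)
    groups = np.unique(labels)
    if groups.size != 2:
        raise ValidationError(f"compare_groups expects exactly 2 groups, got {groups.size}")
    a = metric[labels == groups[0]]
    b = metric[labels == groups[1]]
    if a.size == 0 or b.size == 0:
        raise ValidationError("both groups must be non-empty")
    u, p = stats.mannwhitneyu(a, b, alternative="two-sided")
    return float(u), float(p)
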