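"""Slice-quality metrics and silhouette-selected k-means clustering.

Generates a deliberately heterogeneous cohort (half low-noise, half
high-noise acquisitions), computes SNR/CNR/entropy/dynamic-range/CoV per
slice, clusters the standardized quality vectors, and compares scar
burden between clusters with a rank test.
"""

import numpy as np

from scarseg.phantom import PhantomSpec, generate_slice
from scarseg.quality import cluster_quality, compare_groups, quality_metrics

records = []
for i in range(30):
    noisy = i >= 15
    spec = PhantomSpec(
        grid_size=96, pixel_spacing_mm=1.5,
        noise_sd=25.0 if noisy else 4.0,
        bias_amplitude=0.15 if noisy else 0.02,
        scar_extent_deg=60 + 4 * (i % 15), seed=i,  # burden independent of quality group
    )
    records.append(generate_slice(spec))

vectors = [quality_metrics(r) for r in records]
print(f"SNR range: {min(v.snr for v in vectors):.1f} – {max(v.snr for v in vectors):.1f}")

best_k, labels, scores = cluster_quality(vectors, (2, 3, 4), seed=0)
print(f"silhouette per k: " + ", ".join(f"{k}: {v:.2f}" for k, v in scores.items()))
print(f"optimal k = {best_k}")

u, p = compare_groups([v.scar_pixels for v in vectors], labels)
print(f"scar burden across clusters: Mann-Whitney U = {u:.0f}, p = {p:.3f}")
# k=2 recovers the planted acquisition-quality split; a non-significant p
# means lesion size is not what separates the clusters.
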