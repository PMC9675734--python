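"""Histogram main-peak Gaussian fitting shared by the conductance and
rupture-force analyses."""

from __future__ import annotations

import numpy as np
from lmfit.models import GaussianModel


def gaussian_peak_fit(values, bins="fd"):
    """Histogram ``values`` and fit a Gaussian around the highest peak.

    Returns ``(center, width, counts, bin_edges)``.  The fit is local: it
    uses the contiguous bins around the main peak with counts above 20%
    of the peak (plus a 2-bin margin), so a secondary population or a
    skewed tail does not pull the center.  Degenerate histograms (single
    occupied bin, or identical values) fall back to the peak-bin center
    with the bin width as the width.
    """
    values = np.asarray(values, dtype=float).ravel()
    if values.size == 0:
        raise ValueError("no values to histogram")
    if np.ptp(values) == 0:
        return float(values[0]), 0.0, np.array([values.size]), np.array(
            [values[0] - 0.5, values[0] + 0.5]
        )
    counts, edges = np.histogram(values, bins=bins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    bin_width = edges[1] - edges[0]
    ipk = int(np.argmax(counts))
    thresh = 0.2 * counts[ipk]
    lo = ipk
    while lo > 0 and counts[lo - 1] >= thresh:
        lo -= 1
    hi = ipk
    while hi < counts.size - 1 and counts[hi + 1] >= thresh:
        hi += 1
    lo = max(0, lo - 2)
    hi = min(counts.size - 1, hi + 2)
    sel = slice(lo, hi + 1)
    x, y = centers[sel], counts[sel].astype(float)
    if np.count_nonzero(y) < 3:
        return float(centers[ipk]), float(bin_width), counts, edges
    model = GaussianModel()
    sigma0 = max(np.std(values[(values >= x[0]) & (values <= x[-1])]), bin_width / 2)
    params = model.make_params(
        amplitude=dict(value=float(y.max() * sigma0 * np.sqrt(2 * np.pi)), min=0),
        center=float(centers[ipk]),
        sigma=dict(value=float(sigma0), min=bin_width / 10),
    )
    try:
        res = model.fit(y, params, x=x)
        center = float(res.params["center"].value)
        width = float(res.params["sigma"].value)
    except Exception:
        return float(centers[ipk]), float(bin_width), counts, edges
    if not np.isfinite(center) or not np.isfinite(width):
        return float(centers[ipk]), float(bin_width), counts, edges
    return center, width, counts, edges
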