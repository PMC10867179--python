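"""Histogram-based global thresholding primitives.

Both rules operate on a 1-D histogram of counts with optional bin centers and
return the *value* (bin center) of the chosen cut bin.  The binarization
convention throughout the package is ``pixel > threshold``.

Otsu's rule maximizes the between-class variance of the two-class split;
the triangle rule picks the bin furthest from the chord joining the histogram
peak to the far end of its longer tail.  Ties are always broken toward the
lower intensity so that runs are deterministic.
"""

from __future__ import annotations

import numpy as np


def _check_hist(hist: np.ndarray) -> np.ndarray:
    hist = np.asarray(hist, dtype=np.float64)
    if hist.ndim != 1 or hist.size < 2:
        raise ValueError("histogram must be 1-D with at least 2 bins")
    if np.any(hist < 0):
        raise ValueError("histogram counts must be nonnegative")
    return hist


def otsu_threshold(hist: np.ndarray, bin_centers: np.ndarray | None = None) -> float:
    """Otsu threshold of a histogram.

    The returned value is the center of the last background bin; foreground is
    ``value > threshold``.  Raises ``ValueError`` on a histogram with fewer
    than two populated bins (constant input).
    """
    hist = _check_hist(hist)
    if bin_centers is None:
        bin_centers = np.arange(hist.size, dtype=np.float64)
    else:
        bin_centers = np.asarray(bin_centers, dtype=np.float64)
    if np.count_nonzero(hist) < 2:
        raise ValueError("degenerate histogram: fewer than 2 populated bins")

    # cumulative class weights/means for cuts after bin k (background 0..k)
    w0 = np.cumsum(hist)
    total = w0[-1]
    m = np.cumsum(hist * bin_centers)
    mu_total = m[-1]

    w0 = w0[:-1]
    m = m[:-1]
    w1 = total - w0
    valid = (w0 > 0) & (w1 > 0)
    sigma_b = np.full(hist.size - 1, -np.inf)
    mu0 = np.divide(m, w0, out=np.zeros_like(m), where=w0 > 0)
    mu1 = np.divide(mu_total - m, w1, out=np.zeros_like(m), where=w1 > 0)
    sigma_b[valid] = (w0 * w1)[valid] * (mu0 - mu1)[valid] ** 2
    k = int(np.argmax(sigma_b))  # argmax takes the first (lowest) maximizer
    return float(bin_centers[k])


def triangle_threshold(hist: np.ndarray, bin_centers: np.ndarray | None = None) -> float:
    """Triangle threshold of a histogram.

    A line is drawn from the histogram peak to the far end of the longer tail
    (the nonzero extremity farther from the peak); the threshold is the bin
    maximizing the perpendicular distance to that line, tie-broken to the
    lower intensity.
    """
    hist = _check_hist(hist)
    if bin_centers is None:
        bin_centers = np.arange(hist.size, dtype=np.float64)
    else:
        bin_centers = np.asarray(bin_centers, dtype=np.float64)
    nz = np.flatnonzero(hist)
    if nz.size < 2:
        raise ValueError("degenerate histogram: fewer than 2 populated bins")

    peak = int(np.argmax(hist))
    lo, hi = int(nz[0]), int(nz[-1])
    # pick the side with the longer run from peak to the tail end
    if (hi - peak) >= (peak - lo):
        end = hi
    else:
        end = lo
    if end == peak:
        raise ValueError("degenerate histogram: peak coincides with tail end")

    # perpendicular distance from (x, h[x]) to the line (peak, h[peak])-(end, h[end])
    x = np.arange(min(peak, end), max(peak, end) + 1)
    x1, y1 = float(peak), float(hist[peak])
    x2, y2 = float(end), float(hist[end])
    num = np.abs((y2 - y1) * x - (x2 - x1) * hist[x] + x2 * y1 - y2 * x1)
    den = float(np.hypot(y2 - y1, x2 - x1))
    dist = num / den
    k = int(x[np.argmax(dist)])  # first maximizer along x; x ascends, so lowest bin
    return float(bin_centers[k])


def histogram(image: np.ndarray, nbins: int = 256) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of an image with bin centers, for use with the rules above."""
    image = np.asarray(image)
    counts, edges = np.histogram(image.ravel(), bins=nbins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return counts.astype(np.float64), centers


def otsu_threshold_image(image: np.ndarray, nbins: int = 256) -> float:
    counts, centers = histogram(image, nbins)
    return otsu_threshold(counts, centers)


def triangle_threshold_image(image: np.ndarray, nbins: int = 256) -> float:
    counts, centers = histogram(image, nbins)
    return triangle_threshold(counts, centers)


def robust_floor(values: np.ndarray, k: float = 3.0) -> float:
    """Robust background ceiling: median + k * 1.4826 * MAD.

    Used as a lower bound on data-driven channel thresholds so that Otsu's
    rule, which assumes a bimodal histogram, cannot binarize pure background
    noise on a channel whose marker is absent from the ROI.
    """
    values = np.asarray(values, dtype=np.float64).ravel()
    med = float(np.median(values))
    mad = float(np.median(np.abs(values - med)))
    return med + k * 1.4826 * mad
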