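"""Pearson colocalization with Costes auto-thresholds and a flipped control.

``Rcoloc`` is the Pearson correlation over pixels where either channel
exceeds its automatically determined threshold (pixels sub-threshold in both
channels are excluded, the plugin convention).  The negative control mirrors
the second channel horizontally, destroying the spatial correspondence while
preserving its intensity histogram; for left-right symmetric content this
control is degenerate (documented caveat).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ColocResult",
    "pearson",
    "costes_thresholds",
    "pearson_above_threshold",
]


@dataclass
class ColocResult:
    r_full: float
    r_above_threshold: float
    thresholds: tuple[float, float]
    r_inverted_control: float
    n_pixels_used: int


def _masked(a: np.ndarray, mask: np.ndarray | None) -> np.ndarray:
    a = np.asarray(a, dtype=float)
    if mask is None:
        return a.ravel()
    return a[np.asarray(mask, dtype=bool)]


def pearson(a: np.ndarray, b: np.ndarray, mask: np.ndarray | None = None) -> float:
    """Sample Pearson correlation over in-mask pixels."""
    x = _masked(a, mask)
    y = _masked(b, mask)
    if x.size != y.size:
        raise ValueError("channel shapes disagree")
    if x.size < 2:
        raise ValueError("need at least 2 in-mask pixels")
    dx = x - x.mean()
    dy = y - y.mean()
    sx = np.sqrt((dx * dx).sum())
    sy = np.sqrt((dy * dy).sum())
    if sx == 0 or sy == 0:
        raise ValueError("zero variance in one of the channels")
    r = float((dx * dy).sum() / (sx * sy))
    return min(1.0, max(-1.0, r))


def costes_thresholds(
    a: np.ndarray,
    b: np.ndarray,
    mask: np.ndarray | None = None,
    max_candidates: int = 4096,
) -> tuple[float, float]:
    """Costes automatic threshold pair on the orthogonal regression line.

    The second channel is regressed on the first by total least squares
    (major axis of the joint covariance), giving ``b = m a + c``.  Candidate
    thresholds ``(T, m T + c)`` are scanned from the highest intensity of
    ``a`` downward; the returned pair is the highest ``T`` for which the
    Pearson correlation of the pixels *below* both thresholds is <= 0 (or
    undefined).  If the sub-threshold correlation stays positive all the way
    down (perfectly correlated data), the minimum intensity is returned and
    all pixels are retained.
    """
    x = _masked(a, mask)
    y = _masked(b, mask)
    if x.size < 2:
        raise ValueError("need at least 2 in-mask pixels")
    dx = x - x.mean()
    dy = y - y.mean()
    sxx = (dx * dx).sum()
    syy = (dy * dy).sum()
    sxy = (dx * dy).sum()
    if sxx == 0 or syy == 0:
        raise ValueError("orthogonal regression undefined for constant channel")
    # Major-axis (total least squares) slope; sign follows the covariance.
    term = syy - sxx
    m = (term + np.sqrt(term * term + 4.0 * sxy * sxy)) / (2.0 * sxy) if sxy != 0 else 0.0
    if sxy == 0:
        # Uncorrelated: fall back to the axis with larger variance.
        m = 0.0 if sxx >= syy else np.inf
    if not np.isfinite(m):
        raise ValueError("orthogonal regression undefined (vertical axis)")
    c = y.mean() - m * x.mean()

    cand = np.unique(x)[::-1]
    if cand.size > max_candidates:
        idx = np.linspace(0, cand.size - 1, max_candidates).astype(int)
        cand = cand[idx]

    t_final = float(cand[-1])
    for t in cand:
        tb = m * t + c
        below = (x < t) & (y < tb)
        n = int(below.sum())
        if n < 2:
            continue
        xb = x[below]
        yb = y[below]
        if xb.std() == 0 or yb.std() == 0:
            r_below = 0.0
        else:
            r_below = float(np.corrcoef(xb, yb)[0, 1])
        if r_below <= 0:
            t_final = float(t)
            break
    return t_final, float(m * t_final + c)


def pearson_above_threshold(
    a: np.ndarray,
    b: np.ndarray,
    mask: np.ndarray | None = None,
) -> ColocResult:
    """Pearson above Costes thresholds, plus the flipped-channel control.

    ``r_above_threshold`` uses pixels where *either* channel exceeds its
    threshold.  ``r_inverted_control`` repeats the entire procedure
    (thresholds included) after mirroring channel 2 along the horizontal
    (last) axis within the same mask.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    ta, tb = costes_thresholds(a, b, mask)
    sel = (a > ta) | (b > tb)
    if mask is not None:
        sel &= np.asarray(mask, dtype=bool)
    if sel.sum() < 2:
        raise ValueError("fewer than 2 supra-threshold pixels")
    r_above = pearson(a[sel], b[sel])
    r_full = pearson(a, b, mask)

    b_flip = b[..., ::-1]
    ta_i, tb_i = costes_thresholds(a, b_flip, mask)
    sel_i = (a > ta_i) | (b_flip > tb_i)
    if mask is not None:
        sel_i &= np.asarray(mask, dtype=bool)
    r_inv = pearson(a[sel_i], b_flip[sel_i]) if sel_i.sum() >= 2 else float("nan")

    return ColocResult(
        r_full=r_full,
        r_above_threshold=r_above,
        thresholds=(ta, tb),
        r_inverted_control=r_inv,
        n_pixels_used=int(sel.sum()),
    )
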